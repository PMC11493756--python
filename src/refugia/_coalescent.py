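"""Monte-Carlo structured-coalescent engine for expected joint-SFS branch lengths.

Simulates genealogies of n1 + n2 lineages sampled from two demes backward in
time through a sequence of epochs.  Within epoch e (ending at scaled time
``t_end[e]``) deme sizes interpolate exponentially between ``nu*_s`` (epoch
start, nearer the present) and ``nu*_e`` (epoch end); per-lineage backward
migration rates are M12/2 (deme 0 -> 1) and M21/2.  After the last epoch all
lineages merge into an ancestral deme of relative size 1.  Time is in units
of 2*N_ref generations; coalescence rate in deme i is C(k_i,2)/nu_i(t).

Time-varying rates are handled by thinning (rejection sampling against the
epoch's maximal coalescence rate).  Branch lengths are accrued per lineage
lifetime (a lineage's class (i pop-1, j pop-2 descendants) never changes
between merges, so accrual at merge time is O(1) per event); the expected
SFS entry is (theta/2) * out[i, j] / n_reps.

Two unbiased variance reductions apply once every lineage is in the
ancestral deme: interval lengths are replaced by their conditional
expectations (interval lengths and merge topology are independent in the
Kingman coalescent), and the last two merges are averaged analytically over
the three equiprobable pair choices at k = 3.

The kernel is numba-compiled; seeding numpy's legacy RNG inside the kernel
makes repeated calls bit-identical (common random numbers across likelihood
evaluations, which keeps the Monte-Carlo likelihood surface deterministic
for the optimizer).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sim_branch_lengths(n1, n2, t_end, nu1_s, nu1_e, nu2_s, nu2_e,
                       m12, m21, n_reps, seed):
    np.random.seed(seed)
    n_epochs = t_end.shape[0]
    n = n1 + n2
    out = np.zeros((n1 + 1, n2 + 1))
    d1 = np.empty(2 * n, np.int64)       # descendant counts per lineage slot
    d2 = np.empty(2 * n, np.int64)
    tb = np.empty(2 * n, np.float64)     # birth time per lineage slot
    memb = np.empty((2, n), np.int64)    # lineage slots by deme
    where = np.empty(2 * n, np.int64)    # deme of a slot
    posin = np.empty(2 * n, np.int64)    # position of a slot in its deme list

    for _rep in range(n_reps):
        nslot = n
        for i in range(n1):
            d1[i] = 1
            d2[i] = 0
            tb[i] = 0.0
            memb[0, i] = i
            where[i] = 0
            posin[i] = i
        for i in range(n1, n):
            d1[i] = 0
            d2[i] = 1
            tb[i] = 0.0
            memb[1, i - n1] = i
            where[i] = 1
            posin[i] = i - n1
        k0 = n1
        k1 = n2
        t = 0.0
        e = 0
        while k0 + k1 > 1:
            k = k0 + k1
            if e < n_epochs:
                t0 = 0.0 if e == 0 else t_end[e - 1]
                t1 = t_end[e]
                numin0 = min(nu1_s[e], nu1_e[e])
                numin1 = min(nu2_s[e], nu2_e[e])
                rc0max = 0.5 * k0 * (k0 - 1) / numin0
                rc1max = 0.5 * k1 * (k1 - 1) / numin1
                rm0 = 0.5 * k0 * m12[e]
                rm1 = 0.5 * k1 * m21[e]
                R = rc0max + rc1max + rm0 + rm1
                if R <= 0.0:
                    t = t1
                    e += 1
                    continue
                dt = np.random.exponential(1.0 / R)
                if t + dt >= t1:
                    t = t1
                    e += 1
                    continue
                t += dt
                span = t1 - t0
                frac = (t - t0) / span if span > 0.0 else 1.0
                nu0t = nu1_s[e] * (nu1_e[e] / nu1_s[e]) ** frac
                nu1t = nu2_s[e] * (nu2_e[e] / nu2_s[e]) ** frac
                rc0 = 0.5 * k0 * (k0 - 1) / nu0t
                rc1 = 0.5 * k1 * (k1 - 1) / nu1t
                u = np.random.random() * R
                if u < rc0 or (u >= rc0max and u < rc0max + rc1):
                    dm = 0 if u < rc0 else 1
                    km = k0 if dm == 0 else k1
                    r1 = int(np.random.random() * km)
                    r2 = int(np.random.random() * (km - 1))
                    if r2 >= r1:
                        r2 += 1
                    s1 = memb[dm, r1]
                    s2 = memb[dm, r2]
                    out[d1[s1], d2[s1]] += t - tb[s1]
                    out[d1[s2], d2[s2]] += t - tb[s2]
                    # new lineage in slot nslot replaces s1; remove s2
                    d1[nslot] = d1[s1] + d1[s2]
                    d2[nslot] = d2[s1] + d2[s2]
                    tb[nslot] = t
                    where[nslot] = dm
                    memb[dm, r1] = nslot
                    posin[nslot] = r1
                    last = memb[dm, km - 1]
                    memb[dm, r2] = last
                    posin[last] = r2
                    if dm == 0:
                        k0 -= 1
                    else:
                        k1 -= 1
                    nslot += 1
                elif u >= rc0max + rc1max:
                    if u < rc0max + rc1max + rm0:
                        src, dst, ks = 0, 1, k0
                    else:
                        src, dst, ks = 1, 0, k1
                    r1 = int(np.random.random() * ks)
                    s = memb[src, r1]
                    last = memb[src, ks - 1]
                    memb[src, r1] = last
                    posin[last] = r1
                    kd = k1 if dst == 1 else k0
                    memb[dst, kd] = s
                    posin[s] = kd
                    where[s] = dst
                    if src == 0:
                        k0 -= 1
                        k1 += 1
                    else:
                        k1 -= 1
                        k0 += 1
                # else: thinning rejection, no event
            else:
                # ancestral panmictic deme of relative size 1; merge the
                # deme lists once on entry
                if k1 > 0:
                    for i in range(k1):
                        s = memb[1, i]
                        memb[0, k0 + i] = s
                        posin[s] = k0 + i
                        where[s] = 0
                    k0 += k1
                    k1 = 0
                    k = k0
                if k == 3:
                    # finish analytically: flush lifetimes, then average the
                    # k=3 -> k=2 merge over its three equiprobable pairs and
                    # add the deterministic expected k=2 accrual (length 1
                    # for each remaining branch), plus 1/3 per lineage for
                    # the expected k=3 interval.
                    third = 1.0 / 3.0
                    for i in range(3):
                        s = memb[0, i]
                        out[d1[s], d2[s]] += t - tb[s] + third
                    for a in range(3):
                        for b in range(a + 1, 3):
                            c = 3 - a - b
                            sa = memb[0, a]
                            sb = memb[0, b]
                            sc = memb[0, c]
                            out[d1[sa] + d1[sb], d2[sa] + d2[sb]] += third
                            out[d1[sc], d2[sc]] += third
                    break
                if k == 2:
                    s1 = memb[0, 0]
                    s2 = memb[0, 1]
                    out[d1[s1], d2[s1]] += t - tb[s1] + 1.0
                    out[d1[s2], d2[s2]] += t - tb[s2] + 1.0
                    break
                # expected interval (independent of merge choice)
                t += 1.0 / (0.5 * k * (k - 1))
                r1 = int(np.random.random() * k)
                r2 = int(np.random.random() * (k - 1))
                if r2 >= r1:
                    r2 += 1
                s1 = memb[0, r1]
                s2 = memb[0, r2]
                out[d1[s1], d2[s1]] += t - tb[s1]
                out[d1[s2], d2[s2]] += t - tb[s2]
                d1[nslot] = d1[s1] + d1[s2]
                d2[nslot] = d2[s1] + d2[s2]
                tb[nslot] = t
                where[nslot] = 0
                memb[0, r1] = nslot
                posin[nslot] = r1
                last = memb[0, k - 1]
                memb[0, r2] = last
                posin[last] = r2
                k0 -= 1
                nslot += 1
    return out / n_reps
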