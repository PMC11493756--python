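"""Windowed diversity and between-habitat effect sizes.

Per-population pi, Watterson theta and Tajima's D in non-overlapping 100-kb
windows (pool-corrected estimators), observed heterozygosity, and Welch
t-test / Hedges' g contrasts between invaded and refuge habitats.
"""

import sys

sys.path.insert(0, "analysis")
from common import default_config  # noqa: E402

from refugia.pipeline import run_all  # noqa: E402


def main():
    cfg = default_config()
    summary = run_all(cfg, stages=["simulate", "filter", "diversity"])
    dv = summary["diversity"]
    print(f"mean pi = {dv['mean_pi']:.4f}, mean thetaW = {dv['mean_theta_w']:.4f}, "
          f"mean Tajima's D = {dv['mean_tajima_d']:.3f}")
    print(f"heterozygosity Welch t = {dv['het_t']:.3f} (p = {dv['het_p']:.3f})")
    for stat, es in dv["effect_sizes"].items():
        print(f"Hedges' g[{stat}] = {es['hedges_g']:+.3f} "
              f"95% CI [{es['ci'][0]:+.3f}, {es['ci'][1]:+.3f}]")


if __name__ == "__main__":
    main()
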