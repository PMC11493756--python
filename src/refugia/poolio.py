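"""Pooled count data: sync format I/O, SNP filtering, pool-seq sample-size utilities.

Pool sequencing estimates population allele frequencies from read counts over
a pool of individuals.  The central container is :class:`PoolCounts`: per-site,
per-population reference/alternate read counts plus the haploid pool sizes.
Data arrive in the popoolation2 "sync" dialect (one line per site; per
population an ``A:T:C:G:N:del`` colon-separated count string).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NUCLEOTIDES = "ATCG"
_NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}


class SyncParseError(ValueError):
    """Raised on a malformed sync line; message carries the 1-based line number."""


@dataclass
class PoolCounts:
    """Biallelic read counts for L sites across J populations.

    ``ref_count``/``alt_count`` are (L, J) integer matrices.  Positions are
    1-based (mpileup convention) and strictly increasing within a scaffold.
    ``del_count`` tracks deletion reads per site/pool (never part of depth)
    so the indel filter can act on them.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_base: np.ndarray
    alt_base: np.ndarray
    ref_count: np.ndarray
    alt_count: np.ndarray
    pool_haploids: np.ndarray
    pop_ids: list
    multiallelic: np.ndarray = None
    del_count: np.ndarray = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_base = np.asarray(self.ref_base, dtype="U1")
        self.alt_base = np.asarray(self.alt_base, dtype="U1")
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        self.pool_haploids = np.asarray(self.pool_haploids, dtype=np.int64)
        if self.ref_count.shape != self.alt_count.shape:
            raise ValueError("ref_count and alt_count must share shape")
        if self.multiallelic is None:
            self.multiallelic = np.zeros(self.n_sites, dtype=bool)
        if self.del_count is None:
            self.del_count = np.zeros_like(self.ref_count)
        if np.any(self.pool_haploids <= 1):
            raise ValueError("pool_haploids must be > 1")
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ValueError("negative read counts")

    @property
    def n_sites(self) -> int:
        return self.ref_count.shape[0]

    @property
    def n_pops(self) -> int:
        return self.ref_count.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele read frequency; NaN where depth is zero."""
        d = self.depth.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, self.alt_count / d, np.nan)

    def take(self, idx) -> "PoolCounts":
        """Subset sites (positional index or boolean mask)."""
        idx = np.asarray(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_base=self.ref_base[idx],
            alt_base=self.alt_base[idx],
            ref_count=self.ref_count[idx],
            alt_count=self.alt_count[idx],
            multiallelic=self.multiallelic[idx],
            del_count=self.del_count[idx],
        )


@dataclass
class FilterSpec:
    """SNP retention rules applied jointly across populations.

    Defaults follow the standard pool-seq pipeline for this kind of study:
    minimum read count per allele of 2 (summed over pools, removes
    sequencing-error singletons), per-population depth in [5, 300], minor
    allele frequency >= 0.0125 (= 1/80, one chromosome in a pool of 80)
    computed on pooled read counts, and indel-carrying sites discarded.
    All thresholds are inclusive at their boundaries.
    """

    min_count: int = 2
    min_cov: int = 5
    max_cov: int = 300
    min_maf: float = 0.0125
    drop_indels: bool = True

    def __post_init__(self):
        if self.min_cov > self.max_cov:
            raise ValueError("min_cov must be <= max_cov")
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")


@dataclass
class FilterLog:
    """Per-rule removal tally from one filter_snps pass (rules applied in order)."""

    n_input: int = 0
    removed_indel: int = 0
    removed_multiallelic: int = 0
    removed_coverage: int = 0
    removed_min_count: int = 0
    removed_maf: int = 0
    n_retained: int = 0

    def to_tsv(self) -> str:
        rows = [("n_input", self.n_input),
                ("removed_indel", self.removed_indel),
                ("removed_multiallelic", self.removed_multiallelic),
                ("removed_coverage", self.removed_coverage),
                ("removed_min_count", self.removed_min_count),
                ("removed_maf", self.removed_maf),
                ("n_retained", self.n_retained)]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def read_sync(path, pool_haploids=80, pop_ids=None, min_count=2) -> PoolCounts:
    """Parse a popoolation2 sync file into biallelic :class:`PoolCounts`.

    The two most frequent nucleotides summed across pools define the
    reference/alternate pair; the file's reference-base column wins the
    "reference" label whenever it is one of the two.  Sites with a third
    nucleotide reaching ``min_count`` reads (summed over pools) are flagged
    multiallelic but retained (filtering is a separate pass).  N and deletion
    reads never count toward depth.
    """
    chroms, poss, refb, altb = [], [], [], []
    refc, altc, multi, delc = [], [], [], []
    n_pops = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split()
            if len(fields) < 4:
                raise SyncParseError(f"line {lineno}: expected >= 4 columns, got {len(fields)}")
            if n_pops is None:
                n_pops = len(fields) - 3
            elif len(fields) - 3 != n_pops:
                raise SyncParseError(f"line {lineno}: expected {n_pops} count columns, got {len(fields) - 3}")
            scaf, pos_s, refbase = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(f"line {lineno}: non-integer position {pos_s!r}") from None
            counts = np.zeros((n_pops, 6), dtype=np.int64)
            for j, tok in enumerate(fields[3:]):
                parts = tok.split(":")
                if len(parts) != 6:
                    raise SyncParseError(f"line {lineno}: count string {tok!r} does not have 6 fields")
                try:
                    counts[j] = [int(x) for x in parts]
                except ValueError:
                    raise SyncParseError(f"line {lineno}: non-integer count in {tok!r}") from None
            nuc_tot = counts[:, :4].sum(axis=0)
            # rank nucleotides: by total count desc, ties in A,T,C,G order
            order = sorted(range(4), key=lambda i: (-nuc_tot[i], i))
            top2 = order[:2]
            ref_i = _NUC_INDEX.get(refbase, None)
            if ref_i in top2:
                alt_i = top2[0] if top2[1] == ref_i else top2[1]
            else:
                ref_i, alt_i = top2[0], top2[1]
            if nuc_tot[alt_i] == 0:
                # monomorphic (or all-zero) site: deterministic alternate label
                alt_i = next(i for i in range(4) if i != ref_i)
            n_seg = int(np.sum(nuc_tot >= max(min_count, 1)))
            chroms.append(scaf)
            poss.append(pos)
            refb.append(NUCLEOTIDES[ref_i])
            altb.append(NUCLEOTIDES[alt_i])
            refc.append(counts[:, ref_i])
            altc.append(counts[:, alt_i])
            delc.append(counts[:, 5])
            multi.append(n_seg > 2)
    if n_pops is None:
        raise SyncParseError("empty sync file")
    if np.isscalar(pool_haploids):
        pool_haploids = np.full(n_pops, pool_haploids)
    if pop_ids is None:
        pop_ids = [f"pop{j + 1}" for j in range(n_pops)]
    return PoolCounts(
        chrom=np.array(chroms, dtype=object), pos=np.array(poss),
        ref_base=np.array(refb), alt_base=np.array(altb),
        ref_count=np.array(refc), alt_count=np.array(altc),
        pool_haploids=pool_haploids, pop_ids=list(pop_ids),
        multiallelic=np.array(multi), del_count=np.array(delc),
    )


def write_sync(pc: PoolCounts, path) -> None:
    """Write :class:`PoolCounts` in the sync dialect (A:T:C:G:N:del columns)."""
    with open(path, "w") as fh:
        for l in range(pc.n_sites):
            cols = [str(pc.chrom[l]), str(pc.pos[l]), pc.ref_base[l]]
            ri = _NUC_INDEX[pc.ref_base[l]]
            ai = _NUC_INDEX[pc.alt_base[l]]
            for j in range(pc.n_pops):
                c = [0, 0, 0, 0, 0, 0]
                c[ri] = int(pc.ref_count[l, j])
                c[ai] = int(pc.alt_count[l, j])
                c[5] = int(pc.del_count[l, j])
                cols.append(":".join(str(x) for x in c))
            fh.write("\t".join(cols) + "\n")


def filter_snps(pc: PoolCounts, spec: FilterSpec = None):
    """Apply the SNP retention rules; returns (filtered PoolCounts, FilterLog).

    Rules run in order (indels, multiallelic, per-population coverage,
    per-allele minimum count, pooled MAF); each removal is attributed to the
    first rule that fails.  Boundary values are retained (inclusive
    thresholds).  An empty result is allowed.
    """
    if spec is None:
        spec = FilterSpec()
    log = FilterLog(n_input=pc.n_sites)
    keep = np.ones(pc.n_sites, dtype=bool)

    if spec.drop_indels:
        bad = keep & (pc.del_count.sum(axis=1) > 0)
        log.removed_indel = int(bad.sum())
        keep &= ~bad

    if spec.min_count > 0:  # biallelic selection is moot without a count floor
        bad = keep & pc.multiallelic
        log.removed_multiallelic = int(bad.sum())
        keep &= ~bad

    depth = pc.depth
    cov_ok = np.all((depth >= spec.min_cov) & (depth <= spec.max_cov), axis=1)
    bad = keep & ~cov_ok
    log.removed_coverage = int(bad.sum())
    keep &= ~bad

    ref_tot = pc.ref_count.sum(axis=1)
    alt_tot = pc.alt_count.sum(axis=1)
    count_ok = (ref_tot >= spec.min_count) & (alt_tot >= spec.min_count)
    bad = keep & ~count_ok
    log.removed_min_count = int(bad.sum())
    keep &= ~bad

    tot = ref_tot + alt_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(tot > 0, alt_tot / np.maximum(tot, 1), 0.0)
    maf = np.minimum(f, 1.0 - f)
    bad = keep & (maf < spec.min_maf)
    log.removed_maf = int(bad.sum())
    keep &= ~bad

    log.n_retained = int(keep.sum())
    return pc.take(keep), log


def effective_sample_size(n_chr, depth):
    """Effective number of chromosomes represented by pooled reads.

    Reads resample the same pool of ``n_chr`` haploid genomes, so ``depth``
    reads carry less information than ``depth`` independent chromosomes:
    n_eff = (n_chr * depth - 1) / (n_chr + depth).  Monotone in both
    arguments and bounded by min(n_chr, depth) + 1.
    """
    n_chr = np.asarray(n_chr, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(n_chr <= 1):
        raise ValueError("n_chr must be > 1")
    if np.any(depth < 1):
        raise ValueError("depth must be >= 1 (undefined at depth 0)")
    return (n_chr * depth - 1.0) / (n_chr + depth)


def expected_coverage(read_length, n_reads, genome_length):
    """Expected fold coverage = read_length * n_reads / genome_length."""
    if read_length <= 0 or n_reads <= 0 or genome_length <= 0:
        raise ValueError("all arguments must be positive")
    return read_length * n_reads / genome_length
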