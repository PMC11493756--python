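import numpy as np
import pytest

from refugia import poolio, synthpool


@pytest.fixture(scope="session")
def neutral_scan_data():
    """Neutral (s = 0) metapopulation with the default two-cluster layout,
    pooled reads, and the standard SNP filters applied; shared by the scan
    calibration tests."""
    cfg = synthpool.SimConfig(n_loci=20_000, p_selected=0.0, seed=11)
    freqs, truth = synthpool.simulate_metapopulation(cfg)
    pc = synthpool.simulate_pool_reads(freqs, seed=12)
    pcf, _ = poolio.filter_snps(pc)
    return cfg, pcf


@pytest.fixture(scope="session")
def selected_scan_data():
    """Default study conditions (2% of loci under divergent selection,
    s = 0.1, covariable correlation 0.71) with filters applied, plus the row
    -> simulated-locus map; shared by the planted-outlier tests."""
    cfg = synthpool.SimConfig(seed=31)
    freqs, truth = synthpool.simulate_metapopulation(cfg)
    pc = synthpool.simulate_pool_reads(freqs, seed=32)
    pcf, _ = poolio.filter_snps(pc)
    locus_of_row = (pcf.pos // 100 - 1).astype(int)
    return cfg, truth, pcf, locus_of_row


def make_poolcounts(ref, alt, pool_haploids=80, spacing=100, **kw):
    """Small PoolCounts from explicit (L, J) count matrices."""
    ref = np.atleast_2d(np.asarray(ref))
    alt = np.atleast_2d(np.asarray(alt))
    L, J = ref.shape
    pairs = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]
    return poolio.PoolCounts(
        chrom=np.array(["scaf_1"] * L, dtype=object),
        pos=np.arange(1, L + 1) * spacing,
        ref_base=np.array([pairs[i % 6][0] for i in range(L)]),
        alt_base=np.array([pairs[i % 6][1] for i in range(L)]),
        ref_count=ref, alt_count=alt,
        pool_haploids=np.full(J, pool_haploids),
        pop_ids=[f"pop{j + 1}" for j in range(J)], **kw)
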