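"""Shared configuration for the numbered analysis drivers: one seed, one
output directory, study-scale defaults."""

from refugia.pipeline import RunConfig


def default_config(seed: int = 1, outdir: str = "results/pipeline") -> RunConfig:
    cfg = RunConfig()
    cfg.seed = seed
    cfg.outdir = outdir
    return cfg
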