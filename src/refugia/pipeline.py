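"""End-to-end orchestration: synthetic generation -> filtering -> scans ->
diversity -> structure -> demography, with one config, reproducible seeds,
stage caching and a summary report.

Stage outputs feed the next stage (scan outliers are excluded from the
F_ST matrix and the SFS).  Each stage is cached on a hash of its config
section plus the upstream hash, so rerunning with an identical config is a
no-op and editing, say, the demography block does not re-simulate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, diversity, genomescan, poolio, popstructure, synthpool

log = logging.getLogger("refugia")

_SECTIONS = ("simulate", "filter", "scan", "diversity", "structure", "demography")


@dataclass
class RunConfig:
    """All pipeline thresholds in one place; defaults are the study's
    (coverage 5-300, MAF 0.0125, XtX p < 0.001, FDR 0.01, 100 kb windows,
    1000 tree bootstraps / 100 block bootstraps, SFS mask <= 5, bottleneck
    age 12 generations, mu = 7.6e-9)."""

    seed: int = 1
    outdir: str = "results/pipeline"
    # spacing: distance between simulated sites on the synthetic genome (bp);
    # 16 bp gives an assayable-site density of 0.0625, which clears the
    # windowed-diversity minimum covered fraction of 0.05 after coverage
    # dropouts
    simulate: dict = field(default_factory=lambda: dict(spacing=16))
    filter: dict = field(default_factory=lambda: dict(
        min_count=2, min_cov=5, max_cov=300, min_maf=0.0125))
    scan: dict = field(default_factory=lambda: dict(
        xtx_p=0.001, fdr=0.01, omega_reg_q=0.001))
    diversity: dict = field(default_factory=lambda: dict(
        window_size=100_000, min_cov=20, min_cov_d=13, min_fraction=0.05))
    structure: dict = field(default_factory=lambda: dict(
        n_boot=1000, n_perm=9999))
    demography: dict = field(default_factory=lambda: dict(
        models=list(demography.DEFAULT_MODELS), n_reps=3000, mask_max=5,
        g_b=12, mu=7.6e-9, n1=12, n2=12, max_runs=4, nm_maxiter=200,
        polish_reps=12_000, n_scan=64))

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for k, v in raw.items():
            if isinstance(v, dict):
                merged = dict(getattr(base, k))
                extra = set(v) - set(merged) if merged else set()
                if k == "simulate":
                    extra = set(v) - {f.name for f in dataclasses.fields(synthpool.SimConfig)} - {"spacing"}
                if extra:
                    raise ValueError(f"unknown keys in section {k!r}: {sorted(extra)}")
                merged.update(v)
                setattr(base, k, merged)
            else:
                setattr(base, k, v)
        return base

    def section_hash(self, *sections) -> str:
        blob = json.dumps([self.seed] + [getattr(self, s) for s in sections],
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def config_hash(self) -> str:
        return self.section_hash(*_SECTIONS)


def _stamp(outdir: Path, stage: str) -> Path:
    return outdir / f".{stage}.hash"


def _cached(outdir: Path, stage: str, h: str) -> bool:
    p = _stamp(outdir, stage)
    return p.exists() and p.read_text().strip() == h


def run_all(config: RunConfig, force: bool = False, stages=None) -> dict:
    """Execute stages in dependency order; returns the machine-readable
    summary (also written as JSON + a markdown report).  A stage failure
    aborts with the stage named; completed stage outputs stay on disk.
    ``stages`` restricts execution (downstream stages then load their inputs
    from disk and refuse to run when those are missing)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(_SECTIONS if stages is None else stages)
    summary = {"config_hash": config.config_hash(), "seed": config.seed,
               "thresholds": {s: getattr(config, s) for s in _SECTIONS}}
    log.info("run config hash %s", summary["config_hash"])
    for s in _SECTIONS:
        log.info("thresholds[%s] = %s", s, getattr(config, s))

    # --- simulate -----------------------------------------------------
    h_sim = config.section_hash("simulate")
    sync_path = outdir / "synthetic.sync"
    covar_path = outdir / "covariates.tsv"
    truth_path = outdir / "truth_selected.tsv"
    sim_kwargs = dict(config.simulate)
    spacing = sim_kwargs.pop("spacing", 20)
    if "simulate" in stages and (force or not (_cached(outdir, "simulate", h_sim)
                                               and sync_path.exists())):
        log.info("stage simulate (seed %d)", config.seed)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = synthpool.SimConfig(**sim_kwargs)
        freqs, truth = synthpool.simulate_metapopulation(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        pc = synthpool.simulate_pool_reads(freqs, rng=rng, spacing=spacing)
        poolio.write_sync(pc, sync_path)
        synthpool.covariate_table(cfg).to_csv(covar_path, sep="\t", index=False)
        truth.selected_table().to_csv(truth_path, sep="\t", index=False)
        _stamp(outdir, "simulate").write_text(h_sim)
    elif "simulate" in stages:
        log.info("stage simulate: cached")
    if not sync_path.exists():
        raise RuntimeError("stage 'filter' requires the outputs of stage "
                           "'simulate'; rerun it first")
    covars = pd.read_csv(covar_path, sep="\t")
    truth_tab = pd.read_csv(truth_path, sep="\t")
    pc_raw = poolio.read_sync(sync_path)
    summary["simulate"] = {"n_sites": pc_raw.n_sites, "n_pops": pc_raw.n_pops,
                           "n_selected_true": int(len(truth_tab))}

    # --- filter ---------------------------------------------------------
    spec = poolio.FilterSpec(**config.filter)
    pc, flog = poolio.filter_snps(pc_raw, spec)
    (outdir / "filter_log.tsv").write_text(flog.to_tsv())
    summary["filter"] = dataclasses.asdict(flog)
    log.info("stage filter: %d -> %d SNPs", flog.n_input, flog.n_retained)
    # map retained rows back to simulated locus ids (position / spacing)
    locus_of_row = (pc.pos // spacing - 1).astype(int)

    # --- scans ----------------------------------------------------------
    goby = covars["goby"].to_numpy()
    calcium = covars["calcium_mgL"].to_numpy()
    ca_group = (calcium >= np.median(calcium)).astype(int)
    scan_path = outdir / "scan.tsv"
    outlier_path = outdir / "outliers.tsv"
    if "scan" in stages:
        omega = genomescan.estimate_omega(pc)
        xtx = genomescan.xtx_scan(pc, omega, p_threshold=config.scan["xtx_p"])
        c2 = genomescan.c2_scan(pc, omega, goby, fdr=config.scan["fdr"])
        oreg = genomescan.omega_regression(pc, omega, calcium,
                                           q_threshold=config.scan["omega_reg_q"])
        glm_ca = genomescan.quasibinomial_scan(pc, ca_group)
        glm_go = genomescan.quasibinomial_scan(pc, goby)
        for df in (glm_ca, glm_go):
            ok = df["p_raw"].notna().to_numpy()
            recal = genomescan.genomic_control(df.loc[ok, "p_raw"].to_numpy())
            df.loc[ok, "p_recal"] = recal.p_recal
            df.loc[ok, "q"] = genomescan.storey_qvalues(recal.p_recal)
            df.attrs["lambda_gc"] = recal.lam
        cands = genomescan.candidate_intersection(
            pc, {"calcium": oreg, "goby": c2},
            {"calcium": glm_ca, "goby": glm_go},
            {"calcium": ca_group, "goby": goby}, glm_fdr=config.scan["fdr"])
        scan_table = pd.concat([xtx, c2, oreg,
                                glm_ca.assign(covariable="calcium"),
                                glm_go.assign(covariable="goby")],
                               ignore_index=True)
        scan_table.to_csv(scan_path, sep="\t", index=False)
        outliers = set(xtx.loc[xtx["outlier"], "snp"].tolist())
        for cs in cands.values():
            outliers |= set(cs.snp_ids.tolist())
        pd.DataFrame({"snp": sorted(outliers)}).to_csv(outlier_path, sep="\t",
                                                       index=False)
        # recall/precision of the candidate sets against the planted truth
        truth_by_cov = {c: set(truth_tab.loc[truth_tab["covariable"] == c, "locus"])
                        for c in ("calcium", "goby")}
        perf = {}
        for c, cs in cands.items():
            hit_loci = set(locus_of_row[list(cs.snp_ids)].tolist())
            tp = len(hit_loci & truth_by_cov.get(c, set()))
            perf[c] = {"n_candidates": int(cs.snp_ids.size),
                       "recall": tp / max(len(truth_by_cov.get(c, set())), 1),
                       "precision": tp / max(len(hit_loci), 1)}
        summary["scan"] = {
            "n_xtx_outliers": int(xtx["outlier"].sum()),
            "lambda_gc_calcium": glm_ca.attrs["lambda_gc"],
            "lambda_gc_goby": glm_go.attrs["lambda_gc"],
            "candidates": {c: int(cs.snp_ids.size) for c, cs in cands.items()},
            "truth_performance": perf,
        }
        log.info("stage scan: %s", summary["scan"])
    else:
        outliers = set()
        if {"structure", "demography"} & stages:
            if not outlier_path.exists():
                raise RuntimeError("stage 'structure' requires the outputs of "
                                   "stage 'scan'; rerun it first")
            outliers = set(pd.read_csv(outlier_path, sep="\t")["snp"].tolist())
            summary["scan"] = {"loaded_from": str(outlier_path),
                               "candidates": None}

    if not {"diversity", "structure", "demography"} & stages:
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=float))
        return summary

    # --- diversity --------------------------------------------------------
    if "diversity" in stages:
        wins = diversity.window_stats(pc_raw, **config.diversity)
        wins.to_csv(outdir / "diversity_windows.tsv", sep="\t", index=False)
        het = diversity.observed_heterozygosity(pc_raw)
        eff = {}
        for stat in ("pi", "theta_w", "tajima_d"):
            per_pop = wins.groupby("pop")[stat].mean()
            vals = per_pop.reindex(covars["pop_id"]).to_numpy()
            ok = np.isfinite(vals)
            if ok.sum() >= 4 and len(np.unique(goby[ok])) == 2:
                es = diversity.compare_groups(vals[ok], goby[ok])
                eff[stat] = {"hedges_g": es.hedges_g,
                             "ci": [es.ci_low, es.ci_high],
                             "t": es.t, "p": es.p}
        es_het = diversity.compare_groups(
            het.reindex(covars["pop_id"]).to_numpy(), goby)
        summary["diversity"] = {
            "mean_pi": float(np.nanmean(wins["pi"])),
            "mean_theta_w": float(np.nanmean(wins["theta_w"])),
            "mean_tajima_d": float(np.nanmean(wins["tajima_d"])),
            "het_t": es_het.t, "het_p": es_het.p,
            "effect_sizes": eff,
        }
        log.info("stage diversity: pi=%.4g D=%.3f",
                 summary["diversity"]["mean_pi"],
                 summary["diversity"]["mean_tajima_d"])

    # --- structure ---------------------------------------------------------
    if "structure" in stages:
        neutral = np.array(sorted(set(range(pc.n_sites)) - outliers), dtype=int)
        fst = popstructure.pairwise_fst(pc, neutral)
        fst.to_csv(outdir / "fst.tsv", sep="\t")
        support = popstructure.bootstrap_support(
            pc, neutral, n_boot=config.structure["n_boot"],
            seed=config.seed + 7)
        Z, labels = popstructure.upgma(fst)
        (outdir / "upgma.nwk").write_text(
            popstructure.to_newick(Z, labels, support))
        pos_m = covars["river_position_m"].to_numpy()
        geo = np.abs(pos_m[:, None] - pos_m[None, :])
        gen = popstructure.ibd_transform(fst.to_numpy())
        np.fill_diagonal(geo, 0.0)
        logd = np.zeros_like(geo)
        iu = np.triu_indices(geo.shape[0], 1)
        logd[iu] = np.log(geo[iu])
        logd = logd + logd.T
        ibd = popstructure.mantel(logd, gen, n_perm=config.structure["n_perm"],
                                  seed=config.seed + 11)
        env = popstructure.env_distance(calcium, goby)
        ibe = popstructure.mantel(env, gen, n_perm=config.structure["n_perm"],
                                  seed=config.seed + 13)
        within = [fst.iloc[i, j] for i in range(pc.n_pops)
                  for j in range(i + 1, pc.n_pops) if goby[i] == goby[j]]
        summary["structure"] = {
            "fst_mean_within": float(np.mean(within)),
            "ibd": ibd, "ibe": ibe,
        }
        log.info("stage structure: IBD r2=%.3f p=%.4f", ibd["r2"], ibd["p"])

    # --- demography ----------------------------------------------------------
    if "demography" in stages:
        dcfg = config.demography
        pair = (int(np.flatnonzero(goby == 1)[0]),
                int(np.flatnonzero(goby == 0)[0]))
        obs = demography.build_sfs(pc, pair, n1=dcfg["n1"], n2=dcfg["n2"],
                                   exclude=outliers, mask_max=dcfg["mask_max"],
                                   seed=config.seed + 17)
        fits = []
        for mname in dcfg["models"]:
            fit = demography.fit_model(
                obs, mname, mu=dcfg["mu"], g_b=dcfg["g_b"],
                n_reps=dcfg["n_reps"], seed=config.seed + 19,
                max_runs=dcfg["max_runs"], nm_maxiter=dcfg.get("nm_maxiter"),
                polish_reps=dcfg.get("polish_reps"),
                n_scan=dcfg.get("n_scan", 64))
            fits.append(fit)
            log.info("stage demography: %s ll=%.1f converged=%s",
                     mname, fit.loglik, fit.converged)
        ranking = demography.compare_models(fits)
        ranking.to_csv(outdir / "model_ranking.tsv", sep="\t", index=False)
        best = fits[int(np.argmax([f.loglik for f in fits]))]
        summary["demography"] = {
            "pair": [pc.pop_ids[pair[0]], pc.pop_ids[pair[1]]],
            "ranking": ranking.to_dict(orient="records"),
            "best_model": best.model,
            "best_params": best.params,
            "two_nem": best.two_nem,
            "gene_flow_class": {k: demography.classify_gene_flow(v)
                                for k, v in best.two_nem.items()},
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    _write_report(outdir, summary)
    return summary


def _write_report(outdir: Path, summary: dict) -> None:
    lines = ["# Pipeline report", "",
             f"Config hash: `{summary['config_hash']}` (seed {summary['seed']})", ""]
    lines += ["## SNP filtering", "",
              f"{summary['filter']['n_input']} sites in, "
              f"{summary['filter']['n_retained']} biallelic SNPs retained.", ""]
    sc = summary.get("scan", {})
    if "n_xtx_outliers" in sc:
        lines += ["## Genome scans", "",
                  f"XtX outliers (p < 0.001): {sc['n_xtx_outliers']}",
                  f"Genomic inflation lambda (calcium / goby GLM): "
                  f"{sc['lambda_gc_calcium']:.3f} / {sc['lambda_gc_goby']:.3f}",
                  f"Candidates: {sc['candidates']}", ""]
    dv = summary.get("diversity")
    if dv:
        lines += ["## Diversity", "",
                  f"mean pi = {dv['mean_pi']:.4g}, "
                  f"mean thetaW = {dv['mean_theta_w']:.4g}, "
                  f"mean Tajima's D = {dv['mean_tajima_d']:.3f}", ""]
    st = summary.get("structure")
    if st:
        lines += ["## Structure", "",
                  f"IBD Mantel r2 = {st['ibd']['r2']:.3f} (p = {st['ibd']['p']:.4f}); "
                  f"IBE r2 = {st['ibe']['r2']:.3f} (p = {st['ibe']['p']:.4f})", ""]
    dm = summary.get("demography")
    if dm:
        lines += ["## Demography", "",
                  f"Pair {dm['pair']}: best model **{dm['best_model']}**; "
                  f"gene flow {dm['gene_flow_class']}", ""]
    (outdir / "report.md").write_text("\n".join(lines))
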