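"""End-to-end harnesses: the full screening pipeline, the null-calibration
study and the power/recovery study.

All harnesses are deterministic under a fixed seed: replicate r of a run
seeded with s uses ``np.random.default_rng([s, r])``, so replicates are
independent and reproducible in any order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import association, ld, levene, ranking, simulate
from .phenotype import prepare_trait

__all__ = ["PipelineConfig", "run_pipeline", "run_null_calibration", "run_power_study"]

log = logging.getLogger("vqscreen")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; every filter and window default is
    the screening design's named default and can be overridden."""

    architecture: simulate.ArchitectureSpec = field(
        default_factory=lambda: simulate.ArchitectureSpec(m_snps=500)
    )
    n_total: int = 2000
    cohort_sizes: list = field(default_factory=list)  # empty -> single cohort
    qc: levene.QCThresholds = field(default_factory=levene.QCThresholds)
    prune: ld.PruneSpec = field(default_factory=ld.PruneSpec)
    subsample_n: int | None = None  # fixed N per analysis (sample-size equalization)
    proximity_bp: int = 500_000
    null_rate: float = 0.05
    centile_cut: float = 95.0
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["architecture"]["maf_range"] = list(d["architecture"]["maf_range"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        arch = d.pop("architecture", {})
        if "maf_range" in arch:
            arch["maf_range"] = tuple(arch["maf_range"])
        return cls(
            architecture=simulate.ArchitectureSpec(**arch),
            qc=levene.QCThresholds(**d.pop("qc", {})),
            prune=ld.PruneSpec(**d.pop("prune", {})),
            **d,
        )


def _stage(name: str, rows_in: int, rows_out: int, extra: str = "") -> None:
    log.info("stage=%s rows_in=%d rows_out=%d %s", name, rows_in, rows_out, extra)


def _fmt_float(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "."
    return format(float(v), ".10g")


def run_pipeline(config: PipelineConfig, out_dir: str,
                 data: simulate.CohortData | None = None,
                 known_loci: pd.DataFrame | None = None) -> dict:
    """Simulate (or take supplied data) -> prepare -> per-cohort summaries ->
    QC -> meta Levene -> marginal & stratified scans -> LD prune -> rank
    table -> correlation/enrichment/rank-shift/OR reports.

    Writes every table to ``out_dir`` (byte-identical under a fixed seed)
    and returns the report bundle as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 0])

    if data is None:
        data = simulate.simulate_cohort(config.architecture, config.n_total)
    data.validate()
    if config.subsample_n is not None and config.subsample_n < data.n:
        idx = np.sort(rng.choice(data.n, size=config.subsample_n, replace=False))
        data = simulate.CohortData(data.genotypes[idx], data.snp_meta,
                                   data.phenotype[idx], data.exposure[idx],
                                   data.cohort_id)
    sizes = list(config.cohort_sizes) or [data.n]
    cohorts = simulate.split_cohorts(data, sizes, rng)
    _stage("simulate", data.m, data.m, f"n={data.n} cohorts={len(cohorts)}")

    # per-cohort preparation and genotype-group summaries
    summaries = []
    for c in cohorts:
        prep = prepare_trait(c.phenotype)
        summaries.append(levene.summarize_cohort(c.genotypes, prep, c.cohort_id, c.snp_meta))
    summary_df = pd.concat(summaries, ignore_index=True)
    levene.write_group_summaries(summary_df, out / "group_summaries.tsv")

    kept, exclusions = levene.qc_filter(summary_df, config.qc)
    exclusions.to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    _stage("qc", len(summary_df), len(kept), f"excluded={len(exclusions)}")
    assert len(kept) + len(exclusions) == len(summary_df)

    meta = levene.meta_levene_table(kept) if len(kept) else pd.DataFrame(
        columns=["snp_id", "N", "L", "df2", "p_v", "n_cohorts", "reason"])
    levene.write_meta_results(meta, out / "meta_levene.tsv")
    _stage("meta_levene", len(kept), int((meta["reason"] == "").sum()) if len(meta) else 0)

    # pooled-sample scans (marginal and exposure-stratified)
    pooled_prep = prepare_trait(data.phenotype)
    snp_ids = data.snp_meta["snp_id"]
    marg = association.marginal_scan(data.genotypes, pooled_prep.values, snp_ids)
    association.write_scan(marg, out / "marginal_scan.tsv")
    strat = association.stratified_interaction_scan(
        data.genotypes, pooled_prep.values, data.exposure, snp_ids)
    association.write_scan(strat, out / "interaction_scan.tsv")
    _stage("scan", data.m, int((marg["flag"] == "").sum()))

    kept_ids, prune_log = ld.prune_windowed(data.genotypes, data.snp_meta, config.prune)
    with open(out / "pruned_snps.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(kept_ids) + ("\n" if kept_ids else ""))
    prune_log.to_csv(out / "prune_removals.tsv", sep="\t", index=False,
                     float_format="%.10g")
    _stage("prune", data.m, len(kept_ids), f"removed={len(prune_log)}")
    assert len(kept_ids) + prune_log["snp_id"].nunique() == data.m

    p_v = meta.set_index("snp_id")["p_v"].reindex(snp_ids).to_numpy()
    table = ranking.build_rank_table(
        data.snp_meta, p_m=marg["p_m"].to_numpy(), p_v=p_v,
        p_int={"expo": strat["p_int"].to_numpy()},
        pruned_ids=kept_ids, known_loci=known_loci,
        proximity_bp=config.proximity_bp,
    )
    table.to_csv(out / "rank_table.tsv", sep="\t", index=False, float_format="%.10g")

    reports = _comparison_reports(table, config)
    with open(out / "reports.json", "w", encoding="utf-8") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True, default=float)
    return reports


def _comparison_reports(table: pd.DataFrame, config: PipelineConfig) -> dict:
    """The comparison statistics on a finished rank table."""
    pm = table["p_m"].to_numpy()
    pv = table["p_v"].to_numpy()
    reports: dict = {}

    ref = ranking.spearman_by_subset(table, np.ones(len(table), bool), "all")
    subsets = {
        "all": np.ones(len(table), bool),
        "pm_lt_0.05": pm < 0.05,
        "pm_lt_1e-4": pm < 1e-4,
        "known": table["known"].to_numpy(),
    }
    reports["spearman"] = {
        label: dataclasses.asdict(
            ranking.spearman_by_subset(table, mask, label,
                                       reference=None if label == "all" else ref))
        for label, mask in subsets.items()
    }

    pruned = table["pruned"].to_numpy()
    ok = pruned & np.isfinite(pm) & np.isfinite(pv)
    a = int(((pm < 0.05) & (pv < 0.05) & ok).sum())
    b = int(((pm >= 0.05) & (pv < 0.05) & ok).sum())
    c = int(((pm < 0.05) & (pv >= 0.05) & ok).sum())
    d = int(((pm >= 0.05) & (pv >= 0.05) & ok).sum())
    orr, ci, flag = ranking.odds_ratio_2x2(a, b, c, d)
    reports["or_pm_given_pv"] = {"or": orr, "ci": list(ci), "cells": [a, b, c, d],
                                 "flag": flag}

    if table["known"].any():
        known = table["known"].to_numpy() & np.isfinite(pv)
        rep = ranking.binomial_enrichment(int(known.sum()),
                                          int((pv[known] < 0.05).sum()),
                                          config.null_rate)
        reports["known_enrichment_pv"] = dataclasses.asdict(rep)

    reports["rank_shift"] = {}
    for split, tested in (("pct_m", "pct_v"), ("pct_v", "pct_m")):
        for band in ("100th", "99th"):
            for excl_label, excl in (("included", None),
                                     ("excluded", table["near_known"].to_numpy())):
                key = f"{split}_to_{tested}_{band}_{excl_label}"
                try:
                    reports["rank_shift"][key] = ranking.rank_shift_test(
                        table, split, tested, band, excl)
                except ValueError as err:
                    reports["rank_shift"][key] = {"error": str(err)}

    for label in [c[8:] for c in table.columns if c.startswith("pct_int_")]:
        pi = table[f"p_int_{label}"].to_numpy()
        ok_i = pruned & np.isfinite(pi) & np.isfinite(pv)
        ai = int(((pi < 0.05) & (pv < 0.05) & ok_i).sum())
        bi = int(((pi >= 0.05) & (pv < 0.05) & ok_i).sum())
        ci_ = int(((pi < 0.05) & (pv >= 0.05) & ok_i).sum())
        di = int(((pi >= 0.05) & (pv >= 0.05) & ok_i).sum())
        orr, ci2, flag = ranking.odds_ratio_2x2(ai, bi, ci_, di)
        reports[f"or_pint_given_pv_{label}"] = {
            "or": orr, "ci": list(ci2), "cells": [ai, bi, ci_, di], "flag": flag}
        if ok_i.any() and (pi[ok_i] < 0.05).sum():
            rep = ranking.binomial_enrichment(int((pi[ok_i] < 0.05).sum()),
                                              int(((pi < 0.05) & (pv < 0.05) & ok_i).sum()),
                                              config.null_rate)
            reports[f"pint_enrichment_pv_{label}"] = dataclasses.asdict(rep)
    return reports


def _replicate_pvalues(spec: simulate.ArchitectureSpec, n: int,
                       qc: levene.QCThresholds, rng) -> pd.DataFrame:
    """One replicate of the simulation pipeline: P_m, P_v, P_int per SNP
    for the SNPs that pass QC and have all three tests defined."""
    truth = simulate.sample_architecture(spec, rng)
    geno = simulate.simulate_genotypes(truth, n, rng)
    expo = simulate.simulate_exposure(n, spec.exposure_prevalence, rng)
    pheno = simulate.simulate_phenotype(geno, truth, expo, spec, rng)
    prep = prepare_trait(pheno)

    summaries = levene.summarize_cohort(geno, prep, "sim", truth)
    kept, _ = levene.qc_filter(summaries, qc)
    meta = levene.meta_levene_table(kept)
    meta = meta.loc[meta["reason"] == "", ["snp_id", "p_v"]]

    marg = association.marginal_scan(geno, prep.values, truth["snp_id"])
    strat = association.stratified_interaction_scan(geno, prep.values, expo,
                                                    truth["snp_id"])
    df = truth[["snp_id", "chrom", "pos", "beta", "delta"]].merge(meta, on="snp_id")
    df = df.merge(marg[["snp_id", "p_m"]], on="snp_id")
    df = df.merge(strat[["snp_id", "p_int"]], on="snp_id")
    return df.dropna(subset=["p_m", "p_v", "p_int"]).reset_index(drop=True)


def run_null_calibration(spec: simulate.ArchitectureSpec, n: int,
                         replicates: int, seed: int = 0,
                         qc: levene.QCThresholds | None = None,
                         band: str = "100th") -> dict:
    """Repeat the three comparison analyses on freshly simulated data.

    Per replicate: (i) pairwise Spearman correlation P among P_m/P_v/P_int,
    (ii) exact binomial enrichment P of P_v<0.05 among P_m<0.05 and among
    P_int<0.05, (iii) Mann-Whitney P for the top-centile rank shift (both
    directions), plus the fraction of P_v<0.05. Summaries report
    Kolmogorov-Smirnov uniformity statistics two-sided and one-sided
    ('greater' = excess of small P-values, i.e. inflation): the enrichment
    and Mann-Whitney P-values are discrete and conservative at small SNP
    counts, so the inflation-sided test is the calibrated check for them.
    """
    qc = qc or levene.QCThresholds()
    cols = ["spearman_m_v", "spearman_m_int", "spearman_v_int",
            "binom_pm", "binom_pint", "mw_m_to_v", "mw_v_to_m"]
    recs = []
    frac_num = frac_den = 0
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        df = _replicate_pvalues(spec, n, qc, rng)
        if len(df) < 30:
            raise ValueError("degenerate replicate: fewer than 30 usable SNPs")
        row = {}
        for key, (x, y) in {
            "spearman_m_v": ("p_m", "p_v"),
            "spearman_m_int": ("p_m", "p_int"),
            "spearman_v_int": ("p_v", "p_int"),
        }.items():
            row[key] = float(stats.spearmanr(df[x], df[y]).pvalue)
        for key, sel in (("binom_pm", "p_m"), ("binom_pint", "p_int")):
            elig = df[sel] < 0.05
            row[key] = ranking.binomial_enrichment(
                int(elig.sum()), int((df.loc[elig, "p_v"] < 0.05).sum())).p_binomial
        table = ranking.build_rank_table(df, p_m=df["p_m"], p_v=df["p_v"])
        row["mw_m_to_v"] = ranking.rank_shift_test(table, "pct_m", "pct_v", band)["p_mw"]
        row["mw_v_to_m"] = ranking.rank_shift_test(table, "pct_v", "pct_m", band)["p_mw"]
        recs.append(row)
        frac_num += int((df["p_v"] < 0.05).sum())
        frac_den += len(df)
    pvals = pd.DataFrame(recs, columns=cols)

    summary = {}
    for col in cols:
        x = pvals[col].to_numpy()
        summary[col] = {
            "ks_p_two_sided": float(stats.kstest(x, "uniform").pvalue),
            "ks_p_inflation": float(stats.kstest(x, "uniform",
                                                 alternative="greater").pvalue),
            "mean": float(np.mean(x)),
        }
    return {
        "pvalues": pvals,
        "summary": summary,
        "frac_pv_lt_05": frac_num / frac_den,
        "n_snp_tests": frac_den,
    }


def run_power_study(base_spec: simulate.ArchitectureSpec, n: int,
                    delta_grid, replicates: int = 20, seed: int = 0,
                    qc: levene.QCThresholds | None = None) -> pd.DataFrame:
    """Detection rates of the variance and interaction tests along a grid of
    interaction effect sizes, with the OR of P_int<0.05 given P_v<0.05.

    Every grid point re-simulates ``replicates`` datasets in which the
    designated interaction SNPs carry effect ``delta``; null SNPs in the
    same datasets provide the calibration reference.
    """
    qc = qc or levene.QCThresholds()
    rows = []
    for gi, delta in enumerate(delta_grid):
        # delta_scale=1 marks the designated interaction subset; the actual
        # effect is then pinned at exactly +/- delta (possibly 0 for the
        # calibration row) so the grid point is the effect size itself
        spec = base_spec.with_(delta_scale=1.0,
                               prop_interaction=base_spec.prop_interaction or 0.25)
        hits_v = hits_int = hits_both = n_delta = 0
        cells = np.zeros(4)
        for rep in range(replicates):
            rng = np.random.default_rng([seed, gi, rep])
            truth = simulate.sample_architecture(spec, rng)
            designated = truth["delta"].to_numpy() != 0
            truth = truth.assign(
                delta=np.where(designated, np.sign(truth["delta"]) * float(delta), 0.0),
                is_interaction=designated)
            geno = simulate.simulate_genotypes(truth, n, rng)
            expo = simulate.simulate_exposure(n, spec.exposure_prevalence, rng)
            pheno = simulate.simulate_phenotype(geno, truth, expo, spec, rng)
            prep = prepare_trait(pheno)
            kept, _ = levene.qc_filter(
                levene.summarize_cohort(geno, prep, "sim", truth), qc)
            meta = levene.meta_levene_table(kept)
            meta = meta.loc[meta["reason"] == ""]
            strat = association.stratified_interaction_scan(
                geno, prep.values, expo, truth["snp_id"])
            df = truth.merge(meta[["snp_id", "p_v"]], on="snp_id")
            df = df.merge(strat[["snp_id", "p_int"]], on="snp_id").dropna(
                subset=["p_v", "p_int"])
            dmask = df["is_interaction"].to_numpy()
            pv = df["p_v"].to_numpy() < 0.05
            pi = df["p_int"].to_numpy() < 0.05
            hits_v += int(pv[dmask].sum())
            hits_int += int(pi[dmask].sum())
            hits_both += int((pv & pi)[dmask].sum())
            n_delta += int(dmask.sum())
            cells += [int((pi & pv).sum()), int((~pi & pv).sum()),
                      int((pi & ~pv).sum()), int((~pi & ~pv).sum())]
        orr, ci, flag = ranking.odds_ratio_2x2(*cells)
        rows.append({
            "delta": float(delta),
            "n_interaction_snps": n_delta,
            "power_pv": hits_v / n_delta if n_delta else np.nan,
            "power_pint": hits_int / n_delta if n_delta else np.nan,
            "power_both": hits_both / n_delta if n_delta else np.nan,
            "or_pint_given_pv": orr, "or_ci_low": ci[0], "or_ci_high": ci[1],
            "or_flag": flag,
        })
    return pd.DataFrame(rows)
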