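"""Rank-based comparison machinery for prioritizing G-by-E candidates.

P-values from the marginal scan (P_m), the variance-heterogeneity scan
(P_v) and the stratified interaction scan (P_int) are placed on a common
percentile scale — ascending rank r of the P-value (average rank for ties,
1 = lowest P) mapped to percentile 100*(m - r + 1)/m, so the smallest P sits
at the 100th percentile. On top of that scale sit the subset Spearman
correlations with equality tests, exact binomial enrichment of known loci at
nominal significance, 2x2 odds ratios, Mann-Whitney centile-shift tests with
+/- 500 kb proximity exclusion, and average-rank enrichment across two
exposure-specific interaction scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentReport",
    "CorrelationReport",
    "percentile_ranks",
    "build_rank_table",
    "spearman_by_subset",
    "correlation_equality_test",
    "binomial_enrichment",
    "odds_ratio_2x2",
    "mannwhitney_u",
    "rank_shift_test",
    "exclude_proximal",
    "average_rank_enrichment",
]


@dataclass
class EnrichmentReport:
    n_eligible: int
    k_observed: int
    expected: float
    p_binomial: float
    null_rate: float = 0.05
    flag: str = ""


@dataclass
class CorrelationReport:
    label: str
    n: int
    rho: float
    p_value: float
    p_equality: float = np.nan  # vs the reference subset's rho
    flag: str = ""


def percentile_ranks(p_values) -> np.ndarray:
    """Percentile-scaled ranks: lowest P -> 100th percentile.

    Ascending average ranks r (ties share their mean rank) over the m finite
    P-values are mapped to 100*(m - r + 1)/m; non-finite entries get NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        raise ValueError("no finite P-values")
    m = ok.sum()
    r = stats.rankdata(p[ok], method="average")
    out[ok] = 100.0 * (m - r + 1.0) / m
    return out


def build_rank_table(snp_meta: pd.DataFrame, p_m=None, p_v=None,
                     p_int: dict | None = None, pruned_ids=None,
                     known_loci: pd.DataFrame | None = None,
                     proximity_bp: int = 500_000) -> pd.DataFrame:
    """Assemble the per-SNP table driving all prioritization statistics.

    ``p_int`` maps exposure labels to P-value vectors (one percentile column
    per exposure). Flags: ``pruned`` (in the LD-pruned set), ``known``
    (listed known locus) and ``near_known`` (within ``proximity_bp`` of one,
    known loci included).
    """
    table = snp_meta[["snp_id", "chrom", "pos"]].copy()
    if p_m is not None:
        table["p_m"] = np.asarray(p_m, dtype=float)
        table["pct_m"] = percentile_ranks(table["p_m"])
    if p_v is not None:
        table["p_v"] = np.asarray(p_v, dtype=float)
        table["pct_v"] = percentile_ranks(table["p_v"])
    for label, vals in (p_int or {}).items():
        table[f"p_int_{label}"] = np.asarray(vals, dtype=float)
        table[f"pct_int_{label}"] = percentile_ranks(table[f"p_int_{label}"])
    table["pruned"] = (
        table["snp_id"].isin(set(pruned_ids)) if pruned_ids is not None else True
    )
    if known_loci is not None and len(known_loci):
        known_set = set(known_loci["snp_id"])
        table["known"] = table["snp_id"].isin(known_set)
        table["near_known"] = exclude_proximal(table, known_loci, proximity_bp)
    else:
        table["known"] = False
        table["near_known"] = False
    return table


def spearman_by_subset(rank_table: pd.DataFrame, subset, label: str,
                       x: str = "p_m", y: str = "p_v",
                       reference: CorrelationReport | None = None) -> CorrelationReport:
    """Spearman rho between two P-value columns on a subset of pruned SNPs.

    ``subset`` is a boolean mask over the table (combined with the pruned
    flag). Two-sided P via the t approximation; if ``reference`` is given,
    also the Fisher-z equality test against its rho.
    """
    mask = np.asarray(subset, dtype=bool) & rank_table["pruned"].to_numpy()
    sub = rank_table.loc[mask, [x, y]].dropna()
    if len(sub) < 3:
        return CorrelationReport(label, len(sub), np.nan, np.nan, flag="TOO_FEW")
    rho, p = stats.spearmanr(sub[x], sub[y])
    rep = CorrelationReport(label, len(sub), float(rho), float(p))
    if reference is not None and not np.isnan(reference.rho):
        degenerate = (abs(rep.rho) >= 1.0 or abs(reference.rho) >= 1.0
                      or rep.n <= 3 or reference.n <= 3)
        if degenerate:
            rep.flag = "EQUALITY_UNDEFINED"
        else:
            rep.p_equality = correlation_equality_test(rep.rho, rep.n,
                                                       reference.rho, reference.n)
    return rep


def correlation_equality_test(rho1: float, n1: int, rho2: float, n2: int) -> float:
    """Fisher-z test for equality of two correlations (independent-samples
    form): z = (atanh r1 - atanh r2)/sqrt(1/(n1-3) + 1/(n2-3)), two-sided."""
    for rho, n in ((rho1, n1), (rho2, n2)):
        if abs(rho) >= 1.0:
            raise ValueError("|rho| must be < 1 for the Fisher transform")
        if n <= 3:
            raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def binomial_enrichment(n_eligible: int, k_observed: int, null_rate: float = 0.05,
                        alternative: str = "greater") -> EnrichmentReport:
    """Exact binomial enrichment of nominal significance among eligible SNPs.

    One-sided upper tail P(X >= k) under Binomial(n, null_rate) by default
    (``alternative="two-sided"`` is available behind the flag).
    """
    if not (0 <= k_observed <= n_eligible):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < null_rate < 1.0):
        raise ValueError("null_rate must be in (0, 1)")
    if alternative == "greater":
        p = float(stats.binom.sf(k_observed - 1, n_eligible, null_rate))
    elif alternative == "two-sided":
        p = float(stats.binomtest(k_observed, n_eligible, null_rate).pvalue)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentReport(n_eligible, k_observed, n_eligible * null_rate,
                            min(p, 1.0), null_rate)


def odds_ratio_2x2(a: float, b: float, c: float, d: float):
    """Cross-product odds ratio with Woolf 95% CI.

    Cells: a = both indicators, b = first only, c = second only, d = neither.
    A zero cell triggers the Haldane 0.5 correction (flagged); two zero
    cells on a diagonal leave the OR undefined.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be nonnegative")
    flag = ""
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return np.nan, (np.nan, np.nan), "UNDEFINED"
    if (cells == 0).any():
        cells = cells + 0.5
        flag = "HALDANE"
    a2, b2, c2, d2 = cells
    log_or = np.log(a2 * d2 / (b2 * c2))
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    lo, hi = np.exp(log_or - 1.959963985 * se), np.exp(log_or + 1.959963985 * se)
    return float(np.exp(log_or)), (float(lo), float(hi)), flag


def exclude_proximal(snp_table: pd.DataFrame, known_loci: pd.DataFrame,
                     window_bp: int = 500_000) -> np.ndarray:
    """Mask of SNPs on the same chromosome within +/- window_bp (inclusive)
    of any known-locus position; known loci themselves are masked too."""
    mask = np.zeros(len(snp_table), dtype=bool)
    if not len(known_loci):
        return mask
    chrom = snp_table["chrom"].astype(str).to_numpy()
    pos = snp_table["pos"].to_numpy()
    known_ids = set(known_loci["snp_id"]) if "snp_id" in known_loci else set()
    for _, row in known_loci.iterrows():
        if pd.isna(row.get("chrom")) or pd.isna(row.get("pos")):
            continue
        hit = (chrom == str(row["chrom"])) & (np.abs(pos - int(row["pos"])) <= window_bp)
        mask |= hit
    if known_ids:
        mask |= snp_table["snp_id"].isin(known_ids).to_numpy()
    return mask


def _band_masks(pct: np.ndarray, band: str):
    """Centile-band split. '100th' = percentile > 99 vs the rest;
    '99th' = (98, 99] vs (0, 98] (half-open on the left)."""
    if band in ("100th", "top1"):
        return pct > 99.0, pct <= 99.0
    if band == "99th":
        return (pct > 98.0) & (pct <= 99.0), pct <= 98.0
    raise ValueError(f"unknown centile band {band!r}")


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (the routine behind every rank-shift test):
    exact null distribution on small tie-free samples, otherwise the normal
    approximation with tie correction."""
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(u), float(p)


def rank_shift_test(rank_table: pd.DataFrame, split: str = "pct_m",
                    tested: str = "pct_v", band: str = "100th",
                    exclusion: np.ndarray | None = None) -> dict:
    """Mann-Whitney test for a shift in the tested P-type's percentile ranks
    between a centile band of the splitting P-type and the remaining SNPs.

    Operates on pruned SNPs; with ``exclusion`` (e.g. the near-known mask)
    percentiles are recomputed on the surviving set before splitting, so the
    band boundaries refer to the post-exclusion distribution. Small
    instances use the exact U distribution; larger ones the normal
    approximation with tie correction (scipy's default policy).
    """
    keep = rank_table["pruned"].to_numpy().copy()
    if exclusion is not None:
        keep &= ~np.asarray(exclusion, dtype=bool)
    sub = rank_table.loc[keep]
    split_p = "p" + split[3:]  # pct_m -> p_m
    tested_p = "p" + tested[3:]
    sub = sub.dropna(subset=[split_p, tested_p])
    pct_split = percentile_ranks(sub[split_p])
    pct_tested = percentile_ranks(sub[tested_p])
    top, rest = _band_masks(pct_split, band)
    if top.sum() == 0 or rest.sum() == 0:
        raise ValueError(f"empty centile band {band!r}")
    x, y = pct_tested[top], pct_tested[rest]
    u, p = mannwhitney_u(x, y)
    return {
        "band": band, "split": split, "tested": tested,
        "n_band": int(top.sum()), "n_rest": int(rest.sum()),
        "median_band": float(np.median(x)), "median_rest": float(np.median(y)),
        "U": float(u), "p_mw": float(p),
        "split_p_min_band": float(sub[split_p].to_numpy()[top].min()),
        "split_p_max_band": float(sub[split_p].to_numpy()[top].max()),
    }


def average_rank_enrichment(rank_table: pd.DataFrame, labels: tuple[str, str],
                            eligible, centile_cut: float = 95.0) -> EnrichmentReport:
    """Enrichment of high average interaction rank across two exposures.

    Per eligible SNP, the two exposure-specific P_int percentile ranks are
    averaged; success = average above ``centile_cut``; the exact binomial
    enrichment uses null rate (100 - cut)/100, the same nominal rate as a
    single-scan P < 0.05 cut-off.
    """
    cols = [f"pct_int_{lab}" for lab in labels]
    mask = np.asarray(eligible, dtype=bool)
    sub = rank_table.loc[mask, cols]
    complete = sub.notna().all(axis=1)
    flag = "" if complete.all() else f"DROPPED_{int((~complete).sum())}_INCOMPLETE"
    avg = sub.loc[complete].mean(axis=1)
    k = int((avg > centile_cut).sum())
    rep = binomial_enrichment(int(complete.sum()), k, (100.0 - centile_cut) / 100.0)
    rep.flag = flag
    return rep
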