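"""Marginal per-SNP regression, stratified scans and the between-strata
heterogeneity (interaction) test, plus ingestion of external GWAS summary
tables.

The marginal model is additive ordinary least squares of the prepared trait
on dosage; the interaction test compares the two stratum-specific slopes
with z = (b1 - b0)/sqrt(se1^2 + se0^2) (identical to 1-df Cochran's Q).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "marginal_scan",
    "stratified_interaction_scan",
    "heterogeneity_test",
    "read_summary_table",
    "write_scan",
    "DEFAULT_COLUMN_MAP",
]

P_FLOOR = 1e-300
MIN_N = 10


def marginal_scan(genotypes: np.ndarray, phenotype: np.ndarray,
                  snp_ids=None, min_n: int = MIN_N) -> pd.DataFrame:
    """Additive OLS of the prepared trait on dosage, one SNP at a time
    (vectorized across SNPs; per-SNP complete cases).

    Returns snp_id, beta, se, p_m (two-sided, t with n-2 df), n, flag.
    Monomorphic SNPs or n below ``min_n`` are flagged with NaN statistics.
    """
    g = np.asarray(genotypes, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    n, m = g.shape
    if len(y) != n:
        raise ValueError("phenotype length must match genotype rows")
    valid = ~np.isnan(g) & ~np.isnan(y)[:, None]
    g0 = np.where(valid, g, 0.0)
    y0 = np.where(np.isnan(y), 0.0, y)

    nn = valid.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        gbar = g0.sum(axis=0) / nn
        ybar = (y0[:, None] * valid).sum(axis=0) / nn
        sxx = (g0 * g0).sum(axis=0) - nn * gbar**2
        syy = ((y0 * y0) @ valid) - nn * ybar**2
        sxy = (y0 @ g0) - nn * gbar * ybar
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        sigma2 = rss / (nn - 2)
        se = np.sqrt(sigma2 / sxx)

    flag = np.full(m, "", dtype=object)
    flag[nn < min_n] = "LOW_N"
    flag[(flag == "") & (sxx <= 0)] = "MONOMORPHIC"
    ok = flag == ""

    p = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat[ok] = beta[ok] / se[ok]
    # identity fits (rss == 0) underflow to the floor rather than P = 0
    p[ok] = np.maximum(2.0 * stats.t.sf(np.abs(tstat[ok]), nn[ok] - 2), P_FLOOR)
    beta[~ok] = np.nan
    se[~ok] = np.nan
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(m)]
    return pd.DataFrame(
        {"snp_id": np.asarray(snp_ids), "beta": beta, "se": se, "p_m": p,
         "n": nn.astype(np.int64), "flag": flag}
    )


def heterogeneity_test(beta1, se1, beta2, se2):
    """Between-strata difference test: z = (b1-b2)/sqrt(se1^2+se2^2),
    two-sided normal P. Accepts scalars or arrays; SEs must be positive."""
    b1, s1 = np.asarray(beta1, float), np.asarray(se1, float)
    b2, s2 = np.asarray(beta2, float), np.asarray(se2, float)
    if np.any(s1[~np.isnan(s1)] <= 0) or np.any(s2[~np.isnan(s2)] <= 0):
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(s1**2 + s2**2)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)
    if np.ndim(beta1) == 0 and np.ndim(beta2) == 0:
        return float(z), float(p)
    return z, p


def stratified_interaction_scan(genotypes: np.ndarray, phenotype: np.ndarray,
                                exposure: np.ndarray, snp_ids=None,
                                min_n: int = MIN_N) -> pd.DataFrame:
    """Marginal scans within the exposed and unexposed strata and the
    heterogeneity test on the two slopes.

    Returns per SNP the stratum results (beta/se/n suffixed _exp and _unexp)
    plus het_z and p_int. SNPs flagged in either stratum (low n, empty
    stratum, monomorphic) carry no p_int.
    """
    e = np.asarray(exposure)
    if set(np.unique(e[~pd.isna(e)])) - {0, 1}:
        raise ValueError("exposure must be binary 0/1")
    e = e.astype(bool)
    res1 = marginal_scan(genotypes[e], np.asarray(phenotype)[e], snp_ids, min_n)
    res0 = marginal_scan(genotypes[~e], np.asarray(phenotype)[~e], snp_ids, min_n)
    out = pd.DataFrame(
        {
            "snp_id": res1["snp_id"],
            "beta_exp": res1["beta"], "se_exp": res1["se"], "n_exp": res1["n"],
            "beta_unexp": res0["beta"], "se_unexp": res0["se"], "n_unexp": res0["n"],
        }
    )
    ok = (res1["flag"] == "").to_numpy() & (res0["flag"] == "").to_numpy()
    z = np.full(len(out), np.nan)
    p = np.full(len(out), np.nan)
    if ok.any():
        z[ok], p[ok] = heterogeneity_test(
            out["beta_exp"].to_numpy()[ok], out["se_exp"].to_numpy()[ok],
            out["beta_unexp"].to_numpy()[ok], out["se_unexp"].to_numpy()[ok],
        )
    out["het_z"] = z
    out["p_int"] = p
    flag = np.where(res1["flag"] != "", "EXPOSED:" + res1["flag"].astype(str), "")
    flag = np.where((flag == "") & (res0["flag"] != ""),
                    "UNEXPOSED:" + res0["flag"].astype(str), flag)
    out["flag"] = flag
    return out


DEFAULT_COLUMN_MAP = {
    "snp_id": "MarkerName", "ea": "Allele1", "oa": "Allele2",
    "beta": "b", "se": "SE", "p": "p", "n": "N",
}


def read_summary_table(path: str, column_map: dict | None = None,
                       reference: pd.DataFrame | None = None):
    """Parse an external GWAS summary-statistic table.

    ``column_map`` maps standard names (snp_id, ea, oa, beta, se, p, n) to
    the file's column headers (defaults follow common consortium exports).
    Rows with unparseable beta/se/P are dropped and counted. With a
    ``reference`` allele table (snp_id, ea, oa), rows are harmonized to the
    reference effect allele: swapped alleles flip the beta sign; allele
    mismatches are dropped. Returns (table, log dict).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=None, engine="python")
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(f"summary file lacks mapped columns: {missing}")
    df = raw[[cmap[k] for k in cmap]].copy()
    df.columns = list(cmap)

    n_in = len(df)
    for col in ("beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["beta"].isna() | df["se"].isna() | df["p"].isna() | (df["se"] <= 0) \
        | (df["p"] <= 0) | (df["p"] > 1)
    df = df.loc[~bad].reset_index(drop=True)
    log = {"rows_in": n_in, "rows_dropped_malformed": int(bad.sum()),
           "rows_dropped_alleles": 0}

    for col in ("ea", "oa"):
        df[col] = df[col].astype(str).str.upper()
    if reference is not None:
        ref = reference.set_index("snp_id")
        keep = np.ones(len(df), dtype=bool)
        for k, row in df.iterrows():
            sid = row["snp_id"]
            if sid not in ref.index:
                keep[k] = False
                continue
            r = ref.loc[sid]
            if (row["ea"], row["oa"]) == (r["ea"], r["oa"]):
                continue
            if (row["ea"], row["oa"]) == (r["oa"], r["ea"]):
                df.loc[k, "beta"] = -row["beta"]
                df.loc[k, ["ea", "oa"]] = [r["ea"], r["oa"]]
            else:
                keep[k] = False
        log["rows_dropped_alleles"] = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
    log["rows_out"] = len(df)
    return df, log


def write_scan(result: pd.DataFrame, path: str) -> None:
    """Tab-delimited scan output ('.' for missing, 10 significant digits)."""
    def fmt(v):
        if isinstance(v, (int, np.integer)):
            return str(int(v))
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "."
        if isinstance(v, float):
            return format(v, ".10g")
        return str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(result.columns) + "\n")
        for row in result.itertuples(index=False):
            fh.write("\t".join(fmt(v) for v in row) + "\n")
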