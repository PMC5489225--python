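"""Variance-heterogeneity (Levene) scan from genotype-group summary statistics.

Cohorts contribute, per SNP, the per-genotype-group counts n_is, means
Zbar_is and sample variances var_is of the absolute deviations Z. These are
combined with the natural weights

    omega_is = n_is / n_i        (within-group, across studies)
    gamma_i  = n_i / N           (across genotype groups)

into the meta-analysis Levene statistic

    L = (N - 3)/2 * [ sum_i gamma_i * Zbar_i^2 - Zbar^2 ]
                  / [ sum_i gamma_i * sum_s omega_is (var_is + Zbar_is^2)
                      - sum_{i,s} (n_is - 1) var_is / N ... ]  (see below)

where Zbar_i = sum_s omega_is Zbar_is and Zbar = sum_i gamma_i Zbar_i.
Algebraically the numerator is SSB/N and the denominator SSW/N of the
classical one-way ANOVA on Z, so for a single cohort L reproduces the
classical mean-centred Levene statistic exactly; that equivalence is the
binding contract for the expansion used here (the per-study variance term
enters as (n_is - 1) * var_is / N, i.e. omega_is*var_is*gamma_i minus
var_is/N, which is the reading under which the identity holds).  P_v is the
upper tail of F(2, N-3) at L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import PreparedPhenotype, absolute_deviations

__all__ = [
    "GroupSummary",
    "MetaVarianceResult",
    "QCThresholds",
    "call_genotypes",
    "summarize_groups",
    "summarize_cohort",
    "hwe_test",
    "qc_filter",
    "harmonize_alleles",
    "meta_levene",
    "meta_levene_table",
    "levene_direct",
    "write_group_summaries",
    "read_group_summaries",
    "write_meta_results",
]

P_FLOOR = 1e-300

SUMMARY_COLUMNS = [
    "snp_id", "cohort", "ea", "oa", "eaf", "info", "callrate",
    "n0", "n1", "n2",
    "meanZ0", "meanZ1", "meanZ2",
    "varZ0", "varZ1", "varZ2",
]


@dataclass
class GroupSummary:
    """Per SNP x cohort genotype-group summaries of Z (the exchange unit)."""

    snp_id: str
    cohort: str
    ea: str
    oa: str
    eaf: float
    info: float
    callrate: float
    n: np.ndarray        # counts per genotype group 0/1/2
    mean_z: np.ndarray   # NaN where n == 0
    var_z: np.ndarray    # sample variance (n-1); NaN where n < 2


@dataclass
class MetaVarianceResult:
    snp_id: str
    L: float
    df1: int
    df2: float
    N: int
    p_v: float
    cohorts_used: list = field(default_factory=list)
    reason: str = ""
    weights: dict = field(default_factory=dict)  # omega (S x 3) and gamma (3,)


@dataclass(frozen=True)
class QCThresholds:
    """SNP x cohort retention filters (defaults follow common GWAS practice:
    imputation info >= 0.3, HWE P >= 1e-6, call rate >= 0.95, MAF >= 1%,
    and >= 30 observations in every genotype group per cohort)."""

    info_min: float = 0.3
    hwe_p_min: float = 1e-6
    callrate_min: float = 0.95
    maf_min: float = 0.01
    min_group_n: int = 30
    strict_three_groups: bool = True  # if False, an absent (n=0) group is tolerated

    @classmethod
    def most_permissive(cls) -> "QCThresholds":
        return cls(info_min=0.0, hwe_p_min=0.0, callrate_min=0.0,
                   maf_min=0.0, min_group_n=0, strict_three_groups=False)


def call_genotypes(dosage, threshold: float | None = None) -> np.ndarray:
    """Hard-call dosages to classes 0/1/2 (nearest integer); -1 = missing.

    With ``threshold`` t, a dosage farther than t from every integer is set
    missing rather than rounded.
    """
    d = np.asarray(dosage)
    if np.issubdtype(d.dtype, np.integer):  # hard calls already
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        return d.astype(np.int8, copy=True)
    d = d.astype(float)
    finite = ~np.isnan(d)
    if finite.any() and (np.min(d[finite]) < 0 or np.max(d[finite]) > 2):
        raise ValueError("dosages must lie in [0, 2]")
    calls = np.where(finite, np.rint(d), -1).astype(np.int8)
    if threshold is not None:
        too_far = finite & (np.abs(d - np.rint(d)) > threshold)
        calls[too_far] = -1
    return calls


def _group_stats(classes: np.ndarray, y: np.ndarray):
    """Vectorized per-SNP genotype-group stats of Z over a class matrix.

    classes: (n, m) int with -1 for missing; y: (n,) prepared trait (NaN ok).
    Returns counts/meanZ/varZ with shape (3, m) plus call rate and effect-
    allele (class-2 allele) frequency per SNP.
    """
    n, m = classes.shape
    y_ok = ~np.isnan(y)
    y0 = np.where(y_ok, y, 0.0)
    valid = (classes >= 0) & y_ok[:, None]

    # flat group index per cell: 3*snp + genotype, accumulated with bincount
    col = np.broadcast_to(np.arange(m, dtype=np.int64), (n, m))
    flat = np.where(valid, 3 * col + classes, 3 * m)  # sentinel bin for invalid
    flat = flat.ravel()
    nbins = 3 * m + 1
    w_valid = valid.ravel().astype(np.float64)
    counts = np.bincount(flat, weights=w_valid, minlength=nbins)[:-1]
    sums = np.bincount(flat, weights=(y0[:, None] * valid).ravel(),
                       minlength=nbins)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        means_y = sums / counts  # NaN where empty

    # Z matrix: |y - mean of own genotype group|, per SNP
    m_sel = np.nan_to_num(means_y)[np.where(valid, 3 * col + classes, 0)]
    z = np.where(valid, np.abs(y0[:, None] - m_sel), 0.0)
    s1 = np.bincount(flat, weights=z.ravel(), minlength=nbins)[:-1]
    s2 = np.bincount(flat, weights=(z * z).ravel(), minlength=nbins)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = s1 / counts
        var = (s2 - counts * mu * mu) / (counts - 1)
    mean_z = np.where(counts >= 1, mu, np.nan).reshape(m, 3).T
    var_z = np.where(counts >= 2, np.maximum(var, 0.0), np.nan).reshape(m, 3).T
    counts = counts.reshape(m, 3).T

    geno_ok = classes >= 0
    called = geno_ok.sum(axis=0)
    callrate = called / n
    dose = np.where(geno_ok, classes, 0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        eaf = dose.sum(axis=0) / (2.0 * called)
    return counts, mean_z, var_z, callrate, eaf


def summarize_cohort(
    genotypes: np.ndarray,
    prepared: PreparedPhenotype,
    cohort_id: str,
    snp_meta: pd.DataFrame,
    info=None,
    call_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-genotype-group summaries of Z for every SNP in one cohort.

    Returns the tab-delimited exchange table (one row per SNP) described in
    the module docs; ``info`` defaults to 1.0 (directly observed data).
    """
    if genotypes.shape[0] != len(prepared.values):
        raise ValueError("genotype rows must match phenotype length")
    classes = call_genotypes(genotypes, call_threshold)
    counts, mean_z, var_z, callrate, eaf = _group_stats(classes, prepared.values)
    m = genotypes.shape[1]
    info_col = np.full(m, 1.0) if info is None else np.asarray(info, dtype=float)
    return pd.DataFrame(
        {
            "snp_id": snp_meta["snp_id"].to_numpy(),
            "cohort": cohort_id,
            "ea": snp_meta["ea"].to_numpy(),
            "oa": snp_meta["oa"].to_numpy(),
            "eaf": eaf,
            "info": info_col,
            "callrate": callrate,
            "n0": counts[0].astype(np.int64),
            "n1": counts[1].astype(np.int64),
            "n2": counts[2].astype(np.int64),
            "meanZ0": mean_z[0], "meanZ1": mean_z[1], "meanZ2": mean_z[2],
            "varZ0": var_z[0], "varZ1": var_z[1], "varZ2": var_z[2],
        }
    )


def summarize_groups(
    dosage_col, prepared: PreparedPhenotype, cohort_id: str,
    snp_id: str = "snp", ea: str = "A", oa: str = "G",
) -> GroupSummary:
    """Single-SNP convenience wrapper around the cohort summarizer."""
    classes = call_genotypes(dosage_col)
    dev = absolute_deviations(prepared, np.where(classes < 0, np.nan, classes))
    n = np.zeros(3)
    mean_z = np.full(3, np.nan)
    var_z = np.full(3, np.nan)
    for g in (0, 1, 2):
        zg = dev.values[dev.group_assignment == g]
        zg = zg[~np.isnan(zg)]
        n[g] = len(zg)
        if len(zg) >= 1:
            mean_z[g] = zg.mean()
        if len(zg) >= 2:
            var_z[g] = zg.var(ddof=1)
    ok = classes >= 0
    eaf = float(classes[ok].sum() / (2 * ok.sum())) if ok.any() else np.nan
    return GroupSummary(snp_id, cohort_id, ea, oa, eaf, 1.0,
                        float(ok.mean()), n, mean_z, var_z)


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """1-df chi-square goodness-of-fit P against HWE expectations computed
    from the observed allele frequency. Monomorphic -> P = 1 by convention."""
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("empty genotype counts")
    f = (n1 + 2 * n2) / (2 * n)
    if f == 0.0 or f == 1.0:
        return 1.0
    exp = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    chi2 = float(np.sum((np.array([n0, n1, n2]) - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_test_vec(n0, n1, n2) -> np.ndarray:
    """Vectorized form of :func:`hwe_test`."""
    n0, n1, n2 = (np.asarray(a, float) for a in (n0, n1, n2))
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (n1 + 2 * n2) / (2 * n)
        exp = np.stack([n * (1 - f) ** 2, 2 * n * f * (1 - f), n * f**2])
        chi2 = np.nansum(np.where(exp > 0, (np.stack([n0, n1, n2]) - exp) ** 2 / exp, 0.0),
                         axis=0)
    p = stats.chi2.sf(chi2, df=1)
    return np.where((f <= 0) | (f >= 1) | (n < 1), 1.0, p)


def qc_filter(summaries: pd.DataFrame, thresholds: QCThresholds = QCThresholds()):
    """Apply the retention filters to a SNP x cohort summary table.

    Returns ``(kept, exclusions)``; exclusions carry one row per dropped
    SNP x cohort with a reason code (INFO, HWE, CALLRATE, MAF, MIN_GROUP_N).
    A pair is retained iff every filter passes.
    """
    df = summaries
    n0 = df["n0"].to_numpy(float)
    n1 = df["n1"].to_numpy(float)
    n2 = df["n2"].to_numpy(float)
    hwe_p = _hwe_test_vec(n0, n1, n2)
    maf = np.minimum(df["eaf"].to_numpy(float), 1 - df["eaf"].to_numpy(float))
    counts = np.stack([n0, n1, n2])
    if thresholds.strict_three_groups:
        group_ok = (counts >= thresholds.min_group_n).all(axis=0)
    else:
        group_ok = ((counts == 0) | (counts >= thresholds.min_group_n)).all(axis=0) & (
            counts.sum(axis=0) > 0
        )

    reasons = np.full(len(df), "", dtype=object)
    checks = [
        ("INFO", df["info"].to_numpy(float) < thresholds.info_min),
        ("HWE", hwe_p < thresholds.hwe_p_min),
        ("CALLRATE", df["callrate"].to_numpy(float) < thresholds.callrate_min),
        ("MAF", maf < thresholds.maf_min),
        ("MIN_GROUP_N", ~group_ok),
    ]
    for code, bad in checks:  # first failing filter names the exclusion
        hit = bad & (reasons == "")
        reasons[hit] = code
    keep = reasons == ""
    exclusions = df.loc[~keep, ["snp_id", "cohort"]].copy()
    exclusions["reason"] = reasons[~keep]
    return df.loc[keep].reset_index(drop=True), exclusions.reset_index(drop=True)


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def harmonize_alleles(summaries: pd.DataFrame, reference: pd.DataFrame,
                      freq_margin: float = 0.15):
    """Orient every cohort's rows to the reference effect allele.

    Swapped alleles flip the genotype-group order (n0<->n2 etc.) and the
    frequency; strand flips are complemented first. Strand-ambiguous A/T and
    C/G SNPs are resolved by allele frequency when both frequencies are at
    least ``freq_margin`` from 0.5, otherwise dropped and logged.
    """
    ref = reference.set_index("snp_id")
    rows, dropped = [], []
    for _, row in summaries.iterrows():
        sid = row["snp_id"]
        if sid not in ref.index:
            dropped.append((sid, row["cohort"], "NOT_IN_REFERENCE"))
            continue
        r = ref.loc[sid]
        ea, oa = row["ea"], row["oa"]
        ambiguous = (ea, oa) in _AMBIGUOUS
        if ambiguous:
            eaf, ref_eaf = row["eaf"], r.get("eaf", np.nan)
            if np.isnan(ref_eaf) or abs(eaf - 0.5) <= freq_margin or abs(ref_eaf - 0.5) <= freq_margin:
                dropped.append((sid, row["cohort"], "STRAND_AMBIGUOUS"))
                continue
            flip = (eaf > 0.5) != (ref_eaf > 0.5)
        else:
            if (ea, oa) == (r["ea"], r["oa"]):
                flip = False
            elif (ea, oa) == (r["oa"], r["ea"]):
                flip = True
            elif (_COMP.get(ea), _COMP.get(oa)) == (r["ea"], r["oa"]):
                flip = False
            elif (_COMP.get(ea), _COMP.get(oa)) == (r["oa"], r["ea"]):
                flip = True
            else:
                dropped.append((sid, row["cohort"], "ALLELE_MISMATCH"))
                continue
        row = row.copy()
        row["ea"], row["oa"] = r["ea"], r["oa"]
        if flip:
            row["eaf"] = 1.0 - row["eaf"]
            for a, b in (("n0", "n2"), ("meanZ0", "meanZ2"), ("varZ0", "varZ2")):
                row[a], row[b] = row[b], row[a]
        rows.append(row)
    kept = pd.DataFrame(rows).reset_index(drop=True) if rows else summaries.iloc[:0].copy()
    log = pd.DataFrame(dropped, columns=["snp_id", "cohort", "reason"])
    return kept, log


def _meta_levene_arrays(counts, mean_z, var_z):
    """Meta Levene over arrays shaped (S cohorts, 3 groups, m SNPs).

    NaN means/variances where undefined (count 0 / count < 2). Returns
    (L, df2, N, p_v, reason) vectors of length m.
    """
    counts = np.asarray(counts, dtype=np.float64)
    mz = np.nan_to_num(np.asarray(mean_z, dtype=np.float64))
    # variance enters as (n_is - 1) * var_is, so n_is = 1 contributes zero
    vz = np.nan_to_num(np.asarray(var_z, dtype=np.float64))

    n_i = counts.sum(axis=0)                     # (3, m)
    N = n_i.sum(axis=0)                          # (m,)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = n_i / N                          # (3, m)
        omega = counts / n_i                     # (S, 3, m)
    omega = np.nan_to_num(omega)
    gamma = np.nan_to_num(gamma)

    zbar_i = (omega * mz).sum(axis=0)            # (3, m)
    grand = (gamma * zbar_i).sum(axis=0)         # (m,)
    num = (gamma * zbar_i**2).sum(axis=0) - grand**2

    # denominator = SSW/N: the per-study variance term enters as
    # (n_is - 1) * var_is / N  (equivalently omega*var*gamma - var/N),
    # the reading under which a single cohort reproduces classical Levene
    with np.errstate(invalid="ignore", divide="ignore"):
        den = (
            ((counts - 1.0).clip(min=0.0) * vz + counts * mz**2).sum(axis=(0, 1)) / N
            - (gamma * zbar_i**2).sum(axis=0)
        )
    df2 = N - 3.0

    groups_present = (n_i > 0).sum(axis=0)
    reason = np.full(N.shape, "", dtype=object)
    reason[groups_present < 3] = "NO_3_GROUPS"
    reason[(reason == "") & (df2 < 1)] = "DF2_LT_1"
    ok = reason == ""

    L = np.full(N.shape, np.nan)
    p = np.full(N.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        L_ok = 0.5 * df2 * num / den
    zero_den = ok & (den <= 0)
    L[ok] = L_ok[ok]
    L[zero_den & (num <= 1e-300)] = 0.0
    L[zero_den & (num > 1e-300)] = np.inf
    p[ok] = stats.f.sf(L[ok], 2, df2[ok])
    p[ok] = np.maximum(p[ok], P_FLOOR)
    return L, df2, N.astype(np.int64), p, reason


def meta_levene(summaries: pd.DataFrame | list[GroupSummary]) -> MetaVarianceResult:
    """Combine one SNP's cohort summaries into the meta Levene statistic."""
    if isinstance(summaries, list):
        summaries = pd.DataFrame(
            [
                {
                    "snp_id": s.snp_id, "cohort": s.cohort,
                    "n0": s.n[0], "n1": s.n[1], "n2": s.n[2],
                    "meanZ0": s.mean_z[0], "meanZ1": s.mean_z[1], "meanZ2": s.mean_z[2],
                    "varZ0": s.var_z[0], "varZ1": s.var_z[1], "varZ2": s.var_z[2],
                }
                for s in summaries
            ]
        )
    sids = summaries["snp_id"].unique()
    if len(sids) != 1:
        raise ValueError("meta_levene expects summaries for exactly one SNP")
    counts = summaries[["n0", "n1", "n2"]].to_numpy(float)[:, :, None]
    mz = summaries[["meanZ0", "meanZ1", "meanZ2"]].to_numpy(float)[:, :, None]
    vz = summaries[["varZ0", "varZ1", "varZ2"]].to_numpy(float)[:, :, None]
    L, df2, N, p, reason = _meta_levene_arrays(counts, mz, vz)
    n_i = counts[:, :, 0].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.nan_to_num(counts[:, :, 0] / n_i)
        gamma = np.nan_to_num(n_i / n_i.sum())
    return MetaVarianceResult(
        snp_id=str(sids[0]), L=float(L[0]), df1=2, df2=float(df2[0]),
        N=int(N[0]), p_v=float(p[0]),
        cohorts_used=list(summaries["cohort"]), reason=str(reason[0]),
        weights={"omega": omega, "gamma": gamma},
    )


def meta_levene_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Meta Levene for every SNP in a (possibly multi-cohort) summary table.

    Returns snp_id, N, L, df2, p_v, n_cohorts, reason — NaN statistics where
    a SNP was skipped (fewer than 3 pooled genotype groups, or df2 < 1).
    """
    m_cols = ["n0", "n1", "n2", "meanZ0", "meanZ1", "meanZ2", "varZ0", "varZ1", "varZ2"]
    cohorts = list(pd.unique(summaries["cohort"]))
    snp_ids = pd.unique(summaries["snp_id"])
    order = {s: k for k, s in enumerate(snp_ids)}
    S, m = len(cohorts), len(snp_ids)
    counts = np.zeros((S, 3, m))
    mz = np.full((S, 3, m), np.nan)
    vz = np.full((S, 3, m), np.nan)
    n_cohorts = np.zeros(m, dtype=np.int64)
    for s_idx, (cohort, grp) in enumerate(summaries.groupby("cohort", sort=False)):
        cols = np.array([order[s] for s in grp["snp_id"]])
        vals = grp[m_cols].to_numpy(float)
        counts[s_idx, 0, cols], counts[s_idx, 1, cols], counts[s_idx, 2, cols] = vals[:, 0], vals[:, 1], vals[:, 2]
        mz[s_idx, 0, cols], mz[s_idx, 1, cols], mz[s_idx, 2, cols] = vals[:, 3], vals[:, 4], vals[:, 5]
        vz[s_idx, 0, cols], vz[s_idx, 1, cols], vz[s_idx, 2, cols] = vals[:, 6], vals[:, 7], vals[:, 8]
        n_cohorts[cols] += 1
    L, df2, N, p, reason = _meta_levene_arrays(counts, mz, vz)
    return pd.DataFrame(
        {"snp_id": snp_ids, "N": N, "L": L, "df2": df2, "p_v": p,
         "n_cohorts": n_cohorts, "reason": reason}
    )


def levene_direct(prepared: PreparedPhenotype, genotype_classes) -> tuple[float, float]:
    """Classical individual-level mean-centred Levene test (the oracle route).

    One-way ANOVA on Z across the non-empty genotype groups, delegated to
    scipy; returns (W, P) with P from F(k-1, N-k).
    """
    y = prepared.values
    g = np.asarray(genotype_classes, dtype=float)
    valid = ~np.isnan(y) & ~np.isnan(g) & (g >= 0)
    groups = [y[valid & (g == cls)] for cls in (0, 1, 2)]
    groups = [arr for arr in groups if len(arr) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty genotype groups")
    w, p = stats.levene(*groups, center="mean")
    return float(w), float(max(p, P_FLOOR))


# ---------------------------------------------------------------------------
# exchange formats

def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "."
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return format(float(v), ".10g")


def write_group_summaries(summaries: pd.DataFrame, path: str) -> None:
    """Bit-stable tab-delimited writer ('.' for undefined, 10 sig. digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in summaries[SUMMARY_COLUMNS].itertuples(index=False):
            cells = [
                str(row.snp_id), str(row.cohort), str(row.ea), str(row.oa),
                _fmt(row.eaf), _fmt(row.info), _fmt(row.callrate),
                str(int(row.n0)), str(int(row.n1)), str(int(row.n2)),
                _fmt(row.meanZ0), _fmt(row.meanZ1), _fmt(row.meanZ2),
                _fmt(row.varZ0), _fmt(row.varZ1), _fmt(row.varZ2),
            ]
            fh.write("\t".join(cells) + "\n")


def read_group_summaries(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=".", dtype={"snp_id": str, "cohort": str})
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary file lacks columns: {sorted(missing)}")
    counts = df[["n0", "n1", "n2"]].to_numpy(float)
    if (counts < 0).any():
        raise ValueError("negative genotype-group count")
    var = df[["varZ0", "varZ1", "varZ2"]].to_numpy(float)
    if np.nanmin(var, initial=0.0) < 0:
        raise ValueError("negative variance of Z")
    if np.any(~np.isnan(var) & (counts < 2)):
        raise ValueError("variance defined for a group with n < 2")
    return df


def write_meta_results(results: pd.DataFrame, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tN\tL\tdf2\tp_v\tn_cohorts\treason\n")
        for row in results.itertuples(index=False):
            fh.write(
                f"{row.snp_id}\t{int(row.N)}\t{_fmt(row.L)}\t{_fmt(row.df2)}\t"
                f"{_fmt(row.p_v)}\t{int(row.n_cohorts)}\t{row.reason}\n"
            )
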