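"""Multi-cohort synthetic genotype/phenotype/exposure generator.

Emulates the data-generating design used to validate variance-heterogeneity
screening: independent SNPs in Hardy-Weinberg equilibrium with GWAS-like
allele frequencies and effect sizes, a fixed binary exposure (30% prevalence
by default), optional gene-environment interaction effects, and a non-normal
(right-skewed) error so that the log10 + z-score transformed trait resembles
a transformed anthropometric trait such as BMI.

The phenotype is returned on a raw positive scale: the latent trait

    U_i = sum_j G_ij * beta_j  +  a * E_i  +  sum_j G_ij * delta_j * E_i  +  eps_i

is exponentiated (``raw = 10**U``) so that downstream preparation
(log10 -> z-score -> winsorize) recovers a standardized version of U.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ArchitectureSpec",
    "CohortData",
    "sample_architecture",
    "simulate_genotypes",
    "simulate_genotypes_ld",
    "simulate_exposure",
    "simulate_phenotype",
    "simulate_cohort",
    "split_cohorts",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Per-SNP genetic architecture and trait model for the generator.

    Parameters
    ----------
    m_snps:
        Number of independent SNPs.
    maf_range:
        Uniform sampling range for minor-allele frequencies, within (0, 0.5].
    prop_effect, beta_scale:
        Proportion of SNPs carrying a nonzero marginal effect and the SD of
        those effects (trait z-units per effect allele). The default emulates
        a GWAS-like architecture where most SNPs are effectively null.
    prop_interaction, delta_scale:
        Proportion of SNPs with a nonzero gene-environment effect delta and
        the SD of those effects. Default 0: the reference simulation design
        generates the trait from marginal effects only, with the exposure
        simulated but inert, so interaction tests run under their null.
    exposure_prevalence:
        Bernoulli probability of the binary exposure (default 0.30).
    exposure_main_effect:
        Additive main effect of the exposure on the latent trait (z-units).
    error_family:
        ``"lognormal"`` (shifted/scaled to mean 0, right-skewed; default) or
        ``"normal"``. ``error_sd`` scales the error; ``error_shape`` is the
        log-scale sigma of the lognormal (default 0.11, giving transformed
        trait skewness near 0.3, the mild residual skew typical of a
        log-transformed anthropometric trait).
    seed:
        Seed for the convenience generator :func:`simulate_cohort`.
    """

    m_snps: int
    maf_range: tuple[float, float] = (0.01, 0.5)
    prop_effect: float = 0.05
    beta_scale: float = 0.02
    prop_interaction: float = 0.0
    delta_scale: float = 0.0
    exposure_prevalence: float = 0.3
    exposure_main_effect: float = 0.0
    error_family: str = "lognormal"
    error_sd: float = 1.0
    error_shape: float = 0.11
    position_spacing: int = 10_000
    chromosome: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("prop_effect", "prop_interaction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.exposure_prevalence < 1.0):
            raise ValueError("exposure_prevalence must be in (0, 1)")
        if self.error_family not in ("lognormal", "normal", "none"):
            raise ValueError(f"unknown error_family {self.error_family!r}")

    def with_(self, **kwargs) -> "ArchitectureSpec":
        return replace(self, **kwargs)


@dataclass
class CohortData:
    """Individual-level data for one cohort.

    ``genotypes`` is an n_individuals x m_snps dosage matrix in [0, 2]
    (hard calls by construction, float dosages allowed); ``snp_meta`` carries
    one row per SNP (snp_id, chrom, pos, ea, oa, maf, beta, delta);
    ``phenotype`` is the raw positive trait; ``exposure`` is 0/1.
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    phenotype: np.ndarray
    exposure: np.ndarray
    cohort_id: str = "cohort1"

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        g = self.genotypes
        if np.nanmin(g) < 0 or np.nanmax(g) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if len(self.snp_meta) != self.m:
            raise ValueError("snp_meta rows must match genotype columns")
        if self.snp_meta["snp_id"].isna().any():
            raise ValueError("missing SNP ids")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing within chromosome")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_architecture(spec: ArchitectureSpec, rng=None) -> pd.DataFrame:
    """Draw the per-SNP truth table (MAF, beta_j, delta_j, coordinates).

    Exactly ``round(prop * m)`` SNPs (a random subset) carry nonzero effects;
    effect sizes are N(0, scale). Positions are laid out on one synthetic
    chromosome at fixed spacing so that window/proximity logic has
    coordinates to work with.
    """
    rng = _rng(spec.seed if rng is None else rng)
    m = spec.m_snps
    lo, hi = spec.maf_range
    maf = rng.uniform(lo, hi, size=m)

    beta = np.zeros(m)
    n_eff = int(round(spec.prop_effect * m))
    if n_eff and spec.beta_scale > 0:
        idx = rng.choice(m, size=n_eff, replace=False)
        beta[idx] = rng.normal(0.0, spec.beta_scale, size=n_eff)

    delta = np.zeros(m)
    n_int = int(round(spec.prop_interaction * m))
    if n_int and spec.delta_scale > 0:
        idx = rng.choice(m, size=n_int, replace=False)
        delta[idx] = rng.normal(0.0, spec.delta_scale, size=n_int)

    alleles = np.array([["A", "G"], ["C", "T"], ["A", "C"], ["G", "T"]])
    pick = rng.integers(0, len(alleles), size=m)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(m)],
            "chrom": spec.chromosome,
            "pos": np.arange(1, m + 1, dtype=np.int64) * spec.position_spacing,
            "ea": alleles[pick, 0],
            "oa": alleles[pick, 1],
            "maf": maf,
            "beta": beta,
            "delta": delta,
        }
    )


def simulate_genotypes(truth: pd.DataFrame, n: int, rng=0) -> np.ndarray:
    """HWE hard-call genotypes: per SNP, counts of the effect allele drawn
    Binomial(2, maf) i.i.d. across individuals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(rng)
    maf = np.asarray(truth["maf"], dtype=float)
    if np.any((maf < 0) | (maf > 1)):
        raise ValueError("MAF out of [0, 1]")
    return rng.binomial(2, maf[None, :], size=(n, len(maf))).astype(np.int8)


def simulate_genotypes_ld(
    truth: pd.DataFrame, n: int, block_size: int = 10, rho: float = 0.9, rng=0
) -> np.ndarray:
    """Genotypes with autoregressive within-block LD (for pruning tests).

    Two latent Gaussian haplotypes per individual follow an AR(1) process
    across SNPs within blocks of ``block_size``; each is thresholded at the
    allele-frequency quantile, so marginal HWE holds while adjacent SNPs in a
    block are correlated (r^2 roughly rho^(2*distance) on the latent scale).
    """
    from scipy.stats import norm

    rng = _rng(rng)
    maf = np.asarray(truth["maf"], dtype=float)
    m = len(maf)
    thresh = norm.ppf(maf)
    geno = np.zeros((n, m), dtype=np.int8)
    for hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, m))
        for j in range(1, m):
            if j % block_size == 0:  # block boundary: restart the chain
                z[:, j] = innov[:, j]
            else:
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * innov[:, j]
        geno += (z < thresh[None, :]).astype(np.int8)
    return geno


def simulate_exposure(n: int, prevalence: float, rng=0, exact: bool = False) -> np.ndarray:
    """Binary exposure vector; ``exact=True`` fixes the count at round(p*n)."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    rng = _rng(rng)
    if exact:
        k = int(round(prevalence * n))
        e = np.zeros(n, dtype=np.int8)
        e[rng.choice(n, size=k, replace=False)] = 1
        return e
    return (rng.random(n) < prevalence).astype(np.int8)


def _draw_error(n: int, spec: ArchitectureSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.error_family == "none" or spec.error_sd == 0:
        return np.zeros(n)
    if spec.error_family == "normal":
        return rng.normal(0.0, spec.error_sd, size=n)
    # shifted lognormal: subtract the mean, scale to unit variance, then to error_sd
    s = spec.error_shape
    x = rng.lognormal(0.0, s, size=n)
    mu = np.exp(s * s / 2)
    sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    return spec.error_sd * (x - mu) / sd


def simulate_phenotype(
    genotypes: np.ndarray,
    truth: pd.DataFrame,
    exposure: np.ndarray,
    spec: ArchitectureSpec,
    rng=0,
) -> np.ndarray:
    """Raw (positive) trait: 10**latent with latent = G@beta + a*E + (G@delta)*E + eps.

    ``exposure`` may be a single binary vector or an (n, q) matrix of
    independent exposures — the screening premise is that variance
    heterogeneity aggregates interactions across multiple (possibly
    unmeasured) exposures. With a matrix, an integer ``exposure_idx``
    column in ``truth`` maps each SNP's delta to one exposure (default 0);
    the main effect ``a`` always applies to exposure 0, the one the
    stratified scan gets to see.
    """
    rng = _rng(rng)
    n, m = genotypes.shape
    if len(truth) != m:
        raise ValueError(f"truth table has {len(truth)} SNPs, genotypes have {m}")
    expo = np.asarray(exposure, dtype=float)
    if expo.ndim == 1:
        expo = expo[:, None]
    if expo.shape[0] != n:
        raise ValueError(f"exposure length {expo.shape[0]} != n individuals {n}")
    beta = np.asarray(truth["beta"], dtype=float)
    delta = np.asarray(truth["delta"], dtype=float)
    if "exposure_idx" in truth.columns:
        eidx = truth["exposure_idx"].to_numpy(dtype=np.int64)
        if eidx.min() < 0 or eidx.max() >= expo.shape[1]:
            raise ValueError("exposure_idx outside the supplied exposure columns")
    else:
        eidx = np.zeros(m, dtype=np.int64)
    g = genotypes.astype(np.float64, copy=False)
    latent = g @ beta + spec.exposure_main_effect * expo[:, 0]
    if np.any(delta):
        for k in np.unique(eidx[delta != 0]):
            sel = (eidx == k) & (delta != 0)
            latent += (g[:, sel] @ delta[sel]) * expo[:, k]
    latent += _draw_error(n, spec, rng)
    return np.power(10.0, latent)


def simulate_cohort(spec: ArchitectureSpec, n: int, cohort_id: str = "cohort1") -> CohortData:
    """One-call generator: architecture, genotypes, exposure and phenotype
    from ``spec.seed`` (deterministic: same spec and n give identical data)."""
    rng = np.random.default_rng(spec.seed)
    truth = sample_architecture(spec, rng)
    geno = simulate_genotypes(truth, n, rng)
    expo = simulate_exposure(n, spec.exposure_prevalence, rng)
    pheno = simulate_phenotype(geno, truth, expo, spec, rng)
    return CohortData(geno, truth, pheno, expo, cohort_id)


def split_cohorts(data: CohortData, sizes: list[int], rng=0) -> list[CohortData]:
    """Disjoint random partition of individuals into cohorts of given sizes."""
    if sum(sizes) > data.n:
        raise ValueError(f"requested {sum(sizes)} individuals, only {data.n} available")
    rng = _rng(rng)
    perm = rng.permutation(data.n)
    out, start = [], 0
    for k, size in enumerate(sizes):
        idx = np.sort(perm[start : start + size])
        start += size
        out.append(
            CohortData(
                genotypes=data.genotypes[idx],
                snp_meta=data.snp_meta,
                phenotype=data.phenotype[idx],
                exposure=data.exposure[idx],
                cohort_id=f"{data.cohort_id}_part{k + 1}" if len(sizes) > 1 else data.cohort_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# text I/O (tab-delimited, '.' for missing)

def write_cohort(data: CohortData, prefix: str) -> None:
    """Write dosages, phenotype, exposure and SNP metadata as UTF-8 TSV.

    ``<prefix>.dosage.tsv``: header of SNP ids, first column individual id.
    ``<prefix>.pheno.tsv`` / ``<prefix>.expo.tsv``: two columns (id, value).
    ``<prefix>.snps.tsv``: the truth/metadata table.
    """
    ids = [f"{data.cohort_id}_i{i + 1}" for i in range(data.n)]
    snp_ids = list(data.snp_meta["snp_id"])
    with open(f"{prefix}.dosage.tsv", "w", encoding="utf-8") as fh:
        fh.write("iid\t" + "\t".join(snp_ids) + "\n")
        for i, iid in enumerate(ids):
            row = data.genotypes[i]
            cells = ["." if np.isnan(v) else format(float(v), ".10g") for v in row]
            fh.write(iid + "\t" + "\t".join(cells) + "\n")
    for name, vec in (("pheno", data.phenotype), ("expo", data.exposure)):
        with open(f"{prefix}.{name}.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"iid\t{name}\n")
            for iid, v in zip(ids, vec):
                cell = "." if (isinstance(v, float) and np.isnan(v)) else format(float(v), ".10g")
                fh.write(f"{iid}\t{cell}\n")
    data.snp_meta.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False, float_format="%.10g")


def read_cohort(prefix: str, cohort_id: str = "cohort1") -> CohortData:
    dos = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t", na_values=".")
    pheno = pd.read_csv(f"{prefix}.pheno.tsv", sep="\t", na_values=".")
    expo = pd.read_csv(f"{prefix}.expo.tsv", sep="\t", na_values=".")
    meta = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"chrom": str})
    geno = dos.drop(columns="iid").to_numpy(dtype=float)
    return CohortData(geno, meta, pheno.iloc[:, 1].to_numpy(float),
                      expo.iloc[:, 1].to_numpy(float), cohort_id)
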