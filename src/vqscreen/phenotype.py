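"""Trait preparation and per-SNP absolute deviations.

Traits are prepared in a fixed order — log10, z-score (sample SD, n-1),
winsorize at ``winsor_sd`` standard deviations — and the per-SNP deviation
score Z_i = |Y_i - mean(Y over i's genotype group)| is the quantity whose
group means and variances feed the variance-heterogeneity (Levene) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PreparedPhenotype", "DeviationVector", "prepare_trait", "absolute_deviations"]


@dataclass
class PreparedPhenotype:
    values: np.ndarray
    transform_log: dict

    @property
    def n(self) -> int:
        return int(np.sum(~np.isnan(self.values)))


@dataclass
class DeviationVector:
    """Z >= 0 per individual for one SNP; NaN where genotype or trait missing."""

    values: np.ndarray
    group_assignment: np.ndarray


def prepare_trait(raw, winsor_sd: float = 4.0, log10: bool = True) -> PreparedPhenotype:
    """log10 -> z-score -> winsorize; missing values propagate.

    Raises on nonpositive values when log10 is enabled (naming the first
    offending index) and on zero variance. The z-score uses the sample SD
    (n-1 denominator); the mean/SD actually used, the winsor limit and the
    clamp count are recorded in ``transform_log``.
    """
    y = np.asarray(raw, dtype=float).copy()
    obs = ~np.isnan(y)
    if obs.sum() < 2:
        raise ValueError("need at least 2 non-missing trait values")
    if log10:
        bad = obs & (y <= 0)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(f"log10 requested but value at index {idx} is {y[idx]} (must be > 0)")
        y[obs] = np.log10(y[obs])
    mean = float(np.mean(y[obs]))
    sd = float(np.std(y[obs], ddof=1))
    if sd == 0:
        raise ValueError("trait has zero variance")
    y = (y - mean) / sd
    n_clamped = int(np.sum(np.abs(y[obs]) > winsor_sd))
    y = np.clip(y, -winsor_sd, winsor_sd)
    return PreparedPhenotype(
        values=y,
        transform_log={
            "log10": log10,
            "mean": mean,
            "sd": sd,
            "winsor_sd": float(winsor_sd),
            "n_clamped": n_clamped,
            "n_obs": int(obs.sum()),
        },
    )


def absolute_deviations(prepared: PreparedPhenotype, genotype_classes) -> DeviationVector:
    """Z_i = |Y_i - group mean| with groups the genotype classes 0/1/2.

    Individuals with missing genotype (class < 0 or NaN) or missing trait are
    excluded (NaN in the output). A genotype group may be empty; all groups
    empty is an error.
    """
    y = prepared.values
    g = np.asarray(genotype_classes, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype classes and phenotype must have equal length")
    valid = ~np.isnan(y) & ~np.isnan(g) & (g >= 0)
    gi = np.where(valid, g, 0).astype(np.int64)
    if np.any(valid & ((gi > 2) | (g != np.floor(g)))):
        raise ValueError("genotype classes must be 0, 1 or 2 (or missing)")
    if not valid.any():
        raise ValueError("no individual with both genotype and phenotype observed")
    z = np.full_like(y, np.nan)
    for cls in (0, 1, 2):
        sel = valid & (gi == cls)
        if sel.any():
            z[sel] = np.abs(y[sel] - y[sel].mean())
    groups = np.where(valid, gi, -1)
    return DeviationVector(values=z, group_assignment=groups)
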