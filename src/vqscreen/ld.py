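"""Windowed pairwise-r2 LD pruning (PLINK --indep-pairwise style).

Within each placement of a sliding window (``window`` SNPs, advanced by
``step``), any retained pair with squared Pearson correlation above
``r2_max`` loses one member: the SNP with the lower sample MAF is dropped
(ties drop the later-positioned SNP), which makes the procedure
deterministic. Defaults 50/5/0.1; 0.8 is the alternate threshold used for
odds-ratio analyses on a denser marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PruneSpec", "genotype_r2", "prune_windowed", "audit_prune"]


@dataclass(frozen=True)
class PruneSpec:
    window: int = 50
    step: int = 5
    r2_max: float = 0.1

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not (1 <= self.step <= self.window):
            raise ValueError("step must be in [1, window]")
        if not (0.0 <= self.r2_max <= 1.0):
            raise ValueError("r2_max must be in [0, 1]")


def genotype_r2(a, b) -> float:
    """Squared Pearson correlation of two dosage columns over individuals
    with both calls non-missing; zero-variance columns give 0.0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete pairs")
    x, y = a[ok], b[ok]
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """All-pairs r2 for the columns of g (pairwise-complete over missing)."""
    if np.isnan(g).any():
        m = g.shape[1]
        out = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                out[i, j] = out[j, i] = genotype_r2(g[:, i], g[:, j])
        return out
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    cov = gc.T @ gc / g.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr = np.nan_to_num(corr)  # zero-variance columns -> r2 0
    return corr**2


def prune_windowed(genotypes: np.ndarray, snp_meta: pd.DataFrame,
                   spec: PruneSpec = PruneSpec()):
    """Greedy windowed pruning; SNPs must be ordered by chromosome/position.

    Returns (kept snp_id list, removal log DataFrame with columns
    snp_id, window_start, partner, r2). Output preserves input order.
    """
    g = np.asarray(genotypes, dtype=np.float64)
    m = g.shape[1]
    ids = list(snp_meta["snp_id"])
    eaf = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(eaf, 1 - eaf)
    pos = snp_meta["pos"].to_numpy()
    chrom = snp_meta["chrom"].to_numpy()

    kept = np.ones(m, dtype=bool)
    removals = []
    start = 0
    while True:
        stop = min(start + spec.window, m)
        idx = [j for j in range(start, stop) if kept[j]]
        if len(idx) >= 2:
            r2 = _pairwise_r2(g[:, idx])
            alive = {j: True for j in idx}
            for a_pos in range(len(idx)):
                for b_pos in range(a_pos + 1, len(idx)):
                    ja, jb = idx[a_pos], idx[b_pos]
                    if not (alive[ja] and alive[jb]):
                        continue
                    if chrom[ja] != chrom[jb]:
                        continue
                    if r2[a_pos, b_pos] > spec.r2_max:
                        # drop the lower-MAF SNP; ties drop the later one
                        if maf[ja] < maf[jb] or (maf[ja] == maf[jb] and pos[ja] > pos[jb]):
                            drop, partner = ja, jb
                        else:
                            drop, partner = jb, ja
                        alive[drop] = False
                        kept[drop] = False
                        removals.append((ids[drop], start, ids[partner],
                                         float(r2[a_pos, b_pos])))
        if stop >= m:
            break
        start += spec.step
    kept_ids = [ids[j] for j in range(m) if kept[j]]
    log = pd.DataFrame(removals, columns=["snp_id", "window_start", "partner", "r2"])
    return kept_ids, log


def audit_prune(genotypes: np.ndarray, snp_meta: pd.DataFrame, kept_ids,
                spec: PruneSpec = PruneSpec()) -> list:
    """Exhaustively re-scan every window over the kept SNPs; returns the
    list of violating pairs (empty when the prune post-condition holds)."""
    ids = list(snp_meta["snp_id"])
    keep_idx = [j for j, sid in enumerate(ids) if sid in set(kept_ids)]
    g = np.asarray(genotypes, dtype=float)
    violations = []
    m = len(ids)
    start = 0
    while True:
        stop = min(start + spec.window, m)
        in_win = [j for j in keep_idx if start <= j < stop]
        for a in range(len(in_win)):
            for b in range(a + 1, len(in_win)):
                ja, jb = in_win[a], in_win[b]
                r2 = genotype_r2(g[:, ja], g[:, jb])
                if r2 > spec.r2_max:
                    violations.append((ids[ja], ids[jb], r2))
        if stop >= m:
            break
        start += spec.step
    return violations
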