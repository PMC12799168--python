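"""Cell-cycle phase assignment from S and G2/M marker-set scores.

Each cell gets one score per marker set: mean log-normalized expression
of the set minus the mean of a size-matched random background set
(fixed by seed, removing library-depth effects), standardized across
cells.  A cell is G1 when both scores are <= 0, otherwise it takes the
phase of the larger score — the usual convention for marker-based
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .core import LOGNORM, GeneExpressionMatrix, ValidationError, child_rng

PHASES = ("G1", "S", "G2M")


@dataclass(frozen=True)
class PhaseAssignment:
    obs_id: str
    phase: str
    s_score: float
    g2m_score: float


def _matched_background(
    m: GeneExpressionMatrix,
    idx: np.ndarray,
    exclude: np.ndarray,
    rng: np.random.Generator,
    n_bins: int = 10,
) -> np.ndarray:
    """Size-matched random background, stratified by mean expression.

    One background gene is drawn from the same expression bin as each
    marker, so the control set shares the markers' detection level and
    count-noise profile (the usual gene-set scoring convention).  Every
    marker gene of either set is excluded from the pool.
    """
    others = np.setdiff1d(np.arange(m.n_genes), exclude)
    if len(others) < len(idx):
        raise ValidationError("not enough background genes")
    mean_expr = m.values.mean(axis=1)
    edges = np.quantile(mean_expr, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(edges, mean_expr, side="right") - 1, 0, n_bins - 1)
    pool_by_bin = {b: others[bin_of[others] == b] for b in range(n_bins)}
    background = []
    for g in idx:
        pool = pool_by_bin.get(bin_of[g])
        if pool is None or len(pool) == 0:
            pool = others
        background.append(rng.choice(pool))
    return np.array(background)


def _set_score(
    m: GeneExpressionMatrix, genes, exclude: np.ndarray, rng: np.random.Generator, label: str
) -> np.ndarray:
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    idx = np.array([pos[g] for g in genes if g in pos], dtype=int)
    if len(idx) < 5:
        raise ValidationError(f"{label} marker set: only {len(idx)} genes detected; need >= 5")
    background = _matched_background(m, idx, exclude, rng)
    raw = m.values[idx].mean(axis=0) - m.values[background].mean(axis=0)
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()


def score_phase(
    m: GeneExpressionMatrix, s_genes, g2m_genes, seed: int = 0
) -> pd.DataFrame:
    """Assign each cell a phase from S and G2M marker scores.

    Returns a frame indexed by obs_id with columns phase, s_score,
    g2m_score.  Deterministic given the seed (which fixes the random
    background sets).
    """
    if m.layer_tag != LOGNORM:
        raise ValidationError("score_phase expects a lognorm layer")
    rng = child_rng(seed, "score_phase")
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    exclude = np.array(
        sorted({pos[g] for g in list(s_genes) + list(g2m_genes) if g in pos}), dtype=int
    )
    s = _set_score(m, s_genes, exclude, rng, "S")
    g2m = _set_score(m, g2m_genes, exclude, rng, "G2M")
    phase = np.where((s <= 0) & (g2m <= 0), "G1", np.where(s > g2m, "S", "G2M"))
    return pd.DataFrame(
        {"phase": phase, "s_score": s, "g2m_score": g2m},
        index=pd.Index(m.obs_ids, name="obs_id"),
    )


def phase_composition(
    assignments: pd.DataFrame, grouping: pd.Series, reference_group=None
) -> pd.DataFrame:
    """Per-group (G1, S, G2M) fractions, optionally tested against a reference.

    Fractions sum to 1 within each group.  When ``reference_group`` is
    given, each other group gets a two-proportion z-test per phase
    against it (column ``p_<phase>``).
    """
    grouping = pd.Series(grouping)
    phases = assignments["phase"].reindex(grouping.index)
    if phases.isna().any():
        raise ValidationError("grouping contains cells without a phase assignment")
    counts = (
        pd.crosstab(grouping, phases).reindex(columns=list(PHASES), fill_value=0)
    )
    if (counts.sum(axis=1) == 0).any():
        raise ValidationError("empty group in phase_composition")
    frac = counts.div(counts.sum(axis=1), axis=0)
    frac.columns = [f"frac_{p}" for p in PHASES]
    out = frac.copy()
    out["n"] = counts.sum(axis=1)
    if reference_group is not None:
        if reference_group not in counts.index:
            raise ValidationError(f"reference group {reference_group!r} not present")
        ref = counts.loc[reference_group]
        for p in PHASES:
            pvals = []
            for g in counts.index:
                if g == reference_group:
                    pvals.append(np.nan)
                    continue
                stat_counts = np.array([counts.loc[g, p], ref[p]])
                nobs = np.array([counts.loc[g].sum(), ref.sum()])
                pvals.append(proportions_ztest(stat_counts, nobs)[1])
            out[f"p_{p}"] = pvals
    return out
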