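"""Reversal scoring: R_rej, its permutation test, hits, and concordance.

R_rej for a perturbation is the correlation between two per-gene log2
fold-change vectors: old vs young (the aging signature) and perturbed vs
non-targeting control (the perturbation response), over the genes
detected in both contrasts.  A significantly negative R_rej means the
perturbation pushes expression back toward the young state; the screen's
hit rule is R_rej <= -0.3 with significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .core import ComparisonSpec, GeneExpressionMatrix, ValidationError, child_rng, logger
from .diffexp import LFCVector, common_detected, pseudobulk_lfc

MIN_GENES = 20  # smallest gene intersection a correlation is trusted on


@dataclass
class RejuvenationResult:
    """Per-perturbation reversal score and its significance."""

    tf: str
    mode: str
    r_rej: float
    p_perm: float = np.nan
    n_genes: int = 0
    gene_subset_tag: str = "all_detected"
    is_hit: bool = False
    available: bool = True
    p_adj: float = np.nan


@dataclass
class ConcordanceResult:
    """Correlation of a TF's CRA and CRI responses (negative = opposite)."""

    tf: str
    r_cra_cri: float
    n_genes: int = 0
    concordant: bool = False


def _aligned(lfc_aging: LFCVector, lfc_pert: LFCVector, gene_subset=None, min_genes=MIN_GENES):
    genes = common_detected(lfc_aging, lfc_pert, gene_subset)
    if len(genes) < min_genes:
        raise ValidationError(
            f"only {len(genes)} genes in the common detected set; need >= {min_genes}"
        )
    a = lfc_aging.as_series().loc[genes].to_numpy(dtype=float)
    p = lfc_pert.as_series().loc[genes].to_numpy(dtype=float)
    return genes, a, p


def _corr(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance LFC vector; correlation undefined")
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    x = x - x.mean()
    y = y - y.mean()
    return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))


def compute_rrej(
    lfc_aging: LFCVector,
    lfc_pert: LFCVector,
    gene_subset=None,
    method: str = "pearson",
    tf: str = "",
    mode: str = "CRA",
    gene_subset_tag: str | None = None,
    min_genes: int = MIN_GENES,
) -> RejuvenationResult:
    """Reversal correlation between the aging and perturbation LFC vectors.

    Computed over the intersection of the two detected-gene sets
    (optionally further restricted to ``gene_subset``); requires at
    least 20 genes and nonconstant vectors.  No p-value is attached —
    see :func:`permutation_pvalue`.
    """
    genes, a, p = _aligned(lfc_aging, lfc_pert, gene_subset, min_genes)
    tag = gene_subset_tag or ("all_detected" if gene_subset is None else "subset")
    return RejuvenationResult(
        tf=tf, mode=mode, r_rej=_corr(a, p, method), n_genes=len(genes), gene_subset_tag=tag
    )


def permutation_pvalue(
    lfc_aging: LFCVector,
    lfc_pert: LFCVector,
    n_perm: int = 1000,
    seed: int = 0,
    gene_subset=None,
    method: str = "pearson",
) -> float:
    """One-sided permutation p-value for a negative R_rej.

    Gene labels of the perturbation vector are permuted (preserving
    both marginals); p = (1 + #{permuted r <= observed r}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    _, a, p = _aligned(lfc_aging, lfc_pert, gene_subset)
    r_obs = _corr(a, p, method)
    if method == "spearman":
        a, p = stats.rankdata(a), stats.rankdata(p)
    rng = child_rng(seed, "permutation_pvalue")
    xc = a - a.mean()
    xn = xc / np.linalg.norm(xc)
    perms = np.tile(p, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    yc = perms - perms.mean(axis=1, keepdims=True)
    r_perm = (yc @ xn) / np.linalg.norm(yc, axis=1)
    return float((1 + np.sum(r_perm <= r_obs)) / (1 + n_perm))


def select_hits(
    results: list[RejuvenationResult],
    threshold: float = -0.3,
    alpha: float = 0.05,
    adjust: bool = True,
) -> list[RejuvenationResult]:
    """Hit selection: r_rej <= threshold and significant p, sorted by r_rej.

    Significance is Benjamini-Hochberg-adjusted across perturbations
    within each mode (``adjust=False`` uses raw permutation p).  The
    threshold rule is inclusive: r_rej exactly at the threshold is a
    hit.  Mutates ``is_hit``/``p_adj`` on the inputs and returns the
    hits ascending by r_rej.
    """
    if not results:
        raise ValidationError("no results to select hits from")
    scored = [r for r in results if r.available and np.isfinite(r.p_perm)]
    for mode in sorted({r.mode for r in scored}):
        group = [r for r in scored if r.mode == mode]
        pvals = np.array([r.p_perm for r in group])
        if adjust and len(group) > 1:
            adj = multipletests(pvals, method="fdr_bh")[1]
        else:
            adj = pvals
        for r, pa in zip(group, adj):
            r.p_adj = float(pa)
            r.is_hit = bool(r.r_rej <= threshold and pa <= alpha)
    hits = [r for r in scored if r.is_hit]
    return sorted(hits, key=lambda r: (r.r_rej, r.mode, r.tf))


def score_screen(
    m: GeneExpressionMatrix,
    assignments: pd.DataFrame,
    lfc_aging: LFCVector,
    cfg: RunConfig | None = None,
    gene_subset=None,
    method: str = "pearson",
    adjust: bool = True,
) -> list[RejuvenationResult]:
    """Score every perturbation in a screen against the aging signature.

    For each mode, each TF's cells are contrasted with that mode's
    non-targeting controls (pseudobulk LFC), correlated with the aging
    LFC, permutation-tested, and BH-thresholded into hits.
    """
    cfg = cfg or RunConfig()
    results: list[RejuvenationResult] = []
    for mode in sorted(assignments["mode"].unique()):
        sub = assignments[assignments["mode"] == mode]
        nt_cells = sub.loc[sub["is_control"], "obs_id"].tolist()
        if not nt_cells:
            raise ValidationError(f"no non-targeting controls for mode {mode}")
        tfs = sorted(sub.loc[~sub["is_control"], "tf"].unique())
        for i, tf in enumerate(tfs):
            cells = sub.loc[sub["tf"] == tf, "obs_id"].tolist()
            spec = ComparisonSpec(cells, nt_cells, label=f"{mode}_{tf}_vs_NT")
            lfc_pert = pseudobulk_lfc(m, spec, cfg)
            res = compute_rrej(
                lfc_aging, lfc_pert, gene_subset, method, tf=tf, mode=mode
            )
            res.p_perm = permutation_pvalue(
                lfc_aging,
                lfc_pert,
                n_perm=cfg.permutations,
                seed=child_rng(cfg.seed, f"rrej_{mode}_{tf}", i).integers(2**31 - 1),
                gene_subset=gene_subset,
                method=method,
            )
            results.append(res)
    select_hits(results, cfg.hit_threshold, cfg.alpha, adjust=adjust)
    return results


def results_frame(results: list[RejuvenationResult]) -> pd.DataFrame:
    """Results as a tidy table (mode, tf, r_rej, p, n_genes, subset, hit)."""
    return pd.DataFrame([vars(r) for r in results])[
        ["mode", "tf", "r_rej", "p_perm", "p_adj", "n_genes", "gene_subset_tag", "is_hit", "available"]
    ]


def phase_restricted_rrej(
    m_state: GeneExpressionMatrix,
    spec_aging: ComparisonSpec,
    m_screen: GeneExpressionMatrix,
    spec_pert: ComparisonSpec,
    phase_of: pd.Series,
    phase: str,
    cfg: RunConfig | None = None,
    tf: str = "",
    mode: str = "CRA",
    n_perm: int | None = None,
) -> RejuvenationResult:
    """R_rej recomputed using only cells of one cycle phase in all four groups.

    Separates genuine transcriptional reversal from an apparent reversal
    caused purely by a shift in cell-cycle composition.  A phase group
    smaller than ``min_cells_per_group`` yields an unavailable result
    rather than an exception.
    """
    cfg = cfg or RunConfig()
    phase_of = pd.Series(phase_of)

    def restrict(group):
        return [o for o in group if phase_of.get(o) == phase]

    groups = [
        restrict(spec_aging.group_a),
        restrict(spec_aging.group_b),
        restrict(spec_pert.group_a),
        restrict(spec_pert.group_b),
    ]
    if min(len(g) for g in groups) < cfg.min_cells_per_group:
        logger.warning("phase %s: a restricted group is below min_cells_per_group", phase)
        return RejuvenationResult(
            tf=tf, mode=mode, r_rej=np.nan, gene_subset_tag=f"phase:{phase}", available=False
        )
    lfc_aging = pseudobulk_lfc(
        m_state, ComparisonSpec(groups[0], groups[1], f"{spec_aging.label}|{phase}"), cfg
    )
    lfc_pert = pseudobulk_lfc(
        m_screen, ComparisonSpec(groups[2], groups[3], f"{spec_pert.label}|{phase}"), cfg
    )
    res = compute_rrej(lfc_aging, lfc_pert, tf=tf, mode=mode, gene_subset_tag=f"phase:{phase}")
    if n_perm:
        res.p_perm = permutation_pvalue(lfc_aging, lfc_pert, n_perm=n_perm, seed=cfg.seed)
    return res


def direction_concordance(
    lfc_cra: LFCVector, lfc_cri: LFCVector, concordance_cut: float = 0.3, tf: str = ""
) -> ConcordanceResult:
    """Do activation and repression of one TF move expression oppositely?

    Pearson correlation of the two perturbation LFC vectors; strongly
    negative (r <= -cut) means the two directions of perturbation gave
    opposite global responses.
    """
    genes, a, b = _aligned(lfc_cra, lfc_cri)
    r = _corr(a, b)
    return ConcordanceResult(
        tf=tf, r_cra_cri=r, n_genes=len(genes), concordant=bool(r <= -concordance_cut)
    )
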