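"""TF modules (regulons): inference, per-cell activity, and group scores.

A regulon is a TF plus the genes it is inferred to regulate.  Here the
motif evidence arrives as an input TF -> target map and is pruned by
expression covariation (Spearman correlation with the TF across single
cells) — a deterministic, desk-scale stand-in for ensemble-regression
network inference.

Per-cell activity is an AUCell-style statistic: the normalized area
under the recovery curve of regulon genes among the cell's top-ranked
expressed genes.  Rank-based, hence invariant to any monotone transform
of a cell's expression values.  The TF *module score* for a two-group
comparison is a Welch z-statistic on the two AUCell score samples, so
the differential-module threshold (|score| > 5) is a z-scale cut that a
randomized repartition null can calibrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import LOGNORM, GeneExpressionMatrix, ValidationError, child_rng, logger
from .prioritize import TFTargetMap

_SCORE_CAP = 1e6  # guard for zero-variance, unequal-mean degenerate input


@dataclass
class Regulon:
    """A TF with its pruned, weighted target-gene set."""

    tf: str
    genes: tuple
    weights: tuple = ()
    mode: str = "activating"  # "activating" | "repressive"
    min_size: int = 10

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"regulon {self.tf}: duplicate genes")
        if self.mode not in ("activating", "repressive"):
            raise ValidationError(f"regulon {self.tf}: unknown mode {self.mode!r}")
        if len(self.genes) < self.min_size:
            raise ValidationError(
                f"regulon {self.tf}: {len(self.genes)} genes, below min_size={self.min_size}"
            )

    @property
    def name(self) -> str:
        sign = "+" if self.mode == "activating" else "-"
        return f"{self.tf}({sign})"


@dataclass
class ModuleScoreMatrix:
    """Comparisons x regulons table of module z-scores with group sizes."""

    scores: pd.DataFrame  # rows: comparison labels, cols: regulon names
    n_a: pd.Series
    n_b: pd.Series

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates or self.scores.columns.has_duplicates:
            raise ValidationError("duplicate row or column labels")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("non-finite module scores")


def infer_regulons(
    m: GeneExpressionMatrix,
    maps: list[TFTargetMap],
    min_abs_corr: float = 0.1,
    min_size: int = 10,
) -> list[Regulon]:
    """Prune each TF's target map by covariation with the TF.

    Keeps targets whose Spearman correlation with the TF across cells
    has |r| >= min_abs_corr; the sign of the mean retained correlation
    sets the regulon mode.  TFs absent from the matrix are skipped with
    a warning; regulons below ``min_size`` are dropped.
    """
    if m.layer_tag != LOGNORM:
        raise ValidationError("infer_regulons expects a lognorm layer")
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    ranks = stats.rankdata(m.values, axis=1)  # per-gene ranks across cells
    out = []
    for mp in maps:
        if mp.tf not in gene_pos:
            logger.warning("TF %s not in the expression matrix; skipped", mp.tf)
            continue
        targets = [g for g in mp.targets if g in gene_pos and g != mp.tf]
        if not targets:
            continue
        tf_r = ranks[gene_pos[mp.tf]]
        tgt_r = ranks[[gene_pos[g] for g in targets]]
        tf_c = tf_r - tf_r.mean()
        tg_c = tgt_r - tgt_r.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(tf_c) * np.linalg.norm(tg_c, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, tg_c @ tf_c / np.where(denom > 0, denom, 1), 0.0)
        keep = np.abs(corr) >= min_abs_corr
        if keep.sum() < min_size:
            logger.info("regulon %s dropped: %d genes after pruning", mp.tf, int(keep.sum()))
            continue
        kept = [t for t, k in zip(targets, keep) if k]
        w = tuple(corr[keep])
        mode = "activating" if float(np.mean(w)) >= 0 else "repressive"
        out.append(Regulon(mp.tf, tuple(kept), w, mode, min_size))
    return out


def _top_rank_count(n_genes: int, top_fraction: float) -> int:
    if not 0 < top_fraction <= 0.5:
        raise ValidationError("top_fraction must lie in (0, 0.5]")
    return int(math.ceil(top_fraction * n_genes))


def _max_area(n_top: int, n_set: int) -> int:
    k = min(n_set, n_top)
    return k * (k + 1) // 2 + (n_top - k) * k


def aucell_score(
    cell_expression: np.ndarray, gene_ids, regulon: Regulon, top_fraction: float = 0.05
) -> float:
    """Per-cell regulon activity in [0, 1] from the gene-rank recovery curve.

    Genes are ranked by descending expression (ties broken by position
    in ``gene_ids``); the area under the step curve counting regulon
    genes within the top ``ceil(top_fraction * n)`` ranks is normalized
    by its maximum (all regulon genes ranked first).
    """
    expr = np.asarray(cell_expression, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    members = [pos[g] for g in regulon.genes if g in pos]
    if not members:
        raise ValidationError(f"regulon {regulon.tf}: no genes in this universe")
    n = len(expr)
    n_top = _top_rank_count(n, top_fraction)
    order = np.lexsort((np.arange(n), -expr))  # descending, stable on gene order
    rank_of = np.empty(n, dtype=int)
    rank_of[order] = np.arange(1, n + 1)
    hit_ranks = rank_of[members]
    area = int(np.sum(n_top - hit_ranks[hit_ranks <= n_top] + 1))
    return area / _max_area(n_top, len(members))


def aucell_matrix(
    m: GeneExpressionMatrix, regulon: Regulon, top_fraction: float = 0.05
) -> pd.Series:
    """AUCell scores for every cell in the matrix (vectorized)."""
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    members = np.array([pos[g] for g in regulon.genes if g in pos], dtype=int)
    if members.size == 0:
        raise ValidationError(f"regulon {regulon.tf}: no genes in this universe")
    n, n_cells = m.n_genes, m.n_obs
    n_top = _top_rank_count(n, top_fraction)
    order = np.argsort(-m.values, axis=0, kind="stable")
    rank_of = np.empty_like(order)
    np.put_along_axis(rank_of, order, np.arange(1, n + 1)[:, None], axis=0)
    hit = rank_of[members]  # members x cells
    contrib = np.where(hit <= n_top, n_top - hit + 1, 0)
    scores = contrib.sum(axis=0) / _max_area(n_top, len(members))
    return pd.Series(scores, index=m.obs_ids, name=regulon.name)


def module_score(scores_a, scores_b) -> float:
    """Welch z comparing a regulon's AUCell scores between two cell groups.

    Positive means higher activity in group A.  Degenerate inputs: both
    variances zero with equal means -> 0; with unequal means -> signed
    1e6 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("module_score needs >= 2 cells per group")
    se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0
        logger.warning("module_score: zero variance with unequal means; capping")
        return float(np.sign(diff) * _SCORE_CAP)
    return float(diff / np.sqrt(se2))


def build_module_scores(
    m: GeneExpressionMatrix,
    regulons: list[Regulon],
    comparisons: list,
    top_fraction: float = 0.05,
) -> ModuleScoreMatrix:
    """Module z-scores for every (comparison, regulon) pair.

    AUCell scores are computed once per regulon over all cells, then
    each :class:`ComparisonSpec` contributes one row of Welch z values.
    """
    if not regulons or not comparisons:
        raise ValidationError("need at least one regulon and one comparison")
    cell_scores = {r.name: aucell_matrix(m, r, top_fraction) for r in regulons}
    rows, n_a, n_b = {}, {}, {}
    for spec in comparisons:
        row = {}
        for name, s in cell_scores.items():
            row[name] = module_score(s.loc[list(spec.group_a)], s.loc[list(spec.group_b)])
        rows[spec.label] = row
        n_a[spec.label] = len(spec.group_a)
        n_b[spec.label] = len(spec.group_b)
    scores = pd.DataFrame.from_dict(rows, orient="index")
    return ModuleScoreMatrix(scores, pd.Series(n_a), pd.Series(n_b))


def differential_modules(msm: ModuleScoreMatrix, reference_row: str, cut: float = 5.0) -> list:
    """Regulons whose |score| exceeds ``cut`` in the reference comparison."""
    if reference_row not in msm.scores.index:
        raise ValidationError(f"reference row {reference_row!r} not found")
    ref = msm.scores.loc[reference_row]
    return list(ref.index[np.abs(ref.to_numpy()) > cut])


def repartition_null(
    m: GeneExpressionMatrix,
    cells_a,
    cells_b,
    regulon: Regulon,
    n_draws: int = 1000,
    seed: int = 0,
    top_fraction: float = 0.05,
) -> np.ndarray:
    """Null module scores from random repartitions of the pooled groups.

    The two groups are merged and randomly re-split at their original
    sizes; each draw yields one module score.  Per-cell AUCell scores
    are computed once (they do not depend on the grouping).
    """
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    scores = aucell_matrix(m.subset_obs(list(cells_a) + list(cells_b)), regulon, top_fraction)
    return repartition_null_from_scores(
        scores.iloc[: len(cells_a)].to_numpy(), scores.iloc[len(cells_a):].to_numpy(),
        n_draws, seed,
    )


def repartition_null_from_scores(
    scores_a: np.ndarray, scores_b: np.ndarray, n_draws: int = 1000, seed: int = 0
) -> np.ndarray:
    """Repartition null given precomputed per-cell activity scores."""
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    rng = child_rng(seed, "repartition_null")
    pooled = np.concatenate([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    n_a = len(scores_a)
    out = np.empty(n_draws)
    for i in range(n_draws):
        perm = rng.permutation(pooled)
        out[i] = module_score(perm[:n_a], perm[n_a:])
    return out


def cluster_rows(msm: ModuleScoreMatrix, selected_cols=None):
    """Cluster comparisons by their module-score profiles.

    Distance is 1 - Pearson correlation over the selected regulon
    columns, average linkage.  Constant rows get the maximum distance
    (2.0) to every other row.  Returns ``(ordered row labels, linkage
    matrix, newick string)``; leaf order is deterministic (rows are
    pre-sorted by label so equal-height merges tie-break consistently).
    """
    cols = list(selected_cols) if selected_cols is not None else list(msm.scores.columns)
    if len(cols) < 2:
        raise ValidationError("need >= 2 selected columns to correlate rows")
    data = msm.scores.loc[sorted(msm.scores.index), cols]
    if len(data) < 2:
        raise ValidationError("need >= 2 rows to cluster")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("constant row(s) %s: distance set to maximum", list(data.index[constant]))
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1)
    safe = np.where(norm > 0, norm, 1.0)
    corr = (xc @ xc.T) / np.outer(safe, safe)
    dist = 1.0 - corr
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    np.clip(dist, 0.0, 2.0, out=dist)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(link)
    labels = list(data.index)
    ordered = [labels[i] for i in leaves]
    return ordered, link, _newick(link, labels)


def _newick(link: np.ndarray, labels: list) -> str:
    n = len(labels)
    nodes = {i: str(labels[i]) for i in range(n)}
    for i, (a, b, h, _) in enumerate(link):
        nodes[n + i] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
    root = n + len(link) - 1 if len(link) else 0
    return nodes[root] + ";"
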