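"""Per-gene log2 fold-change vectors between two observation groups.

The log fold change is computed from the ratio of group-mean
library-size-normalized expression (pseudobulk), not from per-cell logs:
this is robust to dropout and makes the single-cell and bulk paths share
one definition, so a screen contrast and an in vivo contrast are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .core import COUNTS, ComparisonSpec, GeneExpressionMatrix, ValidationError


@dataclass
class LFCVector:
    """Per-gene log2 fold change of group A over group B.

    ``detected_mask`` marks genes passing the expression filter; ``lfc``
    is finite wherever the mask is true.
    """

    gene_ids: np.ndarray
    lfc: np.ndarray
    n_a: int
    n_b: int
    detected_mask: np.ndarray
    mean_a: np.ndarray = None  # type: ignore[assignment]
    mean_b: np.ndarray = None  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.lfc = np.asarray(self.lfc, dtype=float)
        self.detected_mask = np.asarray(self.detected_mask, dtype=bool)
        if not (len(self.gene_ids) == len(self.lfc) == len(self.detected_mask)):
            raise ValidationError("LFCVector field lengths differ")
        if not np.all(np.isfinite(self.lfc[self.detected_mask])):
            raise ValidationError("non-finite lfc on detected genes")

    def as_series(self):
        import pandas as pd

        return pd.Series(self.lfc, index=self.gene_ids, name=self.label or "lfc")


def common_detected(a: LFCVector, b: LFCVector, gene_subset=None) -> np.ndarray:
    """Gene ids detected in both vectors (optionally intersected with a subset)."""
    det_a = set(a.gene_ids[a.detected_mask])
    det_b = set(b.gene_ids[b.detected_mask])
    common = det_a & det_b
    if gene_subset is not None:
        common &= set(gene_subset)
    # preserve a's gene order for determinism
    return np.array([g for g in a.gene_ids if g in common], dtype=object)


def _normalized_means(values: np.ndarray, idx: np.ndarray, scale: float) -> np.ndarray:
    totals = values[:, idx].sum(axis=0)
    if np.any(totals == 0):
        totals = np.where(totals == 0, 1.0, totals)
    return (values[:, idx] * (scale / totals)).mean(axis=1)


def pseudobulk_lfc(
    m: GeneExpressionMatrix, spec: ComparisonSpec, cfg: RunConfig | None = None
) -> LFCVector:
    """log2 fold change of group A vs group B from pseudobulk means.

    Per gene: ``log2((mean_a + pc) / (mean_b + pc))`` where means are
    over library-size-normalized counts (``cfg.norm_scale`` total per
    cell) and ``pc = pseudocount / norm_scale``.  A gene is detected
    when it has nonzero counts in at least ``detect_fraction`` of the
    cells of either group.
    """
    cfg = cfg or RunConfig()
    if m.layer_tag != COUNTS:
        raise ValidationError("pseudobulk_lfc expects a counts layer")
    idx_a = m.obs_index(spec.group_a)
    idx_b = m.obs_index(spec.group_b)
    for name, idx in (("A", idx_a), ("B", idx_b)):
        if len(idx) < cfg.min_cells_per_group:
            raise ValidationError(
                f"comparison {spec.label!r}: group {name} has {len(idx)} cells, "
                f"fewer than min_cells_per_group={cfg.min_cells_per_group}"
            )
    pc = cfg.pseudocount / cfg.norm_scale
    mean_a = _normalized_means(m.values, idx_a, cfg.norm_scale)
    mean_b = _normalized_means(m.values, idx_b, cfg.norm_scale)
    lfc = np.log2(mean_a + pc) - np.log2(mean_b + pc)
    frac_a = (m.values[:, idx_a] > 0).mean(axis=1)
    frac_b = (m.values[:, idx_b] > 0).mean(axis=1)
    detected = (frac_a >= cfg.detect_fraction) | (frac_b >= cfg.detect_fraction)
    return LFCVector(
        m.gene_ids, lfc, len(idx_a), len(idx_b), detected, mean_a, mean_b, label=spec.label
    )


def bulk_lfc(table, spec: ComparisonSpec, pseudocount_rate: float = 0.0) -> LFCVector:
    """log2 ratio of group means for a bulk genes x samples table.

    ``table`` is a pandas DataFrame of normalized expression with gene
    ids as index and sample ids as columns (the in vivo path: samples
    are individual animals, 3-5 per group).  Genes with zero mean in
    both groups are masked out.
    """
    vals_a = table.loc[:, list(spec.group_a)].to_numpy(dtype=float)
    vals_b = table.loc[:, list(spec.group_b)].to_numpy(dtype=float)
    mean_a = vals_a.mean(axis=1)
    mean_b = vals_b.mean(axis=1)
    detected = ~((mean_a == 0) & (mean_b == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_a + pseudocount_rate) - np.log2(mean_b + pseudocount_rate)
    lfc[~np.isfinite(lfc)] = np.nan
    detected &= np.isfinite(lfc)
    return LFCVector(
        table.index.to_numpy(dtype=object),
        np.where(detected, lfc, np.nan),
        vals_a.shape[1],
        vals_b.shape[1],
        detected,
        mean_a,
        mean_b,
        label=spec.label,
    )
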