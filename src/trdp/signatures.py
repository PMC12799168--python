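"""Gene-set threshold filters and cross-dataset signature comparisons.

These are the pure set-selection rules used around the screen: which
aging changes a treatment reverses, which changes recur across disease
models (the consensus cancer signature), how a treatment's response
overlaps such a signature, and ranking comparisons by similarity of
their module-score profiles.  Every rule is a plain threshold predicate,
so each is testable against exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError, logger
from .diffexp import LFCVector
from .regulons import ModuleScoreMatrix


@dataclass
class ReversalGeneSet:
    """Genes whose aging change a treatment flips, split by direction."""

    down_in_old_reversed: frozenset
    up_in_old_reversed: frozenset
    lfc_cut: float = 1.5

    def __post_init__(self) -> None:
        if set(self.down_in_old_reversed) & set(self.up_in_old_reversed):
            raise ValidationError("reversal sets must be disjoint")


@dataclass
class ConsensusSignature:
    """Genes moving consistently (same direction) across >= min_models models."""

    up_set: frozenset
    down_set: frozenset
    min_models: int = 3
    lfc_cut: float = 1.0


@dataclass(frozen=True)
class PassageCategory:
    """Replicative-age bin from cumulative population doublings."""

    pd: float
    category: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pd < 0:
            raise ValidationError("population doublings must be nonnegative")
        cat = "early" if self.pd <= 20 else ("middle" if self.pd <= 30 else "late")
        object.__setattr__(self, "category", cat)


def _lfc_map(v: LFCVector) -> dict:
    return {g: x for g, x, d in zip(v.gene_ids, v.lfc, v.detected_mask) if d}


def reversal_genes(
    lfc_aging: LFCVector, lfc_treatment: LFCVector, cut: float = 1.5
) -> ReversalGeneSet:
    """Genes strongly changed with age and strongly flipped by treatment.

    down_in_old_reversed: aging lfc < -cut and treatment lfc > +cut;
    up_in_old_reversed: the mirror image.  Both |lfc| must exceed the
    cut in their respective comparisons.
    """
    a, t = _lfc_map(lfc_aging), _lfc_map(lfc_treatment)
    common = [g for g in a if g in t]
    if len(common) < 20:
        raise ValidationError(f"only {len(common)} genes shared; need >= 20")
    down = frozenset(g for g in common if a[g] < -cut and t[g] > cut)
    up = frozenset(g for g in common if a[g] > cut and t[g] < -cut)
    return ReversalGeneSet(down, up, cut)


def consensus_signature(
    model_lfcs: list[LFCVector], cut: float = 1.0, min_models: int = 3
) -> ConsensusSignature:
    """Recurrent up/down genes across independent disease models.

    A gene joins up_set when lfc > cut in at least ``min_models`` models
    and no model shows lfc < -cut (sign-conflicted genes are treated as
    inconsistent, not majority-voted); down_set is symmetric.
    """
    if len(model_lfcs) < min_models:
        raise ValidationError(f"need >= {min_models} models, got {len(model_lfcs)}")
    maps = [_lfc_map(v) for v in model_lfcs]
    universes = [set(mp) for mp in maps]
    common = set.intersection(*universes)
    if any(u - common for u in universes):
        logger.warning("inconsistent gene universes; intersecting to %d genes", len(common))
    up, down = set(), set()
    for g in common:
        vals = [mp[g] for mp in maps]
        n_up = sum(v > cut for v in vals)
        n_down = sum(v < -cut for v in vals)
        if n_up >= min_models and n_down == 0:
            up.add(g)
        elif n_down >= min_models and n_up == 0:
            down.add(g)
    return ConsensusSignature(frozenset(up), frozenset(down), min_models, cut)


def signature_similarity(
    msm: ModuleScoreMatrix, reference_row: str, selected_cols, top_k: int = 10
) -> pd.DataFrame:
    """Rank comparisons by similarity of module profiles to a reference.

    Pearson correlation between each row and the reference over the
    selected regulon columns, descending; constant rows are excluded
    with a warning.  Returns the full ranking with a ``top`` flag on
    the first ``top_k``.
    """
    cols = list(selected_cols)
    if len(cols) < 5:
        raise ValidationError("need >= 5 shared selected columns")
    if reference_row not in msm.scores.index:
        raise ValidationError(f"reference row {reference_row!r} not found")
    ref = msm.scores.loc[reference_row, cols].to_numpy(dtype=float)
    if ref.std() == 0:
        raise ValidationError("reference row is constant; similarity undefined")
    rows = []
    for label in msm.scores.index:
        if label == reference_row:
            continue
        x = msm.scores.loc[label, cols].to_numpy(dtype=float)
        if x.std() == 0:
            logger.warning("row %r constant; excluded from similarity ranking", label)
            continue
        rows.append({"label": label, "similarity": float(np.corrcoef(x, ref)[0, 1])})
    out = pd.DataFrame(rows).sort_values(
        ["similarity", "label"], ascending=[False, True], ignore_index=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out["top"] = out["rank"] <= top_k
    return out


def overlap_with_treatment(
    signature: ConsensusSignature, treatment_lfc: LFCVector, cut: float = 1.0
) -> pd.DataFrame:
    """How much of a consensus signature a treatment recapitulates.

    For each signature set, the fraction of genes the treatment leaves
    unaltered (|lfc| <= cut), moves in the same direction (shared), or
    moves oppositely (reversed); the three fractions sum to 1 per set.
    Genes missing from the treatment contrast count as unaltered.
    """
    if not signature.up_set and not signature.down_set:
        raise ValidationError("empty consensus signature")
    t = _lfc_map(treatment_lfc)
    rows = []
    for name, genes, sign in (
        ("up_set", signature.up_set, 1),
        ("down_set", signature.down_set, -1),
    ):
        if not genes:
            continue
        unaltered = shared = reversed_ = 0
        for g in sorted(genes):
            v = t.get(g, 0.0)
            if abs(v) <= cut:
                unaltered += 1
            elif np.sign(v) == sign:
                shared += 1
            else:
                reversed_ += 1
        n = len(genes)
        rows.append(
            {
                "set": name,
                "n_genes": n,
                "frac_unaltered": unaltered / n,
                "frac_shared": shared / n,
                "frac_reversed": reversed_ / n,
            }
        )
    return pd.DataFrame(rows)
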