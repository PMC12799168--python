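"""Candidate-TF ranking from a two-state contrast and TF -> target maps.

Given the genes differentially expressed between the old and young
states and a motif-derived target set per TF, each TF is scored by a
one-sided hypergeometric over-representation test of its targets in the
DE set, plus a signed direction bias.  The top-k ranked TFs form the
candidate list for perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import ValidationError, logger
from .diffexp import LFCVector


@dataclass
class TFTargetMap:
    """One TF's predicted target genes (e.g. motif-proximal promoters)."""

    tf: str
    targets: tuple
    weights: tuple | None = None
    provenance_tag: str = "unspecified"

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        if not self.targets:
            raise ValidationError(f"TF {self.tf}: empty target set")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError(f"TF {self.tf}: duplicate targets")
        if self.weights is not None:
            self.weights = tuple(self.weights)
            if len(self.weights) != len(self.targets):
                raise ValidationError(f"TF {self.tf}: weights/targets length mismatch")


def maps_from_table(table: pd.DataFrame, provenance_tag: str = "table") -> list[TFTargetMap]:
    """TFTargetMaps from a long (tf, target[, weight]) table."""
    out = []
    for tf, grp in table.groupby("tf", sort=True):
        w = tuple(grp["weight"]) if "weight" in grp.columns else None
        out.append(TFTargetMap(str(tf), tuple(grp["target"]), w, provenance_tag))
    return out


@dataclass
class TFPriorityResult:
    tf: str
    n_targets: int
    overlap_de: int
    enrichment_p: float
    signed_bias: float
    rank: int = 0
    p_adj: float = np.nan


def de_gene_set(lfc: LFCVector, lfc_cut: float = 1.0, top_n: int | None = None) -> dict:
    """Signed differential gene set from an LFC vector.

    Genes with |lfc| >= lfc_cut among the detected genes (or the top_n
    by |lfc| if given), mapped to the sign of their change.  Ties at a
    top_n boundary are broken by gene id for determinism.
    """
    genes = lfc.gene_ids[lfc.detected_mask]
    vals = lfc.lfc[lfc.detected_mask]
    order = sorted(range(len(genes)), key=lambda i: (-abs(vals[i]), genes[i]))
    if top_n is not None:
        chosen = order[: int(top_n)]
    else:
        chosen = [i for i in order if abs(vals[i]) >= lfc_cut]
    if not chosen:
        raise ValidationError(
            f"no genes pass |lfc| >= {lfc_cut}; try a lower cut or top_n selection"
        )
    return {genes[i]: int(np.sign(vals[i])) for i in chosen}


def prioritize_tfs(
    maps: list[TFTargetMap], de: dict, universe, k: int | None = None
) -> list[TFPriorityResult]:
    """Rank TFs by target-set enrichment in the DE genes.

    Per TF: the one-sided hypergeometric tail P(overlap >= observed)
    given (|universe|, |targets in universe|, |DE in universe|), with BH
    adjustment reported alongside.  Ranks ascend by raw p, ties broken
    by larger overlap then TF name; the top k results are returned.
    """
    universe = set(universe)
    de_in = {g for g in de if g in universe}
    missing_de = len(de) - len(de_in)
    if missing_de:
        logger.warning("%d DE genes outside the universe ignored", missing_de)
    results = []
    for m in maps:
        tset = set(m.targets)
        if len(tset) > len(universe):
            raise ValidationError(f"TF {m.tf}: target set larger than the universe")
        t_in = tset & universe
        if not t_in:
            raise ValidationError(f"TF {m.tf}: no targets in the analysis universe")
        if len(t_in) < len(tset):
            logger.warning("TF %s: %d target(s) outside universe", m.tf, len(tset) - len(t_in))
        overlap = t_in & de_in
        # P(X >= |overlap|) for X ~ Hypergeom(M=|U|, n=|DE|, N=|targets|)
        p = float(hypergeom.sf(len(overlap) - 1, len(universe), len(de_in), len(t_in)))
        if overlap:
            up = sum(1 for g in overlap if de[g] > 0)
            bias = (up - (len(overlap) - up)) / len(overlap)
        else:
            bias = 0.0
        results.append(
            TFPriorityResult(m.tf, len(t_in), len(overlap), p, float(bias))
        )
    if not results:
        raise ValidationError("no TF maps supplied")
    if k is not None and k > len(results):
        raise ValidationError(f"k={k} exceeds the {len(results)} TFs supplied")
    pvals = [r.enrichment_p for r in results]
    adj = multipletests(pvals, method="fdr_bh")[1] if len(results) > 1 else pvals
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    results.sort(key=lambda r: (r.enrichment_p, -r.overlap_de, r.tf))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results[: k if k is not None else len(results)]


def priority_frame(results: list[TFPriorityResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])[
        ["rank", "tf", "n_targets", "overlap_de", "enrichment_p", "p_adj", "signed_bias"]
    ]
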