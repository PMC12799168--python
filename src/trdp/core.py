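"""Core data model for the rejuvenation-screen pipeline.

The universal container is a genes x observations expression matrix
(:class:`GeneExpressionMatrix`); observations are single cells in the
Perturb-seq path and bulk samples in the in vivo path.  All group
contrasts are expressed through :class:`ComparisonSpec`, and cell ->
perturbation bookkeeping through :class:`PerturbationAssignment` tables.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("trdp")
if not logger.handlers:  # stderr, level-prefixed, configured once
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s [%(name)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: sentinel perturbation label for non-targeting control cells
NT_SENTINEL = "NT"

COUNTS = "counts"
LOGNORM = "lognorm"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def child_rng(seed: int, name: str, replicate: int = 0) -> np.random.Generator:
    """Derive an independent random stream from (root seed, operation, replicate).

    Each stochastic stage draws from its own stream, so reordering stages
    or re-running a single stage cannot change the results of another.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(replicate)]))


@dataclass
class GeneExpressionMatrix:
    """Genes x observations expression values with aligned annotations.

    ``values`` holds raw counts (``layer_tag="counts"``, integer-valued,
    nonnegative) or log2 library-size-normalized expression
    (``layer_tag="lognorm"``).  ``obs_meta`` is indexed by ``obs_ids`` and
    carries per-observation labels (perturbation, mode, phase, state ...).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    obs_ids: np.ndarray
    obs_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    layer_tag: str = COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.obs_ids = np.asarray(self.obs_ids, dtype=object)
        if self.obs_meta is None:
            self.obs_meta = pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id"))
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x observations array")
        n_genes, n_obs = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.obs_ids) != n_obs:
            raise ValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} gene ids, {len(self.obs_ids)} obs ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.obs_ids)) != n_obs:
            raise ValidationError("duplicate observation ids")
        if self.layer_tag not in (COUNTS, LOGNORM):
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == COUNTS:
            if np.any(self.values < 0):
                raise ValidationError("counts layer contains negative values")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("counts layer is not integer-valued")
        if not self.obs_meta.index.equals(pd.Index(self.obs_ids)):
            self.obs_meta = self.obs_meta.reindex(pd.Index(self.obs_ids, name="obs_id"))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Integer positions of ``genes``; unknown ids raise KeyError."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:
            raise KeyError(f"gene id not in matrix: {e.args[0]!r}") from None

    def obs_index(self, obs) -> np.ndarray:
        lookup = {o: i for i, o in enumerate(self.obs_ids)}
        try:
            return np.array([lookup[o] for o in obs], dtype=int)
        except KeyError as e:
            raise KeyError(f"observation id not in matrix: {e.args[0]!r}") from None

    def subset_obs(self, mask_or_ids) -> "GeneExpressionMatrix":
        """New matrix restricted to a boolean mask or list of obs ids."""
        arr = np.asarray(mask_or_ids)
        idx = np.flatnonzero(arr) if arr.dtype == bool else self.obs_index(arr)
        return replace(
            self,
            values=self.values[:, idx],
            obs_ids=self.obs_ids[idx],
            obs_meta=self.obs_meta.iloc[idx],
        )


@dataclass(frozen=True)
class PerturbationAssignment:
    """Mapping of one observation to its perturbation.

    ``is_control`` is true exactly when ``tf`` is the non-targeting
    sentinel; ``mode`` distinguishes the activation (CRA) and repression
    (CRI) screens.
    """

    obs_id: str
    tf: str
    mode: str  # "CRA" | "CRI"
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("CRA", "CRI"):
            raise ValidationError(f"mode must be CRA or CRI, got {self.mode!r}")
        if self.is_control != (self.tf == NT_SENTINEL):
            raise ValidationError("is_control must hold exactly when tf is the NT sentinel")


def assignments_to_frame(assignments) -> pd.DataFrame:
    """Assignment records (or an existing frame) as a validated DataFrame."""
    if isinstance(assignments, pd.DataFrame):
        df = assignments.copy()
    else:
        df = pd.DataFrame([vars(a) for a in assignments])
    required = {"obs_id", "tf", "mode"}
    if not required.issubset(df.columns):
        raise ValidationError(f"assignment table needs columns {sorted(required)}")
    if "is_control" not in df.columns:
        df["is_control"] = df["tf"] == NT_SENTINEL
    if not (df["is_control"] == (df["tf"] == NT_SENTINEL)).all():
        raise ValidationError("is_control inconsistent with NT sentinel")
    return df


@dataclass(frozen=True)
class ComparisonSpec:
    """A labeled two-group contrast over observation ids (A vs B).

    Conventions downstream: group A is the 'numerator' state (old,
    perturbed, treated), group B the reference (young, NT control).
    """

    group_a: tuple
    group_b: tuple
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))
        if not self.group_a or not self.group_b:
            raise ValidationError(f"comparison {self.label!r}: empty group")
        if set(self.group_a) & set(self.group_b):
            raise ValidationError(f"comparison {self.label!r}: groups overlap")
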