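"""Run configuration: one object holding every pipeline-wide knob.

Serialized to/from plain YAML so a run is reproducible from a text file
plus the root seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .core import ValidationError


@dataclass
class RunConfig:
    """Pipeline-wide parameters.

    pseudocount
        Added before every log2, on the normalized scale as
        ``pseudocount / norm_scale`` per-gene rate.
    min_cells_per_group
        Smallest group size accepted for any pseudobulk contrast.
    permutations
        Gene-label permutations for the R_rej significance test.
    seed
        Root seed; every stochastic stage derives its own child stream.
    aucell_top_fraction
        Fraction of the ranked gene list scanned by the recovery curve.
    hit_threshold
        R_rej at or below this value (with significance) marks a hit.
    module_score_cut
        |z| threshold calling a TF module differential between states.
    """

    pseudocount: float = 1.0
    min_cells_per_group: int = 10
    permutations: int = 1000
    seed: int = 0
    aucell_top_fraction: float = 0.05
    hit_threshold: float = -0.3
    module_score_cut: float = 5.0
    # secondary knobs (conventional defaults, documented in the methods note)
    norm_scale: float = 1e4
    detect_fraction: float = 0.05
    alpha: float = 0.05
    concordance_cut: float = 0.3
    min_abs_corr: float = 0.1
    regulon_min_size: int = 10

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.min_cells_per_group < 1:
            raise ValidationError("min_cells_per_group must be >= 1")
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")
        if not 0 < self.aucell_top_fraction < 1:
            raise ValidationError("aucell_top_fraction must lie in (0, 1)")
        if self.norm_scale <= 0:
            raise ValidationError("norm_scale must be positive")
        if not 0 <= self.detect_fraction <= 1:
            raise ValidationError("detect_fraction must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
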