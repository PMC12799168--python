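"""Synthetic Perturb-seq screens and two-state datasets with known truth.

The generative model, in outline:

* A sparse *aging axis*: a per-gene log2 fold-change vector that is
  nonzero on an "affected" gene subset (drawn N(0, lfc_scale)) and
  exactly zero elsewhere.  Old-state gene means equal young means times
  ``2**aging_lfc``.
* Per-TF perturbations: the true perturbation log2 FC equals
  ``-rho * aging_lfc`` plus independent off-axis noise, so ``rho`` is the
  fraction of the aging signature the perturbation undoes (rho = 0 with
  zero off-axis noise is a null TF).  Off-axis effects are confined to
  the affected gene set, which keeps the analytic reversal correlation
  (:func:`expected_rrej`) valid for the genome-wide statistic.
* Counts are negative binomial (mean mu, variance mu + mu^2/dispersion)
  around cell-specific expected values: per-gene relative abundances are
  renormalized per cell and scaled by a lognormal library size.
* Optional cell-cycle structure: two marker blocks (S and G2M) elevated
  ``2**1.5``-fold in cells of the matching phase; per-condition phase
  fractions are part of the stated truth, which lets composition-only
  confounds be constructed deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import NT_SENTINEL, GeneExpressionMatrix, ValidationError, child_rng, logger

MARKER_LOG2FC = 1.5  # phase-marker elevation, log2 scale


@dataclass
class AgingAxisSpec:
    """Sparse aging signature: which genes move with age, and how much."""

    n_genes: int = 2000
    n_affected: int = 1000
    lfc_scale: float = 1.0
    affected_set: np.ndarray | None = None
    affected_lfc: np.ndarray | None = None  # pin exact per-gene values (else drawn)

    def __post_init__(self) -> None:
        if self.n_affected > self.n_genes:
            raise ValidationError("n_affected cannot exceed n_genes")
        if self.lfc_scale < 0:
            raise ValidationError("lfc_scale must be nonnegative")
        if self.affected_lfc is not None and self.affected_set is None:
            raise ValidationError("affected_lfc requires an explicit affected_set")


@dataclass
class PerturbationEffectSpec:
    """One TF perturbation's true effect.

    ``rho`` in [-1, 1] is the reversal fraction: the perturbation's true
    log2 FC is ``-rho * aging_lfc`` plus N(0, off_axis_sd) noise on the
    affected genes.  rho = 0 encodes a null TF; rho < 0 exaggerates the
    aging signature instead of reversing it.
    """

    tf: str
    mode: str = "CRA"
    rho: float = 0.0
    off_axis_sd: float = 0.0

    def __post_init__(self) -> None:
        if not -1 <= self.rho <= 1:
            raise ValidationError("rho must lie in [-1, 1]")
        if self.off_axis_sd < 0:
            raise ValidationError("off_axis_sd must be nonnegative")
        if self.mode not in ("CRA", "CRI"):
            raise ValidationError("mode must be CRA or CRI")


@dataclass
class NoiseModel:
    """Count noise: NB dispersion, lognormal library sizes, lognormal baselines.

    The default dispersion (NB size 10) describes clean UMI-counting
    data; smaller values give markedly noisier per-gene fold changes.
    """

    nb_dispersion: float = 10.0
    mean_library_size: float = 5000.0
    library_size_cv: float = 0.3
    baseline_expression: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.mean_library_size <= 0:
            raise ValidationError("mean_library_size must be positive")
        if self.library_size_cv < 0:
            raise ValidationError("library_size_cv must be nonnegative")


@dataclass
class SyntheticScreenTruth:
    """Everything needed to recompute the expected answer downstream."""

    gene_ids: np.ndarray
    aging_lfc: np.ndarray
    affected_idx: np.ndarray
    effects: list[PerturbationEffectSpec]
    seed: int
    sigma_axis: float
    baseline: np.ndarray | None = None
    # (tf, mode) -> true log2 FC vector on the measurement (library-normalized)
    # scale, i.e. the nominal effect minus the constant total-content shift
    perturbation_lfc: dict = field(default_factory=dict)
    cellcycle_fractions: dict = field(default_factory=dict)  # condition -> (G1, S, G2M)
    s_genes: list = field(default_factory=list)
    g2m_genes: list = field(default_factory=list)

    def expected_rrej_by_tf(self) -> dict:
        axis = AgingAxisSpec(
            n_genes=len(self.gene_ids),
            n_affected=len(self.affected_idx),
            lfc_scale=self.sigma_axis,
        )
        return {(e.tf, e.mode): expected_rrej(e, axis) for e in self.effects}


def expected_rrej(effect: PerturbationEffectSpec, axis: AgingAxisSpec) -> float:
    """Population reversal correlation implied by the generative model.

    Over the affected genes, aging LFC has SD sigma_axis and the
    perturbation LFC is -rho * aging + N(0, off_axis_sd), so the Pearson
    correlation is ``-rho * sigma / sqrt(rho^2 sigma^2 + off_axis_sd^2)``
    (verified against brute-force Monte Carlo in the test suite).
    """
    if axis.lfc_scale == 0:
        raise ValidationError("expected_rrej needs an axis with nonzero variance")
    sigma = axis.lfc_scale
    denom = np.sqrt(effect.rho**2 * sigma**2 + effect.off_axis_sd**2)
    if denom == 0:
        logger.warning("expected_rrej: zero-effect perturbation, returning 0")
        return 0.0
    return float(-effect.rho * sigma / denom)


def _library_sizes(rng: np.random.Generator, noise: NoiseModel, n: int) -> np.ndarray:
    if noise.library_size_cv == 0:
        return np.full(n, noise.mean_library_size)
    s2 = np.log1p(noise.library_size_cv**2)
    mu = np.log(noise.mean_library_size) - s2 / 2
    return rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n)


def _baseline(rng: np.random.Generator, noise: NoiseModel, n_genes: int) -> np.ndarray:
    if noise.baseline_expression is not None:
        base = np.asarray(noise.baseline_expression, dtype=float)
        if len(base) != n_genes or np.any(base <= 0):
            raise ValidationError("baseline_expression must be positive, one per gene")
        return base
    return rng.lognormal(mean=np.log(5.0), sigma=1.0, size=n_genes)


def _condition_counts(
    rng: np.random.Generator,
    rel_mean: np.ndarray,
    noise: NoiseModel,
    n_cells: int,
    fractions=(1.0, 0.0, 0.0),
    s_idx=(),
    g2m_idx=(),
    marker_log2fc: float = MARKER_LOG2FC,
):
    """NB counts for one condition; returns (counts, phase codes 0/1/2)."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or np.any(fractions < 0) or not np.isclose(fractions.sum(), 1):
        raise ValidationError("phase fractions must be a (G1, S, G2M) simplex")
    phases = rng.choice(3, size=n_cells, p=fractions)
    lib = _library_sizes(rng, noise, n_cells)
    counts = np.zeros((len(rel_mean), n_cells), dtype=np.int64)
    for ph in (0, 1, 2):
        cells = np.flatnonzero(phases == ph)
        if cells.size == 0:
            continue
        rel = rel_mean.copy()
        if ph == 1 and len(s_idx):
            rel[np.asarray(s_idx)] *= 2.0**marker_log2fc
        if ph == 2 and len(g2m_idx):
            rel[np.asarray(g2m_idx)] *= 2.0**marker_log2fc
        mu = np.outer(rel / rel.sum(), lib[cells])
        lam = rng.gamma(noise.nb_dispersion, mu / noise.nb_dispersion)
        counts[:, cells] = rng.poisson(lam)
    return counts, phases


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"g{i:05d}" for i in range(n)], dtype=object)


def _universe(rng, axis: AgingAxisSpec, noise: NoiseModel, n_s: int, n_g2m: int):
    """Gene ids, baselines, affected indices, aging LFC, marker indices."""
    gene_ids = _gene_ids(axis.n_genes)
    base = _baseline(rng, noise, axis.n_genes)
    n_marker = n_s + n_g2m
    if n_marker + axis.n_affected > axis.n_genes:
        raise ValidationError("marker blocks and affected set exceed the gene universe")
    s_idx = np.arange(axis.n_genes - n_marker, axis.n_genes - n_g2m)
    g2m_idx = np.arange(axis.n_genes - n_g2m, axis.n_genes)
    if n_marker and noise.baseline_expression is None:
        # cycle markers are well-detected genes by construction (that is why
        # they make usable marker lists); draw them from a moderate stratum
        marker_idx = np.concatenate([s_idx, g2m_idx])
        base[marker_idx] = rng.lognormal(np.log(20.0), 0.5, size=n_marker)
    if axis.affected_set is not None:
        affected = np.asarray(axis.affected_set, dtype=int)
    else:
        affected = rng.choice(axis.n_genes - n_marker, size=axis.n_affected, replace=False)
        affected.sort()
    aging = np.zeros(axis.n_genes)
    if axis.affected_lfc is not None:
        if len(axis.affected_lfc) != len(affected):
            raise ValidationError("affected_lfc length must match affected_set")
        aging[affected] = np.asarray(axis.affected_lfc, dtype=float)
    else:
        aging[affected] = rng.normal(0.0, axis.lfc_scale, size=len(affected))
    return gene_ids, base, affected, aging, s_idx, g2m_idx


def simulate_two_state(
    axis: AgingAxisSpec,
    noise: NoiseModel,
    n_young: int,
    n_old: int,
    seed: int = 0,
    fractions_young=(1.0, 0.0, 0.0),
    fractions_old=(1.0, 0.0, 0.0),
    n_s_markers: int = 0,
    n_g2m_markers: int = 0,
):
    """Simulate a young/old (early/late passage) two-state dataset.

    Old-state gene means are young means times ``2**aging_lfc``; both
    states can carry distinct cell-cycle phase compositions.  Returns
    ``(matrix, truth)``; ``truth.aging_lfc`` records the realized axis.
    """
    if n_young < 2 or n_old < 2:
        raise ValidationError("need at least 2 cells per state")
    rng = child_rng(seed, "simulate_two_state")
    gene_ids, base, affected, aging, s_idx, g2m_idx = _universe(
        rng, axis, noise, n_s_markers, n_g2m_markers
    )
    young, ph_y = _condition_counts(rng, base, noise, n_young, fractions_young, s_idx, g2m_idx)
    old, ph_o = _condition_counts(
        rng, base * 2.0**aging, noise, n_old, fractions_old, s_idx, g2m_idx
    )
    values = np.hstack([young, old])
    obs_ids = np.array(
        [f"young_{i:04d}" for i in range(n_young)] + [f"old_{i:04d}" for i in range(n_old)],
        dtype=object,
    )
    phase_names = np.array(["G1", "S", "G2M"])
    obs_meta = pd.DataFrame(
        {
            "state": ["young"] * n_young + ["old"] * n_old,
            "true_phase": phase_names[np.concatenate([ph_y, ph_o])],
        },
        index=pd.Index(obs_ids, name="obs_id"),
    )
    truth = SyntheticScreenTruth(
        gene_ids=gene_ids,
        aging_lfc=aging,
        affected_idx=affected,
        effects=[],
        seed=seed,
        sigma_axis=axis.lfc_scale,
        baseline=base,
        cellcycle_fractions={"young": tuple(fractions_young), "old": tuple(fractions_old)},
        s_genes=list(gene_ids[s_idx]),
        g2m_genes=list(gene_ids[g2m_idx]),
    )
    return GeneExpressionMatrix(values, gene_ids, obs_ids, obs_meta), truth


def simulate_screen(
    axis: AgingAxisSpec,
    effects: list[PerturbationEffectSpec],
    noise: NoiseModel,
    cells_per_perturbation: int = 200,
    n_nt: int = 200,
    seed: int = 0,
    fractions_nt=(1.0, 0.0, 0.0),
    fractions_by_tf: dict | None = None,
    n_s_markers: int = 0,
    n_g2m_markers: int = 0,
    shared_truth: SyntheticScreenTruth | None = None,
):
    """Simulate a Perturb-seq screen on the late-passage background.

    NT control cells express the late-passage (old-state) means, i.e.
    baseline times ``2**aging_lfc``; a perturbed condition's means are
    the NT means times ``2**(-rho * aging_lfc + off-axis noise)``.
    Passing ``shared_truth`` (from :func:`simulate_two_state`) reuses
    that run's realized universe — gene baselines, affected set and
    aging axis — so the screen and the two-state contrast describe the
    same synthetic biology, as they would in a real experiment.
    Returns ``(matrix, assignment frame, truth)``.
    """
    if n_nt < 1 or cells_per_perturbation < 1:
        raise ValidationError("need at least one NT control cell and one cell per perturbation")
    keys = [(e.tf, e.mode) for e in effects]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (tf, mode) perturbation specs")
    fractions_by_tf = fractions_by_tf or {}
    rng = child_rng(seed, "simulate_screen")
    if shared_truth is not None:
        if shared_truth.baseline is None:
            raise ValidationError("shared_truth carries no baseline expression")
        gene_ids = shared_truth.gene_ids
        base = shared_truth.baseline
        affected = np.asarray(shared_truth.affected_idx)
        aging = shared_truth.aging_lfc
        pos = {g: i for i, g in enumerate(gene_ids)}
        s_idx = np.array([pos[g] for g in shared_truth.s_genes], dtype=int)
        g2m_idx = np.array([pos[g] for g in shared_truth.g2m_genes], dtype=int)
        if n_s_markers or n_g2m_markers:
            raise ValidationError("marker blocks come from shared_truth; do not respecify")
    else:
        gene_ids, base, affected, aging, s_idx, g2m_idx = _universe(
            rng, axis, noise, n_s_markers, n_g2m_markers
        )
    base = base * 2.0**aging  # screen background: late-passage cells
    modes = sorted({e.mode for e in effects}) or ["CRA"]

    blocks, rows = [], []
    phase_names = np.array(["G1", "S", "G2M"])

    def add_condition(tf, mode, rel, n_cells, fractions):
        counts, ph = _condition_counts(rng, rel, noise, n_cells, fractions, s_idx, g2m_idx)
        start = sum(b.shape[1] for b in blocks)
        blocks.append(counts)
        for j in range(n_cells):
            rows.append(
                {
                    "obs_id": f"c{start + j:06d}",
                    "tf": tf,
                    "mode": mode,
                    "is_control": tf == NT_SENTINEL,
                    "true_phase": phase_names[ph[j]],
                }
            )

    for mode in modes:
        add_condition(NT_SENTINEL, mode, base, n_nt, fractions_nt)

    truth_lfc = {}
    for e in effects:
        pert = -e.rho * aging
        if e.off_axis_sd > 0:
            pert = pert.copy()
            pert[affected] += rng.normal(0.0, e.off_axis_sd, size=len(affected))
        # truth on the measurement scale: library normalization can only see
        # relative abundances, so every gene shifts by -log2(total-content ratio)
        shift = np.log2((base * 2.0**pert).sum() / base.sum())
        truth_lfc[(e.tf, e.mode)] = pert - shift
        fr = fractions_by_tf.get((e.tf, e.mode), fractions_nt)
        add_condition(e.tf, e.mode, base * 2.0**pert, cells_per_perturbation, fr)

    values = np.hstack(blocks)
    assign = pd.DataFrame(rows)
    obs_ids = assign["obs_id"].to_numpy(dtype=object)
    obs_meta = assign.set_index("obs_id")
    matrix = GeneExpressionMatrix(values, gene_ids, obs_ids, obs_meta)
    fractions_all = {("NT", m): tuple(fractions_nt) for m in modes}
    for e in effects:
        fractions_all[(e.tf, e.mode)] = tuple(
            fractions_by_tf.get((e.tf, e.mode), fractions_nt)
        )
    truth = SyntheticScreenTruth(
        gene_ids=gene_ids,
        aging_lfc=aging,
        affected_idx=affected,
        effects=list(effects),
        seed=seed,
        sigma_axis=axis.lfc_scale if shared_truth is None else shared_truth.sigma_axis,
        baseline=base,
        perturbation_lfc=truth_lfc,
        cellcycle_fractions=fractions_all,
        s_genes=list(gene_ids[s_idx]),
        g2m_genes=list(gene_ids[g2m_idx]),
    )
    return matrix, assign[["obs_id", "tf", "mode", "is_control"]], truth


def simulate_tf_network(
    truth: SyntheticScreenTruth,
    n_driver_tfs: int = 5,
    n_null_tfs: int = 45,
    targets_per_tf: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """TF -> target table consistent with the aging axis.

    Driver TFs draw their targets from the affected gene set, null TFs
    from the unaffected remainder; returns a (tf, target, is_driver)
    long table for the prioritization path.
    """
    rng = child_rng(seed, "simulate_tf_network")
    n_genes = len(truth.gene_ids)
    affected = np.asarray(truth.affected_idx)
    others = np.setdiff1d(np.arange(n_genes), affected)
    if targets_per_tf > min(len(affected), len(others)):
        raise ValidationError("targets_per_tf exceeds available genes")
    rows = []
    for i in range(n_driver_tfs):
        tgt = rng.choice(affected, size=targets_per_tf, replace=False)
        rows += [
            {"tf": f"DRV{i:02d}", "target": truth.gene_ids[t], "is_driver": True} for t in tgt
        ]
    for i in range(n_null_tfs):
        tgt = rng.choice(others, size=targets_per_tf, replace=False)
        rows += [
            {"tf": f"NUL{i:02d}", "target": truth.gene_ids[t], "is_driver": False} for t in tgt
        ]
    return pd.DataFrame(rows)


def simulate_coexpression(
    tf_targets: dict,
    n_cells: int = 500,
    noise: NoiseModel | None = None,
    seed: int = 0,
    effect_log2fc: float = 1.0,
    repressed: frozenset = frozenset(),
    n_background: int = 300,
):
    """Counts with latent-activity-driven TF/target covariation.

    Each TF gets a per-cell standard-normal latent activity; the TF gene
    and its targets scale by ``2**(effect * activity)`` (targets of a
    repressive TF by the negative).  ``n_background`` unregulated genes
    pad the universe — without them library normalization would cancel a
    shared latent factor outright.  Used to exercise regulon inference.
    """
    noise = noise or NoiseModel()
    rng = child_rng(seed, "simulate_coexpression")
    tfs = sorted(tf_targets)
    targets = sorted({g for ts in tf_targets.values() for g in ts})
    overlap = set(tfs) & set(targets)
    if overlap:
        raise ValidationError(f"genes cannot be both TF and target here: {sorted(overlap)[:3]}")
    background = [f"bg{i:04d}" for i in range(n_background)]
    gene_ids = np.array(tfs + targets + background, dtype=object)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    base = _baseline(rng, noise, len(gene_ids))
    log2fc = np.zeros((len(gene_ids), n_cells))
    for tf in tfs:
        act = rng.normal(size=n_cells)
        log2fc[gidx[tf]] += effect_log2fc * act
        sign = -1.0 if tf in repressed else 1.0
        for g in tf_targets[tf]:
            log2fc[gidx[g]] += sign * effect_log2fc * act
    rel = base[:, None] * 2.0**log2fc
    lib = _library_sizes(rng, noise, n_cells)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib
    lam = rng.gamma(noise.nb_dispersion, mu / noise.nb_dispersion)
    counts = rng.poisson(lam)
    obs_ids = np.array([f"c{i:05d}" for i in range(n_cells)], dtype=object)
    return GeneExpressionMatrix(counts, gene_ids, obs_ids)
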