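import numpy as np
import pytest

from trdp import (
    AgingAxisSpec,
    ComparisonSpec,
    NoiseModel,
    RunConfig,
    pseudobulk_lfc,
    simulate_two_state,
)


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def two_state_bundle(noise):
    """A mid-sized young/old simulation shared by recovery-style tests."""
    axis = AgingAxisSpec(n_genes=800, n_affected=400, lfc_scale=1.0)
    cfg = RunConfig(permutations=199, seed=7)
    m, truth = simulate_two_state(axis, noise, 200, 200, seed=7)
    young = list(m.obs_ids[:200])
    old = list(m.obs_ids[200:])
    aging = pseudobulk_lfc(m, ComparisonSpec(old, young, "old_vs_young"), cfg)
    return {
        "axis": axis,
        "cfg": cfg,
        "matrix": m,
        "truth": truth,
        "aging": aging,
        "young": young,
        "old": old,
    }


@pytest.fixture()
def tiny_counts():
    """Deterministic 30-gene x 12-cell counts matrix."""
    from trdp import GeneExpressionMatrix

    rng = np.random.default_rng(42)
    vals = rng.integers(0, 25, size=(30, 12))
    vals[:, 0] += 1  # no all-zero cells
    genes = [f"g{i:02d}" for i in range(30)]
    cells = [f"c{j:02d}" for j in range(12)]
    return GeneExpressionMatrix(vals, genes, cells)
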