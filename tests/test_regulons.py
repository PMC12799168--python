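"""AUCell scoring, module z-scores, repartition null, and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trdp import (
    ComparisonSpec,
    GeneExpressionMatrix,
    ModuleScoreMatrix,
    Regulon,
    TFTargetMap,
    ValidationError,
    aucell_matrix,
    aucell_score,
    build_module_scores,
    cluster_rows,
    differential_modules,
    infer_regulons,
    module_score,
    normalize_lognorm,
    repartition_null_from_scores,
    simulate_coexpression,
)


def brute_force_auc(ranking, members, top_fraction):
    """Independent oracle: walk the recovery step function rank by rank."""
    import math

    n = len(ranking)
    n_top = math.ceil(top_fraction * n)
    hits = set(members)
    found = 0
    area = 0
    for x in range(1, n_top + 1):
        if ranking[x - 1] in hits:
            found += 1
        area += found
    k = len(members)
    max_area = sum(min(x, k) for x in range(1, n_top + 1))
    return area / max_area


def _regulon(genes, **kw):
    kw.setdefault("min_size", 1)
    return Regulon("T", tuple(genes), **kw)


class TestAUCell:
    def test_members_on_top_score_one(self):
        genes = [f"g{i}" for i in range(20)]
        expr = np.arange(20, 0, -1)  # g0 highest
        assert aucell_score(expr, genes, _regulon(genes[:3]), 0.25) == 1.0

    def test_members_outside_top_score_zero(self):
        genes = [f"g{i}" for i in range(20)]
        expr = np.arange(20, 0, -1)
        assert aucell_score(expr, genes, _regulon(genes[-3:]), 0.25) == 0.0

    def test_fixed_ranking_matches_brute_force(self):
        """20-gene universe, 5-gene regulon, top 25%: printed ranking oracle."""
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(17)
        expr = rng.normal(size=20)
        members = ["g3", "g7", "g11", "g0", "g19"]
        ranking = [genes[i] for i in np.lexsort((np.arange(20), -expr))]
        expected = brute_force_auc(ranking, members, 0.25)
        assert aucell_score(expr, genes, _regulon(members), 0.25) == pytest.approx(
            expected, abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        genes = [f"g{i}" for i in range(50)]
        rng = np.random.default_rng(18)
        expr = rng.normal(size=50)
        reg = _regulon(list(rng.choice(genes, 8, replace=False)))
        base = aucell_score(expr, genes, reg, 0.2)
        for f in (np.exp, lambda x: 3 * x + 7, lambda x: x**3):
            assert aucell_score(f(expr), genes, reg, 0.2) == base

    def test_matrix_agrees_with_per_cell(self, tiny_counts):
        ln = normalize_lognorm(tiny_counts, scale=100)
        reg = _regulon(list(ln.gene_ids[:5]))
        mat = aucell_matrix(ln, reg, 0.2)
        for j, obs in enumerate(ln.obs_ids):
            assert mat[obs] == pytest.approx(
                aucell_score(ln.values[:, j], ln.gene_ids, reg, 0.2), abs=1e-12
            )

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            aucell_score(np.ones(5), [f"g{i}" for i in range(5)], _regulon(["x"]), 0.2)


class TestModuleScore:
    def test_identity_zero_and_antisymmetry(self):
        rng = np.random.default_rng(19)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        assert module_score(a, a.copy()) == 0.0
        assert module_score(a, b) == pytest.approx(-module_score(b, a), abs=1e-12)

    def test_matches_welch_statistic(self):
        """Matches scipy's independently implemented Welch t statistic."""
        rng = np.random.default_rng(20)
        a = rng.normal(0.5, 0.1, size=200)
        b = rng.normal(0.4, 0.1, size=200)
        expected = stats.ttest_ind(a, b, equal_var=False).statistic
        assert module_score(a, b) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_variance_guard(self):
        assert module_score([1.0, 1.0], [1.0, 1.0]) == 0.0
        capped = module_score([2.0, 2.0], [1.0, 1.0])
        assert capped == pytest.approx(1e6)


class TestInferRegulons:
    def test_driven_targets_recovered(self):
        """A TF driving 30 targets is recovered at >= 80% at n=500 cells."""
        targets = [f"t{i:02d}" for i in range(30)]
        m = simulate_coexpression({"TF1": targets}, n_cells=500, seed=23)
        ln = normalize_lognorm(m)
        regs = infer_regulons(ln, [TFTargetMap("TF1", targets)], min_abs_corr=0.1)
        assert len(regs) == 1
        assert regs[0].mode == "activating"
        assert len(set(regs[0].genes) & set(targets)) >= 24

    def test_uncorrelated_map_dropped(self):
        targets = [f"t{i:02d}" for i in range(12)]
        m = simulate_coexpression({"TF1": targets}, n_cells=400, seed=24, effect_log2fc=0.0)
        ln = normalize_lognorm(m)
        regs = infer_regulons(ln, [TFTargetMap("TF1", targets)], min_abs_corr=0.2)
        assert regs == []

    def test_no_pruning_at_zero_threshold(self, tiny_counts):
        ln = normalize_lognorm(tiny_counts)
        targets = list(ln.gene_ids[1:20])
        regs = infer_regulons(
            ln, [TFTargetMap(str(ln.gene_ids[0]), targets)], min_abs_corr=0.0, min_size=5
        )
        assert set(regs[0].genes) == set(targets)

    def test_absent_tf_skipped_with_warning(self, tiny_counts, caplog):
        ln = normalize_lognorm(tiny_counts)
        with caplog.at_level("WARNING", logger="trdp"):
            regs = infer_regulons(ln, [TFTargetMap("GHOST", list(ln.gene_ids[:12]))])
        assert regs == []
        assert "GHOST" in caplog.text


class TestDifferentialModules:
    def _msm(self, row):
        scores = pd.DataFrame([row], index=["ref"], columns=[f"m{i}" for i in range(len(row))])
        return ModuleScoreMatrix(scores, pd.Series({"ref": 10}), pd.Series({"ref": 10}))

    def test_threshold_rule(self):
        msm = self._msm([6.1, -7.2, 4.9])
        assert differential_modules(msm, "ref", cut=5) == ["m0", "m1"]

    def test_zero_cut_keeps_all(self):
        msm = self._msm([6.1, -7.2, 4.9])
        assert differential_modules(msm, "ref", cut=0) == ["m0", "m1", "m2"]

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            differential_modules(self._msm([1.0, 2.0]), "nope")


class TestRepartitionNull:
    def test_deterministic_and_centered(self):
        rng = np.random.default_rng(25)
        a, b = rng.normal(0.5, 0.1, 150), rng.normal(0.52, 0.1, 150)
        s1 = repartition_null_from_scores(a, b, n_draws=1000, seed=3)
        s2 = repartition_null_from_scores(a, b, n_draws=1000, seed=3)
        np.testing.assert_array_equal(s1, s2)
        assert abs(s1.mean()) < 0.2

    def test_minimum_draws_enforced(self):
        with pytest.raises(ValidationError):
            repartition_null_from_scores(np.ones(10), np.ones(10), n_draws=10)


class TestClusterRows:
    def _msm(self, rows, labels):
        scores = pd.DataFrame(
            rows, index=labels, columns=[f"m{i}" for i in range(len(rows[0]))]
        )
        n = pd.Series(10, index=scores.index)
        return ModuleScoreMatrix(scores, n, n.copy())

    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(26)
        r = rng.normal(size=6)
        msm = self._msm([r, r.copy(), rng.normal(size=6)], ["a", "b", "c"])
        _, link, _ = cluster_rows(msm)
        # first merge joins the two identical rows at height 0
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_anticorrelated_rows_merge_last(self):
        rng = np.random.default_rng(27)
        r = rng.normal(size=8)
        mid = r + rng.normal(scale=0.4, size=8)
        msm = self._msm([r, mid, -r], ["a", "b", "c"])
        ordered, link, newick = cluster_rows(msm)
        assert link[-1, 2] == pytest.approx(2.0, abs=0.1)
        assert newick.endswith(";")

    def test_linkage_matches_brute_force_agglomeration(self):
        """6-row toy: heights equal an independent average-linkage merge."""
        rng = np.random.default_rng(28)
        rows = rng.normal(size=(6, 10))
        labels = list("abcdef")
        msm = self._msm(list(rows), labels)
        _, link, _ = cluster_rows(msm)

        # independent oracle: naive agglomeration over all pairs
        d = 1 - np.corrcoef(rows)
        clusters = {i: [i] for i in range(6)}
        heights = []
        nxt = 6
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a < b:
                        h = np.mean(
                            [d[i, j] for i in clusters[a] for j in clusters[b]]
                        )
                        if best is None or h < best[0]:
                            best = (h, a, b)
            h, a, b = best
            heights.append(h)
            clusters[nxt] = clusters.pop(a) + clusters.pop(b)
            nxt += 1
        np.testing.assert_allclose(sorted(link[:, 2]), sorted(heights), atol=1e-10)

    def test_constant_row_pushed_to_max_distance(self, caplog):
        rng = np.random.default_rng(29)
        msm = self._msm(
            [rng.normal(size=5), rng.normal(size=5), np.zeros(5)], ["a", "b", "c"]
        )
        with caplog.at_level("WARNING", logger="trdp"):
            _, link, _ = cluster_rows(msm)
        assert "constant" in caplog.text
        assert link[-1, 2] == pytest.approx(2.0)


class TestModuleScoresEndToEnd:
    def test_build_scores_shape_and_reference(self, tiny_counts):
        ln = normalize_lognorm(tiny_counts)
        regs = [
            Regulon("R1", tuple(ln.gene_ids[:8]), min_size=5),
            Regulon("R2", tuple(ln.gene_ids[10:18]), min_size=5),
        ]
        ids = list(ln.obs_ids)
        comps = [
            ComparisonSpec(ids[:6], ids[6:], "x_vs_y"),
            ComparisonSpec(ids[6:], ids[:6], "y_vs_x"),
        ]
        msm = build_module_scores(ln, regs, comps, top_fraction=0.3)
        assert msm.scores.shape == (2, 2)
        np.testing.assert_allclose(
            msm.scores.loc["x_vs_y"], -msm.scores.loc["y_vs_x"], atol=1e-12
        )


from trdp import PerturbationEffectSpec


def _sign_homogeneous_regulons(truth, n_regulons=6, size=20):
    """Regulons carved from the aging-affected genes, homogeneous in sign."""
    lfc = truth.aging_lfc
    up = [g for g, v in zip(truth.gene_ids, lfc) if v > 0.2]
    down = [g for g, v in zip(truth.gene_ids, lfc) if v < -0.2]
    regs = []
    for k in range(n_regulons):
        pool = up if k % 2 == 0 else down
        chunk = pool[(k // 2) * size : (k // 2) * size + size]
        regs.append(Regulon(f"AX{k}", tuple(chunk), min_size=10))
    return regs


class TestTopHitSimilarity:
    def test_strong_rejuvenators_cluster_together(self, noise):
        """Perturbations with rho >= 0.5 sit closer to each other than to nulls.

        Module-score rows (one per perturbation vs NT) are clustered by
        correlation distance over aging-axis regulons; the rejuvenating
        perturbations share a coherent module signature while null rows
        are uncorrelated noise.
        """
        from trdp import (
            AgingAxisSpec,
            ComparisonSpec,
            build_module_scores,
            simulate_screen,
            simulate_two_state,
        )

        axis = AgingAxisSpec(n_genes=800, n_affected=400, lfc_scale=1.0)
        ok = 0
        for run in range(20):
            m, truth = simulate_two_state(axis, noise, 10, 10, seed=5000 + run)
            effects = [
                PerturbationEffectSpec(f"T{i}", "CRA", 0.6 if i < 4 else 0.0, 0.2 if i < 4 else 0.0)
                for i in range(8)
            ]
            ms, assign, _ = simulate_screen(
                axis, effects, noise, 100, 100, seed=6000 + run, shared_truth=truth
            )
            ln = normalize_lognorm(ms)
            regs = _sign_homogeneous_regulons(truth)
            nt = assign.loc[assign.is_control, "obs_id"].tolist()
            comps = [
                ComparisonSpec(
                    assign.loc[assign.tf == f"T{i}", "obs_id"].tolist(), nt, f"T{i}"
                )
                for i in range(8)
            ]
            msm = build_module_scores(ln, regs, comps, top_fraction=0.1)
            x = msm.scores.to_numpy(dtype=float)
            xc = x - x.mean(axis=1, keepdims=True)
            norm = np.linalg.norm(xc, axis=1)
            dist = 1 - (xc @ xc.T) / np.outer(norm, norm)
            hit_idx, null_idx = list(range(4)), list(range(4, 8))
            within = max(dist[i, j] for i in hit_idx for j in hit_idx if i != j)
            between = min(dist[i, j] for i in hit_idx for j in null_idx)
            if within < between:
                ok += 1
        assert ok >= 18


class TestDifferentialModuleRecovery:
    def test_axis_driven_regulons_selected(self, noise):
        """3 aging-driven regulons of 10 clear |z| > 5 between the states."""
        from trdp import AgingAxisSpec, ComparisonSpec, build_module_scores, simulate_two_state

        axis = AgingAxisSpec(n_genes=800, n_affected=150, lfc_scale=0.6)
        ok = 0
        for run in range(20):
            m, truth = simulate_two_state(axis, noise, 300, 300, seed=7000 + run)
            ln = normalize_lognorm(m)
            driven = _sign_homogeneous_regulons(truth, n_regulons=3, size=20)
            unaffected = [
                g for g, v in zip(truth.gene_ids, truth.aging_lfc) if v == 0
            ]
            null_regs = [
                Regulon(f"NL{k}", tuple(unaffected[k * 30 : k * 30 + 30]), min_size=10)
                for k in range(7)
            ]
            old = list(m.obs_ids[300:])
            young = list(m.obs_ids[:300])
            msm = build_module_scores(
                ln, driven + null_regs, [ComparisonSpec(old, young, "old_vs_young")], 0.1
            )
            selected = differential_modules(msm, "old_vs_young", cut=5.0)
            if set(selected) == {r.name for r in driven}:
                ok += 1
        assert ok >= 18
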