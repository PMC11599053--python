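"""Ablation trajectories against full-recompute oracles, plus curve summaries."""

import numpy as np
import pytest

from isletnet import (
    GenerationConfig,
    ablate_trajectory,
    build_contact_graph,
    delta_beta_connected_fraction,
    generate_islet_cohort,
    run_ablation,
    threshold_crossing,
)
from isletnet.ablation import AblationCurve

from conftest import brute_force_connected_fraction, make_arch, random_arch


class TestTrajectory:
    def test_single_pair_trajectory(self):
        arch = make_arch([[0, 0, 0], [15, 0, 0]], ["beta", "delta"])
        g = build_contact_graph(arch, 30.0)
        traj = ablate_trajectory(g, seed=0)
        np.testing.assert_allclose(traj, [[0.0, 1.0], [1.0, 0.0]])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_full_recompute_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arch = random_arch(rng, n_cells=40)
        g = build_contact_graph(arch, 30.0)
        traj = ablate_trajectory(g, seed=seed)
        # replay the same deletion order and recompute from raw coordinates
        betas = sorted(
            n for n, t in g.graph.nodes(data="cell_type") if t == "beta"
        )
        order = np.random.default_rng(seed).permutation(len(betas))
        removed = []
        for step in range(len(betas) + 1):
            expect = brute_force_connected_fraction(arch, 30.0, removed)
            assert traj[step, 1] == pytest.approx(expect)
            if step < len(betas):
                removed.append(betas[order[step]])

    def test_monotone_and_endpoints(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            arch = random_arch(rng, n_cells=60)
            g = build_contact_graph(arch, 30.0)
            traj = ablate_trajectory(g, seed=int(rng.integers(1 << 16)))
            assert np.all(np.diff(traj[:, 1]) <= 0)
            assert traj[0, 1] == pytest.approx(delta_beta_connected_fraction(g))
            assert traj[-1, 1] == 0.0

    def test_requires_beta_and_delta(self):
        g = build_contact_graph(
            make_arch([[0, 0, 0], [5, 0, 0]], ["alpha", "delta"]), 30.0
        )
        with pytest.raises(ValueError, match="beta"):
            ablate_trajectory(g, seed=0)
        g = build_contact_graph(
            make_arch([[0, 0, 0], [5, 0, 0]], ["alpha", "beta"]), 30.0
        )
        with pytest.raises(ValueError, match="delta"):
            ablate_trajectory(g, seed=0)


class TestRunAblation:
    def test_single_islet_single_replicate_equals_trajectory(self):
        rng = np.random.default_rng(3)
        arch = random_arch(rng, n_cells=50)
        curve = run_ablation([arch], 30.0, n_replicates=1, grid_step=0.01, seed=4)
        # curve endpoints agree with the trajectory contract
        g = build_contact_graph(arch, 30.0)
        assert curve.mean[0] == pytest.approx(delta_beta_connected_fraction(g))
        assert curve.mean[-1] == 0.0
        np.testing.assert_array_equal(curve.ci_low, curve.mean)
        np.testing.assert_array_equal(curve.ci_high, curve.mean)

    def test_determinism(self, small_config):
        cohort = generate_islet_cohort(small_config, 3, seed=2)
        c1 = run_ablation(cohort, 30.0, n_replicates=5, seed=8)
        c2 = run_ablation(cohort, 30.0, n_replicates=5, seed=8)
        np.testing.assert_array_equal(c1.mean, c2.mean)
        np.testing.assert_array_equal(c1.ci_low, c2.ci_low)
        np.testing.assert_array_equal(c1.islet_means, c2.islet_means)

    def test_ci_brackets_mean(self, small_config):
        cohort = generate_islet_cohort(small_config, 4, seed=1)
        curve = run_ablation(cohort, 30.0, n_replicates=3, seed=1)
        assert np.all(curve.ci_low <= curve.mean + 1e-12)
        assert np.all(curve.ci_high >= curve.mean - 1e-12)

    def test_islet_without_delta_cells_skipped_with_warning(self, caplog):
        good = make_arch(
            [[0, 0, 0], [10, 0, 0]], ["beta", "delta"], islet_id="good"
        )
        bad = make_arch(
            [[0, 0, 0], [10, 0, 0]], ["beta", "alpha"], islet_id="no_delta"
        )
        with caplog.at_level("WARNING", logger="isletnet.ablation"):
            curve = run_ablation([good, bad], 30.0, n_replicates=2, seed=0)
        assert curve.n_islets == 1
        assert "no_delta" in caplog.text

    def test_all_islets_skipped_is_an_error(self):
        bad = make_arch([[0, 0, 0]], ["alpha"])
        with pytest.raises(ValueError):
            run_ablation([bad], 30.0, seed=0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_ablation([], 30.0)

    def test_across_seed_stability_at_75pct(self):
        # dense regime: many beta neighbours per delta-cell, so the value at
        # 75% deletion barely moves between cohort seeds
        cfg = GenerationConfig(n_cells=500, seed=0)
        vals = []
        for seed in range(10):
            cohort = generate_islet_cohort(cfg, 2, seed=100 + seed)
            curve = run_ablation(cohort, 30.0, n_replicates=5, seed=seed)
            vals.append(curve.value_at(0.75))
        assert np.std(vals, ddof=1) <= 0.05


class TestThresholdCrossing:
    @staticmethod
    def _curve(grid, mean):
        grid = np.asarray(grid, float)
        mean = np.asarray(mean, float)
        return AblationCurve(
            fraction_deleted=grid,
            mean=mean,
            ci_low=mean,
            ci_high=mean,
            islet_means=mean[None, :],
            islet_ids=("islet_000",),
            n_replicates_per_islet=1,
            seed=0,
        )

    def test_step_curve_crossing(self):
        grid = np.round(np.arange(0, 1.01, 0.1), 10)
        mean = np.where(grid < 0.8, 1.0, 0.0)
        res = threshold_crossing(self._curve(grid, mean), level=0.9)
        assert res.crossed and res.fraction_deleted == pytest.approx(0.8)

    def test_never_crossing_flagged(self):
        grid = np.linspace(0, 1, 11)
        res = threshold_crossing(self._curve(grid, np.full(11, 0.95)), 0.9)
        assert res == (1.0, False)

    def test_stable_under_grid_refinement(self, small_config):
        cohort = generate_islet_cohort(small_config, 3, seed=6)
        coarse = run_ablation(cohort, 30.0, n_replicates=10, grid_step=0.01, seed=5)
        fine = run_ablation(cohort, 30.0, n_replicates=10, grid_step=0.001, seed=5)
        fc = threshold_crossing(coarse, 0.9).fraction_deleted
        ff = threshold_crossing(fine, 0.9).fraction_deleted
        assert abs(fc - ff) <= 0.01 + 1e-9

    def test_invalid_level_rejected(self, small_config):
        cohort = generate_islet_cohort(small_config, 1, seed=0)
        curve = run_ablation(cohort, 30.0, n_replicates=1, seed=0)
        with pytest.raises(ValueError):
            threshold_crossing(curve, level=1.5)
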