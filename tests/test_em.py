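"""EM fitting: posterior correctness, monotonicity, parameter recovery."""

import numpy as np
import pytest

from subclonemix import (
    ConfigSpace,
    Dataset,
    EMOptions,
    ModelParams,
    SimConfig,
    compute_baseline_scale,
    curate_baseline,
    fit,
    simulate_dataset,
    total_loglik,
)
from subclonemix.em import e_step, m_step
from subclonemix.likelihood import PackedData, segment_loglik_matrix
from tests import oracle
from tests.conftest import make_segment

FAST = EMOptions(seed=1, restarts=3, max_iter=30, phi_grid=50)


def _fitted_inputs(sim_config):
    ds, truth = simulate_dataset(sim_config)
    baseline = compute_baseline_scale(ds, curate_baseline(ds))
    return ds, truth, baseline


class TestEStep:
    def test_rows_normalize(self, tiny_dataset, tiny_params_k2, space2,
                            unit_baseline):
        packed = PackedData.from_dataset(tiny_dataset)
        gamma, _ = e_step(packed, tiny_params_k2, unit_baseline, space2)
        assert np.allclose(gamma.sum(axis=(1, 2)), 1.0, atol=1e-10)

    def test_point_mass_prior_gives_point_mass_posterior(
        self, tiny_dataset, space2, unit_baseline
    ):
        H = len(space2.configs)
        rho = np.zeros((2, H))
        rho[:, space2.config_index("PM")] = 1.0
        params = ModelParams(np.array([0.5]), np.array([1.0]), rho)
        packed = PackedData.from_dataset(tiny_dataset)
        gamma, _ = e_step(packed, params, unit_baseline, space2)
        assert np.allclose(gamma.max(axis=(1, 2)), 1.0, atol=1e-12)

    def test_matches_direct_bayes_posterior(
        self, tiny_dataset, tiny_params_k2, space2, unit_baseline
    ):
        packed = PackedData.from_dataset(tiny_dataset)
        gamma, ll = e_step(packed, tiny_params_k2, unit_baseline, space2)
        want = oracle.posterior_direct(
            tiny_dataset, tiny_params_k2, unit_baseline.scale, space2
        )
        assert np.allclose(gamma, want, atol=1e-10)
        assert ll == pytest.approx(
            oracle.total_loglik_exhaustive(
                tiny_dataset, tiny_params_k2, unit_baseline.scale, space2
            ),
            rel=1e-8,
        )


class TestMStep:
    def test_uniform_responsibilities_give_uniform_pi(
        self, tiny_dataset, tiny_params_k2, space2, unit_baseline
    ):
        packed = PackedData.from_dataset(tiny_dataset)
        H = len(space2.configs)
        gamma = np.full((2, 2, H), 1.0 / (2 * H))
        grid = np.linspace(0.01, 0.99, 20)
        grid_ll = segment_loglik_matrix(packed, grid, unit_baseline, space2)
        params, _ = m_step(
            packed, gamma, tiny_params_k2, unit_baseline, space2, FAST,
            grid, grid_ll,
        )
        assert np.allclose(params.pi, 0.5)
        assert np.allclose(params.rho.sum(axis=1), 1.0)

    def test_diploid_only_segment_is_flat_in_phi(self, space2, unit_baseline):
        """A PM-locked segment with no SNP sites gives a phi-flat objective;
        the tie breaks to the lowest grid point."""
        seg = make_segment("s", 100, 110, [])
        packed = PackedData.from_dataset(Dataset(segments=[seg]))
        H = len(space2.configs)
        gamma = np.zeros((1, 1, H))
        gamma[0, 0, space2.config_index("PM")] = 1.0
        grid = np.linspace(0.01, 0.99, 20)
        grid_ll = segment_loglik_matrix(packed, grid, unit_baseline, space2)
        start = ModelParams(
            np.array([0.5]), np.array([1.0]), np.full((1, H), 1.0 / H)
        )
        params, _ = m_step(
            packed, gamma, start, unit_baseline, space2, FAST, grid, grid_ll
        )
        assert params.phi[0] == pytest.approx(0.01)


class TestFit:
    def test_clonal_recovery(self):
        """Single population at prevalence 0.8: the K=1 fit recovers it."""
        ds, truth, baseline = _fitted_inputs(
            SimConfig(J=40, phi_true=(0.8,), seed=21)
        )
        res = fit(ds, 1, baseline, ConfigSpace.build(3), FAST)
        assert res.params.phi[0] == pytest.approx(0.8, abs=0.05)

    def test_two_subclone_recovery(self):
        ds, truth, baseline = _fitted_inputs(
            SimConfig(J=40, phi_true=(0.2, 0.8), seed=22)
        )
        res = fit(ds, 2, baseline, ConfigSpace.build(3), FAST)
        assert res.params.phi == pytest.approx([0.2, 0.8], abs=0.05)

    def test_trace_monotone_and_phi_sorted(self):
        ds, _, baseline = _fitted_inputs(
            SimConfig(J=15, phi_true=(0.3, 0.7), seed=23)
        )
        res = fit(ds, 2, baseline, ConfigSpace.build(3), FAST)
        assert np.all(np.diff(res.loglik_trace) >= -1e-10)
        assert np.all(np.diff(res.params.phi) >= 0)

    def test_responsibilities_and_map_fields_consistent(self):
        ds, _, baseline = _fitted_inputs(
            SimConfig(J=12, phi_true=(0.6,), seed=24)
        )
        space = ConfigSpace.build(3)
        res = fit(ds, 1, baseline, space, FAST)
        assert np.allclose(res.responsibilities.sum(axis=(1, 2)), 1.0,
                           atol=1e-10)
        assert res.segment_prevalence == pytest.approx(
            res.params.phi[res.map_subclone]
        )
        labels = [space.configs[h].label for h in res.map_config]
        assert labels == res.map_config_labels

    def test_refit_from_own_solution_is_stable(self):
        ds, _, baseline = _fitted_inputs(
            SimConfig(J=15, phi_true=(0.7,), seed=25)
        )
        space = ConfigSpace.build(3)
        res = fit(ds, 1, baseline, space, FAST)
        L_again = total_loglik(ds, res.params, baseline, space)
        assert L_again == pytest.approx(res.loglik, rel=1e-9)
        res2 = fit(ds, 1, baseline, space, FAST,
                   warm_starts=[res.params.phi])
        assert res2.loglik >= res.loglik - abs(res.loglik) * FAST.rel_tol

    def test_more_components_than_segments_warns(self):
        ds, _ = simulate_dataset(
            SimConfig(J=3, phi_true=(0.6,), seed=26, snp_per_segment=5)
        )
        baseline = compute_baseline_scale(ds, ds.baseline_ids())
        with pytest.warns(UserWarning, match="exceeds the number of segments"):
            fit(ds, 5, baseline, ConfigSpace.build(3),
                EMOptions(seed=1, restarts=1, max_iter=5, phi_grid=20))

    def test_em_reaches_dense_grid_optimum_on_tiny_instance(
        self, space2, unit_baseline
    ):
        """On an exhaustively searchable instance the EM solution is no
        worse than the best point on a dense (phi x h-assignment) grid."""
        segs = [
            make_segment("a", 100, 160, [(4, 5), (5, 5)]),
            make_segment("b", 100, 110, [(2, 4)], start=20_000),
        ]
        ds = Dataset(segments=segs)
        res = fit(ds, 1, unit_baseline, space2,
                  EMOptions(seed=0, restarts=4, max_iter=50, phi_grid=60))
        H = len(space2.configs)
        best = -np.inf
        for phi in np.linspace(0.01, 0.99, 197):
            for h_a in range(H):
                for h_b in range(H):
                    rho = np.zeros((2, H))
                    rho[0, h_a] = rho[1, h_b] = 1.0
                    params = ModelParams(np.array([phi]), np.array([1.0]), rho)
                    best = max(
                        best,
                        total_loglik(ds, params, unit_baseline, space2),
                    )
        assert res.loglik >= best - 1e-3


def test_em_options_validation():
    with pytest.raises(ValueError):
        EMOptions(max_iter=0)
    with pytest.raises(ValueError):
        EMOptions(phi_min=0.5, phi_max=0.2)
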