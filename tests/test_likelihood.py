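"""The Poisson-binomial likelihood against closed forms and brute force."""

import numpy as np
import pytest

from subclonemix import (
    BaselineScale,
    Dataset,
    ModelParams,
    avg_baf,
    avg_copy_number,
    expected_depth,
    segment_loglik,
    site_loglik,
    total_loglik,
)
from subclonemix.likelihood import (
    LAMBDA_FLOOR,
    PackedData,
    segment_loglik_matrix,
)
from tests import oracle
from tests.conftest import make_segment


class TestAvgCopyNumber:
    @pytest.mark.parametrize(
        "phi,n_h,expected",
        [(0.0, 5, 2.0), (1.0, 3, 3.0), (0.8, 3, 2.8), (0.5, 0, 1.0)],
    )
    def test_closed_form(self, phi, n_h, expected):
        assert avg_copy_number(phi, n_h) == pytest.approx(expected)


class TestExpectedDepth:
    def test_baseline_self_case_collapses_to_tumor_reads(self):
        """With S = {s} and j = s at copy number 2, the expectation equals
        the observed tumor reads of s for any prevalence."""
        seg = make_segment("s", 5000, 5700, [])
        baseline = BaselineScale(scale=5700 / 5000, source_ids=("s",))
        for phi in (0.1, 0.5, 0.9):
            assert expected_depth(seg, phi, 2, baseline) == pytest.approx(5700)

    def test_hand_evaluated_gain(self):
        seg = make_segment("j", 10_000, 0, [])
        baseline = BaselineScale(scale=1.1, source_ids=("s",))
        assert expected_depth(seg, 0.8, 3, baseline) == pytest.approx(15_400)

    def test_zero_copy_pure_tumor_floored(self):
        seg = make_segment("j", 10_000, 0, [])
        baseline = BaselineScale(scale=1.0, source_ids=("s",))
        assert expected_depth(seg, 1.0, 0, baseline) == LAMBDA_FLOOR

    def test_zero_normal_depth_rejected(self):
        seg = make_segment("j", 0, 10, [])
        baseline = BaselineScale(scale=1.0, source_ids=("s",))
        with pytest.raises(ValueError, match="zero normal depth"):
            expected_depth(seg, 0.5, 2, baseline)


class TestAvgBaf:
    def test_balanced_states_stay_half(self, space3):
        ab = space3.genotypes[space3.genotype_index("AB")].baf
        for phi in (0.0, 0.3, 1.0):
            assert avg_baf(phi, ab, 2) == pytest.approx(0.5)

    def test_pure_normal_is_half(self, space3):
        for g in space3.genotypes:
            assert avg_baf(0.0, g.baf, 3) == pytest.approx(0.5)

    def test_pure_tumor_loh_reaches_clamped_extreme(self, space3):
        bb = space3.genotypes[space3.genotype_index("BB")].baf
        assert avg_baf(1.0, bb, 2) == pytest.approx(0.99)

    def test_zero_denominator_returns_mu0(self):
        assert avg_baf(1.0, 0.3, 0) == pytest.approx(0.5)

    def test_monotone_in_phi_for_unbalanced_genotype(self, space3):
        b = space3.genotypes[space3.genotype_index("ABB")].baf
        phis = np.linspace(0, 1, 50)
        vals = [avg_baf(p, b, 3) for p in phis]
        assert np.all(np.diff(vals) > 0)


class TestSiteLoglik:
    def test_degenerate_q_reduces_to_single_binomial(self):
        from scipy import stats

        from subclonemix import ConfigSpace

        space = ConfigSpace.build(3, sigma=0.0)
        hi = space.config_index("PM")
        got = site_loglik(3, 8, hi, 0.4, space)
        assert got == pytest.approx(stats.binom.logpmf(3, 8, 0.5), abs=1e-12)

    def test_empty_observation_is_zero(self, space3):
        assert site_loglik(0, 0, space3.config_index("PM"), 0.5, space3) == 0.0

    @pytest.mark.parametrize("h_label", ["P/M", "PP/MM", "PM", "PPM/PMM"])
    @pytest.mark.parametrize("b,d", [(0, 1), (2, 5), (5, 5), (1, 4)])
    def test_matches_direct_summation(self, space3, h_label, b, d):
        hi = space3.config_index(h_label)
        got = site_loglik(b, d, hi, 0.37, space3)
        want = oracle.site_loglik_direct(b, d, hi, 0.37, space3)
        assert got == pytest.approx(want, abs=1e-10)


class TestSegmentLoglik:
    def test_empty_site_list_is_poisson_only(self, space3, unit_baseline):
        from scipy import stats

        seg = make_segment("s1", 100, 115, [])
        hi = space3.config_index("PM")
        lam = 0.5 * 2.0 * 100 * unit_baseline.scale
        got = segment_loglik(seg, hi, 0.5, unit_baseline, space3)
        assert got == pytest.approx(stats.poisson.logpmf(115, lam), abs=1e-12)

    @pytest.mark.parametrize("h_label", ["EMPTY", "P/M", "PP/MM", "PM"])
    def test_matches_exhaustive_enumeration(self, space2, unit_baseline,
                                            h_label):
        seg = make_segment("s1", 100, 110, [(1, 3), (2, 4)])
        hi = space2.config_index(h_label)
        got = segment_loglik(seg, hi, 0.6, unit_baseline, space2)
        want = np.log(
            oracle.segment_prob_exhaustive(
                seg, hi, 0.6, unit_baseline.scale, space2
            )
        )
        assert got == pytest.approx(want, abs=1e-10)


class TestTotalLoglik:
    def test_point_mass_mixture_collapses(self, space2, unit_baseline):
        """J=1, K=1 and a rho point mass reduce the mixture to one
        segment log-likelihood."""
        seg = make_segment("s1", 100, 110, [(1, 3)])
        ds = Dataset(segments=[seg])
        hi = space2.config_index("PM")
        rho = np.zeros((1, len(space2.configs)))
        rho[0, hi] = 1.0
        params = ModelParams(phi=np.array([0.7]), pi=np.array([1.0]), rho=rho)
        got = total_loglik(ds, params, unit_baseline, space2)
        want = segment_loglik(seg, hi, 0.7, unit_baseline, space2)
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_exhaustive_enumeration(
        self, tiny_dataset, tiny_params_k2, space2, unit_baseline
    ):
        got = total_loglik(tiny_dataset, tiny_params_k2, unit_baseline, space2)
        want = oracle.total_loglik_exhaustive(
            tiny_dataset, tiny_params_k2, unit_baseline.scale, space2
        )
        assert got == pytest.approx(want, rel=1e-8)

    def test_label_switching_symmetry(
        self, tiny_dataset, tiny_params_k2, space2, unit_baseline
    ):
        """Jointly permuting (phi, pi) leaves the mixture value unchanged;
        checked against the raw mixture formula since the container
        canonicalizes label order."""
        ll = total_loglik(tiny_dataset, tiny_params_k2, unit_baseline, space2)
        phi = tiny_params_k2.phi[::-1]
        pi = tiny_params_k2.pi[::-1]
        permuted = 0.0
        for j, seg in enumerate(tiny_dataset.segments):
            seg_prob = 0.0
            for k in range(2):
                for hi in range(len(space2.configs)):
                    seg_prob += (
                        pi[k]
                        * tiny_params_k2.rho[j, hi]
                        * np.exp(
                            segment_loglik(
                                seg, hi, float(phi[k]), unit_baseline, space2
                            )
                        )
                    )
            permuted += np.log(seg_prob)
        assert ll == pytest.approx(permuted, rel=1e-10)

    def test_segment_order_invariance(
        self, tiny_dataset, tiny_params_k2, space2, unit_baseline
    ):
        ll = total_loglik(tiny_dataset, tiny_params_k2, unit_baseline, space2)
        rev = Dataset(segments=list(reversed(tiny_dataset.segments)))
        ll_rev = total_loglik(rev, tiny_params_k2, unit_baseline, space2)
        assert ll == pytest.approx(ll_rev, abs=1e-12)

    def test_site_order_invariance(
        self, tiny_dataset, tiny_params_k2, space2, unit_baseline
    ):
        ll = total_loglik(tiny_dataset, tiny_params_k2, unit_baseline, space2)
        for seg in tiny_dataset.segments:
            seg.sites.reverse()
        ll2 = total_loglik(tiny_dataset, tiny_params_k2, unit_baseline, space2)
        assert ll == pytest.approx(ll2, abs=1e-12)

    def test_duplicated_component_identity(
        self, tiny_dataset, space2, unit_baseline
    ):
        """Splitting a component's pi mass over a duplicate leaves the
        mixture likelihood unchanged."""
        H = len(space2.configs)
        rho = np.full((2, H), 1.0 / H)
        two = ModelParams(np.array([0.3, 0.7]), np.array([0.4, 0.6]), rho)
        three = ModelParams(
            np.array([0.3, 0.7, 0.7]), np.array([0.4, 0.25, 0.35]), rho.copy()
        )
        ll2 = total_loglik(tiny_dataset, two, unit_baseline, space2)
        ll3 = total_loglik(tiny_dataset, three, unit_baseline, space2)
        assert ll2 == pytest.approx(ll3, abs=1e-10)

    def test_dimension_mismatch_rejected(
        self, tiny_dataset, space2, space3, unit_baseline, tiny_params_k2
    ):
        with pytest.raises(ValueError, match="rho has shape"):
            total_loglik(tiny_dataset, tiny_params_k2, unit_baseline, space3)


class TestVectorizedEngine:
    def test_matrix_agrees_with_scalar_path(self, tiny_dataset, space2,
                                            unit_baseline):
        packed = PackedData.from_dataset(tiny_dataset)
        phis = np.array([0.15, 0.5, 0.92])
        mat = segment_loglik_matrix(packed, phis, unit_baseline, space2)
        for pi_, phi in enumerate(phis):
            for j, seg in enumerate(tiny_dataset.segments):
                for hi in range(len(space2.configs)):
                    want = segment_loglik(seg, hi, phi, unit_baseline, space2)
                    assert mat[pi_, j, hi] == pytest.approx(want, abs=1e-9)

    def test_lambda_monotone_in_phi_for_gain(self, space3, unit_baseline):
        seg = make_segment("s", 1000, 1000, [])
        phis = np.linspace(0.0, 1.0, 30)
        vals = [expected_depth(seg, p, 3, unit_baseline) for p in phis]
        assert np.all(np.diff(vals) > 0)


def test_model_params_validation():
    H = 4
    rho = np.full((1, H), 1.0 / H)
    with pytest.raises(ValueError, match="ascending"):
        ModelParams(np.array([0.7, 0.3]), np.array([0.5, 0.5]), rho)
    with pytest.raises(ValueError, match="sum to 1"):
        ModelParams(np.array([0.3, 0.7]), np.array([0.6, 0.6]), rho)
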