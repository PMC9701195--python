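"""Sequential binding model: partition function, depletion, fitting,
replicate aggregation, and cooperativity ratios."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msbalipid import (
    BindingModel,
    FitResult,
    TitrationPoint,
    TitrationSeries,
    aggregate_replicates,
    cooperativity_profile,
    fit_series,
    mole_fractions,
    predict_abundances,
    pseudo_chi2,
    solve_free_lipid,
)
from msbalipid.binding import mean_bound

from conftest import adair_fractions_reference

ka_lists = st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=6)


# ---------------------------------------------------------------------------
# mole fractions
# ---------------------------------------------------------------------------

class TestMoleFractions:
    @pytest.mark.parametrize("ka, l_free, expected", [
        ((5.0, 0.2, 7.0), 0.0, (1, 0, 0, 0)),       # zero ligand forces apo
        ((1.0 / 0.7,), 0.7, (0.5, 0.5)),            # half saturation at K_D
        ((2.0, 0.5), 1.0, (0.25, 0.50, 0.25)),      # partition function 1+2+1
    ])
    def test_known_values(self, ka, l_free, expected):
        f = mole_fractions(BindingModel(ka), l_free)
        np.testing.assert_allclose(f, expected, atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(ka=ka_lists, l_free=st.floats(0.0, 1e3))
    def test_normalized_and_bounded(self, ka, l_free):
        f = mole_fractions(BindingModel(tuple(ka)), l_free)
        assert abs(f.sum() - 1.0) < 1e-12
        assert np.all(f >= 0) and np.all(f <= 1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ka=ka_lists, l_free=st.floats(1e-6, 1e3))
    def test_matches_direct_polynomial(self, ka, l_free):
        f = mole_fractions(BindingModel(tuple(ka)), l_free)
        ref = adair_fractions_reference(list(ka), l_free)
        np.testing.assert_allclose(f, ref, rtol=1e-9, atol=1e-12)

    def test_log_domain_survives_extreme_products(self):
        # ka*l products up to 1e36 overflow a naive polynomial evaluation
        f = mole_fractions(BindingModel((1e3,) * 6), 1e3)
        assert abs(f.sum() - 1.0) < 1e-12
        assert f[-1] > 0.999

    def test_negative_ligand_rejected(self):
        with pytest.raises(ValueError):
            mole_fractions(BindingModel((1.0,)), -0.1)

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            BindingModel(())
        with pytest.raises(ValueError):
            BindingModel((1.0, -2.0))
        with pytest.raises(ValueError):
            BindingModel((1.0, math.inf))
        assert BindingModel((2.0, 0.5)).kd == (0.5, 2.0)


# ---------------------------------------------------------------------------
# free-lipid depletion
# ---------------------------------------------------------------------------

def quadratic_free_lipid(kd, p_total, l_total):
    """Closed-form single-site depletion: root of x^2 + (K_D + P - L)x - K_D L."""
    b = kd + p_total - l_total
    return (-b + math.sqrt(b * b + 4.0 * kd * l_total)) / 2.0


class TestFreeLipid:
    def test_zero_lipid(self):
        assert solve_free_lipid(BindingModel((1.0,)), 0.0, 1.0) == 0.0

    def test_vanishing_protein_means_no_depletion(self):
        lf = solve_free_lipid(BindingModel((1.0,)), 2.0, 1e-12)
        assert lf == pytest.approx(2.0, abs=1e-9)

    def test_single_site_closed_form_sqrt2_case(self):
        # K_D = 1 uM, p_total = 2 uM, l_total = 1 uM has root sqrt(2) - 1
        lf = solve_free_lipid(BindingModel((1.0,)), 1.0, 2.0)
        assert lf == pytest.approx(math.sqrt(2.0) - 1.0, abs=1e-10)

    def test_single_site_closed_form_sweep(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            kd = 10.0 ** rng.uniform(-2, 2)
            p = 10.0 ** rng.uniform(-2, 1)
            l = 10.0 ** rng.uniform(-2, 2)
            lf = solve_free_lipid(BindingModel((1.0 / kd,)), l, p)
            assert lf == pytest.approx(quadratic_free_lipid(kd, p, l),
                                       abs=1e-10 * max(1.0, l))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(ka=ka_lists, l_total=st.floats(0.0, 100.0),
           p_total=st.floats(1e-3, 10.0))
    def test_mass_balance(self, ka, l_total, p_total):
        model = BindingModel(tuple(ka))
        lf = solve_free_lipid(model, l_total, p_total)
        assert 0.0 <= lf <= l_total
        recon = lf + p_total * mean_bound(model, lf)
        assert abs(recon - l_total) <= 1e-10 * max(1.0, l_total)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ka=ka_lists)
    def test_mean_bound_monotone_in_free_lipid(self, ka):
        model = BindingModel(tuple(ka))
        grid = np.geomspace(1e-4, 1e3, 60)
        nbar = [mean_bound(model, x) for x in grid]
        assert np.all(np.diff(nbar) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_free_lipid(BindingModel((1.0,)), -1.0, 1.0)
        with pytest.raises(ValueError):
            solve_free_lipid(BindingModel((1.0,)), 1.0, 0.0)


class TestPredictAbundances:
    def test_zero_lipid_is_apo_only(self):
        point = TitrationPoint(0.0, 0.3, (1.0, 0.0))
        np.testing.assert_allclose(
            predict_abundances(BindingModel((2.0,)), point), [1.0, 0.0])

    def test_composes_depletion_and_partition(self):
        model = BindingModel((1.0,))
        point = TitrationPoint(1.0, 2.0, (1.0, 0.0))
        lf = math.sqrt(2.0) - 1.0
        np.testing.assert_allclose(
            predict_abundances(model, point),
            [1.0 / (1.0 + lf), lf / (1.0 + lf)], atol=1e-10)

    def test_depletion_free_limit(self):
        model = BindingModel((2.0, 0.5))
        point = TitrationPoint(1.0, 1e-10, (1.0, 0.0, 0.0))
        np.testing.assert_allclose(predict_abundances(model, point),
                                   mole_fractions(model, 1.0), atol=1e-8)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class TestPseudoChi2:
    def test_self_consistency_is_zero(self, exact_series):
        model = BindingModel.from_kd((0.6, 1.2))
        assert pseudo_chi2(model, exact_series) < 1e-20

    def test_hand_value(self):
        # one informative point: prediction (0.5, 0.5) vs observation (1, 0)
        # contributes 2 * 0.25; the zero/near-zero points contribute nothing
        model = BindingModel((1.0,))
        series = TitrationSeries(points=(
            TitrationPoint(1.0, 1e-9, (1.0, 0.0)),
            TitrationPoint(0.0, 1e-9, (1.0, 0.0)),
            TitrationPoint(1e-12, 1e-9, (1.0, 0.0))))
        assert pseudo_chi2(model, series) == pytest.approx(0.5, abs=1e-6)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        model = BindingModel(tuple(10.0 ** rng.uniform(-1, 1, 3)))
        points = []
        for l in (0.0, 0.3, 0.9, 2.7):
            f = rng.dirichlet(np.ones(4))
            points.append(TitrationPoint(l, 0.3, tuple(f)))
        series = TitrationSeries(points=tuple(points))
        brute = 0.0
        for p in points:
            f_calc = adair_fractions_reference(
                list(model.ka), solve_free_lipid(model, p.l_total, p.p_total))
            for k in range(4):
                brute += (p.f_obs[k] - f_calc[k]) ** 2
        assert pseudo_chi2(model, series) == pytest.approx(brute, rel=1e-9)

    def test_shape_error_on_too_many_species(self):
        model = BindingModel((1.0,))
        pts = tuple(TitrationPoint(l, 0.3, (0.5, 0.3, 0.2)) for l in (0, 1, 2))
        with pytest.raises(ValueError, match="species"):
            pseudo_chi2(model, TitrationSeries(points=pts))

    def test_shorter_observation_vector_padded(self, exact_series):
        # a 3-event model against 2-event data pads the absent species with 0
        model = BindingModel.from_kd((0.6, 1.2, 1e4))
        assert pseudo_chi2(model, exact_series) < 1e-6


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFitSeries:
    def test_noiseless_round_trip(self, exact_series):
        fit = fit_series(exact_series, n_max=2)
        assert fit.converged and not fit.boundary
        np.testing.assert_allclose(fit.kd, (0.6, 1.2), rtol=1e-4)

    def test_kd_is_reciprocal_ka(self, exact_series):
        fit = fit_series(exact_series, n_max=2)
        np.testing.assert_array_equal(
            fit.kd, tuple(1.0 / k for k in fit.model.ka))

    def test_apo_only_data_is_boundary_flagged(self):
        pts = tuple(TitrationPoint(l, 0.3, (1.0, 0.0)) for l in (0.0, 1.0, 2.0, 4.0))
        fit = fit_series(TitrationSeries(points=pts), n_max=1)
        assert fit.boundary and not fit.converged
        assert fit.kd[0] >= 1e4 * (1 - 1e-9)

    def test_n_max_inferred_from_one_percent_rule(self, exact_series):
        fit = fit_series(exact_series)
        assert fit.model.n_max == 2

    def test_grid_oracle_equivalence(self, exact_series):
        fit = fit_series(exact_series, n_max=2)
        grid = np.linspace(-4, 3, 50)
        best = min(
            pseudo_chi2(BindingModel((10.0 ** a, 10.0 ** b)), exact_series)
            for a in grid for b in grid)
        assert fit.chi2 <= best + 1e-15

    def test_deterministic(self, default_truth):
        from msbalipid import generate_titration
        series = generate_titration(default_truth, 1)[0]
        kd1 = fit_series(series, n_max=2).kd
        kd2 = fit_series(series, n_max=2).kd
        assert kd1 == kd2

    def test_too_few_points_rejected(self):
        pts = tuple(TitrationPoint(l, 0.3, (0.7, 0.3)) for l in (0.0, 0.5, 1.0))
        with pytest.raises(ValueError, match="points"):
            fit_series(TitrationSeries(points=pts), n_max=2)


class TestAggregateReplicates:
    def _fit(self, kd, boundary=False, converged=True):
        return FitResult(model=BindingModel.from_kd(kd), chi2=0.0,
                         converged=converged, n_points=8, boundary=boundary)

    def test_identical_triplicate_has_zero_sd(self):
        s = aggregate_replicates([self._fit((0.5, 1.0))] * 3)
        assert s.kd_mean == (0.5, 1.0)
        assert s.kd_sd == (0.0, 0.0)

    def test_mean_and_sample_sd(self):
        s = aggregate_replicates([self._fit((k,)) for k in (0.5, 0.6, 0.7)])
        assert s.kd_mean[0] == pytest.approx(0.6)
        assert s.kd_sd[0] == pytest.approx(0.1)
        assert s.n_replicates == 3

    def test_boundary_fits_excluded_with_warning(self):
        fits = [self._fit((0.5,)), self._fit((0.5,)),
                self._fit((1e4,), boundary=True)]
        with pytest.warns(UserWarning, match="excluded"):
            s = aggregate_replicates(fits)
        assert s.n_replicates == 2 and s.n_excluded == 1

    def test_single_replicate_has_no_sd(self):
        s = aggregate_replicates([self._fit((0.5,))])
        assert s.kd_sd is None

    def test_zero_usable_fits_error(self):
        with pytest.raises(ValueError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aggregate_replicates([self._fit((1.0,), boundary=True)])


class TestCooperativity:
    def test_identical_independent_sites_correct_to_unity(self):
        # macroscopic K_Ds of N=4 identical sites: K * n/(N-n+1)
        n_sites, k = 4, 0.8
        kd = [k * n / (n_sites - n + 1) for n in range(1, n_sites + 1)]
        prof = cooperativity_profile(kd, n_sites=n_sites)
        np.testing.assert_allclose(prof["corrected_ratio"], 1.0, rtol=1e-12)

    def test_equal_kds_raw_ratio_one(self):
        prof = cooperativity_profile((0.3, 0.3))
        assert prof["raw_ratio"][0] == pytest.approx(1.0)
        # relative to the statistical expectation this is positive cooperativity
        assert prof["label"][0] == "positive cooperativity"

    def test_hand_evaluated_correction(self):
        # N=2: factors 1/2 and 2; corrected K_Ds 2 and 2 -> ratio 1, raw 4
        prof = cooperativity_profile((1.0, 4.0), n_sites=2)
        assert prof["raw_ratio"][0] == pytest.approx(4.0)
        assert prof["corrected_ratio"][0] == pytest.approx(1.0)
        assert prof["statistical_factor"] == (0.5, 2.0)

    def test_single_event_not_applicable(self):
        with pytest.raises(ValueError):
            cooperativity_profile((0.5,))
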