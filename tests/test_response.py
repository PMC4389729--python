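import numpy as np
import pandas as pd
import pytest

from fapsense import (
    InductionMap,
    dose_response,
    induction_to_rate,
    normalize_rfp_od,
    param_induction_correlation,
    pearson_r,
    readout_at_od,
    replicate_cv,
    substrate_effect_test,
    well_summaries,
)
from fapsense.errors import InvalidParameterError, NoGrowthError


class TestReadoutAtOd:
    def test_on_grid_crossing_returns_that_sample(self):
        t = np.array([0.0, 12.0, 24.0])
        fl, tc = readout_at_od(t, np.array([0.4, 0.6, 0.8]), np.array([10.0, 20.0, 30.0]))
        assert fl == 20.0 and tc == 12.0

    def test_midpoint_interpolation(self):
        t = np.array([0.0, 12.0])
        fl, tc = readout_at_od(t, np.array([0.5, 0.7]), np.array([100.0, 200.0]))
        assert fl == pytest.approx(150.0)
        assert tc == pytest.approx(6.0)

    def test_plateau_below_threshold_is_no_growth(self):
        t = np.arange(5.0)
        with pytest.raises(NoGrowthError, match="0.6"):
            readout_at_od(t, np.full(5, 0.3), np.zeros(5))

    def test_series_starting_above_threshold_rejected(self):
        with pytest.raises(InvalidParameterError):
            readout_at_od(np.arange(3.0), np.array([0.7, 0.8, 0.9]), np.zeros(3))

    def test_first_upward_crossing_wins_over_later_ones(self):
        # lysis dip below the threshold and a second rise are ignored
        od = np.array([0.4, 0.65, 0.5, 0.7])
        rfp = np.array([1.0, 2.0, 3.0, 4.0])
        fl, _ = readout_at_od(np.arange(4.0), od, rfp)
        assert 1.0 < fl <= 2.0

    def test_invariant_to_grid_refinement_for_piecewise_linear_signal(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        od = np.array([0.1, 0.3, 0.7, 0.9])
        rfp = np.array([0.0, 50.0, 150.0, 250.0])
        fine = np.linspace(0, 30, 301)
        fl_coarse, tc_coarse = readout_at_od(t, od, rfp)
        fl_fine, tc_fine = readout_at_od(fine, np.interp(fine, t, od), np.interp(fine, t, rfp))
        assert fl_fine == pytest.approx(fl_coarse, rel=1e-9)
        assert tc_fine == pytest.approx(tc_coarse, rel=1e-9)


class TestNormalize:
    def test_proportional_signals_give_constant_ratio(self):
        od = np.array([0.1, 0.5, 1.0])
        ratio = normalize_rfp_od(od, 2 * od, od_floor=0.05)
        assert np.allclose(ratio.compressed(), 2.0)

    def test_zero_od_masked_not_infinite(self):
        ratio = normalize_rfp_od(np.array([0.0, 0.5]), np.array([1.0, 1.0]), od_floor=0.05)
        assert ratio.mask[0] and not ratio.mask[1]
        assert np.isfinite(ratio.filled(0.0)).all()

    def test_reporter_lag_produces_initial_dip_then_recovery(self):
        # growth outpaces reporter expression early on, so RFP/OD dips before
        # the reporter catches up
        t = np.linspace(0, 300, 301)
        od = 0.1 + 0.9 / (1 + np.exp(-(t - 100) / 30))
        rfp = np.interp(t - 60, t, 5 * od, left=0.5)  # delayed, scaled copy
        ratio = normalize_rfp_od(od, rfp, od_floor=0.05)
        i_min = np.argmin(ratio)
        assert 0 < i_min < len(t) - 1
        assert ratio[-1] > ratio[i_min]


class TestDoseResponse:
    def test_single_replicate_means_are_raw_values(self):
        curve = dose_response([1.0, 0.1], [20.0, 10.0])
        np.testing.assert_array_equal(curve.concentrations_mm, [0.1, 1.0])
        np.testing.assert_array_equal(curve.mean, [10.0, 20.0])
        np.testing.assert_array_equal(curve.sd, [0.0, 0.0])

    def test_input_order_invariance(self, rng):
        doses = np.repeat([0.01, 0.1, 1.0, 10.0], 3)
        vals = rng.random(doses.size)
        perm = rng.permutation(doses.size)
        c1 = dose_response(doses, vals)
        c2 = dose_response(doses[perm], vals[perm])
        np.testing.assert_allclose(c1.mean, c2.mean)
        np.testing.assert_allclose(c1.sd, c2.sd)

    def test_hill_generated_curve_is_monotone(self, rng):
        imap = InductionMap(basal=1.0, vmax=10.0, kh=0.3)
        doses, vals = [], []
        for dose in (0.01, 0.1, 0.3, 1.0, 10.0):
            for _ in range(4):
                doses.append(dose)
                vals.append(induction_to_rate(dose, imap) * (1 + 0.01 * rng.standard_normal()))
        curve = dose_response(doses, vals)
        assert np.all(np.diff(curve.mean) > 0)

    def test_single_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            dose_response([1.0, 1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_orthogonal_vectors(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # symmetric in x
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_against_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSubstrateEffect:
    def test_identical_groups_not_significant(self):
        eff = substrate_effect_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not eff.significant and eff.direction == 0

    def test_widely_separated_groups_significant(self):
        # ten pooled standard deviations apart at n=3
        eff = substrate_effect_test([10.0, 10.5, 9.5], [5.0, 5.5, 4.5])
        assert eff.significant and eff.direction == 1
        assert eff.p_value < 0.01

    def test_swapping_groups_flips_direction_keeps_p(self):
        a, b = [10.0, 10.5, 9.5], [5.0, 5.5, 4.5]
        e1 = substrate_effect_test(a, b)
        e2 = substrate_effect_test(b, a)
        assert e1.p_value == pytest.approx(e2.p_value, rel=1e-12)
        assert e1.direction == -e2.direction

    def test_single_replicate_rejected(self):
        with pytest.raises(InvalidParameterError):
            substrate_effect_test([1.0], [1.0, 2.0])


class TestReplicateCv:
    def test_identical_replicates_give_zero(self):
        assert replicate_cv([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_value(self):
        # sd((90,110), ddof=1)/mean = sqrt(200)/100
        assert replicate_cv([90.0, 110.0]) == pytest.approx(np.sqrt(200) / 100)

    def test_scale_invariance(self):
        vals = np.array([80.0, 100.0, 130.0])
        assert replicate_cv(7.3 * vals) == pytest.approx(replicate_cv(vals), rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InvalidParameterError):
            replicate_cv([-1.0, 1.0])


class TestParamInductionCorrelation:
    @staticmethod
    def fits_frame(rng, k_by_dose):
        rows = []
        for construct, (tau1, tau2) in {"a": (300.0, 15.0), "b": (150.0, 10.0)}.items():
            for dose in (0.01, 0.1, 0.3, 0.6, 1.0, 10.0):
                for _ in range(3):
                    rows.append(
                        {
                            "construct": construct,
                            "iptg_mM": dose,
                            "K": k_by_dose(dose) * (1 + 0.05 * rng.standard_normal()),
                            "tau_1": tau1 * (1 + 0.05 * rng.standard_normal()),
                            "tau_2": tau2 * (1 + 0.05 * rng.standard_normal()),
                            "tau_z": 5.0,
                        }
                    )
        return pd.DataFrame(rows)

    def test_dose_dependent_gain_detected(self, rng):
        fits = self.fits_frame(rng, lambda d: 100 * d / (0.3 + d))
        rep = param_induction_correlation(fits)
        assert rep.correlations["K"][0] > 0.7
        assert abs(rep.correlations["tau_1"][0]) < 0.3
        assert rep.clusters_by_construct

    def test_constant_production_gives_null_gain_correlation(self, rng):
        fits = self.fits_frame(rng, lambda d: 100.0)
        rep = param_induction_correlation(fits)
        assert abs(rep.correlations["K"][0]) < 0.3

    def test_too_few_induction_levels_rejected(self, rng):
        fits = self.fits_frame(rng, lambda d: 100.0)
        with pytest.raises(InvalidParameterError):
            param_induction_correlation(fits[fits["iptg_mM"] < 0.3])


def test_well_summaries_flags_no_growth_wells(small_plate):
    df = well_summaries(small_plate, od_threshold=0.6)
    assert len(df) == len(small_plate.wells)
    assert df["grew"].all()
    assert (df.loc[df["grew"], "fluorescence_at_od"] > 0).all()
    high = well_summaries(small_plate, od_threshold=5.0)
    assert not high["grew"].any()
    assert high["fluorescence_at_od"].isna().all()
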