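"""Calibration: NIF, linear windows, LOD/LOQ, rRFN/UVF fits, stability."""
import numpy as np
import pytest

import silis
from silis.calibrate import (
    LinearRangeError,
    calibrate_table,
    compute_nif,
    estimate_lod_loq,
    fit_linear_range,
    fit_rrfn,
    fit_uvf,
    nif_by_level,
    rrfn_by_session,
    session_stability,
)
from silis.simulate import default_model, expected_signals, simulate_calibration


class TestComputeNif:
    def test_zero_analyte_gives_zero(self):
        assert compute_nif(0.0, 123.0) == 0.0

    def test_equal_signals_give_one(self):
        assert compute_nif(5.5, 5.5) == 1.0

    def test_suppression_cancels_in_ratio(self):
        # amounts with a 7:1 ratio measured under heavy suppression
        m = default_model(k_sat=0.01)
        s12, s13 = expected_signals(m, 0.7, 0.1, "Am")
        assert compute_nif(s12, s13) == pytest.approx(7.0, rel=1e-12)

    def test_missing_internal_standard_rejected(self):
        with pytest.raises(ValueError, match="SIL-IS"):
            compute_nif(1.0, 0.0)


class TestFitLinearRange:
    def test_perfect_line_spans_all_levels(self):
        x = np.logspace(-3, 3, 7)
        model = fit_linear_range(x, 50.0 * x, nucleoside="Am")
        assert model.linear_lo == x[0] and model.linear_hi == x[-1]
        assert model.r2 == pytest.approx(1.0)
        assert model.slope == pytest.approx(50.0)

    def test_saturated_top_levels_are_excluded(self):
        x = np.logspace(-3, 2, 11)
        y = 100.0 * x / (1 + x / 2.0)  # saturating response
        model = fit_linear_range(x, y)
        assert model.linear_hi < 10.0

    def test_error_reports_best_window(self):
        x = np.logspace(0, 2, 5)
        y = np.array([1.0, 100.0, 2.0, 300.0, 4.0])  # garbage
        with pytest.raises(LinearRangeError):
            fit_linear_range(x, y)

    def test_default_simulation_raw_window_spans_four_decades(self, default_calibration):
        _, _, _, models = default_calibration
        assert models["Am"]["MS12"].decades >= 4.0

    def test_default_simulation_nif_window_spans_six_decades(self, default_calibration):
        _, _, _, models = default_calibration
        assert models["Am"]["NIF"].decades >= 6.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = np.repeat(np.logspace(-2, 2, 9), 3)
        y = 10 * x * (1 + rng.normal(0, 0.01, x.size))
        a = fit_linear_range(x, y)
        perm = rng.permutation(x.size)
        b = fit_linear_range(x[perm], y[perm])
        assert (a.slope, a.linear_lo, a.linear_hi) == (b.slope, b.linear_lo, b.linear_hi)


class TestLodLoq:
    def test_zero_variance_flagged_as_zero(self):
        with pytest.warns(UserWarning):
            assert estimate_lod_loq([5.0, 5.0, 5.0], 1000.0) == (0.0, 0.0)

    def test_three_and_ten_sigma_rule(self):
        blanks = [0.0, 3.0, -3.0, 3.0, -3.0]  # sd = 3 exactly
        lod, loq = estimate_lod_loq(blanks, 1000.0)
        assert lod == pytest.approx(3 * 3.0 / 1000.0)
        assert loq == pytest.approx(10 * 3.0 / 1000.0)

    def test_monte_carlo_recovery_from_simulated_blanks(self):
        # blanks with additive sd 3 and slope 1000 -> (0.009, 0.03) pmol
        rng = np.random.default_rng(123)
        lods = []
        for _ in range(100):
            blanks = np.maximum(rng.normal(9.0, 3.0, size=10), 0.0)
            lod, loq = estimate_lod_loq(blanks, 1000.0)
            lods.append((lod, loq))
        lod, loq = np.mean(lods, axis=0)
        assert lod == pytest.approx(0.009, rel=0.30)
        assert loq == pytest.approx(0.030, rel=0.30)


class TestFitRrfn:
    def test_exact_proportionality_recovers_published_magnitude(self):
        # a response factor of the size reported for 2'-O-methyladenosine
        x = np.logspace(-2, 2, 9)
        fit = fit_rrfn(x, 0.04538 * x)
        assert fit.slope == pytest.approx(0.04538, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_all_zero_nifs_degenerate(self):
        fit = fit_rrfn([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert fit.slope == 0.0 and fit.r2 == 0.0 and fit.degenerate

    def test_negative_nif_rejected(self):
        with pytest.raises(ValueError):
            fit_rrfn([1.0, 2.0], [0.5, -0.1])

    def test_simulated_rrfn_is_inverse_silis_spike(self, default_calibration):
        # true NIF = a12 / a13, so the slope must be 1 / (0.1 pmol spike)
        _, _, rf, _ = default_calibration
        fit = rf.rrfn["Am"]
        assert abs(fit.slope - 10.0) <= 3 * fit.se + 0.05 * 10.0

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_rrfn_recovery_across_seeds(self, seed):
        model = default_model(("Am",), seed=seed)
        df = simulate_calibration(model, seed=seed)
        agg = nif_by_level(df, "Am").groupby("level_pmol")["nif"].median()
        x = agg.index.to_numpy()
        fit = fit_rrfn(x[x >= 1e-4], agg.to_numpy()[x >= 1e-4])
        assert abs(fit.slope - 10.0) <= max(3 * fit.se, 0.02 * 10.0)


class TestFitUvf:
    def test_exact_proportionality(self):
        x = np.array([1.0, 5.0, 20.0])
        assert fit_uvf(x, 500.0 * x, "G") == pytest.approx(500.0)

    def test_simulated_uv_channel_recovery(self):
        model = default_model(("G",), seed=21)
        df = simulate_calibration(model, seed=21)
        rf, _ = calibrate_table(df)
        assert rf.uvf["G"] == pytest.approx(model.uvf_true["G"], rel=0.01)

    def test_modified_nucleoside_rejected(self):
        with pytest.raises(ValueError):
            fit_uvf([1.0, 2.0], [500.0, 1000.0], "Am")


class TestSessionStability:
    def test_identical_values_have_zero_rsd(self):
        assert session_stability({"w1": 10.0, "w2": 10.0}) == 0.0

    def test_known_spread(self):
        assert session_stability({"a": 9.8, "b": 10.0, "c": 10.2}) == pytest.approx(2.0)

    def test_single_session_rejected(self):
        with pytest.raises(ValueError):
            session_stability({"only": 10.0})

    def test_drift_dominated_sessions_raw_unstable_rrfn_stable(self):
        # shared lognormal drift CV 24% over 6 sessions: the raw signal
        # fluctuates by tens of percent while the rRFN stays within 2%
        model = default_model(("Am",), seed=1, drift_cv=0.24)
        df = simulate_calibration(model, n_sessions=6, seed=11)
        per = rrfn_by_session(df, "Am", window=(1e-4, 100.0))
        rrfn_rsd = session_stability({s: f.slope for s, f in per.items()})
        top = df[(df.level_pmol == 0.1) & (df.channel == "MS12")]
        raw = top.groupby("session_id").peak_area.median()
        raw_rsd = session_stability(dict(raw))
        assert rrfn_rsd < 2.0
        assert raw_rsd > 10.0
        assert rrfn_rsd < raw_rsd


class TestCalibrateTable:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_isotope_normalization_only_extends_the_linear_range(self, seed):
        # Suppression cancels in the NIF, so the NIF window always reaches
        # at least as high as the raw window and spans at least as many
        # decades.  At the noise-limited LOW edge both channels see the
        # same counting noise, so the NIF low edge matches the raw one to
        # within a single half-decade grid step.
        model = default_model(("Am",), seed=seed)
        df = simulate_calibration(model, seed=seed)
        _, models = calibrate_table(df)
        raw, nif = models["Am"]["MS12"], models["Am"]["NIF"]
        assert nif.linear_hi >= raw.linear_hi * (1 - 1e-9)
        assert nif.decades >= raw.decades - 1e-9
        assert nif.linear_lo <= raw.linear_lo * np.sqrt(10.0) * (1 + 1e-9)

    def test_rftable_csv_round_trip(self, default_calibration, tmp_path):
        _, _, rf, _ = default_calibration
        path = tmp_path / "rf.csv"
        rf.to_csv(path)
        back = rf.from_csv(path)
        assert back.rrfn["Am"].slope == pytest.approx(rf.rrfn["Am"].slope, rel=1e-12)
        assert back.valid_range["Am"][0] == pytest.approx(rf.valid_range["Am"][0])
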