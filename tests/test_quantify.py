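"""Absolute quantification: amounts, UV-based RNA amount, yields, spikes."""
import numpy as np
import pytest

import silis
from silis.calibrate import calibrate_table
from silis.quantify import (
    MissingCalibrationError,
    QuantResult,
    absolute_amount,
    modification_yield,
    quantify_table,
    rna_amount_from_uv,
    spike_check,
)
from silis.simulate import default_model, expected_signals


class TestAbsoluteAmount:
    def test_zero_signal_is_zero_pmol(self):
        assert absolute_amount(0.0, 1000.0, 0.04538) == 0.0

    def test_nif_equal_to_rrfn_is_one_picomole(self):
        # a measured NIF numerically equal to the response factor -> 1 pmol
        assert absolute_amount(0.04538, 1.0, 0.04538) == pytest.approx(1.0)

    def test_inverts_the_instrument_exactly_in_noiseless_limit(self):
        # suppression and drift cancel: NIF/rRFN returns a12 for ANY k_sat
        for k_sat in [0.01, 5.0, 1e9]:
            for drift in [0.3, 1.0, 2.5]:
                m = default_model(k_sat=k_sat)
                s12, s13 = expected_signals(m, 0.5, 0.1, "Am")
                amount = absolute_amount(s12 * drift, s13 * drift, rrfn=1 / 0.1)
                assert amount == pytest.approx(0.5, rel=1e-12)

    def test_replicates_propagate_to_standard_error(self):
        s12 = np.array([10.0, 11.0, 9.0])
        s13 = np.array([100.0, 100.0, 100.0])
        amount, se = absolute_amount(s12, s13, rrfn=1.0)
        assert amount == pytest.approx(0.1)
        assert se == pytest.approx(np.std(s12 / s13, ddof=1) / np.sqrt(3))

    def test_simulated_digest_recovery_within_five_percent(self, registry):
        m = silis.default_model(("m5C", "C", "U", "G", "A"), seed=8)
        cal = silis.simulate_calibration(m, seed=8)
        rf, _ = calibrate_table(cal)
        truth = silis.SampleTruth(
            amounts_12c={"m5C": 0.5},
            silis_amounts={"m5C": 0.1, "C": 20.0, "U": 20.0, "G": 20.0, "A": 20.0},
            sequence_counts={"G": 23, "A": 18, "C": 18, "U": 17},
            rna_pmol=10.0,
        )
        digest = silis.simulate_digest(m, truth, seed=9)
        res = quantify_table(digest, rf, sequence_counts=truth.sequence_counts, registry=registry)
        assert res.amounts["m5C"] == pytest.approx(0.5, rel=0.05)

    def test_uncalibratable_nucleosides_listed_in_error(self, trub_assay, registry):
        model, rf, truth, digest, counts = trub_assay
        digest = digest.copy()
        extra = digest[digest.analyte == "Y"].copy()
        extra["analyte"] = "m1G"  # detectable species without an rRFN
        with pytest.raises(MissingCalibrationError, match="m1G"):
            quantify_table(
                __import__("pandas").concat([digest, extra], ignore_index=True),
                rf, sequence_counts=counts, registry=registry,
            )


class TestRnaAmountFromUv:
    def test_worked_guanosine_example(self):
        # corrected G area equivalent to 303.6 pmol G over 23 G per molecule
        uvf = 800.0
        assert rna_amount_from_uv(303.6 * uvf, 0.0, uvf, 23) == pytest.approx(13.2)

    def test_all_signal_from_internal_standard_is_zero_rna(self):
        assert rna_amount_from_uv(5000.0, 5000.0, 800.0, 23) == 0.0

    def test_overspiked_internal_standard_rejected(self):
        with pytest.raises(ValueError):
            rna_amount_from_uv(100.0, 200.0, 800.0, 23)

    def test_linear_in_corrected_area_and_inverse_in_residues(self):
        base = rna_amount_from_uv(1000.0, 200.0, 10.0, 10)
        assert rna_amount_from_uv(1800.0, 200.0, 10.0, 10) == pytest.approx(2 * base)
        assert rna_amount_from_uv(1000.0, 200.0, 10.0, 20) == pytest.approx(base / 2)

    def test_simulated_digest_recovers_rna_within_two_percent(self, trub_assay, registry):
        _, rf, truth, digest, counts = trub_assay
        res = quantify_table(digest, rf, sequence_counts=counts, registry=registry)
        assert res.rna_pmol == pytest.approx(truth.rna_pmol, rel=0.02)


class TestModificationYield:
    def test_equimolar_single_site_is_full_turnover(self):
        y = modification_yield(7.3, 7.3, sites=1)
        assert y.per_molecule == pytest.approx(1.0)
        assert y.occupancy == pytest.approx(1.0)

    def test_parent_and_sequence_normalizations(self):
        y = modification_yield(1.0, 10.0, sites=1, parent_count=20, total_residues=80)
        assert y.per_molecule == pytest.approx(0.1)
        assert y.pct_of_parent == pytest.approx(100 * 1.0 / (10.0 * 20))
        assert y.mol_pct == pytest.approx(100 * 0.1 / 80)

    def test_mol_pct_absent_without_sequence(self):
        assert modification_yield(1.0, 10.0).mol_pct is None

    def test_simulated_partial_occupancy_recovered(self, registry):
        m = silis.default_model(("Y", "C", "U", "G", "A"), seed=14)
        cal = silis.simulate_calibration(m, seed=14)
        rf, _ = calibrate_table(cal)
        counts = {"G": 23, "A": 18, "C": 18, "U": 17}
        truth = silis.SampleTruth.from_occupancy(
            13.2, counts, {"Y": (1, 0.75)},
            {"Y": 0.1, "C": 20.0, "U": 20.0, "G": 20.0, "A": 20.0},
        )
        digest = silis.simulate_digest(m, truth, seed=15)
        res = quantify_table(digest, rf, sequence_counts=counts, sites={"Y": 1}, registry=registry)
        assert res.yields["Y"].occupancy == pytest.approx(0.75, abs=0.02)

    def test_occupancy_bounded_by_noise_width(self, trub_assay, registry):
        _, rf, truth, digest, counts = trub_assay
        res = quantify_table(digest, rf, sequence_counts=counts, sites={"Y": 1}, registry=registry)
        assert res.yields["Y"].occupancy <= 1.0 + 3 * 0.02


class TestSpikeCheck:
    def r(self, amount):
        return QuantResult(amounts={"Y": amount})

    def test_identical_results_fail(self):
        recovery, ok = spike_check(self.r(1.0), self.r(1.0), 0.1, "Y")
        assert recovery == 0.0 and not ok

    def test_exact_spike_difference_passes(self):
        recovery, ok = spike_check(self.r(1.0), self.r(1.1), 0.1, "Y")
        assert recovery == pytest.approx(1.0) and ok

    def test_missing_nucleoside_rejected(self):
        with pytest.raises(KeyError):
            spike_check(self.r(1.0), QuantResult(amounts={}), 0.1, "Y")

    def test_monte_carlo_recovery_within_ten_percent(self, registry):
        # paired simulated digests differing by a 0.1 pmol spike on a
        # spike-sized analyte level, at default noise
        m = silis.default_model(("Y",), seed=30)
        cal = silis.simulate_calibration(m, seed=30)
        rf, _ = calibrate_table(cal)
        ok = 0
        n_trials = 200
        for i in range(n_trials):
            base = silis.SampleTruth(amounts_12c={"Y": 0.1}, silis_amounts={"Y": 0.1})
            spiked = silis.SampleTruth(amounts_12c={"Y": 0.2}, silis_amounts={"Y": 0.1})
            d0 = silis.simulate_digest(m, base, seed=1000 + i, n_replicates=3)
            d1 = silis.simulate_digest(m, spiked, seed=2000 + i, n_replicates=3)
            r0 = quantify_table(d0, rf, registry=registry)
            r1 = quantify_table(d1, rf, registry=registry)
            recovery, _ = spike_check(r0, r1, 0.1, "Y", tolerance=0.1)
            if 0.9 <= recovery <= 1.1:
                ok += 1
        assert ok / n_trials >= 0.95
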