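"""Relative-standard-curve quantification and fold differences."""

import numpy as np
import pytest

from barrierkit import (
    fit_standard_curve,
    normalized_fold_difference,
    quantify_plate,
    relative_quantity,
    simulate_qpcr_plate,
)
from barrierkit.qpcr import mean_ct, validate_controls


def ladder(slope, intercept, n=5):
    q = [10.0 ** (-j) for j in range(n)]
    ct = [intercept + slope * np.log10(x) for x in q]
    return q, ct


class TestStandardCurve:
    def test_full_efficiency_slope(self):
        """A −3.3219 Ct/decade ladder amplifies at 100% efficiency, r² = 1."""
        curve = fit_standard_curve(*ladder(-3.3219, 25.0))
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(-3.3219, rel=1e-9)

    def test_imperfect_efficiency(self):
        curve = fit_standard_curve(*ladder(-3.6, 25.0))
        assert curve.efficiency == pytest.approx(0.896, abs=5e-4)

    def test_two_points_fit_exactly(self):
        curve = fit_standard_curve([1.0, 0.1], [24.0, 27.4])
        assert curve.r_squared == 1.0
        assert curve.slope == pytest.approx(-3.4)

    def test_failed_runs_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fit_standard_curve([1.0, 0.1], [25.0, 24.0])  # Ct rising with dilution
        with pytest.raises(ValueError):
            fit_standard_curve([1.0, 1.0], [25.0, 25.0])


class TestInversion:
    def test_standard_point_round_trips(self):
        curve = fit_standard_curve(*ladder(-3.3219, 25.0))
        assert relative_quantity(25.0 + 2 * 3.3219, curve) == pytest.approx(0.01, rel=1e-9)

    def test_ct_at_intercept_is_unit_quantity(self):
        curve = fit_standard_curve(*ladder(-3.3219, 25.0))
        assert relative_quantity(25.0, curve) == pytest.approx(1.0, rel=1e-12)

    def test_one_cycle_earlier_is_twofold(self):
        curve = fit_standard_curve(*ladder(-3.3219, 25.0))
        ratio = relative_quantity(24.0, curve) / relative_quantity(25.0, curve)
        assert ratio == pytest.approx(2.0, rel=1e-4)

    def test_undetected_ct_propagates(self):
        curve = fit_standard_curve(*ladder(-3.3219, 25.0))
        assert np.isnan(relative_quantity(float("nan"), curve))

    def test_mean_ct_drops_undetected_with_warning(self):
        with pytest.warns(UserWarning, match="undetected"):
            assert mean_ct([24.0, np.nan, 26.0]) == pytest.approx(25.0)
        with pytest.warns(UserWarning, match="missing"):
            assert np.isnan(mean_ct([np.nan, np.nan]))


class TestFoldDifference:
    def test_normalisation_arithmetic(self):
        """Target 4 / reference 2 vs target 1 / reference 2 → fold 4."""
        fd = normalized_fold_difference([4.0 / 2.0], [1.0 / 2.0])
        assert fd.fold == pytest.approx(4.0) and fd.significant

    def test_identical_groups_not_significant(self):
        fd = normalized_fold_difference([1.3, 1.1], [1.3, 1.1])
        assert fd.fold == pytest.approx(1.0) and not fd.significant

    @pytest.mark.parametrize(
        "fold, significant",
        [(1.5, False), (2.0, True), (2.5, True), (0.5, True), (0.6, False), (0.4, True)],
    )
    def test_symmetric_two_fold_rule(self, fold, significant):
        fd = normalized_fold_difference([fold], [1.0])
        assert fd.significant is significant

    def test_rescaling_gene_quantities_cancels(self):
        """Standard-curve units are arbitrary: a common factor drops out."""
        a = normalized_fold_difference([2.0, 2.2], [1.0, 1.1])
        b = normalized_fold_difference([200.0, 220.0], [100.0, 110.0])
        assert a.fold == pytest.approx(b.fold, rel=1e-12)


class TestPlatePipeline:
    def test_noiseless_round_trip_recovers_programmed_fold(self):
        truth = {
            "GAPDH": {"cal_0": 1.0, "cal_1": 1.0, "tst_0": 1.0, "tst_1": 1.0},
            "BCRP": {"cal_0": 1.0, "cal_1": 1.0, "tst_0": 1.7, "tst_1": 1.7},
        }
        plate = simulate_qpcr_plate(truth, replicate_sd=0.0)
        quant = quantify_plate(plate, "GAPDH")
        sub = quant[quant["gene"] == "BCRP"]
        fd = normalized_fold_difference(
            sub.loc[sub["sample_id"].str.startswith("tst"), "nt"],
            sub.loc[sub["sample_id"].str.startswith("cal"), "nt"],
        )
        assert fd.fold == pytest.approx(1.7, rel=1e-6)

    def test_negative_controls_validated(self):
        plate = simulate_qpcr_plate({"g": {"a": 1.0}})
        assert validate_controls(plate)["ok"].all()
        bad = plate.data.copy()
        bad.loc[bad["role"] == "ntc", "ct"] = 24.0
        from barrierkit.qpcr import QpcrPlate

        with pytest.warns(UserWarning, match="negative-control"):
            ctrl = validate_controls(QpcrPlate(bad))
        assert not ctrl["ok"].all()

    def test_fold_recovery_calibration_under_replicate_noise(self):
        """With 0.15-Ct replicate noise, triplicates and 6 samples per group,
        a programmed 2-fold change is recovered within [1.7, 2.3] in ≥95% of
        500 seeded plates (brute-force resampling of the full pipeline)."""
        inside = 0
        for seed in range(500):
            truth = {"GAPDH": {}, "BCRP": {}}
            for i in range(6):
                truth["GAPDH"][f"cal_{i}"] = truth["GAPDH"][f"tst_{i}"] = 1.0
                truth["BCRP"][f"cal_{i}"] = 1.0
                truth["BCRP"][f"tst_{i}"] = 2.0
            plate = simulate_qpcr_plate(truth, replicate_sd=0.15, seed=seed)
            quant = quantify_plate(plate, "GAPDH")
            sub = quant[quant["gene"] == "BCRP"]
            is_test = sub["sample_id"].str.startswith("tst")
            fd = normalized_fold_difference(sub.loc[is_test, "nt"], sub.loc[~is_test, "nt"])
            inside += int(1.7 <= fd.fold <= 2.3)
        assert inside >= 0.95 * 500
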