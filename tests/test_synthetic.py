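"""The assay generators: exactness of the mass balance, noise, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from barrierkit import (
    InsertGeometry,
    SUCROSE_TRACER,
    TracerSpec,
    TransferSchedule,
    simulate_qpcr_plate,
    simulate_screen_table,
    simulate_teer_batch,
    simulate_transwell,
    simulate_uptake_plate,
    transwell_interval_amounts,
)
from barrierkit.synthetic import SimulationConfig, simulate_alp_plate


def ode_oracle(papp_cm_s, geom, initial_donor, schedule):
    """Independent fine-step integration of the two-compartment balance.

    dA_R/dt = PS·(A_D/V_D − A_R/V_R), dA_D/dt = −dA_R/dt, with the receiver
    emptied at every transfer.  Returns receiver amounts at collection times.
    """
    ps_ul_min = papp_cm_s * geom.area_cm2 * 6e4
    v_d, v_r = geom.donor_volume_ul, geom.receiver_volume_ul

    def rhs(_t, y):
        flux = ps_ul_min * (y[0] / v_d - y[1] / v_r)
        return [-flux, flux]

    donor, collected = initial_donor, []
    for dt in schedule.interval_durations:
        sol = solve_ivp(rhs, (0.0, dt), [donor, 0.0], rtol=1e-11, atol=1e-9)
        donor, receiver = sol.y[0, -1], sol.y[1, -1]
        collected.append(receiver)
    return np.asarray(collected)


class TestTranswellMassBalance:
    def test_matches_independent_ode_integration(self, geom, schedule):
        """Closed-form interval amounts agree with brute-force ODE integration."""
        initial = SUCROSE_TRACER.dpm_per_ul * geom.donor_volume_ul
        amounts = transwell_interval_amounts(1e-5, geom, initial, schedule)
        oracle = ode_oracle(1e-5, geom, initial, schedule)
        assert amounts["receiver_dpm"].to_numpy() == pytest.approx(oracle, rel=1e-6)

    def test_mass_conserved_within_each_interval(self, geom, schedule):
        initial = SUCROSE_TRACER.dpm_per_ul * geom.donor_volume_ul
        amounts = transwell_interval_amounts(6.07e-6, geom, initial, schedule)
        total = amounts["receiver_dpm"] + amounts["donor_end_dpm"]
        assert total.to_numpy() == pytest.approx(
            amounts["donor_start_dpm"].to_numpy(), rel=1e-9
        )

    def test_sink_limit_cleared_volume(self, geom, schedule):
        """For Papp·A·t ≪ V_D, cumulative cleared volume ≈ Papp·A·t."""
        papp = 1e-6
        table = simulate_transwell(
            SimulationConfig(papp, 0.0, 1, seed=0, noise_model="none"), geom
        )
        cleared = (
            table["receiver_dpm"].cumsum() / table["donor_dpm_per_ul"]
        ).to_numpy()
        expected = papp * geom.area_cm2 * 6e4 * np.asarray(schedule.times_min)
        assert cleared == pytest.approx(expected, rel=0.01)

    def test_zero_permeability_reads_background_only(self, geom):
        tracer = TracerSpec("t", 0.15, 643.0, background_dpm=30.0)
        table = simulate_transwell(
            SimulationConfig(0.0, 0.0, 2, seed=0, noise_model="none"), geom, tracer
        )
        assert (table["receiver_dpm"] == 30.0).all()

    def test_monotone_in_time_and_permeability(self, geom, schedule):
        initial = SUCROSE_TRACER.dpm_per_ul * geom.donor_volume_ul
        cum_low = transwell_interval_amounts(2e-6, geom, initial, schedule)[
            "receiver_dpm"
        ].cumsum()
        cum_high = transwell_interval_amounts(8e-6, geom, initial, schedule)[
            "receiver_dpm"
        ].cumsum()
        assert cum_low.is_monotonic_increasing and cum_high.is_monotonic_increasing
        assert (cum_high > cum_low).all()

    def test_insert_variability_is_mean_preserving(self, geom):
        table = simulate_transwell(
            SimulationConfig(6.07e-6, 0.28, 4000, seed=7, noise_model="none"), geom
        )
        per_insert = table.groupby("insert_id")["true_papp_cm_s"].first()
        assert per_insert.mean() == pytest.approx(6.07e-6, rel=0.02)
        assert per_insert.std() / per_insert.mean() == pytest.approx(0.28, rel=0.1)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            SimulationConfig(-1e-6)
        with pytest.raises(ValueError):
            InsertGeometry(area_cm2=0.0)
        with pytest.raises(ValueError):
            TransferSchedule(times_min=())
        with pytest.raises(ValueError):
            TransferSchedule(times_min=(5.0, 5.0))


class TestTeerBatchGenerator:
    def test_inverts_correction_formula(self):
        """sd=0 at mean 789 over a 120 Ω blank gives raw 818.2 Ω everywhere."""
        table = simulate_teer_batch(5, 789.0, 0.0, blank_ohm=120.0)
        assert table["raw_ohm"].to_numpy() == pytest.approx(818.23, abs=0.01)

    def test_zero_mean_reads_blank(self):
        table = simulate_teer_batch(5, 0.0, 0.0, blank_ohm=120.0)
        assert (table["raw_ohm"] == 120.0).all()

    def test_raw_never_below_blank(self):
        table = simulate_teer_batch(500, 50.0, 200.0, blank_ohm=120.0, seed=3)
        assert (table["raw_ohm"] >= 120.0).all()

    def test_rejects_empty_batch(self):
        with pytest.raises(ValueError):
            simulate_teer_batch(0, 789.0, 10.0)


class TestUptakeGenerator:
    def test_identity_factor_makes_groups_equal(self):
        table = simulate_uptake_plate(factor=1.0, noise_sd=0.0)
        ctrl = table[table["condition"] == "control"].drop(columns=["well_id", "condition"])
        test = table[table["condition"] == "inhibitor"].drop(columns=["well_id", "condition"])
        assert np.allclose(ctrl.to_numpy(dtype=float), test.to_numpy(dtype=float))

    def test_marker_channel_encodes_nonspecific_space(self):
        table = simulate_uptake_plate(
            vd_control_ul_mg=20.0, factor=1.34, nonspecific_vd_ul_mg=5.0, noise_sd=0.0
        )
        marker_vd = (
            table["marker_dpm"]
            / (table["marker_aliquot_dpm"] / table["aliquot_ul"])
            / table["protein_mg"]
        )
        assert marker_vd.to_numpy() == pytest.approx(5.0, rel=1e-12)

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            simulate_uptake_plate(noise_sd=-0.1)


class TestQpcrGenerator:
    def test_two_fold_quantity_is_one_ct_at_full_efficiency(self):
        plate = simulate_qpcr_plate({"g": {"a": 1.0, "b": 2.0}}, curve_slope=-3.3219)
        cts = plate.samples.groupby("sample_id")["ct"].mean()
        assert cts["a"] - cts["b"] == pytest.approx(1.0, rel=1e-4)

    def test_standard_ladder_is_tenfold(self):
        plate = simulate_qpcr_plate({"g": {"a": 1.0}}, n_standards=5)
        assert plate.standards["quantity"].tolist() == pytest.approx(
            [1.0, 0.1, 0.01, 0.001, 0.0001]
        )

    def test_zero_noise_triplicates_identical(self):
        plate = simulate_qpcr_plate({"g": {"a": 0.7}}, replicate_sd=0.0)
        assert plate.samples.groupby("sample_id")["ct"].std().fillna(0).eq(0).all()

    def test_rejects_positive_slope(self):
        with pytest.raises(ValueError):
            simulate_qpcr_plate({"g": {"a": 1.0}}, curve_slope=3.3)


@pytest.mark.parametrize(
    "factory",
    [
        lambda s: simulate_transwell(SimulationConfig(6e-6, 0.2, 5, seed=s)),
        lambda s: simulate_teer_batch(20, 789.0, 171.7, seed=s),
        lambda s: simulate_uptake_plate(noise_sd=0.05, seed=s),
        lambda s: simulate_qpcr_plate({"g": {"a": 1.0, "b": 2.0}}, replicate_sd=0.2, seed=s).data,
        lambda s: simulate_alp_plate({"PBEC": 25.0}, absorbance_sd=0.01, seed=s),
        lambda s: simulate_screen_table(seed=s),
    ],
    ids=["transwell", "teer", "uptake", "qpcr", "alp", "screen"],
)
def test_generators_are_seed_deterministic(factory):
    """The same seed reproduces every generated table bit-for-bit."""
    pd.testing.assert_frame_equal(factory(11), factory(11))
    a, b = factory(11), factory(12)
    assert not a.equals(b)
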