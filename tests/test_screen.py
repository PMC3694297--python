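"""Passive-permeation reference line and transporter-substrate calls."""

import math

import numpy as np
import pandas as pd
import pytest

from barrierkit import classify_transport, fit_passive_line, simulate_screen_table

#: four passive calibrators with realistic scatter; OLS gives R² ≈ 0.96 as in
#: a well-behaved reference set (synthetic values, constructed for this test)
REALISTIC_REFS = pd.DataFrame(
    {
        "name": ["sucrose", "naloxone", "propranolol", "diazepam"],
        "logp": [-3.7, 2.1, 3.0, 2.8],
        "papp_cm_s": [6.524e-6, 2.802e-5, 3.188e-5, 2.621e-5],
        "is_reference": [True] * 4,
    }
)


def exact_line_table(slope=4e-6, intercept=2.087e-5, logps=(-3.7, 0.0, 2.0, 3.0)):
    return pd.DataFrame(
        {
            "name": [f"ref{i}" for i in range(len(logps))],
            "logp": logps,
            "papp_cm_s": [slope * x + intercept for x in logps],
            "is_reference": [True] * len(logps),
        }
    )


class TestFitPassiveLine:
    def test_exact_points_fit_perfectly(self):
        line = fit_passive_line(exact_line_table())
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)
        assert line.residual_scale == pytest.approx(0.0, abs=1e-12)
        assert line.slope == pytest.approx(4e-6, rel=1e-9)

    def test_two_references_define_the_line(self):
        table = exact_line_table(logps=(-3.7, 2.8))
        line = fit_passive_line(table)
        assert line.r_squared == 1.0 and line.residual_scale == 0.0

    def test_realistic_reference_scatter(self):
        line = fit_passive_line(REALISTIC_REFS)
        assert line.r_squared == pytest.approx(0.96, abs=0.01)
        assert line.slope > 0

    def test_fit_ignores_non_reference_compounds(self):
        table = exact_line_table()
        base = fit_passive_line(table)
        extra = pd.concat(
            [
                table,
                pd.DataFrame(
                    {"name": ["outlier"], "logp": [1.0], "papp_cm_s": [9e-5],
                     "is_reference": [False]}
                ),
            ],
            ignore_index=True,
        )
        with_extra = fit_passive_line(extra)
        assert with_extra.slope == base.slope and with_extra.intercept == base.intercept

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            fit_passive_line(exact_line_table(logps=(1.0,)))
        with pytest.raises(ValueError):
            fit_passive_line(exact_line_table(logps=(1.0, 1.0)))

    def test_log_scale_option(self):
        """Points exactly on a log-linear relation fit perfectly in log space
        and predict back on the linear scale."""
        logps = np.array([-3.7, 0.0, 2.0, 3.0])
        papp = 10.0 ** (0.3 * logps - 5.0)
        table = pd.DataFrame(
            {"name": [f"r{i}" for i in range(4)], "logp": logps,
             "papp_cm_s": papp, "is_reference": [True] * 4}
        )
        line = fit_passive_line(table, log_scale=True)
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)
        assert line.predict(logps) == pytest.approx(papp, rel=1e-9)


class TestClassification:
    def test_programmed_outliers_called_by_direction(self):
        """Compounds placed five margins off the line are called by sign:
        carrier-uptake above, efflux/active removal below."""
        table = simulate_screen_table(offset_margins=5.0, seed=2)
        line = fit_passive_line(table)
        res = classify_transport(table, line)
        assert (res["transport_class"] == res["known_class"]).all()

    def test_on_line_compound_is_passive(self):
        table = exact_line_table()
        extra = pd.concat(
            [
                table,
                pd.DataFrame(
                    {"name": ["onliner"], "logp": [1.5],
                     "papp_cm_s": [4e-6 * 1.5 + 2.087e-5], "is_reference": [False]}
                ),
            ],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="absolute-margin"):
            res = classify_transport(extra, fit_passive_line(extra))
        assert (res["transport_class"] == "passive").all()

    def test_infinite_k_calls_everything_passive(self):
        table = simulate_screen_table(offset_margins=5.0, ref_noise_sd_cm_s=0.3e-6, seed=0)
        line = fit_passive_line(table)
        assert line.residual_scale > 0
        res = classify_transport(table, line, k=math.inf)
        assert (res["transport_class"] == "passive").all()

    def test_row_order_does_not_matter(self):
        table = simulate_screen_table(seed=5)
        line = fit_passive_line(table)
        straight = classify_transport(table, line)
        shuffled = classify_transport(
            table.sample(frac=1.0, random_state=1), line
        ).sort_index()
        assert (straight["transport_class"] == shuffled["transport_class"]).all()

    def test_reference_compounds_keep_their_residuals(self):
        table = simulate_screen_table(seed=3)
        res = classify_transport(table, fit_passive_line(table))
        refs = res[res["is_reference"]]
        assert refs["residual"].notna().all()
        assert (refs["transport_class"] == "passive").all()
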