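"""Permeability screen: passive Log P line and transporter-substrate calls.

Reads results/raw/screen_table.csv (regenerated if absent), fits the
passive-permeation reference line over the four calibrators, classifies all
ten compounds and writes results/screen_classes.csv plus a figure of Papp
against calculated Log P (results/screen_plot.png).
"""

import assay_conditions as cond

from barrierkit import io as bio
from barrierkit.cli import plot_screen
from barrierkit.screen import classify_transport, fit_passive_line
from barrierkit.synthetic import simulate_screen_table


def main():
    path = cond.RAW / "screen_table.csv"
    table = (bio.read_screen_csv(path) if path.exists()
             else simulate_screen_table(seed=cond.SEED + 5))
    line = fit_passive_line(table)
    res = classify_transport(table, line)
    bio.write_table(res, cond.RESULTS / "screen_classes.csv")
    plot_screen(res, line, str(cond.RESULTS / "screen_plot.png"))

    print(f"Passive line: Papp = {line.slope:.3g}·LogP + {line.intercept:.3g} cm/s, "
          f"R² = {line.r_squared:.3f}")
    for row in res.itertuples(index=False):
        mark = "ref" if row.is_reference else f"{row.residual:+.2g} residual"
        print(f"  {row.name:<12} LogP {row.logp:+5.2f}  "
              f"Papp {row.papp_cm_s:.3g}  → {row.transport_class} ({mark})")
    agree = (res["transport_class"] == res["known_class"]).mean()
    print(f"Agreement with programmed classes: {agree:.0%}")


if __name__ == "__main__":
    main()
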