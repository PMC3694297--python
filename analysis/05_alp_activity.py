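"""ALP marker-enzyme activity per mg protein and the PBEC/RBE4 ratio.

Reads results/raw/alp_plate.csv (regenerated if absent), writes
results/alp_activity.csv and prints group means and their ratio.
"""

import assay_conditions as cond

from barrierkit import io as bio
from barrierkit.synthetic import simulate_alp_plate
from barrierkit.uptake import alp_group_ratio, process_alp_table


def main():
    path = cond.RAW / "alp_plate.csv"
    table = (bio.read_alp_csv(path) if path.exists() else simulate_alp_plate(
        cond.ALP_ACTIVITIES, n_wells=cond.N_PER_CONDITION,
        absorbance_sd=0.01, seed=cond.SEED + 3))
    res = process_alp_table(table)
    bio.write_table(res, cond.RESULTS / "alp_activity.csv")

    means = res.groupby("group")["activity_au_per_mg"].mean()
    for group, mean in means.items():
        print(f"{group}: {mean:.2f} AU/mg protein")
    ratio = alp_group_ratio(
        res.loc[res["group"] == "PBEC", "activity_au_per_mg"],
        res.loc[res["group"] == "RBE4", "activity_au_per_mg"])
    print(f"PBEC/RBE4 activity ratio: {ratio:.1f}× "
          "(barrier-type cultures retain the marker enzyme)")


if __name__ == "__main__":
    main()
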