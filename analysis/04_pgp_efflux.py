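"""P-gp function: colchicine distribution volumes ± verapamil → factor increase.

Reads results/raw/uptake_plate.csv (regenerated if absent), writes
results/pgp_vd.csv and prints the marker-corrected group means and the
verapamil factor increase.
"""

import assay_conditions as cond

from barrierkit import io as bio
from barrierkit.synthetic import simulate_uptake_plate
from barrierkit.uptake import process_uptake_table


def main():
    path = cond.RAW / "uptake_plate.csv"
    table = (bio.read_uptake_csv(path) if path.exists() else simulate_uptake_plate(
        cond.N_PER_CONDITION, cond.N_PER_CONDITION, cond.VD_CONTROL,
        cond.PGP_FACTOR, cond.NONSPECIFIC_VD,
        noise_sd=cond.UPTAKE_NOISE_SD, seed=cond.SEED + 2))
    res, factor = process_uptake_table(table)
    bio.write_table(res, cond.RESULTS / "pgp_vd.csv")

    print(f"Corrected colchicine Vd: control {factor.mean_control:.2f}, "
          f"verapamil {factor.mean_test:.2f} μl/mg protein "
          f"(n = {factor.n_control}/{factor.n_test})")
    print(f"Factor increase (verapamil/control): {factor.factor:.3f} "
          f"(programmed {cond.PGP_FACTOR})")
    print("A factor > 1 indicates functional P-gp efflux blocked by the inhibitor.")


if __name__ == "__main__":
    main()
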