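"""Blank/area-correct the TEER batch and apply the 500 Ω·cm² QC gate.

Reads results/raw/teer_batch.csv (regenerated if absent), writes
results/teer_qc.csv and prints the batch mean ± SEM and QC pass rate.
"""

import numpy as np

import assay_conditions as cond

from barrierkit import io as bio
from barrierkit.synthetic import simulate_teer_batch
from barrierkit.teer import process_teer_table


def main():
    path = cond.RAW / "teer_batch.csv"
    table = (bio.read_teer_csv(path) if path.exists() else simulate_teer_batch(
        cond.N_TEER_INSERTS, cond.MEAN_TEER, cond.TEER_SD,
        blank_ohm=cond.BLANK_OHM, seed=cond.SEED))
    res = process_teer_table(table)
    bio.write_table(res, cond.RESULTS / "teer_qc.csv")

    teer = res["teer_ohm_cm2"]
    sem = teer.std(ddof=1) / np.sqrt(len(teer))
    n_pass = int(res["qc_teer_pass"].sum())
    print(f"TEER batch: n={len(res)}, mean±SEM = {teer.mean():.0f}±{sem:.0f} Ω·cm²")
    print(f"QC (> 500 Ω·cm², strict): {n_pass}/{len(res)} inserts pass")
    print("Inserts failing the gate would be excluded from permeability work.")


if __name__ == "__main__":
    main()
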