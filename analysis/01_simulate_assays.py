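"""Generate every raw assay table at the study conditions → results/raw/.

Writes the TEER batch, sucrose clearance series, dual-label uptake plate,
ALP plate, qPCR plate and Log P screen table that the numbered analyses
consume.  All tables are seed-deterministic; the later drivers regenerate
them identically, so this script exists to put the raw data on disk.
"""

import assay_conditions as cond

from barrierkit import io as bio
from barrierkit.synthetic import (
    SimulationConfig,
    simulate_alp_plate,
    simulate_qpcr_plate,
    simulate_screen_table,
    simulate_teer_batch,
    simulate_transwell,
    simulate_uptake_plate,
)


def qpcr_truth():
    truth = {cond.REFERENCE_GENE: {}}
    for i in range(cond.N_SAMPLES_PER_GROUP):
        truth[cond.REFERENCE_GENE][f"batch1_{i}"] = 1.0
        truth[cond.REFERENCE_GENE][f"batch2_{i}"] = 1.0
    for gene, fold in cond.GENE_FOLDS.items():
        truth[gene] = {}
        for i in range(cond.N_SAMPLES_PER_GROUP):
            truth[gene][f"batch1_{i}"] = 1.0
            truth[gene][f"batch2_{i}"] = fold
    return truth


def main():
    cond.RAW.mkdir(parents=True, exist_ok=True)
    tables = {
        "teer_batch.csv": simulate_teer_batch(
            cond.N_TEER_INSERTS, cond.MEAN_TEER, cond.TEER_SD,
            blank_ohm=cond.BLANK_OHM, seed=cond.SEED),
        "sucrose_clearance.csv": simulate_transwell(
            SimulationConfig(cond.MEAN_SUCROSE_PAPP, 0.0, cond.N_PAPP_INSERTS,
                             seed=cond.SEED + 1, noise_model="poisson")),
        "uptake_plate.csv": simulate_uptake_plate(
            cond.N_PER_CONDITION, cond.N_PER_CONDITION, cond.VD_CONTROL,
            cond.PGP_FACTOR, cond.NONSPECIFIC_VD,
            noise_sd=cond.UPTAKE_NOISE_SD, seed=cond.SEED + 2),
        "alp_plate.csv": simulate_alp_plate(
            cond.ALP_ACTIVITIES, n_wells=cond.N_PER_CONDITION,
            absorbance_sd=0.01, seed=cond.SEED + 3),
        "qpcr_plate.csv": simulate_qpcr_plate(
            qpcr_truth(), replicate_sd=cond.QPCR_REPLICATE_SD,
            seed=cond.SEED + 4).data,
        "screen_table.csv": simulate_screen_table(seed=cond.SEED + 5),
    }
    for name, df in tables.items():
        path = bio.write_table(df, cond.RAW / name)
        print(f"wrote {path} ({len(df)} rows)")


if __name__ == "__main__":
    main()
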