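"""Shared study conditions and seeds for the numbered analysis drivers.

Each driver regenerates its inputs deterministically from these constants,
so the scripts can run standalone and in any order; 01_simulate_assays.py
writes the same raw tables to disk for inspection.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
RAW = RESULTS / "raw"

SEED = 20260923

# barrier quality of the primary porcine brain endothelial monolayers
MEAN_TEER = 789.0        # Ω·cm², batch mean (n = 91 inserts)
TEER_SD = 171.7          # Ω·cm² (reported SEM 18 × √91)
N_TEER_INSERTS = 91
BLANK_OHM = 120.0

MEAN_SUCROSE_PAPP = 6.07e-6  # cm/s, batch mean
N_PAPP_INSERTS = 29          # inserts in the permeability batches

# P-gp functional assay
PGP_FACTOR = 1.34        # verapamil / control corrected Vd
VD_CONTROL = 20.0        # μl/mg, specific colchicine distribution volume
NONSPECIFIC_VD = 5.0     # μl/mg, sucrose-marker space
UPTAKE_NOISE_SD = 0.05
N_PER_CONDITION = 6

# ALP marker enzyme: barrier-type culture vs the comparison cell line (~20x)
ALP_ACTIVITIES = {"PBEC": 25.0, "RBE4": 1.25}  # AU/mg

# qPCR batch-stability monitoring: programmed batch2/batch1 fold changes
GENE_FOLDS = {"BCRP": 1.5, "occludin": 1.2, "claudin5": 1.1}
REFERENCE_GENE = "GAPDH"
QPCR_REPLICATE_SD = 0.15
N_SAMPLES_PER_GROUP = 6
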