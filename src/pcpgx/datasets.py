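"""Printed study tables used by the cohort statistics.

Small data tables transcribed from the published characterization of the
RS0 / RS1/2 rat pheochromocytoma models: the embryo-arrest contingency
counts, NMR metabolite abundance profiles, the HIF2a-network RPKM marker
table and the whole-genome mutation counts. These are inputs to the
statistics layer, kept here so analyses are reproducible without any
external download.
"""

from __future__ import annotations

import pandas as pd

from .stats import ContingencyTable2x2

#: Embryos stalled vs developing in heterozygote x heterozygote crosses
#: (9 of 31) compared with wild-type pregnancies (1 of 31).
EMBRYO_ARREST_TABLE = ContingencyTable2x2(a=9, b=22, c=1, d=30)

#: Coding-region size of the rat genome (rn6), in megabases.
CODING_GENOME_MB = 37.48

#: Accepted somatic coding mutation counts per model (2-of-3 caller vote).
MUTATION_COUNTS = {"RS0": 30, "RS1/2": 36}

#: Ten most abundant detectable metabolites (umol/mg tissue), per column of
#: the NMR metabolomic profile table. RS0 shows the diagnostic succinate
#: accumulation (rank 3) absent from normal adrenal medulla (RAM).
METABOLITES_RS0 = [
    ("Lactate", 15.18),
    ("Taurine", 12.11),
    ("Succinate", 5.99),
    ("Glycine", 3.47),
    ("Glutamate", 2.57),
    ("Ascorbate", 2.57),
    ("Alanine", 2.08),
    ("Creatine", 1.39),
    ("sn-Glycero-3-phosphocholine", 1.29),
    ("myo-Inositol", 1.21),
]

METABOLITES_RAM = [
    ("Epinephrine", 16.15),
    ("Norepinephrine", 12.33),
    ("Glucose", 2.31),
    ("Lactate", 0.89),
    ("Taurine", 0.61),
    ("ATP", 0.59),
    ("Ascorbate", 0.44),
    ("AMP", 0.30),
    ("ADP", 0.21),
    ("Glutamate", 0.17),
    ("Succinate", 0.01),
]

METABOLITES_RS12 = [
    ("Norepinephrine", 33.87),
    ("Lactate", 11.45),
    ("Taurine", 10.38),
    ("Ascorbate", 7.61),
    ("myo-Inositol", 6.33),
    ("Glutamate", 4.16),
    ("Dopamine", 2.55),
    ("O-Phosphoethanolamine", 2.06),
    ("AMP", 1.85),
    ("Betaine", 1.83),
    ("Succinate", 0.29),
]

#: HIF2a regulatory-network marker expression (RPKM) in pooled rat adrenal
#: medulla (RAM) and the RS0 / RS1/2 xenografts, with the ratios as printed.
HIF2A_MARKER_RPKM = pd.DataFrame(
    [
        # gene,       RAM,    RS0,     RS1/2,  printed RS0/RAM, printed RS1/2/RAM
        ("Epas1", 80.01, 1074.63, 76.62, 13.43, 0.96),
        ("Egln3", 1.44, 23.29, 0.00, 16.17, 0.00),
        ("Bhlhe40", 10.99, 114.01, 11.77, 10.37, 1.07),
        ("Vegfa", 51.43, 607.36, 62.04, 11.81, 1.21),
        ("Twist1", 1.86, 14.82, 0.50, 7.95, 0.27),
        ("Serpine1", 2.65, 241.62, 5.99, 1.18, 2.23),
        ("Adora2a", 5.41, 593.88, 2.99, 109.78, 0.55),
    ],
    columns=["gene", "RAM", "RS0", "RS12", "printed_rs0_ram", "printed_rs12_ram"],
)

#: Printed ratio cells that cannot be recomputed from the printed RPKM
#: inputs (transcription/arithmetic slips in the source table); the mapping
#: gives the value recomputation yields. They are excluded from
#: printed-value equality checks and reported with a flag instead.
MARKER_RATIO_DISCREPANCIES = {
    ("Twist1", "rs0_ram"): 7.97,      # printed 7.95
    ("Serpine1", "rs0_ram"): 91.18,   # printed 1.18
    ("Serpine1", "rs12_ram"): 2.26,   # printed 2.23
    ("Adora2a", "rs0_ram"): 109.77,   # printed 109.78 (593.88/5.41 = 109.7745)
}
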