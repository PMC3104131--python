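"""Bundled example data: a reported rare-CNV call set.

The table reproduces the rare, gene-containing CNVs reported from a
whole-genome aCGH screen of 186 individuals with single-suture
craniosynostosis: per patient, the affected band, interval coordinates
(NCBI Build 36, printed in Mb), the printed size, the inheritance label
(Inh (M)/Inh (P)/Unk) and the listed candidate genes. It serves as a small
real-world call set for size arithmetic, large-event counting and burden
examples; no probe-level data accompany it.

Two rows are internally inconsistent as printed — their coordinate
difference does not equal the printed size (6p21: 46.12 - 44.99 = 1.13 vs
printed 1.10; SAG02: 74.60 - 74.25 = 0.35 vs printed 0.04) — and are flagged
``consistent=False``. Sizes recomputed here always use coordinates.
"""

from __future__ import annotations

from typing import List

import pandas as pd

from .core import GAIN, LOSS, CnvSegment

COHORT_N = 186
CONTROL_N = 2_493
#: Reported number of control individuals carrying an event > 2 Mb.
CONTROL_LARGE_EVENT_CARRIERS_2MB = 8

# sample, band, chrom, start_mb, end_mb, printed_size_mb, type, inheritance, genes
_ROWS = [
    ("4038", "9q22 del", "chr9", 93.59, 97.51, 3.92, LOSS, "Unk", "ROR2,ECM2"),
    ("1056", "3p25 dup", "chr3", 11.96, 15.30, 3.34, GAIN, "Inh (P)", "FBLN2,TMEM43"),
    ("2082", "5p15 dup", "chr5", 7.59, 10.06, 2.47, GAIN, "Inh (M)", "SEMA5A,FASTKD3"),
    ("1061", "1q43 dup", "chr1", 239.34, 240.99, 1.65, GAIN, "Inh (M)", "RGS7"),
    ("1007", "6p21 dup", "chr6", 44.99, 46.12, 1.10, GAIN, "Inh (M)", "RUNX2"),
    ("1019", "6p21 dup", "chr6", 44.99, 46.12, 1.10, GAIN, "Inh (P)", "RUNX2"),
    ("2076", "2q14 dup", "chr2", 115.97, 116.70, 0.73, GAIN, "Unk", "DPP10"),
    ("1012", "17q25 del", "chr17", 78.05, 78.65, 0.60, LOSS, "Inh (M)", "WDR45L,TBCD"),
    ("1063", "6q26 del", "chr6", 162.84, 163.46, 0.62, LOSS, "Unk", "PARK2,PACRG"),
    ("2003", "11q25 dup", "chr11", 130.22, 130.67, 0.45, GAIN, "Unk", "SNX19"),
    ("1020", "2p21 dup", "chr2", 45.75, 46.15, 0.40, GAIN, "Unk", "PRKCE"),
    ("2024", "7q36 del", "chr7", 158.17, 158.33, 0.16, LOSS, "Unk", "ESYT2"),
    ("4033", "12p12 del", "chr12", 18.12, 18.20, 0.08, LOSS, "Unk", "RERGL"),
    ("SAG02", "9q21 del", "chr9", 74.25, 74.60, 0.04, LOSS, "Unk", "TMC1"),
]


def craniosynostosis_rare_calls() -> pd.DataFrame:
    """The reported rare-CNV table, one row per patient call.

    Columns include exact bp coordinates (printed Mb x 1e6) and a
    ``consistent`` flag marking rows whose printed size equals the coordinate
    difference to 2 decimals.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=["sample", "band", "chromosome", "start_mb", "end_mb",
                 "printed_size_mb", "state", "inheritance", "genes"],
    )
    df["start"] = (df["start_mb"] * 1e6).round().astype(int)
    df["end"] = (df["end_mb"] * 1e6).round().astype(int)
    df["coordinate_size_mb"] = ((df["end"] - df["start"]) / 1e6).round(2)
    df["consistent"] = (df["coordinate_size_mb"] - df["printed_size_mb"]).abs() < 0.005
    return df


def craniosynostosis_segments(consistent_only: bool = False) -> List[CnvSegment]:
    """The same call set as :class:`CnvSegment` objects (coordinate-derived
    sizes; probe counts are not published, so ``n_probes`` is set to the
    5-probe reporting floor and ``mean_z`` to 0)."""
    df = craniosynostosis_rare_calls()
    if consistent_only:
        df = df[df["consistent"]]
    return [
        CnvSegment(
            chromosome=row.chromosome,
            start=row.start,
            end=row.end,
            state=row.state,
            n_probes=5,
            mean_z=0.0,
            sample_id=row.sample,
            genes=row.genes.split(","),
            rare=True,
        )
        for row in df.itertuples()
    ]
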