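"""On-disk formats: probe tables (TSV), BED4 intervals, call tracks and reports.

Probe tables are neutral 3-column TSVs (chromosome, position, log2_ratio) —
one file per sample, platform-independent. All interval files follow BED
conventions: 0-based half-open, name column carrying the payload (gene
symbol, or gain/loss type). Reports display sizes in Mb to 2 decimals; the
BED track keeps exact coordinates so write -> read is the identity.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotate import InheritanceCall
from .core import (
    CnvSegment,
    GenomicInterval,
    ProbeTrack,
    normalize_chromosome,
)
from .errors import (
    DuplicateProbeError,
    IntervalError,
    NonFiniteRatioError,
    ProbeTableParseError,
)

PROBE_COLUMNS = ("chromosome", "position", "log2_ratio")


def read_probe_table(path: Union[str, Path], sample_id: Optional[str] = None) -> ProbeTrack:
    """Read one sample's probe table.

    Rows are grouped by chromosome and sorted by position regardless of file
    order. Malformed rows raise :class:`ProbeTableParseError` naming the
    (1-based) file line; NaN/inf ratios raise :class:`NonFiniteRatioError`;
    repeated (chromosome, position) pairs raise :class:`DuplicateProbeError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ProbeTableParseError(f"{path}: empty probe table")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ProbeTableParseError(f"{path}: missing columns {sorted(missing)}")

    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = pos.isna() | (df["chromosome"].str.strip() == "")
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ProbeTableParseError(f"{path}: malformed row at line {line}")
    ratio = pd.to_numeric(df["log2_ratio"], errors="coerce")
    malformed = ratio.isna() & ~df["log2_ratio"].str.strip().str.lower().isin(
        ["nan", "-nan", "+nan"]
    )
    if malformed.any():
        line = int(malformed.idxmax()) + 2
        raise ProbeTableParseError(f"{path}: malformed row at line {line}")
    # re-parse with Python's correctly-rounded float(): the pandas parser can
    # be one ulp off, breaking bit-exact round trips
    exact = np.array([float(s) for s in df["log2_ratio"]], dtype=np.float64)
    finite = np.isfinite(exact)
    if not finite.all():
        line = int(np.argmin(finite)) + 2
        raise NonFiniteRatioError(f"{path}: non-finite log2 ratio at line {line}")

    work = pd.DataFrame(
        {
            "chromosome": df["chromosome"].map(normalize_chromosome),
            "position": pos.astype(np.int64),
            "log2_ratio": exact,
        }
    )
    dup = work.duplicated(subset=["chromosome", "position"])
    if dup.any():
        row = work[dup].iloc[0]
        raise DuplicateProbeError(
            f"{path}: duplicate probe at {row.chromosome}:{row.position}"
        )
    chroms: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in work.groupby("chromosome", sort=False):
        grp = grp.sort_values("position")
        chroms[chrom] = (grp["position"].to_numpy(), grp["log2_ratio"].to_numpy())
    return ProbeTrack(sample_id or path.stem, chroms)


def write_probe_table(track: ProbeTrack, path: Union[str, Path]) -> None:
    rows = [
        (chrom, int(p), repr(float(v)))
        for chrom, (pos, val) in track
        for p, v in zip(pos, val)
    ]
    pd.DataFrame(rows, columns=list(PROBE_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_bed_intervals(path: Union[str, Path], payload_column: int = 3) -> List[GenomicInterval]:
    """Read BED-style intervals (0-based half-open), preserving file order.

    ``payload_column`` is the 0-based index of the column stored as payload;
    rows shorter than it get an empty payload.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise IntervalError(f"{path}: line {lineno} has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise IntervalError(f"{path}: non-integer coordinate at line {lineno}")
            payload = fields[payload_column] if len(fields) > payload_column else ""
            intervals.append(GenomicInterval(fields[0], start, end, payload))
    return intervals


def write_bed_intervals(intervals: Sequence[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{iv.payload}\n")


REPORT_COLUMNS = ("sample", "locus", "size_mb", "inheritance", "genes", "state",
                  "chromosome", "start", "end", "n_probes", "mean_z", "rare")


def write_calls(
    segments: Sequence[CnvSegment],
    out_prefix: Union[str, Path],
    inheritance: Optional[Sequence[InheritanceCall]] = None,
) -> Tuple[Path, Path]:
    """Write a call set as ``<prefix>.bed`` plus ``<prefix>.report.tsv``.

    The BED track (chromosome, start, end, state) round-trips exactly through
    :func:`read_calls_bed`. The report mirrors a per-patient CNV table: a
    cytoband-free locus string "chrN: <start Mb>-<end Mb> Mb" (coordinates
    divided by 1e6, 2 decimals), size in Mb to 2 decimals, gene list, rarity
    flag, and (when verdicts are supplied) an inheritance label; exact bp
    coordinates ride along in their own columns.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = out_prefix.with_suffix(".bed")
    report_path = out_prefix.with_suffix(".report.tsv")
    with open(bed_path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chromosome}\t{seg.start}\t{seg.end}\t{seg.state}\n")
    labels = (
        [call.label for call in inheritance]
        if inheritance is not None
        else ["Unk"] * len(segments)
    )
    rows = [
        {
            "sample": seg.sample_id,
            "locus": f"{seg.chromosome}: {seg.start / 1e6:.2f}-{seg.end / 1e6:.2f} Mb",
            "size_mb": f"{seg.size_mb:.2f}",
            "inheritance": label,
            "genes": ",".join(seg.genes),
            "state": seg.state,
            "chromosome": seg.chromosome,
            "start": seg.start,
            "end": seg.end,
            "n_probes": seg.n_probes,
            "mean_z": f"{seg.mean_z:.4f}",
            "rare": "" if seg.rare is None else str(bool(seg.rare)),
        }
        for seg, label in zip(segments, labels)
    ]
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(report_path, sep="\t", index=False)
    return bed_path, report_path


def read_calls_bed(path: Union[str, Path]) -> List[GenomicInterval]:
    """Read a call BED track back as intervals with gain/loss payloads."""
    return read_bed_intervals(path, payload_column=3)


def read_call_report(path: Union[str, Path]) -> List[CnvSegment]:
    """Reconstruct segments from a ``.report.tsv`` (used by cohort summaries)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    segments: List[CnvSegment] = []
    for _, row in df.iterrows():
        segments.append(
            CnvSegment(
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
                state=row["state"],
                n_probes=int(row["n_probes"]),
                mean_z=float(row["mean_z"]),
                sample_id=row["sample"],
                genes=[g for g in row["genes"].split(",") if g],
                rare=None if row["rare"] == "" else row["rare"] == "True",
            )
        )
    return segments
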