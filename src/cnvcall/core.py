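"""Core domain containers: probe tracks, intervals, state tracks and CNV segments.

Coordinates are 0-based, half-open (BED convention) throughout the package.
Chromosome names are normalized to the ``chr``-prefixed form on construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .errors import AlignmentError, IntervalError

# Hidden-state codes of the three-state copy-number HMM.
STATE_DECREASED = 0
STATE_NORMAL = 1
STATE_INCREASED = 2
STATE_NAMES = {STATE_DECREASED: "decreased", STATE_NORMAL: "normal", STATE_INCREASED: "increased"}
#: Tie-break preference on equal path scores: bias toward no-call.
STATE_PREFERENCE = (STATE_NORMAL, STATE_INCREASED, STATE_DECREASED)

GAIN = "gain"
LOSS = "loss"


def normalize_chromosome(name: str) -> str:
    """Return a ``chr``-prefixed chromosome name ('1' and 'chr1' both -> 'chr1')."""
    name = str(name).strip()
    if not name:
        raise IntervalError("empty chromosome name")
    return name if name.lower().startswith("chr") else "chr" + name


def chromosome_sort_key(name: str) -> Tuple[int, str]:
    """Natural ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    body = name[3:] if name.lower().startswith("chr") else name
    m = re.fullmatch(r"\d+", body)
    return (int(body), "") if m else (10**9, body)


@dataclass
class GenomicInterval:
    """Half-open genomic interval with a free-text payload (gene name or CNV type)."""

    chromosome: str
    start: int
    end: int
    payload: str = ""

    def __post_init__(self) -> None:
        self.chromosome = normalize_chromosome(self.chromosome)
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0:
            raise IntervalError(f"negative start {self.start} on {self.chromosome}")
        if self.start >= self.end:
            raise IntervalError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class ProbeTrack:
    """Per-chromosome ordered probe positions with one real value per probe.

    The same container holds raw log2 ratios and (in :class:`ZScoreTrack`)
    standardized z-scores; ``values`` is interpreted by context.
    """

    def __init__(
        self,
        sample_id: str,
        chromosomes: Dict[str, Tuple[np.ndarray, np.ndarray]],
        genome_label: str = "",
    ) -> None:
        self.sample_id = sample_id
        self.genome_label = genome_label
        self.chromosomes: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(chromosomes, key=chromosome_sort_key):
            pos, val = chromosomes[chrom]
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.float64)
            if pos.size == 0:
                raise IntervalError(f"chromosome {chrom} has no probes")
            if pos.size != val.size:
                raise AlignmentError(f"{chrom}: {pos.size} positions vs {val.size} values")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise IntervalError(f"{chrom}: probe positions not strictly increasing")
            if not np.all(np.isfinite(val)):
                raise IntervalError(f"{chrom}: non-finite probe values")
            self.chromosomes[normalize_chromosome(chrom)] = (pos, val)

    def n_probes(self) -> int:
        return sum(pos.size for pos, _ in self.chromosomes.values())

    def __iter__(self):
        return iter(self.chromosomes.items())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ProbeTrack({self.sample_id!r}, {len(self.chromosomes)} chromosomes, "
            f"{self.n_probes()} probes)"
        )


class ZScoreTrack(ProbeTrack):
    """Probe track whose values are chromosome-standardized z-scores.

    ``stats`` maps chromosome -> (mean_log2, sd_log2) used in the transform.
    """

    def __init__(
        self,
        sample_id: str,
        chromosomes: Dict[str, Tuple[np.ndarray, np.ndarray]],
        stats: Dict[str, Tuple[float, float]],
        genome_label: str = "",
    ) -> None:
        super().__init__(sample_id, chromosomes, genome_label)
        self.stats = dict(stats)


@dataclass
class StateTrack:
    """Per-probe HMM state calls, aligned 1:1 with a probe track."""

    states: Dict[str, np.ndarray]  # chromosome -> int8 array of state codes

    def check_aligned(self, track: ProbeTrack) -> None:
        if set(self.states) != set(track.chromosomes):
            raise AlignmentError("state track and probe track cover different chromosomes")
        for chrom, s in self.states.items():
            n = track.chromosomes[chrom][0].size
            if len(s) != n:
                raise AlignmentError(f"{chrom}: {len(s)} states vs {n} probes")


@dataclass
class CnvSegment:
    """A called copy-number variant spanning the outermost affected probes."""

    chromosome: str
    start: int  # position of first probe in the run
    end: int  # last probe position + 1 (half-open, non-degenerate for 1-probe runs)
    state: str  # "gain" | "loss"
    n_probes: int
    mean_z: float
    sample_id: str = ""
    genes: List[str] = field(default_factory=list)
    rare: Optional[bool] = None  # None until the common-CNV filter has run

    def __post_init__(self) -> None:
        self.chromosome = normalize_chromosome(self.chromosome)
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(f"invalid segment {self.chromosome}:{self.start}-{self.end}")
        if self.state not in (GAIN, LOSS):
            raise IntervalError(f"segment state must be gain or loss, got {self.state!r}")
        if self.n_probes < 1:
            raise IntervalError("segment must contain at least one probe")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chromosome, self.start, self.end, self.state)


@dataclass
class ControlCatalog:
    """CNV intervals observed in unaffected individuals (the 'common' filter set)."""

    intervals: List[GenomicInterval]
    source_label: str = ""
    n_individuals: int = 1

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise IntervalError("control catalog needs n_individuals > 0")
        for iv in self.intervals:
            if iv.payload not in (GAIN, LOSS):
                raise IntervalError(f"catalog interval payload must be gain/loss, got {iv.payload!r}")


def sort_segments(segments: Iterable[CnvSegment]) -> List[CnvSegment]:
    return sorted(segments, key=lambda s: (chromosome_sort_key(s.chromosome), s.start, s.end))
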