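"""The calling pipeline: z-score normalization, three-state Gaussian-emission
HMM decoding, segment construction, rule-based merging, and filtering.

The five stages compose into :func:`call_sample`::

    zscore_normalize -> decode_states -> segments_from_states
        -> bridge_segments -> filter_min_probes -> filter_common

Probes are classified as copy-number "decreased", "normal" or "increased" by
the global maximum-a-posteriori (Viterbi) path of a three-state HMM whose
emissions are unit-variance Gaussians on per-chromosome z-scores, the outer
states centered ``emission_mean_shift`` standard deviations away from the
normal mean. Decoding runs independently per chromosome, in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .annotate import max_reciprocal_overlap
from .config import RunConfig
from .core import (
    GAIN,
    LOSS,
    STATE_DECREASED,
    STATE_INCREASED,
    STATE_NORMAL,
    STATE_PREFERENCE,
    CnvSegment,
    ControlCatalog,
    ProbeTrack,
    StateTrack,
    ZScoreTrack,
    chromosome_sort_key,
)
from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateVarianceError,
    InsufficientDataError,
    OrderingError,
)

__all__ = [
    "HmmModel",
    "zscore_normalize",
    "build_hmm",
    "decode_states",
    "segments_from_states",
    "bridge_segments",
    "filter_min_probes",
    "filter_common",
    "call_sample",
]


def zscore_normalize(track: ProbeTrack) -> ZScoreTrack:
    """Standardize log2 ratios to z-scores with the chromosome-specific mean
    and (sample, n-1 denominator) standard deviation.

    Raises
    ------
    InsufficientDataError
        if a chromosome carries fewer than 2 probes.
    DegenerateVarianceError
        if a chromosome has zero variance.
    """
    chroms: Dict[str, tuple] = {}
    stats: Dict[str, tuple] = {}
    for chrom, (pos, val) in track:
        if val.size < 2:
            raise InsufficientDataError(
                f"{chrom}: need >=2 probes for a standard deviation, have {val.size}"
            )
        mean = float(val.mean())
        sd = float(val.std(ddof=1))
        # constant input leaves only rounding residue in sd
        if sd < 1e-12 * max(1.0, abs(mean)):
            raise DegenerateVarianceError(f"{chrom}: all {val.size} ratios identical")
        chroms[chrom] = (pos, (val - mean) / sd)
        stats[chrom] = (mean, sd)
    return ZScoreTrack(track.sample_id, chroms, stats, track.genome_label)


@dataclass
class HmmModel:
    """Three-state copy-number HMM with Gaussian emissions on z-scores.

    State order is (decreased, normal, increased); emission means are
    ``(-shift, 0, +shift)`` with a common unit standard deviation.
    """

    emission_means: np.ndarray
    emission_sds: np.ndarray
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.emission_sds = np.asarray(self.emission_sds, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigError("transition matrix rows must sum to 1")
        if not math.isclose(self.initial_distribution.sum(), 1.0, abs_tol=1e-12):
            raise ConfigError("initial distribution must sum to 1")


def build_hmm(config: RunConfig) -> HmmModel:
    """HMM from config: outer emission means at +/- ``emission_mean_shift``
    z-units, unit sds, self-transition ``state_self_transition`` with the
    remaining mass split equally, uniform initial distribution."""
    s = config.state_self_transition
    if not 0.0 < s < 1.0:
        raise ConfigError(f"state_self_transition must lie in (0, 1), got {s}")
    d = config.emission_mean_shift
    off = (1.0 - s) / 2.0
    transition = np.full((3, 3), off)
    np.fill_diagonal(transition, s)
    return HmmModel(
        emission_means=np.array([-d, 0.0, d]),
        emission_sds=np.ones(3),
        transition_matrix=transition,
        initial_distribution=np.full(3, 1.0 / 3.0),
    )


def _viterbi_chromosome(model: HmmModel, z: np.ndarray) -> np.ndarray:
    """Global MAP state path for one chromosome, in log space.

    On exactly tied scores the state earlier in STATE_PREFERENCE
    (normal, increased, decreased) wins, biasing toward no-call.
    """
    means = model.emission_means
    sds = model.emission_sds
    # log N(z | mean_k, sd_k), vectorized over probes; constants kept so path
    # scores equal true log joint probabilities.
    loge = (
        -0.5 * ((z[:, None] - means[None, :]) / sds[None, :]) ** 2
        - np.log(sds)[None, :]
        - 0.5 * math.log(2.0 * math.pi)
    ).tolist()
    lt = np.log(model.transition_matrix).tolist()
    lpi = np.log(model.initial_distribution).tolist()

    n = len(z)
    score = [lpi[k] + loge[0][k] for k in range(3)]
    back = np.empty((n, 3), dtype=np.int8)
    for t in range(1, n):
        et = loge[t]
        new = [0.0, 0.0, 0.0]
        bt = back[t]
        for j in range(3):
            best_i = STATE_NORMAL
            best = score[STATE_NORMAL] + lt[STATE_NORMAL][j]
            for i in STATE_PREFERENCE[1:]:
                v = score[i] + lt[i][j]
                if v > best:
                    best, best_i = v, i
            new[j] = best + et[j]
            bt[j] = best_i
        score = new

    last = STATE_PREFERENCE[0]
    for k in STATE_PREFERENCE[1:]:
        if score[k] > score[last]:
            last = k
    path = np.empty(n, dtype=np.int8)
    path[-1] = last
    for t in range(n - 1, 0, -1):
        last = back[t][last]
        path[t - 1] = last
    return path


def decode_states(model: HmmModel, z: ZScoreTrack) -> StateTrack:
    """Viterbi-decode each chromosome independently (no transitions across
    chromosome boundaries)."""
    states = {chrom: _viterbi_chromosome(model, zvals) for chrom, (_, zvals) in z}
    out = StateTrack(states)
    out.check_aligned(z)
    return out


def segments_from_states(
    states: StateTrack, track: ProbeTrack, config: RunConfig
) -> List[CnvSegment]:
    """Turn per-probe state calls into segments.

    Maximal runs of consecutive same-state non-normal probes become segments;
    a run is split wherever two adjacent same-state probes lie
    ``merge_gap_bp`` or more apart (the merge rule is strict ``<``). Segment
    coordinates are the outermost probe positions of the run, half-open
    (end = last position + 1). ``track`` supplies the per-probe values
    averaged into ``mean_z``; in the standard pipeline it is the z-score track.
    """
    states.check_aligned(track)
    segments: List[CnvSegment] = []
    for chrom, (pos, val) in track:
        s = states.states[chrom]
        i, n = 0, len(s)
        while i < n:
            if s[i] == STATE_NORMAL:
                i += 1
                continue
            state = s[i]
            j = i
            while (
                j + 1 < n
                and s[j + 1] == state
                and pos[j + 1] - pos[j] < config.merge_gap_bp
            ):
                j += 1
            segments.append(
                CnvSegment(
                    chromosome=chrom,
                    start=int(pos[i]),
                    end=int(pos[j]) + 1,
                    state=GAIN if state == STATE_INCREASED else LOSS,
                    n_probes=j - i + 1,
                    mean_z=float(val[i : j + 1].mean()),
                    sample_id=track.sample_id,
                )
            )
            i = j + 1
    return segments


def _check_sorted(segments: List[CnvSegment]) -> None:
    keys = [(chromosome_sort_key(s.chromosome), s.start) for s in segments]
    if keys != sorted(keys):
        raise OrderingError("segments must be sorted by (chromosome, start)")


def bridge_segments(
    segments: List[CnvSegment],
    states: StateTrack,
    track: ProbeTrack,
    config: RunConfig,
) -> List[CnvSegment]:
    """Join nearby same-state segments across a short intervening sequence.

    Two adjacent segments of the same state are called as one variant when the
    intervening probes number at most ``bridge_max_probes`` AND the gap
    between the segments' facing boundaries spans at most ``bridge_max_bp``;
    the merged call includes the intervening probes. Applied iteratively to a
    fixed point, so chains of bridgeable segments collapse; segments of
    different states are never bridged.
    """
    states.check_aligned(track)
    _check_sorted(segments)
    segs = list(segments)
    changed = True
    while changed:
        changed = False
        out: List[CnvSegment] = []
        k = 0
        while k < len(segs):
            cur = segs[k]
            if (
                k + 1 < len(segs)
                and segs[k + 1].chromosome == cur.chromosome
                and segs[k + 1].state == cur.state
            ):
                nxt = segs[k + 1]
                pos, val = track.chromosomes[cur.chromosome]
                gap_lo = np.searchsorted(pos, cur.end, side="left")
                gap_hi = np.searchsorted(pos, nxt.start, side="left")
                n_between = int(gap_hi - gap_lo)
                span = nxt.start - cur.end
                if n_between <= config.bridge_max_probes and span <= config.bridge_max_bp:
                    lo = np.searchsorted(pos, cur.start, side="left")
                    hi = np.searchsorted(pos, nxt.end, side="left")
                    merged = CnvSegment(
                        chromosome=cur.chromosome,
                        start=cur.start,
                        end=nxt.end,
                        state=cur.state,
                        n_probes=int(hi - lo),
                        mean_z=float(val[lo:hi].mean()),
                        sample_id=cur.sample_id,
                    )
                    out.append(merged)
                    k += 2
                    changed = True
                    continue
            out.append(cur)
            k += 1
        segs = out
    return segs


def filter_min_probes(segments: List[CnvSegment], config: RunConfig) -> List[CnvSegment]:
    """Eliminate events containing fewer than ``min_probes`` probes."""
    return [s for s in segments if s.n_probes >= config.min_probes]


def filter_common(
    segments: List[CnvSegment], catalog: ControlCatalog, config: RunConfig
) -> List[CnvSegment]:
    """Remove calls matching the control catalog; survivors are flagged rare.

    A call is common iff some catalog interval of the same type (gain/loss)
    has reciprocal overlap >= ``common_overlap_fraction`` with it.
    """
    by_type: Dict[str, list] = {GAIN: [], LOSS: []}
    for iv in catalog.intervals:
        by_type[iv.payload].append(iv)
    out: List[CnvSegment] = []
    for seg in segments:
        frac = max_reciprocal_overlap(seg.interval(), by_type[seg.state])
        if frac >= config.common_overlap_fraction:
            seg.rare = False
        else:
            seg.rare = True
            out.append(seg)
    return out


def call_sample(
    track: ProbeTrack, catalog: ControlCatalog, config: RunConfig
) -> List[CnvSegment]:
    """Run the full per-sample pipeline; deterministic given inputs and config."""
    z = zscore_normalize(track)
    states = decode_states(build_hmm(config), z)
    segs = segments_from_states(states, z, config)
    segs = bridge_segments(segs, states, z, config)
    segs = filter_min_probes(segs, config)
    return filter_common(segs, catalog, config)
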