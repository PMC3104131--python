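"""Synthetic aCGH data with known ground truth.

Emulates a whole-genome tiling platform: probes on a ~25 kb grid with
positional jitter, i.i.d. Gaussian noise on log2 ratios, and implanted
heterozygous CNVs whose mean shift follows ideal copy-number arithmetic,
``log2(copy_number / 2)`` — +0.585 for a duplication (3 copies), -1.0 for a
deletion (1 copy). Cohorts add a layer of study design: a control-CNV
catalog shared across samples ("common" variants), a synthetic gene map, and
a chosen number of samples carrying one rare, gene-overlapping CNV each.

Dye bias, GC waves and cross-hybridization are deliberately not modeled; the
pipeline (like the platform software it mimics) starts from normalized ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import GAIN, LOSS, ControlCatalog, GenomicInterval, ProbeTrack
from .errors import SimSpecError

__all__ = ["SimSpec", "CohortSpec", "simulate_track", "simulate_cohort"]


def _default_genome() -> Dict[str, int]:
    # Desk-scale synthetic genome: 3 chromosomes of 50 Mb (~2,000 probes each).
    return {"chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000}


@dataclass
class SimSpec:
    """One sample's simulation parameters.

    ``implants`` lists (chromosome, start, end, copy_number) with copy_number
    1 (heterozygous deletion) or 3 (heterozygous duplication); intervals must
    stay within chromosome bounds and not overlap each other.
    """

    chromosome_lengths: Dict[str, int] = field(default_factory=_default_genome)
    probe_spacing_bp: int = 25_000
    spacing_jitter_bp: int = 2_000
    noise_sd_log2: float = 0.15
    implants: List[Tuple[str, int, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_log2 < 0:
            raise SimSpecError("noise_sd_log2 must be >= 0")
        if self.probe_spacing_bp <= 0:
            raise SimSpecError("probe_spacing_bp must be positive")
        if not 0 <= self.spacing_jitter_bp < self.probe_spacing_bp // 2:
            raise SimSpecError("spacing_jitter_bp must be < probe_spacing_bp / 2")
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end, cn in self.implants:
            if cn not in (1, 3):
                raise SimSpecError(f"copy_number must be 1 or 3, got {cn}")
            if chrom not in self.chromosome_lengths:
                raise SimSpecError(f"implant on unknown chromosome {chrom}")
            if start < 0 or end > self.chromosome_lengths[chrom] or start >= end:
                raise SimSpecError(f"implant {chrom}:{start}-{end} out of bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise SimSpecError(f"overlapping implants on {chrom}")


def simulate_track(spec: SimSpec, sample_id: str = "sim") -> Tuple[ProbeTrack, List[GenomicInterval]]:
    """Simulate one probe track; returns the track and truth intervals.

    Truth intervals span the outermost probes actually affected by each
    implant (half-open, end = last probe + 1), matching the coordinate
    convention of called segments; implants covering no probe are dropped
    from the truth. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    chroms: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    truth: List[GenomicInterval] = []
    for chrom in spec.chromosome_lengths:
        length = spec.chromosome_lengths[chrom]
        n = max(1, (length - spec.probe_spacing_bp) // spec.probe_spacing_bp)
        grid = np.arange(1, n + 1, dtype=np.int64) * spec.probe_spacing_bp
        if spec.spacing_jitter_bp > 0:
            grid = grid + rng.integers(
                -spec.spacing_jitter_bp, spec.spacing_jitter_bp + 1, size=n
            )
        values = (
            rng.standard_normal(n) * spec.noise_sd_log2
            if spec.noise_sd_log2 > 0
            else np.zeros(n)
        )
        for imp_chrom, start, end, cn in spec.implants:
            if imp_chrom != chrom:
                continue
            mask = (grid >= start) & (grid < end)
            if not mask.any():
                continue
            values[mask] += math.log2(cn / 2.0)
            hit = grid[mask]
            truth.append(
                GenomicInterval(chrom, int(hit[0]), int(hit[-1]) + 1, GAIN if cn == 3 else LOSS)
            )
        chroms[chrom] = (grid, values)
    return ProbeTrack(sample_id, chroms), truth


@dataclass
class CohortSpec:
    """Study design of a synthetic case cohort.

    Exactly ``n_rare_carriers`` samples receive one rare, gene-overlapping
    implant of ``rare_cnv_size_probes`` probes (range, inclusive) with copy
    number drawn from {1, 3}; every sample may additionally carry any of
    ``n_common_cnv_loci`` catalog CNVs, each with probability
    ``common_carrier_fraction``.

    The synthetic gene map is a sparse set of marker loci (``gene_density``
    genes per Mb) tagging candidate regions, not a realistic gene complement:
    rare implants are anchored on these loci, so "gene-containing" separates
    implanted signal from decoder noise at the cohort level. Densities
    approaching the real genome's (~7 genes/Mb) make nearly every spurious
    call gene-containing and are not what this generator emulates.
    """

    n_samples: int = 186
    n_rare_carriers: int = 14
    rare_cnv_size_probes: Tuple[int, int] = (8, 20)
    n_common_cnv_loci: int = 5
    common_carrier_fraction: float = 0.3
    gene_density: float = 0.05
    chromosome_lengths: Dict[str, int] = field(default_factory=_default_genome)
    probe_spacing_bp: int = 25_000
    spacing_jitter_bp: int = 2_000
    noise_sd_log2: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise SimSpecError("n_samples must be positive")
        if not 0 <= self.n_rare_carriers <= self.n_samples:
            raise SimSpecError("n_rare_carriers must lie in [0, n_samples]")
        if not 0.0 <= self.common_carrier_fraction <= 1.0:
            raise SimSpecError("common_carrier_fraction must lie in [0, 1]")
        lo, hi = self.rare_cnv_size_probes
        if lo < 1 or hi < lo:
            raise SimSpecError("rare_cnv_size_probes must be a non-empty positive range")
        if self.gene_density <= 0:
            raise SimSpecError("gene_density must be positive")
        max_span = (hi + 1) * self.probe_spacing_bp
        if max_span > min(self.chromosome_lengths.values()):
            raise SimSpecError("rare CNV span exceeds the shortest chromosome")


def _place_in_slots(
    rng: np.random.Generator,
    chromosome_lengths: Dict[str, int],
    lengths_bp: Sequence[int],
    margin_bp: int,
) -> List[Tuple[str, int, int]]:
    """Scatter non-overlapping intervals of the given lengths across the genome.

    The usable genome (minus end margins) is cut into equal slots, one
    interval per randomly chosen slot, at a random offset inside its slot —
    non-overlap for free, O(1) per placement.
    """
    chrom_names = list(chromosome_lengths)
    usable = [(c, chromosome_lengths[c] - 2 * margin_bp) for c in chrom_names]
    total = sum(u for _, u in usable)
    k = len(lengths_bp)
    if k == 0:
        return []
    slot = total // k
    if slot <= max(lengths_bp):
        raise SimSpecError("genome too small for the requested interval count")
    chosen = rng.permutation(k)
    out: List[Tuple[str, int, int]] = []
    for idx, slot_i in enumerate(chosen):
        length = int(lengths_bp[idx])
        g_start = slot_i * slot + int(rng.integers(0, slot - length))
        # map linear genome offset back to (chromosome, position)
        for chrom, u in usable:
            if g_start < u:
                start = margin_bp + g_start
                out.append((chrom, start, start + length))
                break
            g_start -= u
        else:  # pragma: no cover - defensive; offsets are < total by construction
            raise SimSpecError("interval placement overflow")
    return out


def simulate_cohort(
    spec: CohortSpec,
) -> Tuple[
    Dict[str, ProbeTrack],
    ControlCatalog,
    List[GenomicInterval],
    Dict[str, List[GenomicInterval]],
]:
    """Simulate a case cohort with known rare-CNV ground truth.

    Returns (tracks by sample, control catalog, gene map, truth by sample);
    ``truth`` holds each sample's rare implants (probe-snapped, like called
    segment coordinates) and is non-empty for exactly ``n_rare_carriers``
    samples. Rare implants overlap >=1 synthetic gene, never overlap any
    catalog interval, and span at least ``rare_cnv_size_probes[0]`` probes.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 2_000_000
    spacing = spec.probe_spacing_bp

    # Gene map: density * Mb genes, 30-120 kb each, scattered without overlap.
    genome_mb = sum(spec.chromosome_lengths.values()) / 1e6
    n_genes = max(1, int(round(spec.gene_density * genome_mb)))
    gene_lengths = rng.integers(30_000, 120_001, size=n_genes)
    genes = [
        GenomicInterval(c, s, e, f"GENE{i + 1:04d}")
        for i, (c, s, e) in enumerate(
            _place_in_slots(rng, spec.chromosome_lengths, gene_lengths, margin)
        )
    ]

    # Common loci: catalog intervals sized to survive the min-probe filter.
    common_probes = rng.integers(8, 26, size=spec.n_common_cnv_loci)
    common_lengths = (common_probes + 1) * spacing
    common_types = rng.choice([GAIN, LOSS], size=spec.n_common_cnv_loci)
    catalog_intervals = [
        GenomicInterval(c, s, e, t)
        for (c, s, e), t in zip(
            _place_in_slots(rng, spec.chromosome_lengths, common_lengths, margin),
            common_types,
        )
    ]
    catalog = ControlCatalog(catalog_intervals, source_label="synthetic-controls",
                             n_individuals=2_493)

    # Genes clear of the catalog neighborhood are eligible rare-CNV hosts.
    lo, hi = spec.rare_cnv_size_probes
    reach = (hi + 2) * spacing  # max half-span of an implant centered on a gene
    def near_catalog(g: GenomicInterval) -> bool:
        return any(
            iv.chromosome == g.chromosome
            and g.start - reach < iv.end
            and iv.start < g.end + reach
            for iv in catalog_intervals
        )
    hosts = [g for g in genes if not near_catalog(g)]
    if spec.n_rare_carriers > 0 and not hosts:
        raise SimSpecError("no gene lies far enough from the control catalog")

    carrier_idx = set(rng.choice(spec.n_samples, size=spec.n_rare_carriers, replace=False).tolist())
    sample_seeds = rng.integers(0, 2**31 - 1, size=spec.n_samples)

    tracks: Dict[str, ProbeTrack] = {}
    truth: Dict[str, List[GenomicInterval]] = {}
    for i in range(spec.n_samples):
        sample_id = f"S{i + 1:03d}"
        implants: List[Tuple[str, int, int, int]] = []
        for iv in catalog_intervals:
            if rng.random() < spec.common_carrier_fraction:
                implants.append((iv.chromosome, iv.start, iv.end, 3 if iv.payload == GAIN else 1))
        rare_spans: List[Tuple[str, int, int, int]] = []
        if i in carrier_idx:
            host = hosts[int(rng.integers(0, len(hosts)))]
            n_probes = int(rng.integers(lo, hi + 1))
            span = (n_probes + 1) * spacing  # guarantees >= n_probes grid probes
            center = (host.start + host.end) // 2
            length_c = spec.chromosome_lengths[host.chromosome]
            start = min(max(center - span // 2, 0), length_c - span)
            cn = int(rng.choice([1, 3]))
            rare_spans.append((host.chromosome, start, start + span, cn))
            implants.append(rare_spans[0])
        track_spec = SimSpec(
            chromosome_lengths=spec.chromosome_lengths,
            probe_spacing_bp=spacing,
            spacing_jitter_bp=spec.spacing_jitter_bp,
            noise_sd_log2=spec.noise_sd_log2,
            implants=implants,
            seed=int(sample_seeds[i]),
        )
        track, _ = simulate_track(track_spec, sample_id)
        tracks[sample_id] = track
        truth[sample_id] = [
            _snap_to_probes(track, chrom, s, e, cn) for chrom, s, e, cn in rare_spans
        ]
    return tracks, catalog, genes, truth


def _snap_to_probes(track: ProbeTrack, chrom: str, start: int, end: int, cn: int) -> GenomicInterval:
    pos, _ = track.chromosomes[chrom]
    hit = pos[(pos >= start) & (pos < end)]
    if hit.size == 0:
        raise SimSpecError(f"implant {chrom}:{start}-{end} covers no probe")
    return GenomicInterval(chrom, int(hit[0]), int(hit[-1]) + 1, GAIN if cn == 3 else LOSS)
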