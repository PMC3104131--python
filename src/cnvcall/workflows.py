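"""Cohort-level driver: simulate (or accept) tracks, call every sample,
annotate genes, and summarize — the glue the analysis scripts and tests share."""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Tuple

from .annotate import GenomeIndex, annotate_genes
from .calling import call_sample
from .config import RunConfig
from .core import CnvSegment, ControlCatalog, GenomicInterval, ProbeTrack
from .simulate import CohortSpec, simulate_cohort
from .stats import CohortSummary, summarize_cohort


def call_cohort(
    tracks: Mapping[str, ProbeTrack],
    catalog: ControlCatalog,
    genes: List[GenomicInterval],
    config: RunConfig,
) -> Dict[str, List[CnvSegment]]:
    """Run the calling pipeline plus gene annotation on every sample."""
    index = GenomeIndex(genes)
    cohort_calls: Dict[str, List[CnvSegment]] = {}
    for sample_id, track in tracks.items():
        calls = call_sample(track, catalog, config)
        for seg in calls:
            annotate_genes(seg, genes, index)
        cohort_calls[sample_id] = calls
    return cohort_calls


def simulate_and_summarize(
    seed: int,
    spec: Optional[CohortSpec] = None,
    config: Optional[RunConfig] = None,
    control_large_event_carriers: int = 8,
) -> Tuple[CohortSummary, Dict[str, List[CnvSegment]], Dict[str, List[GenomicInterval]]]:
    """One full synthetic-cohort experiment at the given seed.

    Returns the cohort summary, the per-sample call sets and the rare-implant
    ground truth. The spec's own seed is replaced by ``seed``.
    """
    spec = CohortSpec(**{**spec.__dict__, "seed": seed}) if spec else CohortSpec(seed=seed)
    config = config or RunConfig(random_seed=seed)
    tracks, catalog, genes, truth = simulate_cohort(spec)
    cohort_calls = call_cohort(tracks, catalog, genes, config)
    summary = summarize_cohort(
        cohort_calls, catalog.n_individuals, control_large_event_carriers, config
    )
    return summary, cohort_calls, truth
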