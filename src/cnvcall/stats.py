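"""Cohort-level summaries and the rare-CNV burden test.

The burden comparison asks whether cases carry large (> threshold Mb) rare
CNVs more often than a reference control cohort, via a two-sided Fisher's
exact test on the 2x2 carrier table. Control carrier counts are supplied as
integers because control call sets are typically not published probe-by-probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Union

import pandas as pd
from scipy.stats import hypergeom

from .config import RunConfig
from .core import CnvSegment
from .errors import ConfigError

#: Relative slack when comparing point masses to the observed table's mass;
#: absorbs floating-point noise in "probability <= observed".
_MASS_RTOL = 1e-7


@dataclass
class BurdenTable:
    """2x2 carrier table: (cases with / without, controls with / without)."""

    a_cases_with_event: int
    b_cases_without: int
    c_controls_with_event: int
    d_controls_without: int

    def __post_init__(self) -> None:
        if min(self.a_cases_with_event, self.b_cases_without,
               self.c_controls_with_event, self.d_controls_without) < 0:
            raise ConfigError("burden table counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a_cases_with_event + self.b_cases_without

    @property
    def n_controls(self) -> int:
        return self.c_controls_with_event + self.d_controls_without


def fisher_exact_two_sided(table: BurdenTable) -> float:
    """Two-sided Fisher's exact p-value by the probability-mass method.

    Sums, over all 2x2 tables with the observed margins, the hypergeometric
    point masses no larger than the observed table's mass (the convention of
    standard statistical software). Returns 1.0 with a warning when any
    margin is zero, where the test is uninformative.
    """
    a, b, c, d = (table.a_cases_with_event, table.b_cases_without,
                  table.c_controls_with_event, table.d_controls_without)
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if min(row1, c + d, col1, b + d) == 0:
        warnings.warn("Fisher's exact test undefined for a zero margin; returning 1.0")
        return 1.0
    dist = hypergeom(n_total, col1, row1)
    k_lo = max(0, row1 - (n_total - col1))
    k_hi = min(row1, col1)
    support = range(k_lo, k_hi + 1)
    pmf = dist.pmf(list(support))
    observed = dist.pmf(a)
    p = float(pmf[pmf <= observed * (1.0 + _MASS_RTOL)].sum())
    return min(p, 1.0)


def count_large_event_carriers(
    cohort_calls: Mapping[str, List[CnvSegment]], threshold_mb: float
) -> int:
    """Number of samples with >=1 rare call strictly larger than threshold_mb."""
    return sum(
        any(seg.rare is not False and seg.size_mb > threshold_mb for seg in calls)
        for calls in cohort_calls.values()
    )


@dataclass
class CohortSummary:
    n_samples: int
    n_rare_gene_cnv_carriers: int
    carrier_percent: float  # 100 * carriers / n_samples, to 1 decimal
    large_event_carriers: Dict[float, int] = field(default_factory=dict)
    burden_tables: Dict[float, BurdenTable] = field(default_factory=dict)
    burden_p_values: Dict[float, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "threshold_mb": th,
                "case_carriers": self.large_event_carriers[th],
                "n_cases": self.n_samples,
                "control_carriers": self.burden_tables[th].c_controls_with_event,
                "n_controls": self.burden_tables[th].n_controls,
                "fisher_p": self.burden_p_values[th],
            }
            for th in sorted(self.large_event_carriers)
        ]
        return pd.DataFrame(rows)


def summarize_cohort(
    cohort_calls: Mapping[str, List[CnvSegment]],
    control_n: int,
    control_large_event_carriers: Union[int, Mapping[float, int]],
    config: RunConfig,
) -> CohortSummary:
    """Cohort carrier rate plus one burden test per size threshold.

    A sample is a carrier when it holds >=1 rare, gene-containing call
    (gene annotation must already have been applied). For each threshold in
    ``config.large_event_thresholds_mb`` the case carrier count is compared
    with the supplied control carrier count (an integer applied to every
    threshold, or a mapping threshold -> count).
    """
    if control_n <= 0:
        raise ConfigError(f"control_n must be positive, got {control_n}")
    n = len(cohort_calls)
    carriers = sum(
        any(seg.rare is not False and seg.genes for seg in calls)
        for calls in cohort_calls.values()
    )
    percent = round(100.0 * carriers / n, 1) if n else 0.0
    summary = CohortSummary(n, carriers, percent)
    for th in config.large_event_thresholds_mb:
        a = count_large_event_carriers(cohort_calls, th)
        if isinstance(control_large_event_carriers, Mapping):
            c = int(control_large_event_carriers.get(th, 0))
        else:
            c = int(control_large_event_carriers)
        table = BurdenTable(a, n - a, c, control_n - c)
        summary.large_event_carriers[th] = a
        summary.burden_tables[th] = table
        summary.burden_p_values[th] = fisher_exact_two_sided(table)
    return summary
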