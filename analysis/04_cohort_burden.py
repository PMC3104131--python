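#!/usr/bin/env python
"""Cohort-level statistics: carrier rate and large-event burden vs controls.

Part 1 aggregates the simulated cohort's calls (from 02_call_cnvs.py) into
the carrier percentage and per-threshold Fisher burden tests against the
synthetic control catalog's cohort (8/2,493 assumed large-event carriers,
mirroring the published control design).

Part 2 applies the same summary machinery to the bundled reported call set
from the 186-sample craniosynostosis screen: 14/186 carriers (7.5%), 3 cases
with events > 2 Mb vs 8/2,493 controls, Fisher's exact P.

Writes results/burden_simulated.tsv and results/burden_reported.tsv.
"""

from pathlib import Path

from cnvcall import RunConfig, read_call_report, summarize_cohort
from cnvcall.datasets import (
    COHORT_N,
    CONTROL_LARGE_EVENT_CARRIERS_2MB,
    CONTROL_N,
    craniosynostosis_segments,
)

ROOT = Path(__file__).resolve().parents[1]


def _report(tag: str, summary) -> None:
    print(f"[{tag}] {summary.n_rare_gene_cnv_carriers}/{summary.n_samples} samples "
          f"({summary.carrier_percent}%) carry >=1 rare gene-containing CNV")
    for th in sorted(summary.burden_p_values):
        t = summary.burden_tables[th]
        print(f"[{tag}] events >{th} Mb: {t.a_cases_with_event}/{t.n_cases} cases vs "
              f"{t.c_controls_with_event}/{t.n_controls} controls, "
              f"Fisher's exact P = {summary.burden_p_values[th]:.3f}")


def main() -> None:
    # the 8/2,493 control carrier count refers to events > 2 Mb only
    config = RunConfig(large_event_thresholds_mb=[2.0])
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    calls_dir = ROOT / "scratch" / "calls"
    if not calls_dir.exists():
        raise SystemExit("run analysis/02_call_cnvs.py first")
    simulated = {
        p.name.replace(".report.tsv", ""): read_call_report(p)
        for p in sorted(calls_dir.glob("*.report.tsv"))
    }
    sim_summary = summarize_cohort(
        simulated, CONTROL_N, CONTROL_LARGE_EVENT_CARRIERS_2MB, config
    )
    sim_summary.to_frame().to_csv(results / "burden_simulated.tsv", sep="\t", index=False)
    _report("simulated", sim_summary)

    reported = {}
    for seg in craniosynostosis_segments():
        reported.setdefault(seg.sample_id, []).append(seg)
    for i in range(COHORT_N - len(reported)):
        reported[f"NEG{i:03d}"] = []
    rep_summary = summarize_cohort(
        reported, CONTROL_N, CONTROL_LARGE_EVENT_CARRIERS_2MB, config
    )
    rep_summary.to_frame().to_csv(results / "burden_reported.tsv", sep="\t", index=False)
    _report("reported", rep_summary)


if __name__ == "__main__":
    main()
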