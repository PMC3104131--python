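# Methods

## Model and pipeline

The pipeline turns per-probe aCGH log2 ratios into per-sample rare-CNV call
sets and cohort statistics. It assumes probes are conditionally independent
given the underlying copy-number state, that state changes are rare along
the genome, and that — after within-chromosome standardization — probe
values in the two-copy state are approximately Gaussian.

**z-transform.** Ratios are standardized per chromosome with the sample
standard deviation (n−1 denominator; at 10^3–10^5 probes per chromosome the
ddof choice is immaterial). Two consequences are intentional:

- calling is invariant to adding a constant to all ratios of a chromosome
  (dye/array offsets cancel);
- a chromosome with zero variance has no defined z-scores and raises an
  error rather than producing arbitrary calls. A chromosome needs ≥ 2
  probes.

Note that standardization uses all probes, CNV probes included, so a large
implant slightly inflates σ_c and compresses z-scores — visible only on
short chromosomes or very large events.

**HMM.** States (decreased, normal, increased) with emissions
N(−d, 1), N(0, 1), N(+d, 1) in z-units; d = `emission_mean_shift` (default
2.0, i.e. the outer states sit two standard deviations from the normal
mean). The transition matrix has self-probability s =
`state_self_transition` (default 0.99) with the remaining mass split
equally; the initial distribution is uniform. At ~25 kb spacing, s = 0.99
gives an expected state run of ~100 probes, which discourages 1-probe flips
while leaving final sensitivity to the ≥ 5-probe filter. Decoding is the
global MAP (Viterbi) path, computed independently per chromosome (no
transitions across biological discontinuities), in log space so 10^5-probe
chromosomes cannot underflow. On exactly tied path scores the decoder
prefers normal over increased over decreased — a bias toward no-call; ties
have measure zero for continuous input. No input smoothing is applied.

**Segments, merging, filters.** Maximal same-state non-normal runs become
segments, split where adjacent same-state probes lie ≥ 50 kb apart (strict
"< 50 kb" merge rule); coordinates are the outermost probe positions,
half-open with end = last probe + 1 so single-probe runs are non-degenerate.
Bridging joins two same-state segments when the intervening sequence has
≤ 5 probes *and* spans ≤ 10 kb (gap between facing boundaries), absorbing
the intervening probes into the call; it is applied to a fixed point, so
chains collapse only when every individual bridge satisfies both
conditions. Calls with < 5 probes are removed, then calls matching the
control catalog — reciprocal overlap min(|A∩B|/|A|, |A∩B|/|B|) ≥ 0.5 with a
same-type (gain/loss) interval — are removed as common; survivors are
flagged rare. The same overlap engine and threshold decide inheritance: a
child call matching a same-type parent call is labeled inherited from that
parent, otherwise absent from the tested parent, and unknown when no parent
track exists. One overlap semantics serves both decisions on purpose.

**Cohort statistics.** A carrier is a sample with ≥ 1 rare, gene-containing
call (a gene counts whether entirely or partially within the CNV; both
lists are reported separately). The burden test compares carrier counts of
events strictly larger than each size threshold against a control cohort
supplied as integers (control call sets are rarely published probe-by-
probe) using a two-sided Fisher's exact test under the probability-mass
convention — the sum of hypergeometric point masses no larger than the
observed table's, the behavior of standard statistical software — computed
via scipy's hypergeometric distribution with a 1e-7 relative slack on the
mass comparison. A zero margin returns p = 1 with a warning. Sizes are
(end − start)/10^6 Mb from outermost probe positions, compared before any
display rounding; reports print 2 decimals.

## Synthetic data: what it emulates, what it does not

`simulate_track` emulates the whole-genome tiling platform: probes on a
25 kb grid with ±2 kb uniform jitter, baseline log2 ratio 0, i.i.d.
Gaussian noise (sd 0.15 log2-units by default), and implanted heterozygous
CNVs shifting affected probes by log2(CN/2) — +0.585 for a 3-copy
duplication, −1.0 for a 1-copy deletion. Truth intervals are reported at
the outermost affected probes, the same convention as calls, so zero-noise
recovery is exact equality. The noise default makes a duplication's
per-probe z ≈ 3.5–3.8: 5-probe events are detectable but not trivial.

`simulate_cohort` adds study structure on a desk-scale genome (3 chromosomes
× 50 Mb ≈ 6,000 probes/sample; configurable): a control catalog of 5 loci
(8–25 probes each) any sample carries with probability 0.3, exactly
`n_rare_carriers` samples (default 14 of 186) with one rare implant of 8–20
probes anchored on a gene and placed clear of the catalog, and a sparse
marker-gene map.

The gene map deserves emphasis: it is a labeling device, not a realistic
gene complement. Its density (default 0.05 genes/Mb) controls how often a
*spurious* call becomes "gene-containing". The specified HMM parameters
produce a ≥ 5-probe spurious call on ~2% of 4,000-probe null chromosomes —
sustained ~1.5–2 σ noise excursions are cheap at d = 2 — which over a
186 × 6,000-probe cohort means a few spurious calls per cohort regardless
of any exposed threshold. With a sparse gene map these calls almost never
overlap a gene, so the cohort carrier rate reflects implanted truth
(14/186 = 7.5%); at real-genome density (~7 genes/Mb) nearly every spurious
call would count and the exact-rate property could not hold. Equally not
modeled: dye bias, GC waves, segmental-duplication cross-hybridization,
aCGH ratio compression, and vendor normalization (the pipeline starts from
normalized ratios). Passing tests therefore certify the calling logic and
its statistics, not robustness to real-array artifacts.

Determinism: every generator takes a seed; cohorts derive per-sample seeds
from the cohort seed, so outputs are bit-reproducible.

## Numerical and design choices

- Coordinates are 0-based half-open (BED) everywhere; Mb display (2
  decimals) happens only at report time. Chromosome names are normalized to
  the `chr` prefix.
- Probe tables are re-parsed with correctly-rounded float conversion so
  write→read round trips are bit-exact.
- The constant-chromosome check uses sd < 1e-12·max(1, |mean|), since a
  constant array leaves only rounding residue in the sample sd.
- Inherited vs common matching share `common_overlap_fraction` (default
  0.5, the field-standard reciprocal-overlap criterion) because no separate
  threshold is defensible.
- Bundled reported call table: two rows of the 14-patient table are
  internally inconsistent as printed (printed size ≠ coordinate difference:
  1.10 vs 1.13 Mb; 0.04 vs 0.35 Mb) and are flagged, not "corrected";
  recomputed sizes always use coordinates.
- Problem sizes in tests and the acceptance script — 3 × 50 Mb genome,
  200-replicate recovery experiments, 20-seed cohort majority votes — are
  the package's desk-scale defaults; all scale up via `SimSpec`/
  `CohortSpec`.

## Known limitations

- **Boundary absorption.** The MAP path absorbs a flanking noise probe
  whenever its z exceeds d/2; at d = 2 and noise sd 0.15 that is ~14–16% per
  flank probe, so ~5–6% of implants are called with a boundary overshoot of
  ≥ 2 probes (measured 94.0% ± 0.8% of implants at the detectability
  boundary recover both boundaries within 1 probe, over 1,000 replicates).
  This is a property of the specified model, confirmed against exhaustive
  path enumeration, not of the implementation; carrier-level statistics are
  unaffected because gene overlap tolerates boundary slack.
- Sex chromosomes get no copy-number baseline adjustment; mosaicism,
  multi-sample joint segmentation, and probe-level GC/wave correction are
  out of scope.
- The common-CNV filter is only as good as the supplied catalog; a rare
  call is "rare" relative to that catalog, nothing more.
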