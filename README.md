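# cnvcall — rare CNV detection from array-CGH log2 ratios

`cnvcall` re-implements, as a tested and reusable pipeline, the copy-number-
variant analysis used in whole-genome aCGH screens of disease cohorts — the
setting where ~135,000 oligonucleotide probes tile the genome every ~25 kb,
each probe reports a normalized log2 fluorescence ratio of test vs reference
DNA, and the question is which individuals carry *rare, gene-containing*
deletions or duplications not seen in unaffected controls, and whether the
case cohort is enriched for large events.

The pipeline:

1. **z-score normalization.** Per chromosome *c*, probe ratios r_i are
   standardized: z_i = (r_i − μ_c) / σ_c with the chromosome-specific mean
   and (sample) standard deviation.
2. **Three-state HMM.** Probes are classified *decreased* / *normal* /
   *increased* by the Viterbi path of a hidden Markov model with Gaussian
   emissions N(−d, 1), N(0, 1), N(+d, 1) on the z-scores (d = 2 by default:
   the outer states sit two standard deviations from the normal mean),
   self-transition probability 0.99, decoded per chromosome in log space.
3. **Segmentation and merging.** Consecutive same-state probes < 50 kb apart
   merge into segments; two same-state segments separated by ≤ 5 intervening
   probes spanning ≤ 10 kb are joined into a single variant.
4. **Filtering.** Events with < 5 probes are eliminated, as are *common*
   CNVs — calls with ≥ 50% reciprocal overlap with a same-type interval in a
   control-CNV catalog. Survivors are the rare calls.
5. **Annotation and cohort statistics.** Rare calls are annotated against a
   gene BED (genes entirely vs partially within the CNV), optionally labeled
   inherited/absent against parent call sets, and aggregated into the cohort
   carrier rate and a large-event burden test: a 2×2 carrier table
   (cases vs controls, event > T Mb) evaluated with a two-sided Fisher's
   exact test (probability-mass convention).

Because probe-level data for such screens are typically not public, the
package ships a synthetic-data module (`cnvcall.simulate`) that emulates the
platform — jittered 25 kb probe grid, i.i.d. Gaussian probe noise, implanted
heterozygous CNVs with ideal copy-number shifts log2(CN/2): +0.585 for 3
copies, −1.0 for 1 copy — and whole cohorts with known ground truth
(186 samples, 14 rare-CNV carriers by default). Every pipeline stage is
validated against independent oracles: exhaustive 3^n path enumeration for
the decoder and exact rational hypergeometric enumeration for Fisher's test.

## Worked example

```python
from cnvcall import (ControlCatalog, RunConfig, SimSpec, call_sample,
                     simulate_track)

spec = SimSpec(chromosome_lengths={"chr1": 20_000_000},
               implants=[("chr1", 5_000_000, 5_260_000, 3)],  # 3-copy dup
               seed=1)
track, truth = simulate_track(spec)
calls = call_sample(track, ControlCatalog([]), RunConfig())
for s in calls:
    print(s.chromosome, s.start, s.end, s.state, s.n_probes, round(s.mean_z, 2))
```

prints

```
chr1 5000901 5251242 gain 11 3.32
```

— the implanted duplication recovered exactly at its outermost probes
(compare `truth[0]`: chr1 5000901–5251242, gain): an 11-probe gain whose
mean z-score of 3.3 reflects the +0.585 log2 shift after chromosome-wise
standardization of 0.15-sd probe noise.

The same from the shell, over whole simulated cohorts:

```bash
cnvcall simulate --out sim --seed 3
cnvcall call --probes sim/probes/S001.tsv --controls sim/controls.bed \
             --genes sim/genes.bed --out calls
cnvcall summarize --calls calls --n-controls 2493 --control-large-events 8 \
                  --threshold-mb 2.0
```

The `analysis/` scripts run the full study-scale experiment: `01` simulates
the 186-sample cohort, `02` calls and annotates every sample (recovering all
14 implanted carriers: `14/186 (7.5%)`), `03` demonstrates trio inheritance
labeling (`Inh (M)` vs `Not inh`), and `04` computes the burden statistics —
for the bundled reported call table of a craniosynostosis screen:
`events >2.0 Mb: 3/186 cases vs 8/2493 controls, Fisher's exact P = 0.036`.
Small output tables land in `results/`, bulky regenerable intermediates in
`scratch/`.

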