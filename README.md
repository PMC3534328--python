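# aflpselect

Quality control for dominant DNA-marker datasets (AFLP and similar
presence/absence fingerprints): estimate per-locus genotyping error
rates from replicated individuals, then select loci with a
**frequency-dependent ("moving") error-rate threshold** instead of a
single fixed cutoff.

## Why

With dominant markers only the band phenotype is observable, so the
error rate of a locus is estimated from independent re-genotypings of
the same individuals: mismatches / comparisons. Error rates rise and
fall with the frequency of the present allele — loci near fixation can
hardly disagree between replicates, intermediate-frequency loci can.
A fixed cutoff (e.g. "drop everything above 10%") therefore strips out
exactly the intermediate-frequency loci that carry most of the
information about population differences, leaving a panel dominated by
rare bands.

`aflpselect` fits ordinary least squares of locus error rate $e_\ell$
on present-allele frequency $f_\ell$ with a second-degree polynomial,

$$\hat y(f) = b_0 + b_1 f + b_2 f^2,$$

and removes the loci with $e_\ell > \max(0, \hat y(f_\ell))$ — the loci
that are unusually error-prone *for their frequency class*. The
procedure can be iterated (re-fit on the survivors, remove again).
Around this core the package provides:

* marker-matrix I/O (native TSV and GenAlEx-style CSV), rare-locus and
  monomorphic-locus pre-filters, an optional negative-control screen;
* replicate-based per-locus error rates and present-allele frequencies
  (each individual counted once, missing calls handled explicitly);
* fixed-threshold selection for comparison;
* a permutation test: is the selected panel's mean error lower than
  that of equally many randomly chosen loci?
* three-level AMOVA (among groups / among populations within groups /
  within populations) with Phi-statistics and stratified permutation
  p-values, to quantify what selection does to detectable structure;
* a seeded simulator of replicated dominant-marker studies with known
  error curves and hierarchy, used by the whole test suite;
* a CLI (`aflpselect`) and a YAML-driven pipeline, plus
  scikit-learn-style transformers (`MovingThresholdSelector`,
  `FixedThresholdSelector`) for composing with sklearn pipelines.

## Worked example

Simulate a large replicated study (3 groups, 88 populations, 440
plants, 81 replicate pairs, 2,711 loci), pre-filter, select for two
rounds, and test:

```yaml
# run.yaml
seed: 42
output_dir: demo
simulate: {large_study: true}
filter: {min_present: 3}
select: {rounds: 2}
fixed_thresholds: [0.20, 0.10, 0.05]
permutation: {n_perm: 1000}
amova: {n_perm: 999}
```

```text
$ aflpselect run --config run.yaml
aflpselect 0.1.0  seed=42  config=c5292a277d99

Selection summary
subset                    # loci   mean freq  error rate
no selection                2350       0.175      15.03%
moving threshold, round 1    1245       0.171      11.69%
moving threshold, round 2     592       0.162       9.22%
fixed threshold 20%         1581       0.083       8.29%
fixed threshold 10%         1036       0.044       4.75%
fixed threshold 5%           608       0.027       2.52%

Round 1: y = 0.0092 + 1.156 f -1.058 f^2   R^2 = 0.862  p = 0  (n = 2350)
Round 2: y = -0.0061 + 1.008 f -0.871 f^2   R^2 = 0.944  p = 0  (n = 1245)

Permutation test: 1000 draws of 592 loci; null mean error 15.03%
(range 13.64-16.34%); observed 9.22%  p = 0.000999
```

Reading it: two rounds of the moving threshold cut the mean error rate
from 15.0% to 9.2% while the mean present-allele frequency barely moves
(0.175 → 0.162); the fixed thresholds reach lower error but collapse
the mean frequency to 0.083–0.027, i.e. they keep mostly rare bands.
No random panel of 592 loci out of 1,000 draws came close to the
selected panel's error rate (null range 13.6–16.3%), so p ≈ 0.001.
The run directory additionally contains the AMOVA tables (structure
detectable among groups and populations strengthens after selection),
the locus statistics TSV, per-round kept-locus lists and filtered
matrices.

Individual stages are available as subcommands (`simulate`, `filter`,
`error`, `select`, `select-fixed`, `permtest`, `amova`) and as library
functions (`locus_error_rates`, `fit_threshold_model`,
`iterate_selection`, `permutation_test`, `amova_three_level`, ...).
See `docs/methods.md` for the statistical conventions and the
simulator's model.

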