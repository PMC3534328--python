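# Methods

## Problem and model

Dominant DNA markers such as AFLP are scored as the presence (1) or
absence (0) of an amplified fragment at each locus. Because only the
band phenotype is observable, genotyping error is estimated by
re-genotyping a subset of individuals independently and counting
disagreements: for locus $\ell$,

$$\hat e_\ell = \frac{\text{mismatched replicate pairs at } \ell}
                     {\text{pairs with both calls scored at } \ell}.$$

Error rates are strongly frequency-dependent. A locus whose present
phenotype is near fixation (frequency $f$ near 0 or 1) gives replicate
pairs little opportunity to disagree, while intermediate-frequency loci
— typically the ones that discriminate populations — can disagree often.
A single fixed error cutoff $\tau$ therefore preferentially discards
intermediate-frequency loci and biases the retained panel toward rare
bands. The moving threshold instead fits ordinary least squares of
$\hat e_\ell$ on $\{1, f_\ell, f_\ell^2\}$ and removes exactly the loci
with $\hat e_\ell$ strictly greater than the fitted value
$\hat y(f_\ell)$: loci that are unusually error-prone *for their
frequency class*. Re-fitting on survivors gives a tighter curve for a
second round; iteration stops when too few loci remain (`min_loci`,
default 50).

Downstream effect is quantified two ways:

* **Permutation test.** The null distribution of the mean error rate of
  $k$ *randomly* chosen loci ($k$ = size of the selected panel) is built
  by resampling without replacement (default 1,000 draws);
  $p = (1 + \#\{\bar e_{null} \le \bar e_{obs}\})/(n_{perm}+1)$. The
  add-one correction keeps $p > 0$; ties count as extreme because a
  random panel as good as the selected one is evidence against the
  selection having mattered.
* **Three-level AMOVA.** Squared distances between samples
  ($d^2_{ij}$ = number of differing calls, rescaled by
  $L/L_{ij}$ when calls are missing) are decomposed into among-group,
  among-population-within-group and within-population strata via
  $SS(S)=\sum_{i<j\in S} d^2_{ij}/|S|$. Variance components are solved
  from the expected mean squares with unbalanced-design coefficients
  computed from the group/population sizes (which reduce to $k$ and
  $kp$ in a balanced design with $k$ samples per population and $p$
  populations per group). $\Phi_{RT}=\sigma^2_a/\sigma^2_{tot}$,
  $\Phi_{PR}=\sigma^2_b/(\sigma^2_b+\sigma^2_c)$,
  $\Phi_{PT}=(\sigma^2_a+\sigma^2_b)/\sigma^2_{tot}$. Significance is
  tested by stratified label permutation (whole populations among groups
  for $\sigma^2_a$; samples among populations within groups for
  $\sigma^2_b$ and $\sigma^2_c$), with the same add-one p-value.

## Key conventions and numerical choices

* **Clamped threshold.** Predictions used for removal are
  $\max(0, \hat y(f))$. A fitted curve can dip below zero at extreme
  frequencies (the second-round fit often has a slightly negative
  intercept); without clamping, a literal "greater than predicted"
  rule would remove loci whose replicates never disagreed, which is the
  opposite of the method's intent. A warning is emitted whenever the
  clamp changes an outcome.
* **Strict inequality, ties kept.** Only loci with error *greater than*
  the threshold are removed, both for the moving and the fixed rule.
* **Undefined error rates.** Loci with zero usable comparisons (missing
  calls in every pair) cannot be certified low-error; they are excluded
  from fitting and removed at selection time, reported separately.
* **One row per individual.** Present-allele frequencies exclude the
  second member of each replicate pair so replicated individuals are not
  double-counted; AMOVA requires replicate partners to be dropped first
  (a pre-flight check warns otherwise). Counting both rows instead
  would change frequencies only marginally at realistic replication
  fractions (~18%), but the single-counting convention is applied
  everywhere for consistency.
* **Missing data.** Replicate comparisons skip pairs with a missing
  call rather than imputing; frequencies divide by non-missing counts;
  distances are rescaled by $L/L_{ij}$. A pair of samples with no
  jointly scored locus is an error.
* **Mean error rate** is the unweighted mean over loci (sum of
  per-locus rates / number of loci), not weighted by comparisons.
* **Unweighted OLS.** The threshold regression is simple (unweighted)
  least squares; the overall F-test p-value and $R^2$ are reported
  descriptively and never gate anything. A constant response is
  reported as a flat curve with $R^2=0$. Rank-deficient designs (fewer
  than 3 distinct frequencies, or fewer than 4 usable loci) are
  rejected.
* **Negative variance components** in AMOVA are truncated to zero
  before percentages and Phi are computed (raw values are also
  reported); a zero total reports 100% within populations and NaN Phi.
* **Fixed-threshold reporting** reuses the selection machinery with a
  degenerate constant model ($b_0=\tau$, $b_1=b_2=0$).
* **Seeding.** Every stochastic routine takes an explicit seed; the
  pipeline derives independent per-stage seeds from one master seed via
  `numpy.random.SeedSequence`.

## The synthetic-data generator

No public dataset ships with the package, so `simulate_dataset`
generates replicated dominant-marker studies with known truth:

1. base present-phenotype frequencies $x_\ell \sim
   \mathrm{Beta}(0.32, 2.60)$ (right-skewed: most bands scarce);
2. group- then population-level frequencies by Balding–Nichols-style
   Beta perturbation with Fst-like dispersions (defaults 0.03 between
   groups, 0.07 between populations within groups);
3. individual phenotypes Bernoulli(population frequency);
4. observed calls flip with per-call probability $\varepsilon_\ell$
   chosen so the *pair mismatch* probability equals
   $q(f) = a + b f + c f^2$ (+ optional per-locus Gaussian noise,
   clamped to $[0, q_{max}]$, $q_{max} \le 0.5$) evaluated at the
   locus's expected **observed** frequency $f$. Because flipping shifts
   the observed frequency ($f = p + \varepsilon(1-2p)$), $f$ and
   $\varepsilon = (1-\sqrt{1-2q})/2$ are solved self-consistently per
   locus. Stating the curve in the units the estimator measures is
   deliberate: a curve stated on the *latent* frequency would appear
   shifted by $\varepsilon(1-2x)$ to any analysis of observed data, and
   no estimator could recover its coefficients unbiasedly;
5. missing calls sprinkled uniformly (default none).

`large_study_config()` freezes a large-study design: 3 groups, 88
populations of 5 plants (440 individuals), 81 replicate pairs, 2,711
loci, error curve $(0.0053, 1.18, -1.11)$, noise SD 0.02. The Beta
shape was calibrated once by a pilot sweep so that the emitted matrix
has mean present frequency ≈ 0.15 and mean error rate ≈ 0.13 across
seeds. The two summaries are coupled through the error curve — pushing
the mean frequency to ~0.17 pushes the mean error to ~0.14 and vice
versa — so the calibration favours the error-rate side, the method's
headline quantity.

What the generator does *not* emulate: primer-combination structure and
fragment-size homoplasy, scoring-software artefacts, plate effects,
linkage between loci (loci are independent given the hierarchy), and a
diploid genotype layer under the dominant phenotype (nothing downstream
consumes one). Passing tests on simulated data therefore demonstrate
the estimators' internal correctness and calibration, not robustness to
those real-data features. The default divergence values produce modest
phenotype-level structure (a few percent of variance among groups and
populations); real studies may show more.

A subtle property found while validating the generator: with per-locus
noise on the curve, the self-consistent frequency depends on the noise
draw, so conditional on observed frequency the noise is not mean-zero
and a regression of error on frequency recovers slightly steepened
coefficients. Coefficient-recovery checks therefore run with zero curve
noise (where the estimator chain is unbiased: 40/40 seeds recover all
three coefficients within 3 SE); the noisy configuration is kept for
realistic scatter in end-to-end runs. The same mechanism exists in real
data whenever locus-specific error deviates from any smooth curve — the
fitted polynomial describes the realized error-frequency relation, not
a causal curve, which is exactly how the selection rule uses it.

## Test and acceptance problem sizes

Counting estimators are verified against exhaustive per-locus
enumeration on 1,000 random ≤10×10 matrices; the regression against
closed-form normal equations on 1,000 random point sets (rtol 1e-10);
selection against brute-force per-locus comparison; the permutation
null against full subset enumeration on 8 loci and a 3-SE centering
check at 1,000 draws; AMOVA against the pairwise-distance identity,
balanced closed-form algebra, 20 structureless calibration seeds and a
group-diagnostic fixture at 999 permutations (60 samples × 200 loci);
coefficient recovery and the two-round error-reduction trend over 40
seeds each (2,000 loci / 500 pairs and the full 440-individual
large-study configuration respectively). The whole suite runs in well
under a minute on one CPU; `scripts/acceptance.py` (full large-study
workflow including two 999-permutation AMOVAs) in under ten seconds.

## Known limitations

* Error rates from 81 pairs have large per-locus binomial noise; the
  regression borrows strength across loci but individual locus
  decisions near the curve are uncertain.
* The selection rule keeps roughly the loci below a conditional-mean
  curve; it is not an optimal classifier of "bad" loci and removes
  ~half of the panel per round by construction when scatter is wide.
* The AMOVA permutation schemes test variance components directly;
  the within-population component's p-value is reported for
  completeness but is rarely of scientific interest.
* Only three hierarchy levels and binary dominant calls are supported.
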