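# Methods

## The model

`tmld` maps quantitative trait loci (QTL) in a random-mating natural
population using **pairs of adjacent SNP markers**.  Three linked biallelic
loci are modelled in tandem order: a left marker M1 (allele frequency
p1), a latent causal locus Q (frequency p2), and a right marker M2
(frequency p3).  Haplotype frequencies follow the classical trigenic
disequilibrium decomposition

```
b1(i) = p1^i (1-p1)^(1-i),  b2(j), b3(k) analogous,  i,j,k in {0,1}

p_ijk = b1(i) b2(j) b3(k)
        + (-1)^(i-j) b3(k) D12  + (-1)^(j-k) b1(i) D23
        + (-1)^(i-k) b2(j) D13  - (-1)^(i+j+k-1) D123
```

with digenic disequilibria D12, D23, D13 and a trigenic residual D123.
Every single- and two-locus margin reproduces the standard digenic
formulas; D123 cancels in all margins.  Setting D12 = D23 = D123 = 0
factorizes the distribution as `b2(j) x (two-locus marker model)`, i.e.
the QTL is independent of the marker pair — this is the null hypothesis
of the association test.  The pairwise-term weighting (the `b` factors)
is the choice that makes the null surface coincide with independence;
an alternative convention weights every pairwise term by 1/2, which
agrees with the `b` form whenever all allele frequencies are 0.5 (the
regime of the entire simulation study) but places the independence
model outside the D = 0 surface.  The sign convention of D123 is a pure
labelling choice (no margin pins it down) and is fixed project-wide.

Under random union of gametes (Hardy–Weinberg), a subject's two
haplotypes are i.i.d. draws, giving a 9 x 3 table of joint probabilities
of the unphased two-marker genotype class (rows 00..22) and the QTL
genotype (qq, Qq, QQ); each cell is a quadratic form in the p_ijk
(corner cells p000², p111², the double heterozygote summing four
phase-ambiguous pairings).  Conditioning a row on its marginal gives the
mixture weights pi_{j|i}.

The trait is normal around its QTL-genotype mean,
`y_i = mu_{j(i)} + e_i`, `e_i ~ N(0, sigma^2)`, and the observed-data
log-likelihood is joint over trait and markers:

```
l(Omega_p, Omega_q) = sum_i [ log P(g_i; Omega_p)
                              + log sum_j pi_{j|i} f_j(y_i; Omega_q) ]
```

The joint (rather than marker-conditional) form is used because the
marker-genotype counts carry the information that drives the inner EM,
and because it makes the null fit factorize exactly.

## Estimation: double-layer EM

* **Outer E-step.**  Posterior QTL-genotype probabilities
  `Pi_{j|i} ∝ pi_{j|i} f_j(y_i)`, computed in log-space with
  log-sum-exp.
* **Outer M-step, trait.**  Standard weighted normal-mixture closed
  forms for (mu_0, mu_1, mu_2, sigma); an empty component's mean is
  frozen with a warning.
* **Outer M-step, population.**  Holding the posteriors fixed, the
  expected complete-data likelihood is a weighted three-locus genotype
  likelihood with fractional counts `W[r, j] = sum_{i in class r}
  Pi_{j|i}`.  It is maximized by an inner EM over latent diplotypes:
  each (marker class, QTL genotype) pseudo-count is split across its
  phase-compatible ordered haplotype pairs proportionally to current
  frequency products, and each haplotype frequency is re-set to expected
  count / 2n.  Frequencies remain in the simplex by construction, so the
  reported D's are always admissible.
* Outer convergence: |change in log-likelihood| < 1e-8, at most 2000
  iterations (an estimate-stability criterion is also available);
  inner: max-abs frequency change < 1e-10, at most 500 iterations.
* **Initialization.**  One moment-based start (marker pair (p1, p3,
  D13) from a standalone two-locus haplotype EM; trait mean spread from
  the regressions of y on each marker, floored at 0.1 SD; QTL frequency
  0.5 with a mild coupling so the start is not a symmetry fixed point)
  plus four jittered variants.  All starts run a 25-iteration burn-in
  and the best continues to convergence (short-run multi-start EM); ties
  break by start order.  The null solution is supplied to the
  alternative fit as one extra start, which guarantees a nonnegative
  likelihood ratio by EM monotonicity (the winner's final likelihood is
  at least its burn-in value, which is at least the null start's).
  The null trait mixture depends on the trait vector alone, so it is
  fitted once and shared between the two-marker and single-marker null
  fits when several tests run on the same phenotype.
* The hot loops are compiled with numba; the pure-numpy operations
  (`joint_loglikelihood`, `e_step`, `m_step_quant`, `m_step_pop`) define
  the reference arithmetic and the tests assert the compiled fitter
  agrees with them.

**Null fit.**  Under H0 the likelihood factorizes into (a) the marker
likelihood, maximized by the standard two-locus haplotype EM over
(p1, p3, D13), and (b) an HWE-weighted three-component normal mixture in
y over (p2, mu, sigma).  The product of the two separate maxima is the
constrained MLE.

**Test.**  LRT = 2(l_alt − l_null), referred to chi-square with 3
degrees of freedom (11 free parameters under H1, 8 under H0).  Values in
(−1e-6, 0) are numerical noise and clamp to zero; anything more negative
triggers a re-start with doubled starts.  An optional phenotype
permutation p-value (B permutations, default off) is available.

## Known limitation: the chi-square(3) reference is anti-conservative

The likelihood surface is weakly identified around the null: Monte-Carlo
Fisher-information spectra at null points show near-zero eigenvalues in
combinations of (mu, sigma, p2), and under the fully null simulation
(equal means) those parameters are not identified at all.  As a result
the large-sample chi-square(3) approximation is poor at practical sample
sizes: with the correctly converged maximum-likelihood fit, the empirical
type-I error of the tmLD LRT at alpha = 0.05 is about 0.2 at n = 500
(and remains so at n = 5000), and the single-marker LD reduction behaves
alike with chi-square(1).  This is a property of the statistic, not of
the optimizer: an independent derivative-free optimizer reproduces the
EM's optimum, the ascent property holds along every trajectory, and the
finite-difference gradient vanishes at interior optima.  Stopping the EM
early can push the rejection rate anywhere between ~0.01 and ~0.2, which
is why the package refuses to tune iteration budgets and instead (a)
documents the miscalibration, and (b) provides the permutation p-value
for users who need exact finite-sample calibration.  The single-marker
ANOVA is exactly calibrated, and the haplotype-dosage test is calibrated
once its best-of-four selection is Bonferroni-adjusted (without the
adjustment its null rejection rate is ~0.17).

## Simulator

Cohorts draw two haplotypes per subject i.i.d. from the eight-frequency
distribution; the QTL genotype is the allele count at locus 2.  The
residual SD derives from the target heritability via
`sigma^2 = V_g (1 - H^2)/H^2` with HWE genotype weights; under H^2 = 0
all means are zero and sigma = 1 (every test considered is
scale-invariant, asserted by a test).  Scenario `latent_qtl` observes
loci (1, 3); scenario `qtl_is_marker1` exposes the QTL itself as the
first observed marker, reusing the same three-locus parameterization, so
the analyzed pair carries the LD D23.  Defaults are the study's
conditions: p1 = p2 = p3 = 0.5, D12 = 0.05, D23 = 0.05, D13 = 0.15,
D123 = 0.04, mu = (0, 5, 10).

The panel generator (`simulate_panel`) embeds that causal triple between
two designated SNPs and extends the flanks as a first-order allele-copy
chain (copy probability 0.5 + delta, default delta = 0.2, i.e. adjacent
digenic LD 0.1 at frequency 0.5).  It emulates a local LD block with a
single causal locus; it does not emulate recombination hotspots,
allele-frequency spectra, genotyping error, or population structure — so
passing scan tests demonstrate signal localization under clean LD decay,
not robustness to real-data artefacts.

What the simulator does not emulate more broadly: covariates, polygenic
background correlated with the markers, non-normal traits, missing-data
mechanisms other than missing-completely-at-random.

## Experiments

`run_grid` simulates each (scenario, n, heritability) cell `reps` times
and tabulates rejection rates at alpha = 0.05 for tmLD, smAT and smLD on
each marker, and the haplotype test, with binomial Monte-Carlo standard
errors.  Replicate seeds derive from a counter-based stream keyed by
(seed, cell index), making grids bit-reproducible.  Cells whose fit
failures exceed 1% of replicates are flagged invalid rather than
renormalized.  The desk-scale default grid is n in {100, 500, 1000},
H^2 in {0, 0.1, 0.3}, 500 replicates; the full published design (n up to
3000, 1000 replicates) is a configuration away.  Desk-scale problem
sizes used by the acceptance checks: 1000 null replicates at n = 500;
250-replicate power cells at n = 1000 and 2000; 50 recovery replicates
at n = 20000; 20 planted-locus scan replicates at n = 500 with a
majority threshold of 12.

## Comparators

* **smAT** — one-way ANOVA of the trait on genotype (the F-test of the
  categorical regression).
* **smLD** — the exact two-locus reduction of the tmLD machinery
  (shared compiled kernel): marker + latent QTL with parameters
  (p1, p2, D); LRT of D = 0 on chi-square(1).
* **haplo** — two-marker haplotype frequencies by EM from unphased
  genotypes; the trait is regressed on each haplotype's expected copy
  number (posterior dosage — no hard phase calls for double
  heterozygotes); the candidate with maximal model likelihood (minimal
  RSS at equal parameter count) is selected and its p-value multiplied
  by the number of candidates tested.  The adjustment is this package's
  resolution of an ambiguity in the selection rule: measured without it,
  the selection inflates the null rejection rate to ~0.17.

## Genome scan

PLINK text PED/MAP input; genotypes are counts of the alphabetically
first allele symbol per SNP (a fixed convention making runs reproducible
regardless of row order); `0 0` is missing.  QC drops SNPs with exact
conditional Hardy–Weinberg test p < 1e-7 or minor allele frequency
< 0.1 (strict inequalities; both filters are per-SNP, so their order is
immaterial).  The exact HWE test is the standard conditional-on-allele-
counts enumeration.  Adjacent pairs form within chromosomes by ascending
position (ties by SNP id); subjects are excluded pairwise-complete;
pairs with fewer than 50 complete subjects (configurable) are skipped
with a reason.  Each SNP's Manhattan-style signal is the p-value of the
pair in which it is the left member — the output schema keeps both pair
memberships recoverable.  The family-wise threshold is Bonferroni,
alpha / (SNPs surviving QC).  FDR control is deliberately not added.

## Numerical choices and degenerate inputs

* All density arithmetic in log space; posteriors via log-sum-exp.
* Haplotype-frequency bound tolerance 1e-9 absolute; values inside the
  tolerance clamp to [0, 1] and renormalize.
* Monomorphic markers are refused with an explicit error (the scan skips
  such pairs); fits require at least 10 subjects.
* sigma is floored at 1e-12; recombination fractions live in [0, 0.5];
  generations are integers.
* Genotypes are allele counts of the named ("1") alleles; a mapping
  layer in the PED reader converts file-level allele letters.
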