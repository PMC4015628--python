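# tmld — two-marker linkage-disequilibrium QTL mapping

`tmld` detects quantitative trait loci (QTL) in samples from natural,
random-mating populations by modelling **two adjacent SNP markers
jointly** with a latent causal locus between or near them.  It is aimed
at statistical geneticists analysing GWAS-style panels with a continuous
phenotype who want to exploit the local linkage-disequilibrium (LD)
structure that single-marker association tests ignore.

## The model

Three linked biallelic loci — marker M1, latent QTL Q, marker M2, with
allele frequencies p1, p2, p3 — have haplotype frequencies in the
classical trigenic disequilibrium decomposition (b·(·) are the
allele-frequency factors):

    p_ijk = b1(i) b2(j) b3(k) + (-1)^(i-j) b3(k) D12
            + (-1)^(j-k) b1(i) D23 + (-1)^(i-k) b2(j) D13
            - (-1)^(i+j+k-1) D123

The trait is a 3-component normal mixture, y_i = mu_j + e_i with
e_i ~ N(0, sigma²) given QTL genotype j, and the mixture weights are the
conditional QTL-genotype probabilities given the subject's two-marker
genotype under Hardy–Weinberg random union of haplotypes.  Both
parameter blocks, Ω_p = (p1, p2, p3, D12, D23, D13, D123) and
Ω_q = (mu_0, mu_1, mu_2, sigma), are estimated by a double-layer EM
(an outer EM over the latent QTL genotype, an inner EM over latent
haplotype phase).  Association is tested by the likelihood ratio of
H0: D12 = D23 = D123 = 0 against chi-square with 3 df.  The baselines it
is compared to — single-marker ANOVA (smAT), single-marker LD mapping
(smLD), and haplotype-dosage regression (haplo) — are included, along
with a heritability-parameterized simulator and a genome-scan driver
with the standard quality-control filters (exact HWE test, MAF cut,
Bonferroni threshold).

See `docs/methods.md` for the estimation details, the simulator's
assumptions, and a documented caveat about the finite-sample calibration
of the chi-square reference.

## Worked example

```python
from tmld import SimulationConfig, simulate_cohort, lrt_test, smat_test

cfg = SimulationConfig(n=1000, h2=0.3, seed=42)   # study defaults:
cohort = simulate_cohort(cfg)                     # p=0.5, D12=D23=0.05,
                                                  # D13=0.15, D123=0.04,
                                                  # mu=(0,5,10)
res = lrt_test(cohort.y, (cohort.g1, cohort.g3))
print(f"LRT = {res.lrt:.2f}, df = {res.df}, p = {res.pvalue:.3g}")
op, oq = res.fit_alt.omega_p, res.fit_alt.omega_q
print(f"D12_hat = {op.d12:.3f}, D23_hat = {op.d23:.3f}, D123_hat = {op.d123:.3f}")
print("smAT_m1 p =", f"{smat_test(cohort.y, cohort.g1).pvalue:.3g}")
```

prints

```
LRT = 39.68, df = 3, p = 1.24e-08
D12_hat = 0.062, D23_hat = 0.053, D123_hat = 0.025
smAT_m1 p = 0.000507
```

The cohort was simulated with a QTL explaining 30 % of the trait
variance, flanked by two markers in LD with it (true D12 = D23 = 0.05,
D123 = 0.04).  The two-marker test recovers the couplings and rejects
the no-association null at p ≈ 1e-8, five orders of magnitude beyond
the single-marker ANOVA on the left marker (p ≈ 5e-4) — the markers
individually carry weak signal, but their joint LD with the latent locus
is highly informative.

## Command line

```sh
tmld simulate --n 1000 --h2 0.3 --seed 42 --out-prefix cohort
tmld fit  --ped cohort.ped --map cohort.map --pheno cohort.pheno.tsv \
          --snp1 snp1 --snp2 snp2
tmld scan --ped panel.ped --map panel.map --pheno trait.tsv \
          --hwe 1e-7 --maf 0.1 --out scan.tsv
tmld power --reps 500 --seed 0 --out grid.tsv
```

`scan` applies the QC filters, tests every within-chromosome adjacent
SNP pair, and writes a TSV with per-method p-values and a Bonferroni
threshold over the SNPs surviving QC; `power` reproduces the simulation
grid (rejection rate per scenario x method x n x heritability cell).

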