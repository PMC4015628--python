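"""Synthetic cohorts for the two-marker LD mapping power study.

Each subject receives two three-locus haplotypes drawn i.i.d. from the
population haplotype distribution (random mating, Hardy-Weinberg).  The
latent QTL genotype is the allele count at locus 2, and the trait is
Normal around the QTL-genotype mean:

    y_i = mu_{j(i)} + e_i,   e_i ~ N(0, sigma^2)

The residual SD is derived from a target heritability H^2, the fraction
of trait variance explained by the QTL means under HWE genotype weights:
sigma^2 = V_g (1 - H^2) / H^2 with V_g = sum_j w_j (mu_j - mu_bar)^2.

Two observation scenarios are supported:

* ``latent_qtl`` — the QTL is unobserved; the analyzed marker pair is
  (locus 1, locus 3) flanking it.
* ``qtl_is_marker1`` — the QTL itself is genotyped and exposed as the
  first marker; the pair is (locus 2, locus 3).  The same three-locus
  parameterization is reused, so the analyzed pair carries the LD D23.

Under the null (H^2 = 0, equal means) the trait scale is arbitrary
because every test considered is scale-invariant; the generator uses
sigma = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .ld_model import HAPLOTYPES, ThreeLocusParams, haplotype_frequencies

__all__ = [
    "SimulationConfig",
    "Cohort",
    "heritability_to_sigma",
    "simulate_cohort",
    "group_means_variance",
    "write_plink_text",
    "write_panel_plink_text",
    "simulate_panel",
]

Scenario = Literal["latent_qtl", "qtl_is_marker1"]

#: default population parameters of the simulation study
DEFAULT_PARAMS = ThreeLocusParams(
    p1=0.5, p2=0.5, p3=0.5, d12=0.05, d23=0.05, d13=0.15, d123=0.04
)
#: default QTL genotype means (qq, Qq, QQ) in trait units
DEFAULT_MU = (0.0, 5.0, 10.0)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition: cohort size, population and trait model."""

    n: int
    params: ThreeLocusParams = DEFAULT_PARAMS
    mu: tuple[float, float, float] = DEFAULT_MU
    h2: float = 0.1
    scenario: Scenario = "latent_qtl"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("heritability must be in [0, 1)")
        if not all(np.isfinite(self.mu)):
            raise ValueError("genotype means must be finite")
        if self.scenario not in ("latent_qtl", "qtl_is_marker1"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class Cohort:
    """Simulated subjects: observed marker counts, latent truth, trait.

    ``hap_a``/``hap_b`` keep the true (phased) haplotype codes 0..7 for
    diagnostics; real data never provides them.
    """

    g1: np.ndarray
    g3: np.ndarray
    qtl: np.ndarray
    y: np.ndarray
    hap_a: np.ndarray = field(default=None, repr=False)
    hap_b: np.ndarray = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.y)


def heritability_to_sigma(
    mu: tuple[float, float, float], p2: float, h2: float
) -> float:
    """Residual SD giving heritability ``h2`` for QTL means ``mu``.

    Genotype weights are HWE at QTL allele frequency ``p2``:
    ((1-p2)^2, 2 p2 (1-p2), p2^2) over (qq, Qq, QQ).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError(
            "no genetic variance scale: h2 must be in (0, 1); under h2=0 "
            "supply sigma explicitly"
        )
    mu = np.asarray(mu, dtype=float)
    w = np.array([(1 - p2) ** 2, 2 * p2 * (1 - p2), p2 ** 2])
    mbar = w @ mu
    v_g = w @ (mu - mbar) ** 2
    if v_g <= 0.0:
        raise ValueError("no genetic variance scale: equal genotype means")
    return float(np.sqrt(v_g * (1 - h2) / h2))


def _resolve_sigma(config: SimulationConfig) -> float:
    if config.h2 == 0.0:
        # scale-invariant tests; unit residual SD under the null
        return 1.0
    return heritability_to_sigma(config.mu, config.params.p2, config.h2)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort under ``config`` (bit-reproducible given the seed)."""
    dist = haplotype_frequencies(config.params)
    sigma = _resolve_sigma(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    hap = np.asarray(HAPLOTYPES)
    codes = rng.choice(8, size=(n, 2), p=dist.freq.ravel())
    a, b = hap[codes[:, 0]], hap[codes[:, 1]]
    qtl = a[:, 1] + b[:, 1]
    g3 = a[:, 2] + b[:, 2]
    g1 = qtl if config.scenario == "qtl_is_marker1" else a[:, 0] + b[:, 0]
    mu = np.asarray(config.mu, dtype=float)
    y = mu[qtl] + rng.normal(0.0, sigma, size=n)
    return Cohort(
        g1=g1.astype(np.int8), g3=g3.astype(np.int8),
        qtl=qtl.astype(np.int8), y=y,
        hap_a=codes[:, 0].astype(np.int8), hap_b=codes[:, 1].astype(np.int8),
    )


def group_means_variance(cohort: Cohort) -> pd.DataFrame:
    """Per-QTL-genotype trait mean/SD/count plus a pooled-SD row.

    Requires simulation truth labels; groups with fewer than two subjects
    report a missing SD.
    """
    if cohort.qtl is None:
        raise ValueError("cohort has no QTL truth labels")
    rows = []
    ss, df_pool = 0.0, 0
    for j in (0, 1, 2):
        yj = cohort.y[cohort.qtl == j]
        m = float(np.mean(yj)) if len(yj) else np.nan
        s = float(np.std(yj, ddof=1)) if len(yj) > 1 else np.nan
        if len(yj) > 1:
            ss += float(np.sum((yj - m) ** 2))
            df_pool += len(yj) - 1
        rows.append({"qtl": j, "n": len(yj), "mean": m, "sd": s})
    pooled = float(np.sqrt(ss / df_pool)) if df_pool > 0 else np.nan
    out = pd.DataFrame(rows)
    out.attrs["pooled_sd"] = pooled
    return out


def simulate_panel(
    n: int,
    n_snps: int = 10,
    causal_after: int = 4,
    params: ThreeLocusParams = DEFAULT_PARAMS,
    mu: tuple[float, float, float] = DEFAULT_MU,
    h2: float = 0.2,
    adjacent_delta: float = 0.2,
    seed: int = 0,
):
    """Simulate a one-chromosome SNP panel with one hidden causal locus.

    The latent QTL sits between SNPs ``causal_after`` and
    ``causal_after + 1`` (1-based).  Haplotypes are built per chromosome
    copy: the triple (left flank, QTL, right flank) is drawn from the
    three-locus distribution of ``params``, and the remaining SNPs
    extend outward as a first-order allele chain in which each SNP
    copies its inner neighbour's allele with probability
    ``0.5 + adjacent_delta`` (at allele frequency 0.5 this gives
    adjacent digenic LD of ``adjacent_delta / 2``).  Two haplotypes per
    subject are drawn independently (random union); the trait is Normal
    around the QTL-genotype mean at heritability ``h2``.

    Returns ``(genotypes, y, qtl)`` where genotypes has shape
    (n, n_snps) with allele counts.
    """
    if not 1 <= causal_after < n_snps:
        raise ValueError("causal_after must leave SNPs on both sides")
    dist = haplotype_frequencies(params)
    sigma = 1.0 if h2 == 0.0 else heritability_to_sigma(mu, params.p2, h2)
    rng = np.random.default_rng(seed)
    hap = np.asarray(HAPLOTYPES)
    alleles = np.zeros((n, 2, n_snps), dtype=np.int8)
    qtl_allele = np.zeros((n, 2), dtype=np.int8)
    li, ri = causal_after - 1, causal_after  # flank column indices
    codes = rng.choice(8, size=(n, 2), p=dist.freq.ravel())
    triple = hap[codes]
    alleles[:, :, li] = triple[:, :, 0]
    qtl_allele = triple[:, :, 1]
    alleles[:, :, ri] = triple[:, :, 2]
    for col in range(li - 1, -1, -1):
        inner = alleles[:, :, col + 1]
        u = rng.random(size=inner.shape)
        copy = u < 0.5 + adjacent_delta
        alleles[:, :, col] = np.where(copy, inner, 1 - inner)
    for col in range(ri + 1, n_snps):
        inner = alleles[:, :, col - 1]
        u = rng.random(size=inner.shape)
        copy = u < 0.5 + adjacent_delta
        alleles[:, :, col] = np.where(copy, inner, 1 - inner)
    geno = alleles.sum(axis=1).astype(np.int8)
    qtl = qtl_allele.sum(axis=1).astype(np.int8)
    mu_arr = np.asarray(mu, dtype=float)
    y = mu_arr[qtl] + rng.normal(0.0, sigma, size=n)
    return geno, y, qtl


def write_panel_plink_text(
    genotypes: np.ndarray,
    y: np.ndarray,
    out_prefix: str,
    chrom: str = "1",
    positions=None,
    snp_ids=None,
) -> tuple[str, str, str]:
    """Export an (n, m) allele-count matrix as PLINK text plus phenotype TSV.

    Allele coding matches :func:`write_plink_text` (count allele A versus
    C); -1 entries become missing ("0 0").
    """
    genotypes = np.asarray(genotypes)
    n, m = genotypes.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    snp_ids = snp_ids or [f"snp{j + 1}" for j in range(m)]
    geno_str = {0: "C C", 1: "A C", 2: "A A", -1: "0 0"}
    ped_path, map_path = f"{out_prefix}.ped", f"{out_prefix}.map"
    pheno_path = f"{out_prefix}.pheno.tsv"
    with open(ped_path, "w") as fh:
        for i in range(n):
            cells = " ".join(geno_str[int(g)] for g in genotypes[i])
            fh.write(f"F{i + 1} I{i + 1} 0 0 0 -9 {cells}\n")
    with open(map_path, "w") as fh:
        for sid, pos in zip(snp_ids, positions):
            fh.write(f"{chrom} {sid} 0 {pos}\n")
    with open(pheno_path, "w") as fh:
        fh.write("FID\tIID\tPHENO\n")
        for i in range(n):
            fh.write(f"F{i + 1}\tI{i + 1}\t{float(y[i])!r}\n")
    return ped_path, map_path, pheno_path


def write_plink_text(
    cohort: Cohort,
    out_prefix: str,
    snp_ids: tuple[str, str] = ("snp1", "snp2"),
    chrom: str = "1",
    positions: tuple[int, int] = (1000, 2000),
) -> tuple[str, str, str]:
    """Export a two-SNP cohort as PLINK text PED/MAP plus a phenotype TSV.

    The "1" allele of each marker is written as A and the "0" allele as C,
    so the alphabetically-first reference allele convention used by the
    reader recovers the simulated counts.  Returns the three paths.
    """
    ped_path = f"{out_prefix}.ped"
    map_path = f"{out_prefix}.map"
    pheno_path = f"{out_prefix}.pheno.tsv"
    geno_str = {0: "C C", 1: "A C", 2: "A A"}
    with open(ped_path, "w") as fh:
        for i in range(len(cohort)):
            fid, iid = f"F{i + 1}", f"I{i + 1}"
            fh.write(
                f"{fid} {iid} 0 0 0 -9 "
                f"{geno_str[int(cohort.g1[i])]} {geno_str[int(cohort.g3[i])]}\n"
            )
    with open(map_path, "w") as fh:
        fh.write(f"{chrom} {snp_ids[0]} 0 {positions[0]}\n")
        fh.write(f"{chrom} {snp_ids[1]} 0 {positions[1]}\n")
    with open(pheno_path, "w") as fh:
        fh.write("FID\tIID\tPHENO\n")
        for i in range(len(cohort)):
            fh.write(f"F{i + 1}\tI{i + 1}\t{float(cohort.y[i])!r}\n")
    return ped_path, map_path, pheno_path
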