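"""Genome-wide adjacent-pair tmLD scan: file I/O, QC filters, scan driver.

The scan reads genotypes from PLINK text PED/MAP and a quantitative
phenotype table (FID, IID, PHENO), applies the standard GWAS quality
filters (exact Hardy-Weinberg test and minor-allele-frequency cut), and
runs the tmLD likelihood-ratio test plus the comparator tests on every
within-chromosome pair of adjacent SNPs.  Each SNP's displayed signal is
the p-value of the pair in which it is the left member; both memberships
remain recoverable from the output schema.  The family-wise significance
cut-off is Bonferroni over the number of SNPs surviving QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .comparators import haplo_test, smat_test, smld_test
from .tmld_inference import (N_STARTS, OUTER_MAX_ITER, OUTER_TOL,
                             _null_mixture_fit, lrt_test)

__all__ = [
    "SnpRecord",
    "ScanRow",
    "ScanConfig",
    "read_plink_text",
    "read_phenotype",
    "hwe_pvalue",
    "qc_filter",
    "bonferroni_threshold",
    "scan_adjacent_pairs",
    "write_results",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["CHR", "SNP", "BP", "SNP2", "BP2", "MAF", "P_SMAT",
                  "P_SMLD", "P_HAPLO", "P_TMLD", "LRT", "CONVERGED"]


@dataclass
class SnpRecord:
    """One SNP: map information plus per-subject reference-allele counts.

    ``genotypes`` holds counts in {0, 1, 2} of ``ref_allele`` (the
    alphabetically first allele symbol observed, a fixed convention that
    makes runs reproducible irrespective of file row order); -1 marks a
    missing genotype.
    """

    chrom: str
    id: str
    pos: int
    alleles: tuple[str, ...]
    genotypes: np.ndarray = field(repr=False)

    @property
    def ref_allele(self) -> str:
        return self.alleles[0]

    @property
    def maf(self) -> float:
        """Minor allele frequency among non-missing genotypes."""
        g = self.genotypes[self.genotypes >= 0]
        if len(g) == 0:
            return np.nan
        p = float(np.mean(g)) / 2.0
        return min(p, 1.0 - p)

    def hwe_counts(self) -> tuple[int, int, int]:
        g = self.genotypes[self.genotypes >= 0]
        return (int(np.sum(g == 2)), int(np.sum(g == 1)), int(np.sum(g == 0)))


@dataclass
class ScanRow:
    """One adjacent pair's test results (left-member orientation)."""

    chrom: str
    snp: str
    bp: int
    snp2: str
    bp2: int
    maf: float
    p_smat: float = np.nan
    p_smld: float = np.nan
    p_haplo: float = np.nan
    p_tmld: float = np.nan
    lrt: float = np.nan
    converged: bool | None = None
    reason: str = ""


@dataclass(frozen=True)
class ScanConfig:
    """Scan options: QC thresholds mirror the published pipeline."""

    hwe_threshold: float = 1e-7
    maf_threshold: float = 0.1
    alpha: float = 0.05
    min_n: int = 50
    n_starts: int = N_STARTS
    seed: int = 0


def read_plink_text(ped_path: str, map_path: str):
    """Read PLINK text PED/MAP into SNP records plus a subject roster.

    MAP columns are CHR SNP CM BP; PED columns are FID IID PAT MAT SEX
    PHENO followed by two allele columns per SNP.  "0 0" marks a missing
    genotype.  Returns ``(records, roster)`` where roster is a list of
    (FID, IID) pairs in file order.
    """
    snps = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 MAP columns, "
                                 f"got {len(parts)}")
            chrom, snp_id, _cm, bp = parts
            try:
                bp = int(bp)
            except ValueError as exc:
                raise ValueError(f"{map_path}:{ln}: bad position {bp!r}") from exc
            snps.append((chrom, snp_id, bp))
    m = len(snps)
    roster: list[tuple[str, str]] = []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns for "
                    f"{m} SNPs, got {len(parts)}"
                )
            roster.append((parts[0], parts[1]))
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype="U8") if allele_rows else \
        np.empty((0, 2 * m), dtype="U8")
    records = []
    for j, (chrom, snp_id, bp) in enumerate(snps):
        a = alleles[:, 2 * j]
        b = alleles[:, 2 * j + 1]
        half_missing = (a == "0") != (b == "0")
        if np.any(half_missing):
            row = int(np.nonzero(half_missing)[0][0]) + 1
            raise ValueError(
                f"{ped_path}:{row}: half-missing genotype at SNP {snp_id}"
            )
        missing = a == "0"
        symbols = sorted(set(a[~missing]) | set(b[~missing]))
        if len(symbols) > 2:
            raise ValueError(f"SNP {snp_id}: more than two alleles {symbols}")
        geno = np.full(len(a), -1, dtype=np.int8)
        if symbols:
            ref = symbols[0]
            geno[~missing] = ((a[~missing] == ref).astype(np.int8)
                              + (b[~missing] == ref).astype(np.int8))
        records.append(SnpRecord(chrom=chrom, id=snp_id, pos=bp,
                                 alleles=tuple(symbols), genotypes=geno))
    return records, roster


def read_phenotype(pheno_path: str, roster=None) -> np.ndarray | pd.DataFrame:
    """Read a FID IID PHENO table; align to ``roster`` when given.

    The header row is auto-detected (present when the third field is not
    numeric).  With a roster, returns a float array in roster order with
    NaN for subjects absent from the table; unmatched phenotype rows are
    dropped with a logged count.
    """
    with open(pheno_path) as fh:
        first = fh.readline().split()
    if not first or len(first) < 3:
        raise ValueError(f"{pheno_path}: expected 3 columns FID IID PHENO")
    try:
        float(first[2])
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(pheno_path, sep=r"\s+", header=header,
                     names=["FID", "IID", "PHENO"],
                     dtype={"FID": str, "IID": str})
    try:
        df["PHENO"] = df["PHENO"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{pheno_path}: non-numeric trait value") from exc
    if roster is None:
        return df
    lookup = {(f, i): v for f, i, v in
              zip(df["FID"], df["IID"], df["PHENO"])}
    y = np.array([lookup.get(key, np.nan) for key in roster])
    matched_keys = set(roster) & set(lookup)
    unmatched = len(df) - len(matched_keys)
    if unmatched:
        logger.warning("%d phenotype rows did not match any subject",
                       unmatched)
    return y


def hwe_pvalue(counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    ``counts`` are the genotype counts (n_AA, n_Aa, n_aa).  The p-value
    sums, over all heterozygote counts compatible with the observed
    allele counts, the conditional probabilities no larger than the
    observed one.
    """
    n_aa_, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa_, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa_ + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa_ + n_ab
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    homa = (n_a - hets) // 2
    homb = n - homa - hets
    logw = (hets * np.log(2.0) + gammaln(n + 1)
            - gammaln(homa + 1) - gammaln(hets + 1) - gammaln(homb + 1))
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    p_obs = probs[hets == n_ab][0]
    # relative tolerance guards ties broken by floating-point rounding
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def qc_filter(records, hwe_threshold: float = 1e-7,
              maf_threshold: float = 0.1):
    """Drop SNPs failing HWE (p < threshold) or MAF (< threshold).

    Both exclusions are strict "<" comparisons, so a SNP exactly at the
    MAF threshold is retained.  Returns ``(survivors, exclusion_log)``
    where the log is a DataFrame with columns SNP, REASON, VALUE.
    """
    kept, log = [], []
    for rec in records:
        p_hwe = hwe_pvalue(rec.hwe_counts())
        if p_hwe < hwe_threshold:
            log.append({"SNP": rec.id, "REASON": "HWE", "VALUE": p_hwe})
            continue
        maf = rec.maf
        if not maf >= maf_threshold:
            log.append({"SNP": rec.id, "REASON": "MAF", "VALUE": maf})
            continue
        kept.append(rec)
    return kept, pd.DataFrame(log, columns=["SNP", "REASON", "VALUE"])


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance cut-off alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def scan_adjacent_pairs(records, trait, config: ScanConfig = ScanConfig()):
    """Run all four tests on every within-chromosome adjacent SNP pair.

    ``records`` should already be QC-filtered; they are sorted by
    (chromosome, position, id) and paired consecutively, never across a
    chromosome boundary.  Subjects missing either genotype or the trait
    are excluded pairwise; pairs with fewer than ``config.min_n``
    complete subjects are skipped with a reason.  Failures of individual
    tests leave an NA p-value and a reason, never a dropped row.
    """
    trait = np.asarray(trait, dtype=float)
    recs = sorted(records, key=lambda r: (str(r.chrom), r.pos, r.id))
    rows: list[ScanRow] = []
    for left, right in zip(recs, recs[1:]):
        if left.chrom != right.chrom:
            continue
        row = ScanRow(chrom=left.chrom, snp=left.id, bp=left.pos,
                      snp2=right.id, bp2=right.pos, maf=left.maf)
        mask = (left.genotypes >= 0) & (right.genotypes >= 0) \
            & np.isfinite(trait)
        n_ok = int(mask.sum())
        if n_ok < config.min_n:
            row.reason = f"only {n_ok} complete subjects"
            rows.append(row)
            continue
        y = np.ascontiguousarray(trait[mask], dtype=float)
        g1 = left.genotypes[mask].astype(np.int64)
        g3 = right.genotypes[mask].astype(np.int64)
        # the null trait-mixture fit depends on the complete-subject trait
        # vector only; share it between the smLD and tmLD nulls
        mixture = _null_mixture_fit(y, OUTER_TOL, OUTER_MAX_ITER,
                                    config.n_starts, config.seed)
        reasons = []
        try:
            row.p_smat = smat_test(y, g1).pvalue
        except ValueError as exc:
            reasons.append(f"smAT: {exc}")
        try:
            row.p_smld = smld_test(y, g1, n_starts=config.n_starts,
                                   seed=config.seed, mixture=mixture).pvalue
        except (ValueError, RuntimeError) as exc:
            reasons.append(f"smLD: {exc}")
        try:
            row.p_haplo = haplo_test(y, g1, g3).pvalue
        except ValueError as exc:
            reasons.append(f"haplo: {exc}")
        try:
            res = lrt_test(y, (g1, g3), n_starts=config.n_starts,
                           seed=config.seed, mixture=mixture)
            row.p_tmld = res.pvalue
            row.lrt = res.lrt
            row.converged = res.fit_alt.converged and res.fit_null.converged
        except (ValueError, RuntimeError) as exc:
            reasons.append(f"tmLD: {exc}")
        row.reason = "; ".join(reasons)
        if reasons:
            logger.warning("pair %s-%s: %s", left.id, right.id, row.reason)
        rows.append(row)
    return rows


def _fmt(v, spec="%.6g"):
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "NA"
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return spec % v
    return str(v)


def write_results(rows, out_path: str, header_lines: list[str] | None = None):
    """Write scan rows as TSV; missing values serialize as NA.

    ``header_lines`` (provenance) are written first, prefixed with '#'.
    """
    with open(out_path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            conv = "NA" if r.converged is None else str(int(r.converged))
            fh.write("\t".join([
                r.chrom, r.snp, str(r.bp), r.snp2, str(r.bp2),
                _fmt(r.maf, "%.4g"), _fmt(r.p_smat), _fmt(r.p_smld),
                _fmt(r.p_haplo), _fmt(r.p_tmld), _fmt(r.lrt), conv,
            ]) + "\n")
    return out_path
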