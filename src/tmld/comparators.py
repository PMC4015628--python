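"""Baseline association tests the tmLD method is compared against.

* ``smat_test`` — single-marker association: least-squares fit of the
  trait on the marker genotype as a categorical predictor, overall
  F-test (one-way ANOVA).
* ``smld_test`` — single-marker LD mapping: the exact two-locus
  specialization of the tmLD machinery, with one observed marker and a
  latent QTL parameterized by (p1, p2, D); likelihood-ratio test of
  H0: D = 0 against chi-square with 1 df.  Shares the compiled EM kernel
  with the two-marker model.
* ``haplo_test`` — two-marker haplotype analysis: haplotype frequencies
  estimated by EM from unphased genotypes; for each of the four
  candidate haplotypes the trait is regressed on the subject's expected
  haplotype copy number (posterior dosage), and the candidate with the
  best model fit (equivalently, smallest residual sum of squares) is
  selected.  Because the best of several correlated candidate models is
  chosen, the selected slope p-value is Bonferroni-adjusted by the
  number of candidates tested, which keeps the test near nominal size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .tmld_inference import (
    BURN_ITER,
    INNER_MAX_ITER,
    INNER_TOL,
    N_STARTS,
    OUTER_MAX_ITER,
    OUTER_TOL,
    _CELL2,
    _em_kernel,
    _null_mixture_fit,
    _PA2,
    _PB2,
    weighted_haplotype_em,
)

__all__ = ["ComparatorResult", "smat_test", "smld_test", "haplo_test"]

#: two-locus haplotype labels in flat order 2*i + k over (locus A, locus B)
_HAP2_LABELS = ("00", "01", "10", "11")


@dataclass
class ComparatorResult:
    """Uniform result record for the baseline tests."""

    method: Literal["smAT", "smLD", "haplo"]
    statistic: float
    pvalue: float
    detail: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {"method": self.method, "statistic": self.statistic,
               "pvalue": self.pvalue}
        rec.update(self.detail)
        return rec


def _check_marker(g, name="marker"):
    g = np.asarray(g)
    if not np.all((g >= 0) & (g <= 2)):
        raise ValueError(f"{name} genotype counts outside {{0,1,2}}")
    if np.all(g == g[0]):
        raise ValueError(f"monomorphic marker: {name}")
    return g.astype(np.int64)


def smat_test(y, g) -> ComparatorResult:
    """Single-marker association test: one-way ANOVA of y on genotype."""
    y = np.asarray(y, dtype=float)
    g = _check_marker(g)
    groups = [y[g == k] for k in (0, 1, 2) if np.any(g == k)]
    fstat, pvalue = stats.f_oneway(*groups)
    means = {int(k): float(np.mean(y[g == k]))
             for k in (0, 1, 2) if np.any(g == k)}
    return ComparatorResult(
        method="smAT", statistic=float(fstat), pvalue=float(pvalue),
        detail={"df1": len(groups) - 1, "df2": len(y) - len(groups),
                "group_means": means},
    )


def _smld_moment_start(y, g):
    p1 = float(np.mean(g)) / 2.0
    sd_y = float(np.std(y)) or 1.0
    ybar = float(np.mean(y))
    vg = float(np.var(g.astype(float)))
    slope = float(np.cov(y, g)[0, 1] / vg) if vg > 0 else 0.0
    delta = max(abs(slope), 0.1 * sd_y)
    mu = np.array([ybar - delta, ybar, ybar + delta])
    # mild marker-QTL coupling so the start is not at the D = 0 symmetry point
    f = np.array([(1 - p1) * 0.55, (1 - p1) * 0.45, p1 * 0.45, p1 * 0.55])
    return f, mu, sd_y


def _smld_run(y, g, n_g, f, mu, sigma, tol, max_iter):
    return _em_kernel(y, g, n_g, _PA2, _PB2, _CELL2, 3, 4,
                      np.asarray(f, float), np.asarray(mu, float),
                      float(sigma), tol, 0.0, max_iter, INNER_TOL,
                      INNER_MAX_ITER)


def smld_test(y, g, *, n_starts: int = N_STARTS, tol: float = OUTER_TOL,
              max_iter: int = OUTER_MAX_ITER, seed: int = 0,
              mixture=None) -> ComparatorResult:
    """Single-marker LD mapping: latent-QTL mixture with one marker.

    Fits the joint likelihood of the marker genotype (HWE marginal in p1)
    and the trait mixture weighted by the conditional QTL probabilities
    under digenic LD, then tests H0: D = 0 with chi-square(1).
    ``mixture`` may carry a precomputed null trait-mixture fit for this
    trait vector (it depends on y alone and is shared with the
    two-marker test's null).
    """
    y = np.ascontiguousarray(y, dtype=float)
    g = _check_marker(g)
    n_g = np.bincount(g, minlength=3).astype(float)
    rng = np.random.default_rng(seed)

    # null: factorized fit — HWE marker marginal at the allele-count MLE
    # plus the HWE-weighted trait mixture
    p1 = float(np.mean(g)) / 2.0
    w_hwe = np.array([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1 ** 2])
    obs = n_g > 0
    marker_ll = float(n_g[obs] @ np.log(w_hwe[obs]))
    mix_ll, p2_null, mu_null, sigma_null, _post, _it, _conv = (
        mixture or _null_mixture_fit(y, tol, max_iter, n_starts, seed)
    )
    ll_null = marker_ll + mix_ll

    f0, mu0, sd0 = _smld_moment_start(y, g)
    starts = [(f0, mu0, sd0)]
    for _ in range(max(0, n_starts - 1)):
        f = f0 * np.exp(0.3 * rng.standard_normal(4))
        f = np.maximum(f, 1e-6)
        f /= f.sum()
        mu = np.sort(mu0 + 0.5 * (float(np.std(mu0)) or sd0)
                     * rng.standard_normal(3))
        starts.append((f, mu, sd0 * float(np.exp(0.2 * rng.standard_normal()))))
    # the null solution as an extra start keeps the LRT nonnegative
    f_null = np.outer([1 - p1, p1], [1 - p2_null, p2_null]).ravel()
    starts.append((f_null, mu_null, sigma_null))

    burned = [_smld_run(y, g, n_g, f, mu, s, tol, BURN_ITER)
              for f, mu, s in starts]
    f, mu, sigma, _ll, _post, _it, _conv = max(burned, key=lambda r: r[3])
    f, mu, sigma, ll_alt, _post, n_iter, converged = _smld_run(
        y, g, n_g, f, mu, sigma, tol, max_iter)

    lrt = max(2.0 * (ll_alt - ll_null), 0.0)
    pvalue = float(stats.chi2.sf(lrt, df=1))
    p1_hat = float(f[2] + f[3])
    p2_hat = float(f[1] + f[3])
    d_hat = float(f[3] - p1_hat * p2_hat)
    return ComparatorResult(
        method="smLD", statistic=float(lrt), pvalue=pvalue,
        detail={"df": 1, "p1": p1_hat, "p2": p2_hat, "D": d_hat,
                "mu": tuple(float(v) for v in mu), "sigma": float(sigma),
                "loglik_alt": float(ll_alt), "loglik_null": float(ll_null),
                "n_iter": int(n_iter), "converged": bool(converged)},
    )


def haplotype_dosages(g1, g3, freq: np.ndarray | None = None):
    """Expected two-marker haplotype copy numbers per subject.

    Estimates the 4 haplotype frequencies by EM from the unphased
    genotype counts (unless ``freq`` is given), then returns an (n, 4)
    dosage matrix: the posterior expected number of copies of each
    haplotype given the subject's genotype.  Only the double
    heterozygote is phase-ambiguous; all other classes yield integers.
    """
    g1 = np.asarray(g1, dtype=np.int64)
    g3 = np.asarray(g3, dtype=np.int64)
    cls = 3 * g1 + g3
    counts = np.bincount(cls, minlength=9).astype(float)
    if freq is None:
        q1, q3 = float(np.mean(g1)) / 2.0, float(np.mean(g3)) / 2.0
        f0 = np.outer([1 - q1, q1], [1 - q3, q3]).ravel()
        freq, _, _ = weighted_haplotype_em(counts, _PA2, _PB2, _CELL2, 4, f0)
    q = freq[_PA2] * freq[_PB2]
    cs = np.bincount(_CELL2, weights=q, minlength=9)
    share = np.divide(q, cs[_CELL2], out=np.zeros_like(q),
                      where=cs[_CELL2] > 0)
    dos_by_class = np.zeros((9, 4))
    np.add.at(dos_by_class, (_CELL2, _PA2), share)
    np.add.at(dos_by_class, (_CELL2, _PB2), share)
    return dos_by_class[cls], np.asarray(freq)


def haplo_test(y, g1, g3) -> ComparatorResult:
    """Two-marker haplotype analysis with best-fitting risk haplotype.

    Regresses the trait on each haplotype's expected dosage; the
    candidate minimizing the residual sum of squares (all models have
    equal parameter counts, so this is the maximum-likelihood model)
    supplies the test, and its p-value is multiplied by the number of
    candidates examined (Bonferroni over the selection).
    """
    y = np.asarray(y, dtype=float)
    g1 = _check_marker(g1, "marker 1")
    g3 = _check_marker(g3, "marker 2")
    dosage, freq = haplotype_dosages(g1, g3)
    best = None
    n_tested = 0
    for h in range(4):
        d = dosage[:, h]
        if np.var(d) <= 0:
            continue
        n_tested += 1
        res = stats.linregress(d, y)
        rss = float(np.sum((y - res.intercept - res.slope * d) ** 2))
        if best is None or rss < best[0]:
            best = (rss, h, res)
    if best is None:
        raise ValueError("no polymorphic haplotype dosage to test")
    rss, h, res = best
    tstat = float(res.slope / res.stderr)
    return ComparatorResult(
        method="haplo", statistic=tstat * tstat,
        pvalue=float(min(1.0, n_tested * res.pvalue)),
        detail={"haplotype": _HAP2_LABELS[h], "n_candidates": n_tested,
                "pvalue_raw": float(res.pvalue),
                "freq": tuple(map(float, freq)),
                "slope": float(res.slope), "rss": rss},
    )
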