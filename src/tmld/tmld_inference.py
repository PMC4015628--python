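"""Maximum-likelihood fitting of the two-marker LD (tmLD) mixture model.

The observed data are a quantitative trait ``y`` and the unphased
genotypes of two markers flanking a putative latent QTL.  The joint
log-likelihood combines the marker-genotype marginal with a 3-component
normal mixture whose weights are the conditional QTL-genotype
probabilities given the marker class::

    l(Omega_p, Omega_q) = sum_i [ log P(g_i; Omega_p)
                                  + log sum_j pi_{j|i} f_j(y_i; Omega_q) ]

Omega_p = (p1, p2, p3, D12, D23, D13, D123) parameterizes the
three-locus haplotype distribution; Omega_q = (mu_0, mu_1, mu_2, sigma)
the genotype-specific trait normals.  The likelihood is maximized by a
double-layer EM:

* outer E-step: posterior QTL-genotype probabilities Pi_{j|i};
* outer M-step for Omega_q: weighted normal-mixture closed forms;
* outer M-step for Omega_p: an inner EM over latent three-locus
  diplotypes, where each (marker class, QTL genotype) pseudo-count is
  split across its phase-compatible ordered haplotype pairs in
  proportion to current frequency products, and each haplotype frequency
  is re-set to expected count / 2n.

The association test is the likelihood ratio of H1 against
H0: D12 = D23 = D123 = 0 (D13 free), referred to chi-square with 3
degrees of freedom.  Under H0 the likelihood factorizes into a two-locus
marker model, fit by a standard haplotype EM, and an HWE-weighted normal
mixture in y alone.

All density arithmetic is done in log space with log-sum-exp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import chi2

from .genotype_model import _PAIR_A, _PAIR_B, _PAIR_CELL
from .ld_model import (
    HaplotypeDistribution,
    ThreeLocusParams,
    haplotype_frequencies,
    params_from_frequencies,
)

__all__ = [
    "QuantParams",
    "FitResult",
    "TestResult",
    "joint_loglikelihood",
    "e_step",
    "m_step_quant",
    "m_step_pop",
    "fit_alternative",
    "fit_null",
    "lrt_test",
    "weighted_haplotype_em",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_TINY = 1e-300

# default EM controls
OUTER_TOL = 1e-8
OUTER_MAX_ITER = 2000
INNER_TOL = 1e-10
INNER_MAX_ITER = 500
N_STARTS = 5
#: iterations each extra start runs before only the best-ranked states
#: continue to full convergence (classical short-run multi-start EM)
BURN_ITER = 25
MIN_SUBJECTS = 10

# ---------------------------------------------------------------------------
# pair-enumeration structures
#
# 3-locus (haplotypes over loci 1/2/3): reuse the 64-pair enumeration of the
# joint zygote table; cells are flat indices into the 9x3 (marker class, QTL
# genotype) array.
_PA3, _PB3, _CELL3 = _PAIR_A, _PAIR_B, _PAIR_CELL

# 2-locus: 4 haplotypes (a, b) with flat index 2*a+b, 16 ordered pairs,
# cells = 3*(a1+a2) + (b1+b2) in a 3x3 genotype grid.  Serves both the
# marker-pair EM of the null fit and the single-marker LD comparator.
_H2 = np.array([(a, b) for a in (0, 1) for b in (0, 1)])
_PA2, _PB2 = np.divmod(np.arange(16), 4)
_CELL2 = 3 * (_H2[_PA2, 0] + _H2[_PB2, 0]) + (_H2[_PA2, 1] + _H2[_PB2, 1])


def weighted_haplotype_em(
    weights: np.ndarray,
    pair_a: np.ndarray,
    pair_b: np.ndarray,
    pair_cell: np.ndarray,
    n_hap: int,
    f0: np.ndarray,
    tol: float = INNER_TOL,
    max_iter: int = INNER_MAX_ITER,
) -> tuple[np.ndarray, int, bool]:
    """EM for haplotype frequencies from (possibly fractional) cell counts.

    ``weights`` are nonnegative counts over genotype cells; each cell's
    weight is split across its compatible ordered haplotype pairs in
    proportion to the product of current frequencies, and frequencies are
    re-set to expected count / (2 * total).  Returns (frequencies,
    iterations, converged).  Convergence is max-abs frequency change.
    """
    w = np.asarray(weights, dtype=float)
    total2 = 2.0 * w.sum()
    if total2 <= 0:
        raise ValueError("no weight in haplotype EM")
    f = np.asarray(f0, dtype=float).ravel().copy()
    n_cells = len(w)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        q = f[pair_a] * f[pair_b]
        cs = np.bincount(pair_cell, weights=q, minlength=n_cells)
        denom = cs[pair_cell]
        share = np.divide(
            w[pair_cell] * q, denom, out=np.zeros_like(q), where=denom > 0
        )
        cnt = np.bincount(pair_a, weights=share, minlength=n_hap)
        cnt += np.bincount(pair_b, weights=share, minlength=n_hap)
        f_new = cnt / total2
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    return f, it, converged


def _table_from_f(f: np.ndarray) -> np.ndarray:
    """Joint (marker class, QTL genotype) table, shape (9, 3), from flat f."""
    q = f[_PA3] * f[_PB3]
    return np.bincount(_CELL3, weights=q, minlength=27).reshape(9, 3)


def _table2_from_f(f2: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype table from 4 haplotype frequencies."""
    q = f2[_PA2] * f2[_PB2]
    return np.bincount(_CELL2, weights=q, minlength=9).reshape(3, 3)


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class QuantParams:
    """Trait-model parameters: genotype means (mu_0, mu_1, mu_2) and SD."""

    mu: tuple[float, float, float]
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def to_config(self) -> dict[str, float]:
        return {
            "mu0": self.mu[0], "mu1": self.mu[1], "mu2": self.mu[2],
            "sigma": self.sigma,
        }


@dataclass
class FitResult:
    """Converged EM state: estimates, log-likelihood and QTL posteriors."""

    omega_p: ThreeLocusParams
    omega_q: QuantParams
    loglik: float
    n_iter: int
    converged: bool
    posterior: np.ndarray = field(repr=False)

    def to_record(self) -> dict[str, float]:
        rec = {k: v for k, v in self.omega_p.to_config().items()}
        rec.update(self.omega_q.to_config())
        rec.update(
            loglik=self.loglik, n_iter=self.n_iter,
            converged=self.converged,
        )
        return rec


@dataclass
class TestResult:
    """Likelihood-ratio test of H0: D12 = D23 = D123 = 0."""

    lrt: float
    df: int
    pvalue: float
    fit_alt: FitResult
    fit_null: FitResult
    perm_pvalue: float | None = None

    def to_record(self) -> dict[str, float]:
        rec = {"lrt": self.lrt, "df": self.df, "pvalue": self.pvalue}
        rec.update({f"alt_{k}": v for k, v in self.fit_alt.to_record().items()})
        rec.update({f"null_{k}": v for k, v in self.fit_null.to_record().items()})
        if self.perm_pvalue is not None:
            rec["perm_pvalue"] = self.perm_pvalue
        return rec


# ---------------------------------------------------------------------------
# data workspace


class _Workspace:
    """Precomputed per-dataset structures shared by all EM iterations."""

    def __init__(self, y, markers):
        g1, g3 = _as_marker_arrays(markers)
        y = np.asarray(y, dtype=float)
        if len(y) != len(g1) or len(g1) != len(g3):
            raise ValueError("trait and genotype lengths differ")
        if len(y) < MIN_SUBJECTS:
            raise ValueError(f"need at least {MIN_SUBJECTS} subjects")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite trait values")
        for name, g in (("marker 1", g1), ("marker 2", g3)):
            if not np.all((g >= 0) & (g <= 2)):
                raise ValueError(f"{name} genotype counts outside {{0,1,2}}")
            if np.all(g == g[0]):
                raise ValueError(f"monomorphic marker: {name}")
        self.y = y
        self.n = len(y)
        self.g1 = np.asarray(g1, dtype=np.int64)
        self.g3 = np.asarray(g3, dtype=np.int64)
        self.class_idx = 3 * self.g1 + self.g3
        self.n_r = np.bincount(self.class_idx, minlength=9).astype(float)
        order = np.argsort(self.class_idx, kind="stable")
        self.order = order
        cls_sorted = self.class_idx[order]
        self.uniq, self.seg_starts = np.unique(cls_sorted, return_index=True)
        self.observed = self.n_r > 0

    def class_weights(self, posterior: np.ndarray) -> np.ndarray:
        """Aggregate posteriors into (9, 3) fractional genotype counts."""
        w = np.zeros((9, 3))
        w[self.uniq] = np.add.reduceat(posterior[self.order], self.seg_starts, axis=0)
        return w


def _as_marker_arrays(markers):
    if hasattr(markers, "g1") and hasattr(markers, "g3"):
        return np.asarray(markers.g1), np.asarray(markers.g3)
    g1, g3 = markers
    return np.asarray(g1), np.asarray(g3)


def _log_normal_pdf(y: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    z = (y[:, None] - mu[None, :]) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG2PI


def _e_step_core(ws: _Workspace, f: np.ndarray, mu: np.ndarray, sigma: float):
    """Log-likelihood and posterior at (f, mu, sigma).

    Returns (loglik, posterior); loglik is -inf when an observed marker
    class has zero probability under f.
    """
    tab = _table_from_f(f)
    m = tab.sum(axis=1)
    if np.any(m[ws.observed] <= 0):
        return -np.inf, None
    with np.errstate(divide="ignore"):
        log_m = np.log(np.maximum(m, _TINY))
        log_pi = np.log(np.maximum(tab, _TINY)) - log_m[:, None]
    marker_ll = float(ws.n_r[ws.observed] @ log_m[ws.observed])
    a = log_pi[ws.class_idx] + _log_normal_pdf(ws.y, mu, sigma)
    amax = a.max(axis=1)
    lse = amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))
    post = np.exp(a - lse[:, None])
    return marker_ll + float(lse.sum()), post


def _m_step_quant_core(y, post, prev_mu, prev_sigma):
    n = len(y)
    col = post.sum(axis=0)
    empty = col < 1e-9
    mu = np.where(empty, prev_mu, (post.T @ y) / np.maximum(col, _TINY))
    if np.any(empty):
        warnings.warn("empty mixture component: mean frozen", RuntimeWarning)
    resid2 = (y[:, None] - mu[None, :]) ** 2
    sigma = float(np.sqrt(np.sum(post * resid2) / n))
    return mu, max(sigma, 1e-12)


@dataclass
class _EMState:
    f: np.ndarray
    mu: np.ndarray
    sigma: float
    loglik: float = -np.inf
    posterior: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = False


@njit(cache=True)
def _em_kernel(y, class_idx, n_r, pair_a, pair_b, pair_cell, n_class, n_hap,
               f0, mu0, sigma0, tol, theta_tol, max_iter, inner_tol, inner_max):
    """Compiled outer/inner EM loop for a latent-QTL haplotype mixture.

    Generic over the number of observed marker classes: the tmLD model
    uses 9 classes over 8 three-locus haplotypes; the single-marker LD
    reduction uses 3 classes over 4 two-locus haplotypes.  Cells are the
    flat (class, QTL genotype) indices ``3 * class + j``.  Identical in
    exact arithmetic to the pure-numpy operations of this module, which
    serve as its reference in the tests.
    """
    n = y.shape[0]
    n_pairs = pair_a.shape[0]
    n_cells = n_class * 3
    f = f0.copy()
    mu = mu0.copy()
    sigma = sigma0
    post = np.zeros((n, 3))
    w_cell = np.zeros(n_cells)
    logpi = np.empty(n_cells)
    ll = -np.inf
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # joint (marker class, QTL genotype) table under current f
        tab = np.zeros(n_cells)
        for p in range(n_pairs):
            tab[pair_cell[p]] += f[pair_a[p]] * f[pair_b[p]]
        marker_ll = 0.0
        bad = False
        for r in range(n_class):
            m = tab[3 * r] + tab[3 * r + 1] + tab[3 * r + 2]
            if m > 0.0:
                lm = np.log(m)
            else:
                if n_r[r] > 0.0:
                    bad = True
                    break
                lm = 0.0
            marker_ll += n_r[r] * lm
            for j in range(3):
                t = tab[3 * r + j]
                logpi[3 * r + j] = (np.log(t) - lm) if t > 0.0 else -1e308
        if bad:
            ll = -np.inf
            break
        # E-step with running sufficient statistics
        const = -np.log(sigma) - 0.9189385332046727
        inv2s2 = 0.5 / (sigma * sigma)
        ll_mix = 0.0
        for c in range(n_cells):
            w_cell[c] = 0.0
        sy0 = sy1 = sy2 = 0.0
        sw0 = sw1 = sw2 = 0.0
        for i in range(n):
            c = class_idx[i]
            a0 = logpi[3 * c] + const - (y[i] - mu[0]) ** 2 * inv2s2
            a1 = logpi[3 * c + 1] + const - (y[i] - mu[1]) ** 2 * inv2s2
            a2 = logpi[3 * c + 2] + const - (y[i] - mu[2]) ** 2 * inv2s2
            am = max(a0, max(a1, a2))
            e0 = np.exp(a0 - am)
            e1 = np.exp(a1 - am)
            e2 = np.exp(a2 - am)
            s = e0 + e1 + e2
            ll_mix += am + np.log(s)
            p0 = e0 / s
            p1 = e1 / s
            p2 = e2 / s
            post[i, 0] = p0
            post[i, 1] = p1
            post[i, 2] = p2
            w_cell[3 * c] += p0
            w_cell[3 * c + 1] += p1
            w_cell[3 * c + 2] += p2
            sy0 += p0 * y[i]
            sy1 += p1 * y[i]
            sy2 += p2 * y[i]
            sw0 += p0
            sw1 += p1
            sw2 += p2
        ll = marker_ll + ll_mix
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        # M-step for the trait parameters (closed forms, empty -> frozen)
        newmu = np.empty(3)
        newmu[0] = sy0 / sw0 if sw0 > 1e-9 else mu[0]
        newmu[1] = sy1 / sw1 if sw1 > 1e-9 else mu[1]
        newmu[2] = sy2 / sw2 if sw2 > 1e-9 else mu[2]
        ss = 0.0
        for i in range(n):
            for j in range(3):
                d = y[i] - newmu[j]
                ss += post[i, j] * d * d
        new_sigma = np.sqrt(ss / n)
        if new_sigma < 1e-12:
            new_sigma = 1e-12
        # estimate-stability criterion: means/SD on the scale of sigma,
        # haplotype frequencies on their natural scale
        dtheta = abs(new_sigma - sigma) / sigma
        for j in range(3):
            dmu = abs(newmu[j] - mu[j]) / sigma
            if dmu > dtheta:
                dtheta = dmu
        sigma = new_sigma
        mu = newmu
        # M-step for the population parameters: inner haplotype EM on the
        # fractional (class, QTL) counts
        total2 = 0.0
        for c in range(n_cells):
            total2 += w_cell[c]
        total2 *= 2.0
        f_before = f.copy()
        for _inner in range(inner_max):
            cs = np.zeros(n_cells)
            for p in range(n_pairs):
                cs[pair_cell[p]] += f[pair_a[p]] * f[pair_b[p]]
            cnt = np.zeros(n_hap)
            for p in range(n_pairs):
                cval = cs[pair_cell[p]]
                if cval > 0.0:
                    share = w_cell[pair_cell[p]] * f[pair_a[p]] * f[pair_b[p]] / cval
                    cnt[pair_a[p]] += share
                    cnt[pair_b[p]] += share
            delta = 0.0
            for h in range(n_hap):
                nf = cnt[h] / total2
                d = abs(nf - f[h])
                if d > delta:
                    delta = d
                f[h] = nf
            if delta < inner_tol:
                break
        for h in range(n_hap):
            d = abs(f[h] - f_before[h])
            if d > dtheta:
                dtheta = d
        if dtheta < theta_tol:
            converged = True
            break
    return f, mu, sigma, ll, post, it, converged


def _em_run(ws: _Workspace, state: _EMState, tol, max_iter,
            theta_tol=0.0, inner_tol=INNER_TOL,
            inner_max_iter=INNER_MAX_ITER) -> _EMState:
    """Run the outer EM from ``state`` for up to ``max_iter`` iterations."""
    f, mu, sigma, ll, post, it, conv = _em_kernel(
        ws.y, ws.class_idx, ws.n_r, _PA3, _PB3, _CELL3, 9, 8,
        np.asarray(state.f, float), np.asarray(state.mu, float),
        float(state.sigma), tol, theta_tol, max_iter, inner_tol,
        inner_max_iter,
    )
    if np.isfinite(ll):
        # refresh likelihood/posterior at the returned parameters
        ll, post = _e_step_core(ws, f, mu, sigma)
    return _EMState(
        f=f, mu=mu, sigma=sigma, loglik=ll, posterior=post,
        n_iter=state.n_iter + it, converged=conv,
    )


# ---------------------------------------------------------------------------
# initialization


def _marker_pair_em(ws: _Workspace) -> np.ndarray:
    """Two-locus haplotype EM for the observed marker pair; returns f2 (4,)."""
    counts = ws.n_r  # flat 3x3 genotype counts
    q1 = (ws.n_r.reshape(3, 3).sum(1) @ np.arange(3)) / (2 * ws.n)
    q3 = (ws.n_r.reshape(3, 3).sum(0) @ np.arange(3)) / (2 * ws.n)
    f0 = np.outer([1 - q1, q1], [1 - q3, q3]).ravel()
    f2, _, _ = weighted_haplotype_em(counts, _PA2, _PB2, _CELL2, 4, f0)
    return f2


def _moment_start(ws: _Workspace) -> _EMState:
    """Moment-based start: marker EM for (p1, p3, D13); trait regression
    for the mean spread; QTL frequency 0.5 and small digenic coupling."""
    f2 = _marker_pair_em(ws)
    sd_y = float(np.std(ws.y)) or 1.0
    ybar = float(np.mean(ws.y))
    slopes = []
    for g in (ws.g1, ws.g3):
        vg = np.var(g.astype(float))
        slopes.append(np.cov(ws.y, g)[0, 1] / vg if vg > 0 else 0.0)
    delta = max(abs(slopes[0]), abs(slopes[1]), 0.1 * sd_y)
    mu = np.array([ybar - delta, ybar, ybar + delta])
    # f2 indexed by (i, k); insert the QTL index with mild dependence on
    # locus 1 so the population M-step is not started at a symmetry point
    f = np.empty(8)
    for i in (0, 1):
        for k in (0, 1):
            pq_given = 0.5 + (0.1 if i == 1 else -0.1)
            # flat three-locus index is 4*i + 2*j + k with j the QTL allele
            f[4 * i + 2 + k] = f2[2 * i + k] * pq_given
            f[4 * i + k] = f2[2 * i + k] * (1 - pq_given)
    return _EMState(f=f, mu=mu, sigma=sd_y)


def _jitter(state: _EMState, rng: np.random.Generator) -> _EMState:
    f = state.f * np.exp(0.3 * rng.standard_normal(8))
    f = np.maximum(f, 1e-6)
    f /= f.sum()
    sd = float(np.std(state.mu)) or state.sigma
    mu = np.sort(state.mu + 0.5 * sd * rng.standard_normal(3))
    sigma = state.sigma * float(np.exp(0.2 * rng.standard_normal()))
    return _EMState(f=f, mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# public operations


def joint_loglikelihood(y, markers, omega_p: ThreeLocusParams,
                        omega_q: QuantParams) -> float:
    """Joint log-likelihood of trait and marker genotypes at given params.

    Raises if an observed marker class has zero probability under
    ``omega_p``.
    """
    ws = _Workspace(y, markers)
    f = haplotype_frequencies(omega_p).freq.ravel()
    ll, _ = _e_step_core(ws, f, np.asarray(omega_q.mu, float), omega_q.sigma)
    if not np.isfinite(ll):
        raise ValueError("observed marker class has zero probability")
    return ll


def e_step(y, markers, omega_p: ThreeLocusParams,
           omega_q: QuantParams) -> np.ndarray:
    """Posterior QTL-genotype probabilities Pi_{j|i}, shape (n, 3)."""
    ws = _Workspace(y, markers)
    f = haplotype_frequencies(omega_p).freq.ravel()
    ll, post = _e_step_core(ws, f, np.asarray(omega_q.mu, float), omega_q.sigma)
    if not np.isfinite(ll):
        raise ValueError("observed marker class has zero probability")
    return post


def m_step_quant(y, posterior, prev: QuantParams | None = None) -> QuantParams:
    """Closed-form weighted normal-mixture update of the trait parameters."""
    y = np.asarray(y, dtype=float)
    post = np.asarray(posterior, dtype=float)
    prev_mu = np.asarray(prev.mu, float) if prev else np.full(3, np.mean(y))
    prev_sigma = prev.sigma if prev else float(np.std(y)) or 1.0
    mu, sigma = _m_step_quant_core(y, post, prev_mu, prev_sigma)
    return QuantParams(mu=tuple(mu), sigma=sigma)


def m_step_pop(markers, posterior, current: ThreeLocusParams,
               tol: float = INNER_TOL,
               max_iter: int = INNER_MAX_ITER) -> ThreeLocusParams:
    """Inner-EM update of the population parameters given QTL posteriors.

    Aggregates the posterior into fractional (marker class, QTL genotype)
    counts and runs the latent-diplotype EM from the current frequencies.
    """
    g1, g3 = _as_marker_arrays(markers)
    post = np.asarray(posterior, dtype=float)
    ws = _Workspace(np.zeros(len(g1)), (g1, g3))
    w = ws.class_weights(post)
    f0 = haplotype_frequencies(current).freq.ravel()
    f, _, conv = weighted_haplotype_em(
        w.ravel(), _PA3, _PB3, _CELL3, 8, f0, tol=tol, max_iter=max_iter
    )
    if not conv:
        warnings.warn("inner haplotype EM did not converge; best iterate "
                      "returned", RuntimeWarning)
    return params_from_frequencies(HaplotypeDistribution(f.reshape(2, 2, 2)))


def _state_to_fit(state: _EMState) -> FitResult:
    omega_p = params_from_frequencies(
        HaplotypeDistribution(state.f.reshape(2, 2, 2))
    )
    omega_q = QuantParams(mu=tuple(state.mu), sigma=float(state.sigma))
    return FitResult(
        omega_p=omega_p, omega_q=omega_q, loglik=float(state.loglik),
        n_iter=state.n_iter, converged=state.converged,
        posterior=state.posterior,
    )


def fit_alternative(y, markers, *, n_starts: int = N_STARTS,
                    tol: float = OUTER_TOL, max_iter: int = OUTER_MAX_ITER,
                    seed: int = 0, extra_starts=None) -> FitResult:
    """Fit the full tmLD model by the double-layer EM with multiple starts.

    One moment-based start plus ``n_starts - 1`` jittered variants (and
    any caller-supplied ``extra_starts``) are advanced a short burn-in;
    the highest-likelihood state then runs to convergence (ties broken
    by start order).
    """
    ws = _Workspace(y, markers)
    rng = np.random.default_rng(seed)
    base = _moment_start(ws)
    starts = [base] + [_jitter(base, rng) for _ in range(max(0, n_starts - 1))]
    if extra_starts:
        starts.extend(extra_starts)
    if len(starts) > 1:
        burned = [_em_run(ws, s, tol, BURN_ITER) for s in starts]
        winner = max(burned, key=lambda s: s.loglik)
    else:
        winner = starts[0]
    best = _em_run(ws, winner, tol, max_iter)
    if not np.isfinite(best.loglik):
        raise RuntimeError("all EM starts failed (non-finite likelihood)")
    return _state_to_fit(best)


@njit(cache=True)
def _hwe_mixture_kernel(y, p2, mu0, sigma0, tol, max_iter):
    """Compiled EM for the HWE-weighted 3-component normal mixture in y.

    Parameters are (p2, mu_0, mu_1, mu_2, sigma); every subject shares
    the HWE prior ((1-p2)^2, 2 p2 (1-p2), p2^2).
    """
    n = y.shape[0]
    mu = mu0.copy()
    sigma = sigma0
    post = np.zeros((n, 3))
    ll = -np.inf
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lw0 = 2.0 * np.log(1.0 - p2)
        lw1 = np.log(2.0 * p2 * (1.0 - p2))
        lw2 = 2.0 * np.log(p2)
        const = -np.log(sigma) - 0.9189385332046727
        inv2s2 = 0.5 / (sigma * sigma)
        ll = 0.0
        sy0 = sy1 = sy2 = 0.0
        sw0 = sw1 = sw2 = 0.0
        for i in range(n):
            a0 = lw0 + const - (y[i] - mu[0]) ** 2 * inv2s2
            a1 = lw1 + const - (y[i] - mu[1]) ** 2 * inv2s2
            a2 = lw2 + const - (y[i] - mu[2]) ** 2 * inv2s2
            am = max(a0, max(a1, a2))
            e0 = np.exp(a0 - am)
            e1 = np.exp(a1 - am)
            e2 = np.exp(a2 - am)
            s = e0 + e1 + e2
            ll += am + np.log(s)
            post[i, 0] = e0 / s
            post[i, 1] = e1 / s
            post[i, 2] = e2 / s
            sy0 += post[i, 0] * y[i]
            sy1 += post[i, 1] * y[i]
            sy2 += post[i, 2] * y[i]
            sw0 += post[i, 0]
            sw1 += post[i, 1]
            sw2 += post[i, 2]
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        newmu = np.empty(3)
        newmu[0] = sy0 / sw0 if sw0 > 1e-9 else mu[0]
        newmu[1] = sy1 / sw1 if sw1 > 1e-9 else mu[1]
        newmu[2] = sy2 / sw2 if sw2 > 1e-9 else mu[2]
        ss = 0.0
        for i in range(n):
            for j in range(3):
                d = y[i] - newmu[j]
                ss += post[i, j] * d * d
        sigma = np.sqrt(ss / n)
        if sigma < 1e-12:
            sigma = 1e-12
        mu = newmu
        p2 = (sw1 + 2.0 * sw2) / (2.0 * n)
        if p2 < 1e-9:
            p2 = 1e-9
        elif p2 > 1.0 - 1e-9:
            p2 = 1.0 - 1e-9
    return ll, p2, mu, sigma, post, it, converged


def _null_mixture_fit(y, tol, max_iter, n_starts, seed):
    """Multi-start wrapper for the HWE-weighted mixture EM.

    Returns (loglik, p2, mu, sigma, posterior, n_iter, converged).
    """
    y = np.asarray(y, dtype=float)
    sd_y = float(np.std(y)) or 1.0
    ybar = float(np.mean(y))
    rng = np.random.default_rng(seed)
    starts = [(0.5, np.array([ybar - 0.5 * sd_y, ybar, ybar + 0.5 * sd_y]), sd_y)]
    for _ in range(max(0, n_starts - 1)):
        mu = np.sort(ybar + sd_y * rng.standard_normal(3))
        starts.append((float(rng.uniform(0.2, 0.8)), mu,
                       sd_y * float(np.exp(0.2 * rng.standard_normal()))))
    burned = [_hwe_mixture_kernel(y, p2, mu, sigma, tol, BURN_ITER)
              for p2, mu, sigma in starts]
    _ll0, p2, mu, sigma, _post, _it0, _conv = max(burned, key=lambda r: r[0])
    return _hwe_mixture_kernel(y, p2, mu, sigma, tol, max_iter)


def fit_null(y, markers, *, n_starts: int = N_STARTS, tol: float = OUTER_TOL,
             max_iter: int = OUTER_MAX_ITER, seed: int = 0,
             mixture=None) -> FitResult:
    """Fit under H0: D12 = D23 = D123 = 0 (D13 free).

    The joint likelihood factorizes: the marker part is maximized by a
    standard two-locus haplotype EM over (p1, p3, D13), and the trait
    part by the HWE-weighted normal-mixture EM over (p2, mu, sigma).
    ``mixture`` may carry a precomputed :func:`_null_mixture_fit` result
    for this trait vector (the trait part depends on y alone, so callers
    testing several marker pairs against one phenotype can share it).
    """
    ws = _Workspace(y, markers)
    f2 = _marker_pair_em(ws)
    tab2 = _table2_from_f(f2).ravel()
    with np.errstate(divide="ignore"):
        log_m = np.log(np.maximum(tab2, _TINY))
    marker_ll = float(ws.n_r[ws.observed] @ log_m[ws.observed])
    mix_ll, p2, mu, sigma, post, it, conv = mixture or _null_mixture_fit(
        ws.y, tol, max_iter, n_starts, seed
    )
    # assemble the three-locus frequencies with the QTL independent of
    # the markers, as H0 requires
    p1 = float(f2[2] + f2[3])
    p3 = float(f2[1] + f2[3])
    omega_p = ThreeLocusParams(p1=p1, p2=float(p2), p3=p3,
                               d13=float(f2[3] - p1 * p3))
    omega_q = QuantParams(mu=tuple(mu), sigma=float(sigma))
    return FitResult(
        omega_p=omega_p, omega_q=omega_q, loglik=marker_ll + mix_ll,
        n_iter=it, converged=conv, posterior=post,
    )


#: negative LRT values above this (i.e. in (_LRT_CLAMP, 0)) are numerical
#: noise and clamped to zero; anything more negative triggers a re-start
_LRT_CLAMP = -1e-6


def lrt_test(y, markers, *, n_starts: int = N_STARTS, tol: float = OUTER_TOL,
             max_iter: int = OUTER_MAX_ITER, seed: int = 0,
             permutations: int = 0, perm_seed: int | None = None,
             mixture=None) -> TestResult:
    """3-df likelihood-ratio test of association between trait and pair.

    The null solution is supplied to the alternative fit as an extra
    start, which guarantees (by EM monotonicity) that the likelihood
    ratio is nonnegative up to numerical noise.  Optionally a phenotype-
    permutation p-value is computed alongside the chi-square(3) one.
    """
    null = fit_null(y, markers, n_starts=n_starts, tol=tol,
                    max_iter=max_iter, seed=seed, mixture=mixture)
    null_state = _EMState(
        f=haplotype_frequencies(null.omega_p).freq.ravel(),
        mu=np.asarray(null.omega_q.mu, float), sigma=null.omega_q.sigma,
    )
    alt = fit_alternative(y, markers, n_starts=n_starts, tol=tol,
                          max_iter=max_iter, seed=seed,
                          extra_starts=[null_state])
    lrt = 2.0 * (alt.loglik - null.loglik)
    if lrt < _LRT_CLAMP:
        retry = fit_alternative(y, markers, n_starts=2 * n_starts, tol=tol,
                                max_iter=max_iter, seed=seed + 1,
                                extra_starts=[null_state])
        if retry.loglik > alt.loglik:
            alt = retry
        lrt = 2.0 * (alt.loglik - null.loglik)
        if lrt < _LRT_CLAMP:
            alt.converged = False
    lrt = max(lrt, 0.0)
    pvalue = float(chi2.sf(lrt, df=3))
    perm_p = None
    if permutations > 0:
        rng = np.random.default_rng(seed if perm_seed is None else perm_seed)
        y = np.asarray(y, dtype=float)
        exceed = 0
        for _ in range(permutations):
            yp = rng.permutation(y)
            tp = lrt_test(yp, markers, n_starts=n_starts, tol=tol,
                          max_iter=max_iter, seed=seed)
            exceed += tp.lrt >= lrt
        perm_p = (1.0 + exceed) / (permutations + 1.0)
    return TestResult(lrt=float(lrt), df=3, pvalue=pvalue,
                      fit_alt=alt, fit_null=null, perm_pvalue=perm_p)
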