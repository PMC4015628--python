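"""Three-locus haplotype-frequency model with trigenic linkage disequilibrium.

The model considers three ordered biallelic loci on a chromosome: a left
marker M1, a putative quantitative trait locus Q, and a right marker M2
(loci 1, 2, 3).  A haplotype is indexed by ``(i, j, k)`` in ``{0,1}^3``
where 1 denotes the named alleles M1/Q/M2 and 0 their alternatives
m1/q/m2.  The eight haplotype frequencies are parameterized by three
allele frequencies (p1, p2, p3), three digenic disequilibria
(D12, D23, D13) and one trigenic disequilibrium (D123), in the classical
trigenic decomposition where each pairwise term carries the uninvolved
locus's allele-frequency factor::

    b1(i) = p1^i (1-p1)^(1-i)   (and b2, b3 alike)
    p_ijk = b1(i) b2(j) b3(k)
            + (-1)^(i-j) b3(k) D12
            + (-1)^(j-k) b1(i) D23
            + (-1)^(i-k) b2(j) D13
            - (-1)^(i+j+k-1) D123

Summing p_ijk over any one index recovers the classical digenic
two-locus frequencies with the corresponding pairwise D; the trigenic
term cancels in every margin.  Setting D12 = D23 = D123 = 0 makes the
QTL locus independent of the marker pair (the distribution factorizes as
b2(j) times a two-locus marker distribution), which is the null
hypothesis of the association test.  Under recurrent random mating each
digenic D decays geometrically at rate (1 - r) per generation, and D123
decays at rate (1 - r13), which is what makes present-day
disequilibrium informative about tightly linked causal loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "ThreeLocusParams",
    "HaplotypeDistribution",
    "haplotype_frequencies",
    "params_from_frequencies",
    "decay_digenic",
    "decay_trigenic",
    "validate_params",
]

#: absolute tolerance for haplotype-frequency bound checks; values within
#: the tolerance of [0, 1] are clamped and the vector renormalized
FREQ_TOL = 1e-9

# all 8 haplotype index triples, in lexicographic order 000..111
HAPLOTYPES = tuple(itertools.product((0, 1), repeat=3))


@dataclass(frozen=True)
class ThreeLocusParams:
    """Population-genetic parameter vector (p1, p2, p3, D12, D23, D13, D123).

    ``p1``, ``p2``, ``p3`` are the frequencies of alleles M1, Q and M2 at
    loci 1, 2, 3; the D's are the signed digenic and trigenic
    disequilibria.  The sign convention for the trigenic term is the
    ``-(-1)^(i+j+k-1) * D123`` form fixed project-wide (margins cannot pin
    it down, since D123 cancels in every digenic margin).
    """

    p1: float
    p2: float
    p3: float
    d12: float = 0.0
    d23: float = 0.0
    d13: float = 0.0
    d123: float = 0.0

    def to_config(self) -> dict[str, float]:
        """Flat key-value form (keys p1,p2,p3,D12,D23,D13,D123)."""
        return {
            "p1": self.p1, "p2": self.p2, "p3": self.p3,
            "D12": self.d12, "D23": self.d23, "D13": self.d13,
            "D123": self.d123,
        }

    @classmethod
    def from_config(cls, cfg: dict[str, float]) -> "ThreeLocusParams":
        lower = {k.lower(): float(v) for k, v in cfg.items()}
        return cls(**{f.name: lower.get(f.name, 0.0) for f in fields(cls)})


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Probabilities of the 8 three-locus haplotypes.

    ``freq`` is a (2, 2, 2) array indexed by (i, j, k); entry (1, 1, 1) is
    the frequency of haplotype M1-Q-M2.
    """

    freq: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (2, 2, 2):
            raise ValueError(f"freq must have shape (2,2,2), got {f.shape}")
        if np.any(f < -FREQ_TOL) or np.any(f > 1 + FREQ_TOL):
            raise ValueError("haplotype frequencies outside [0, 1]")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(f"haplotype frequencies sum to {f.sum()}, not 1")
        f = np.clip(f, 0.0, 1.0)
        f = f / f.sum()
        object.__setattr__(self, "freq", f)

    def __getitem__(self, ijk: tuple[int, int, int]) -> float:
        return float(self.freq[ijk])

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        return {h: float(self.freq[h]) for h in HAPLOTYPES}

    @property
    def p1(self) -> float:
        return float(self.freq[1].sum())

    @property
    def p2(self) -> float:
        return float(self.freq[:, 1].sum())

    @property
    def p3(self) -> float:
        return float(self.freq[:, :, 1].sum())


def _raw_frequencies(params: ThreeLocusParams) -> np.ndarray:
    """Evaluate the parameterization without bound checks; shape (2,2,2)."""
    p = (params.p1, params.p2, params.p3)
    out = np.empty((2, 2, 2))
    for i, j, k in HAPLOTYPES:
        b1 = p[0] if i else 1 - p[0]
        b2 = p[1] if j else 1 - p[1]
        b3 = p[2] if k else 1 - p[2]
        d = (
            (-1.0) ** ((i - j) % 2) * b3 * params.d12
            + (-1.0) ** ((j - k) % 2) * b1 * params.d23
            + (-1.0) ** ((i - k) % 2) * b2 * params.d13
        ) - (-1.0) ** ((i + j + k - 1) % 2) * params.d123
        out[i, j, k] = b1 * b2 * b3 + d
    return out


def haplotype_frequencies(params: ThreeLocusParams) -> HaplotypeDistribution:
    """Map (p's, D's) to the 8 haplotype frequencies.

    Raises ``ValueError`` if the parameters imply a frequency outside
    [0, 1] beyond :data:`FREQ_TOL` (the disequilibria must respect their
    joint admissible region).
    """
    violations = validate_params(params)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))
    return HaplotypeDistribution(_raw_frequencies(params))


def params_from_frequencies(dist: HaplotypeDistribution) -> ThreeLocusParams:
    """Invert :func:`haplotype_frequencies`.

    Allele frequencies come from single-locus margins, digenic D's from
    pairwise margins, and D123 from the residual of p_111.  The map is a
    bijection, so the round trip reproduces the input exactly.
    """
    f = dist.freq
    p1 = f[1].sum()
    p2 = f[:, 1].sum()
    p3 = f[:, :, 1].sum()
    d12 = f[1, 1].sum() - p1 * p2
    d23 = f[:, 1, 1].sum() - p2 * p3
    d13 = f[1, :, 1].sum() - p1 * p3
    # p_111 = p1 p2 p3 + p3 D12 + p1 D23 + p2 D13 - D123
    d123 = p1 * p2 * p3 + p3 * d12 + p1 * d23 + p2 * d13 - f[1, 1, 1]
    return ThreeLocusParams(
        p1=float(p1), p2=float(p2), p3=float(p3),
        d12=float(d12), d23=float(d23), d13=float(d13), d123=float(d123),
    )


def _check_rt(r: float, t) -> None:
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    if t != int(t) or t < 0:
        raise ValueError(f"generations must be a nonnegative integer, got {t}")


def decay_digenic(d0: float, r: float, t: int) -> float:
    """Digenic LD after t generations of random mating: (1-r)^t * D0."""
    _check_rt(r, t)
    return (1.0 - r) ** int(t) * d0


def decay_trigenic(d123_0: float, r13: float, t: int) -> float:
    """Trigenic LD after t generations: (1-r13)^t * D123(0).

    The trigenic coefficient erodes at the rate of recombination between
    the two outer loci, so it persists on the same time scale as the
    flanking digenic term.
    """
    _check_rt(r13, t)
    return (1.0 - r13) ** int(t) * d123_0


def validate_params(params: ThreeLocusParams) -> list[str]:
    """Report constraint violations; empty list means valid.

    Checks that each allele frequency is strictly inside (0, 1) and that
    every implied haplotype frequency lies in [0, 1] within tolerance.
    Reports rather than raises, so callers can aggregate diagnostics.
    """
    out: list[str] = []
    for name, p in (("p1", params.p1), ("p2", params.p2), ("p3", params.p3)):
        if not 0.0 < p < 1.0:
            out.append(f"{name}={p} not in open interval (0, 1)")
    if out:
        return out
    f = _raw_frequencies(params)
    for i, j, k in HAPLOTYPES:
        v = f[i, j, k]
        if v < -FREQ_TOL or v > 1 + FREQ_TOL:
            out.append(f"haplotype frequency p_{i}{j}{k}={v:.6g} outside [0, 1]")
    return out
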