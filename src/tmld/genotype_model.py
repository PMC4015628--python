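"""Joint zygote probabilities for two marker genotypes and a latent QTL.

Under Hardy-Weinberg random union of haplotypes, a subject's diplotype is
an ordered pair of haplotypes drawn i.i.d. from the population haplotype
distribution.  Collapsing the 64 ordered pairs by allele counts gives the
9 x 3 table of joint probabilities of the two-marker genotype class
(rows, indexed by (g1, g3) allele counts 00..22) and the QTL genotype
(columns qq, Qq, QQ).  Each cell is a quadratic form in the haplotype
frequencies; e.g. the fully homozygous corner cells are p_000^2 and
p_111^2, and the double-heterozygote/Qq cell sums the four
phase-ambiguous pairings 2 p111 p000 + 2 p110 p001 + 2 p101 p010
+ 2 p100 p011.

Normalizing a row by its marginal yields the conditional QTL-genotype
probabilities pi_{j|i} that weight the trait mixture for a subject with
that marker genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .ld_model import HAPLOTYPES, HaplotypeDistribution

__all__ = [
    "MarkerGenotype",
    "JointZygoteTable",
    "DegenerateMarkerClassError",
    "joint_zygote_table",
    "marker_genotype_marginals",
    "conditional_qtl_probs",
]


class MarkerGenotype(NamedTuple):
    """Allele counts of the named alleles M1 and M2, each in {0, 1, 2}."""

    g1: int
    g3: int

    @property
    def row(self) -> int:
        """Row index 0..8 in the joint table (rows ordered 00,01,...,22)."""
        if self.g1 not in (0, 1, 2) or self.g3 not in (0, 1, 2):
            raise ValueError(f"genotype counts must be in {{0,1,2}}: {self}")
        return 3 * self.g1 + self.g3


class DegenerateMarkerClassError(ValueError):
    """A marker genotype class with zero probability was conditioned on."""


# Precomputed enumeration of the 64 ordered haplotype pairs: flat haplotype
# indices of each member and the (row, qtl) cell the pair falls in.
_H = np.array(HAPLOTYPES)  # (8, 3)
_PAIR_A, _PAIR_B = np.divmod(np.arange(64), 8)
_PAIR_ROW = 3 * (_H[_PAIR_A, 0] + _H[_PAIR_B, 0]) + (_H[_PAIR_A, 2] + _H[_PAIR_B, 2])
_PAIR_QTL = _H[_PAIR_A, 1] + _H[_PAIR_B, 1]
_PAIR_CELL = 3 * _PAIR_ROW + _PAIR_QTL  # flat index into the 9x3 table


@dataclass(frozen=True)
class JointZygoteTable:
    """9 x 3 joint probabilities P(marker genotype class, QTL genotype)."""

    prob: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.prob, dtype=float)
        if p.shape != (9, 3):
            raise ValueError(f"table must be 9x3, got {p.shape}")
        if np.any(p < -1e-12):
            raise ValueError("negative joint probability")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"joint probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "prob", p)


def joint_zygote_table(dist: HaplotypeDistribution) -> JointZygoteTable:
    """Build the 9 x 3 joint zygote table from haplotype frequencies.

    Accumulates f_a * f_b over the 64 ordered haplotype pairs into the
    (marker class, QTL genotype) cell of each pair, which reproduces the
    per-cell quadratic expressions exactly.
    """
    f = dist.freq.ravel()
    pair_prob = f[_PAIR_A] * f[_PAIR_B]
    flat = np.bincount(_PAIR_CELL, weights=pair_prob, minlength=27)
    return JointZygoteTable(flat.reshape(9, 3))


def marker_genotype_marginals(table: JointZygoteTable) -> np.ndarray:
    """Two-marker genotype class frequencies (row sums), length 9."""
    return table.prob.sum(axis=1)


def conditional_qtl_probs(
    table: JointZygoteTable, g: MarkerGenotype
) -> np.ndarray:
    """Conditional QTL genotype probabilities (pi_0, pi_1, pi_2) given g.

    Raises :class:`DegenerateMarkerClassError` when the marker class has
    zero marginal probability (monomorphic or impossible genotype).
    """
    row = table.prob[MarkerGenotype(*g).row]
    marg = row.sum()
    if marg <= 0.0:
        raise DegenerateMarkerClassError(
            f"marker genotype class {tuple(g)} has zero probability"
        )
    return row / marg
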