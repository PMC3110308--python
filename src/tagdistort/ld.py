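"""Two-locus linkage disequilibrium parameterized by allele frequencies and r.

A pair of biallelic SNPs A and B (alleles coded 0/1) defines four haplotypes.
With Hardy-Weinberg equilibrium at the haplotype level, the joint distribution
of the two SNP genotypes is fully determined by three numbers: the allele-1
frequencies ``f_A`` and ``f_B`` and the correlation coefficient ``r`` between
the allele indicators on a haplotype (``r**2`` is the usual LD measure).

The central identity used throughout is the covariance representation

    Pr(11) = f_A * f_B + r * sqrt(f_A (1-f_A) f_B (1-f_B))

from which all haplotype, conditional, and diplotype probabilities follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LDInfeasibleError",
    "TwoLocusLD",
    "HaplotypeDistribution",
    "r_bounds",
    "haplotype_distribution",
    "conditional_probs",
    "diplotype_distribution",
    "d_coefficient",
    "r_from_haplotypes",
]

#: probability cells within this of [0, 1] are clamped; larger violations raise
_PROB_TOL = 1e-12


class LDInfeasibleError(ValueError):
    """Raised when (f_A, f_B, r) is inconsistent with a haplotype distribution."""


def _check_freq(f: float, name: str) -> None:
    if not 0.0 < f < 1.0:
        raise ValueError(f"{name} must lie in the open interval (0, 1), got {f}")


def r_bounds(f_A: float, f_B: float) -> tuple[float, float]:
    """Feasible range of the haplotype correlation r for given allele frequencies.

    The haplotype probability Pr(11) must lie in
    [max(0, f_A + f_B - 1), min(f_A, f_B)] (Frechet bounds); translating through
    the covariance identity gives the interval for r.  The upper bound equals 1
    only when f_A = f_B, so a high positive correlation requires nearly equal
    frequencies.
    """
    _check_freq(f_A, "f_A")
    _check_freq(f_B, "f_B")
    s = math.sqrt(f_A * (1.0 - f_A) * f_B * (1.0 - f_B))
    lo = (max(0.0, f_A + f_B - 1.0) - f_A * f_B) / s
    hi = (min(f_A, f_B) - f_A * f_B) / s
    return lo, hi


@dataclass(frozen=True)
class TwoLocusLD:
    """LD between a pair of SNPs, as (f_A, f_B, r).

    Parameters
    ----------
    f_A, f_B
        Frequency of allele 1 at each SNP, in (0, 1).
    r
        Correlation between the allele indicators on a haplotype.  Must lie
        within :func:`r_bounds`; an infeasible value raises
        :class:`LDInfeasibleError` rather than being clipped.  Negative r is
        allowed: correlation in either direction makes the marker informative.
    """

    f_A: float
    f_B: float
    r: float

    def __post_init__(self) -> None:
        lo, hi = r_bounds(self.f_A, self.f_B)
        if not lo - _PROB_TOL <= self.r <= hi + _PROB_TOL:
            raise LDInfeasibleError(
                f"LD infeasible for these frequencies: r={self.r} outside "
                f"[{lo:.6g}, {hi:.6g}] for f_A={self.f_A}, f_B={self.f_B}"
            )

    # -- derived quantities -------------------------------------------------

    def haplotype_distribution(self) -> "HaplotypeDistribution":
        return haplotype_distribution(self)

    def conditional_probs(self) -> tuple[float, float]:
        return conditional_probs(self)

    def diplotype_distribution(self) -> np.ndarray:
        return diplotype_distribution(self)

    @property
    def D(self) -> float:
        return d_coefficient(self)


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Probabilities of the four haplotypes (A, B) = 11, 10, 01, 00."""

    p11: float
    p10: float
    p01: float
    p00: float

    def as_array(self) -> np.ndarray:
        # indexed [a, b]
        return np.array([[self.p00, self.p01], [self.p10, self.p11]])

    @property
    def f_A(self) -> float:
        return self.p11 + self.p10

    @property
    def f_B(self) -> float:
        return self.p11 + self.p01


def _clamp_prob(p: float) -> float:
    if p < -_PROB_TOL or p > 1.0 + _PROB_TOL:
        raise LDInfeasibleError(f"probability {p} outside [0, 1]")
    return min(max(p, 0.0), 1.0)


def haplotype_distribution(ld: TwoLocusLD) -> HaplotypeDistribution:
    """Haplotype distribution induced by (f_A, f_B, r).

    Uses Pr(11) = f_A f_B + Cov(A, B) with Cov = r * sqrt(f_A(1-f_A)f_B(1-f_B));
    the remaining cells follow from the marginals.
    """
    f_A, f_B = ld.f_A, ld.f_B
    p11 = f_A * f_B + d_coefficient(ld)
    p10 = f_A - p11
    p01 = f_B - p11
    p00 = 1.0 - p11 - p10 - p01
    return HaplotypeDistribution(*(_clamp_prob(p) for p in (p11, p10, p01, p00)))


def d_coefficient(ld: TwoLocusLD) -> float:
    """Disequilibrium coefficient D = Pr(11) - f_A * f_B."""
    return ld.r * math.sqrt(
        ld.f_A * (1.0 - ld.f_A) * ld.f_B * (1.0 - ld.f_B)
    )


def r_from_haplotypes(h: HaplotypeDistribution) -> float:
    """Recover the allele-indicator correlation from a haplotype distribution."""
    f_A, f_B = h.f_A, h.f_B
    cov = h.p11 - f_A * f_B
    return cov / math.sqrt(f_A * (1.0 - f_A) * f_B * (1.0 - f_B))


def conditional_probs(ld: TwoLocusLD) -> tuple[float, float]:
    """(q0, q1) = (Pr(A=1 | B=0), Pr(A=1 | B=1)) on a haplotype.

    These satisfy q1 * f_B + q0 * (1 - f_B) = f_A and
    q1 - q0 = r * sqrt(f_A(1-f_A) / (f_B(1-f_B))).
    """
    h = haplotype_distribution(ld)
    q1 = h.p11 / ld.f_B
    q0 = h.p10 / (1.0 - ld.f_B)
    return q0, q1


def conditional_genotype_matrix(ld: TwoLocusLD) -> np.ndarray:
    """3x3 matrix C with C[k, j] = Pr(G_A = j | G_B = k) under haplotype HWE.

    Given the marker genotype G_B = k, the causal genotype is the sum of
    independent Bernoulli draws: Binomial(2, q0) for k = 0, Bernoulli(q0) +
    Bernoulli(q1) for k = 1 and Binomial(2, q1) for k = 2 (the two haplotypes of
    a heterozygote carry B-alleles 0 and 1 respectively).
    """
    q0, q1 = conditional_probs(ld)
    row0 = [(1 - q0) ** 2, 2 * q0 * (1 - q0), q0**2]
    row1 = [
        (1 - q0) * (1 - q1),
        q0 * (1 - q1) + q1 * (1 - q0),
        q0 * q1,
    ]
    row2 = [(1 - q1) ** 2, 2 * q1 * (1 - q1), q1**2]
    return np.array([row0, row1, row2])


def diplotype_distribution(ld: TwoLocusLD) -> np.ndarray:
    """Joint distribution of the genotype pair (G_A, G_B) as a 3x3 array.

    Assumes HWE for haplotypes: an individual's two haplotypes are i.i.d. draws
    from the haplotype distribution.  The double-heterozygote cell sums the two
    underlying (indistinguishable from genotypes) diplotypes.
    """
    h = haplotype_distribution(ld).as_array()  # [a, b]
    joint = np.zeros((3, 3))
    for a1 in (0, 1):
        for b1 in (0, 1):
            for a2 in (0, 1):
                for b2 in (0, 1):
                    joint[a1 + a2, b1 + b2] += h[a1, b1] * h[a2, b2]
    return joint


def hwe_genotype_freqs(f: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-f)^2, 2f(1-f), f^2)."""
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])
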