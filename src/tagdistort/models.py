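"""Single-SNP and two-SNP log-risk disease models.

The workhorse is the *general* model for a single SNP with genotype G in
{0, 1, 2}:

    log Pr(Y = 1 | G) = mu + beta * G + gamma * 1{G = 1}

where ``beta`` is the additive (per-allele) parameter and ``gamma`` the
dominance parameter, i.e. the deviation from a multiplicative model at the
heterozygote.  Special cases: gamma = 0 multiplicative, gamma = beta dominant,
gamma = -beta recessive.

For a pair of SNPs the *interaction* model is defined on haplotypes: a
haplotype carrying alleles (a, a') contributes mu-free log risk
beta1*a + beta2*a' + tau*a*a', and an individual's log risk is mu plus the sum
over its two haplotypes.  tau = 0 recovers the two-SNP multiplicative model.

Log risk is used as the derivation device because, with cohort (population)
controls, a case-control logistic regression estimates log-risk parameters
exactly; with case-based controls the two links agree closely whenever disease
prevalence is small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelValidityError",
    "GeneralModel",
    "InteractionModel",
    "PenetranceSet",
    "DEFAULT_MU",
]

#: default baseline log risk; case-control results of interest are mu-free
DEFAULT_MU = math.log(0.01)

_KINDS = ("multiplicative", "dominant", "recessive")


class ModelValidityError(ValueError):
    """A parameter set implies a penetrance outside (0, 1]."""


@dataclass(frozen=True)
class PenetranceSet:
    """Genotype (or haplotype-pair) disease probabilities.

    ``values`` is a length-3 vector Pr(Y=1 | G=g) for a single SNP, or a 2x2
    matrix over per-haplotype allele pairs for the interaction model.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v <= 0.0) or np.any(v > 1.0):
            raise ModelValidityError(
                f"penetrances must lie in (0, 1], got {v.tolist()}"
            )

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, idx):
        return self.values[idx]


@dataclass(frozen=True)
class GeneralModel:
    """Three-parameter log-risk model at one SNP: mu + beta*G + gamma*1{G=1}."""

    mu: float = DEFAULT_MU
    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        self.penetrances()  # raises if any penetrance exceeds 1

    @classmethod
    def from_homozygous_rr(
        cls, kind: str, hom_rr: float, mu: float = DEFAULT_MU
    ) -> "GeneralModel":
        """Build a named model from its homozygous relative risk.

        beta = 0.5*log(hom_rr) always; gamma is 0, +beta or -beta for the
        multiplicative, dominant and recessive model respectively.
        """
        if kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
        if hom_rr <= 0:
            raise ValueError("hom_rr must be positive")
        beta = 0.5 * math.log(hom_rr)
        gamma = {"multiplicative": 0.0, "dominant": beta, "recessive": -beta}[kind]
        return cls(mu=mu, beta=beta, gamma=gamma)

    def penetrances(self) -> PenetranceSet:
        """(p0, p1, p2) = (e^mu, e^(mu+beta+gamma), e^(mu+2 beta))."""
        log_p = np.array(
            [self.mu, self.mu + self.beta + self.gamma, self.mu + 2.0 * self.beta]
        )
        return PenetranceSet(np.exp(log_p))

    def genotype_relative_risks(self) -> tuple[float, float]:
        """(alpha1, alpha2): risks of genotypes 1 and 2 relative to genotype 0."""
        return math.exp(self.beta + self.gamma), math.exp(2.0 * self.beta)

    def relabel_alleles(self) -> "GeneralModel":
        """The same model with the allele coding swapped (G -> 2 - G).

        Maps (beta, gamma) -> (-beta, gamma) with the baseline moved to the
        other homozygote; dominant and recessive classifications swap.
        """
        return GeneralModel(
            mu=self.mu + 2.0 * self.beta, beta=-self.beta, gamma=self.gamma
        )

    @property
    def kind(self) -> str:
        if math.isclose(self.gamma, 0.0, abs_tol=1e-12):
            return "multiplicative"
        if math.isclose(self.gamma, self.beta, rel_tol=1e-9, abs_tol=1e-12):
            return "dominant"
        if math.isclose(self.gamma, -self.beta, rel_tol=1e-9, abs_tol=1e-12):
            return "recessive"
        return "general"


@dataclass(frozen=True)
class InteractionModel:
    """Two-SNP haplotype log-risk model with a single interaction parameter tau."""

    mu: float = DEFAULT_MU
    beta1: float = 0.0
    beta2: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        self.penetrance_matrix()

    def penetrance_matrix(self) -> PenetranceSet:
        """2x2 matrix with entry (a, a') = exp(mu + a*beta1 + a'*beta2 + a*a'*tau)."""
        a = np.arange(2)[:, None]
        ap = np.arange(2)[None, :]
        log_p = self.mu + a * self.beta1 + ap * self.beta2 + a * ap * self.tau
        return PenetranceSet(np.exp(log_p))

    def haplotype_risk_multipliers(self) -> np.ndarray:
        """mu-free per-haplotype risk factors exp(a*beta1 + a'*beta2 + a*a'*tau)."""
        return self.penetrance_matrix().values / math.exp(self.mu)
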