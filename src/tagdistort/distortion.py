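"""Distortion of disease models at marker SNPs under imperfect LD.

A causal SNP A with a general log-risk model and a marker SNP B in LD with it
induce a disease model at B: the marker penetrances are LD-weighted mixtures of
the causal ones,

    p_B(g) = sum_j Pr(G_A = j | G_B = g) * p_A(j).

Exactly, the second difference of penetrances (the multiplicative-deviation
summary) scales by (q1 - q0)^2, and for the two-SNP interaction model the
penetrance-matrix determinant scales by (q1 - q0)(q1' - q0').  For small
effects this yields the headline approximations

    beta_B ~ c * beta_A        (linear in r when f_A = f_B, c = q1 - q0)
    gamma_B ~ c^2 * gamma_A    (quadratic in r)
    tau_B ~ c * c' * tau       (product of the two tagging correlations)

so dominance and interaction effects decay much faster with LD than additive
effects, and the model observed at a marker is distorted toward a
multiplicative one.

The *effective additive parameter* beta' is the large-sample additive
coefficient obtained when the (possibly misspecified) multiplicative logistic
model is fitted to case-control data generated by an arbitrary truth; it is
computed by fitting to the theoretical genotype frequencies treated as
fractional counts, with cohort (population) controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._wfit import weighted_logit_fit
from .ld import TwoLocusLD, conditional_genotype_matrix, conditional_probs, hwe_genotype_freqs
from .models import GeneralModel, InteractionModel, PenetranceSet

__all__ = [
    "StudyDesign",
    "MarkerModel",
    "marker_penetrances",
    "marker_params_exact",
    "approx_marker_params",
    "marker_interaction",
    "effective_additive",
    "model_space_trajectory",
    "case_control_genotype_freqs",
]


@dataclass(frozen=True)
class StudyDesign:
    """Case-control sample size and composition.

    phi is the proportion of cases in the sample (default 0.5, an equal number
    of cases and controls).
    """

    n_total: int = 4000
    phi: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")

    @property
    def n_cases(self) -> float:
        return self.n_total * self.phi

    @property
    def n_controls(self) -> float:
        return self.n_total * (1.0 - self.phi)


@dataclass(frozen=True)
class MarkerModel:
    """Disease model induced at a marker SNP (or marker SNP pair).

    For a single SNP, (mu_B, beta_B, gamma_B) reproduce the marker penetrances
    exactly; beta_eff is the effective additive parameter beta' of the
    multiplicative fit.  For the interaction model, tau_B is the log
    cross-ratio of the marker penetrance matrix.
    """

    mu_B: float
    beta_B: float = 0.0
    gamma_B: float = 0.0
    tau_B: float | None = None
    beta1_B: float | None = None
    beta2_B: float | None = None
    beta_eff: float | None = None

    def as_general_model(self) -> GeneralModel:
        return GeneralModel(mu=self.mu_B, beta=self.beta_B, gamma=self.gamma_B)


def case_control_genotype_freqs(
    penetrances: PenetranceSet | np.ndarray, f: float
) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical genotype frequencies among cases and (cohort) controls.

    Cases: Pr(G = g | Y = 1) proportional to Pr(G = g) * p(g) with HWE
    population genotype frequencies.  Controls are an unphenotyped population
    sample, so their genotype frequencies are the population ones — the design
    under which logistic regression estimates log-risk parameters exactly.
    """
    p = np.asarray(getattr(penetrances, "values", penetrances), dtype=float)
    pop = hwe_genotype_freqs(f)
    case = pop * p
    return case / case.sum(), pop


def marker_penetrances(causal: GeneralModel, ld: TwoLocusLD) -> PenetranceSet:
    """Penetrances observed at the marker SNP B given the causal model at A.

    Mixes the causal penetrances with the conditional genotype law
    Pr(G_A | G_B) from the diplotype distribution (genotype-level mixing; no
    extra assumptions beyond haplotype HWE).  Population mean risk is
    preserved.
    """
    C = conditional_genotype_matrix(ld)  # C[k, j] = Pr(G_A=j | G_B=k)
    p_A = causal.penetrances().values
    return PenetranceSet(C @ p_A)


def marker_params_exact(causal: GeneralModel, ld: TwoLocusLD) -> MarkerModel:
    """General-model parameters that exactly reproduce the marker penetrances.

    mu_B = log p_B0, beta_B = 0.5*log(p_B2/p_B0),
    gamma_B = log p_B1 - mu_B - beta_B.
    """
    p = marker_penetrances(causal, ld).values
    if np.any(p <= 0.0):
        raise ValueError("marker penetrances must be strictly positive")
    mu_B = math.log(p[0])
    beta_B = 0.5 * math.log(p[2] / p[0])
    gamma_B = math.log(p[1]) - mu_B - beta_B
    return MarkerModel(mu_B=mu_B, beta_B=beta_B, gamma_B=gamma_B)


def approx_marker_params(
    causal: GeneralModel, ld: TwoLocusLD
) -> tuple[float, float]:
    """Small-effect approximations (beta_B, gamma_B) ~ (c*beta_A, c^2*gamma_A).

    c = q1 - q0 = r * sqrt(f_A(1-f_A) / (f_B(1-f_B))); when f_A = f_B this is
    just r, so the additive effect decays linearly and the dominance effect
    quadratically with r.  Accurate for |beta|, |gamma| up to about 0.7.
    """
    q0, q1 = conditional_probs(ld)
    c = q1 - q0
    return c * causal.beta, c * c * causal.gamma


def mixing_matrix(ld: TwoLocusLD) -> np.ndarray:
    """2x2 matrix Q with Q[a, b] = Pr(A = a | B = b) on a haplotype."""
    q0, q1 = conditional_probs(ld)
    return np.array([[1.0 - q0, 1.0 - q1], [q0, q1]])


def marker_interaction(
    causal: InteractionModel, ld: TwoLocusLD, ld2: TwoLocusLD
) -> MarkerModel:
    """Interaction model observed at a pair of marker SNPs.

    With haplotype-level mixing at each locus independently, the marker
    penetrance matrix is P_B = Q' P_A Q'' (Q built from the conditional allele
    probabilities at each locus), so det P_B = (q1-q0)(q1'-q0') det P_A and the
    marker interaction parameter is the log cross-ratio
    tau_B = log(p11 p00 / (p10 p01)).
    """
    P_A = causal.penetrance_matrix().values
    Q1 = mixing_matrix(ld)
    Q2 = mixing_matrix(ld2)
    P_B = Q1.T @ P_A @ Q2
    tau_B = math.log(P_B[1, 1] * P_B[0, 0] / (P_B[1, 0] * P_B[0, 1]))
    mu_B = math.log(P_B[0, 0])
    beta1_B = math.log(P_B[1, 0]) - mu_B
    beta2_B = math.log(P_B[0, 1]) - mu_B
    return MarkerModel(
        mu_B=mu_B, tau_B=tau_B, beta1_B=beta1_B, beta2_B=beta2_B
    )


def marker_interaction_penetrances(
    causal: InteractionModel, ld: TwoLocusLD, ld2: TwoLocusLD
) -> np.ndarray:
    """Marker-pair 2x2 penetrance matrix P_B = Q1' P_A Q2."""
    P_A = causal.penetrance_matrix().values
    return mixing_matrix(ld).T @ P_A @ mixing_matrix(ld2)


def effective_additive(
    causal: GeneralModel, f: float, design: StudyDesign | None = None
) -> float:
    """Effective additive parameter beta' of the multiplicative fit.

    Fits the multiplicative logistic model to the theoretical case/control
    genotype frequencies, weighted phi : (1 - phi), treating the frequencies as
    fractional sample counts.  For a multiplicative truth with cohort controls
    beta' = beta exactly; for dominant/recessive truths beta' interpolates
    between 0 and twice the per-allele log RR as the risk allele frequency
    moves between its extremes.
    """
    if design is None:
        design = StudyDesign()
    case_f, ctrl_f = case_control_genotype_freqs(causal.penetrances(), f)
    X = np.column_stack([np.ones(3), np.arange(3.0)])
    fit = weighted_logit_fit(X, design.phi * case_f, (1.0 - design.phi) * ctrl_f)
    return float(fit.params[1])


def model_space_trajectory(
    causal: GeneralModel, f_A: float, f_B: float, r_grid
) -> np.ndarray:
    """(beta_B, gamma_B) pairs along an r grid — the model-space curve.

    Lower LD moves the point toward the origin, bending toward the
    multiplicative (gamma = 0) line.  Returns an array of shape (len(r_grid), 3)
    with columns (r, beta_B, gamma_B).
    """
    out = []
    for r in np.asarray(r_grid, dtype=float):
        if r == 0.0:
            out.append((0.0, 0.0, 0.0))
            continue
        m = marker_params_exact(causal, TwoLocusLD(f_A, f_B, float(r)))
        out.append((float(r), m.beta_B, m.gamma_B))
    return np.array(out)
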