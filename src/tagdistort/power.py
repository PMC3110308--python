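"""Noncentrality parameters and power for the trend, deviation and interaction tests.

Each test is the Wald test of one coefficient in a case-control logistic
regression (trend: the additive coefficient of the multiplicative model;
deviation: the dominance coefficient of the general model; interaction: the
product-term coefficient of the two-SNP haplotype model).  Under the
alternative the chi-square statistic is asymptotically noncentral chi-square
with one degree of freedom and noncentrality

    eta = N * theta*^2 / v,

where theta* is the population-limit value of the tested coefficient (the
coefficient of the weighted logistic fit to the theoretical case/control
frequencies) and v is the per-individual asymptotic variance of its estimator,
taken from the expected Fisher information of that fit with nuisance
parameters profiled out.  Since eta is proportional to N * theta^2 and the
distortion relations give theta_marker ~ c^k * theta_causal, the equivalent
sample sizes at a marker follow the three power laws

    trend:        N_B = N_A / r^2
    deviation:    N_B = N_A / r^4
    interaction:  N_B = N_A / (r * r')^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._wfit import weighted_logit_fit
from .distortion import MarkerModel, StudyDesign, case_control_genotype_freqs
from .ld import TwoLocusLD, haplotype_distribution
from .models import GeneralModel, InteractionModel

__all__ = [
    "NoncentralityResult",
    "ncp_trend",
    "ncp_deviation",
    "ncp_interaction",
    "power_from_ncp",
    "equivalent_sample_size",
]


@dataclass(frozen=True)
class NoncentralityResult:
    """Noncentrality parameter of a chi-square test statistic.

    theta is the population-limit value of the tested coefficient and
    variance_per_n the per-individual variance of its estimator, so
    ncp = n * theta**2 / variance_per_n.
    """

    ncp: float
    df: int
    theta: float
    variance_per_n: float
    n: float

    def power_at(self, alpha: float) -> float:
        return power_from_ncp(self, alpha)


def _as_general(model) -> GeneralModel:
    if isinstance(model, MarkerModel):
        return model.as_general_model()
    if isinstance(model, GeneralModel):
        return model
    raise TypeError(f"expected GeneralModel or MarkerModel, got {type(model)!r}")


def _single_snp_ncp(
    model, f: float, design: StudyDesign, X: np.ndarray, component: int
) -> NoncentralityResult:
    gm = _as_general(model)
    case_f, ctrl_f = case_control_genotype_freqs(gm.penetrances(), f)
    fit = weighted_logit_fit(X, design.phi * case_f, (1.0 - design.phi) * ctrl_f)
    theta = float(fit.params[component])
    v = float(fit.cov_per_unit()[component, component])
    return NoncentralityResult(
        ncp=design.n_total * theta**2 / v,
        df=1,
        theta=theta,
        variance_per_n=v,
        n=design.n_total,
    )


def ncp_trend(model_at_snp, f: float, design: StudyDesign) -> NoncentralityResult:
    """Noncentrality of the 1-df trend (additive) Wald test at a SNP.

    theta* is the effective additive parameter beta' at this SNP — for a
    multiplicative truth it equals beta; for other truths it is the
    population-limit coefficient of the misspecified multiplicative fit.
    """
    X = np.column_stack([np.ones(3), np.arange(3.0)])
    return _single_snp_ncp(model_at_snp, f, design, X, 1)


def ncp_deviation(model_at_snp, f: float, design: StudyDesign) -> NoncentralityResult:
    """Noncentrality of the 1-df deviation (dominance) Wald test at a SNP.

    The general logistic model is saturated on the three genotype cells, so
    theta* equals the log-risk dominance parameter gamma at the SNP exactly
    (cohort controls); v profiles over the baseline and additive parameters.
    """
    g = np.arange(3.0)
    X = np.column_stack([np.ones(3), g, (g == 1).astype(float)])
    return _single_snp_ncp(model_at_snp, f, design, X, 2)


def _joint_hap(ld: TwoLocusLD | None, f: float) -> np.ndarray:
    """Joint haplotype law J[a, b] of (causal allele a, marker allele b).

    ld = None means the causal SNP is typed directly (marker = causal).
    """
    if ld is None:
        return np.diag([1.0 - f, f])
    if abs(ld.f_A - f) > 1e-9:
        raise ValueError("ld.f_A must match the causal allele frequency f")
    return haplotype_distribution(ld).as_array()


def ncp_interaction(
    model: InteractionModel,
    f1: float,
    f2: float,
    ld: TwoLocusLD | None,
    ld2: TwoLocusLD | None,
    design: StudyDesign,
) -> NoncentralityResult:
    """Noncentrality of the 1-df interaction Wald test at a marker pair.

    Works at the haplotype level (the model factorizes over an individual's two
    haplotypes, so case haplotypes are ascertained independently, each with
    probability proportional to Pr(h) * risk multiplier).  The two causal loci
    are assumed independent of each other; ld / ld2 describe the tagging at
    each locus (None = typed directly).  A sample of N individuals contributes
    2N haplotypes.
    """
    J1 = _joint_hap(ld, f1)  # [a, b]
    J2 = _joint_hap(ld2, f2)  # [a', b']
    m = model.haplotype_risk_multipliers()  # [a, a']
    # case/control frequencies over marker haplotype cells (b, b')
    case = np.einsum("ab,cd,ac->bd", J1, J2, m)
    case = case / case.sum()
    ctrl = np.outer(J1.sum(axis=0), J2.sum(axis=0))
    b = np.array([0.0, 1.0])
    bb = np.array(np.meshgrid(b, b, indexing="ij"))
    X = np.column_stack(
        [
            np.ones(4),
            bb[0].ravel(),
            bb[1].ravel(),
            (bb[0] * bb[1]).ravel(),
        ]
    )
    fit = weighted_logit_fit(
        X, design.phi * case.ravel(), (1.0 - design.phi) * ctrl.ravel()
    )
    theta = float(fit.params[3])
    v = float(fit.cov_per_unit()[3, 3])
    n_hap = 2.0 * design.n_total
    return NoncentralityResult(
        ncp=n_hap * theta**2 / v, df=1, theta=theta, variance_per_n=v, n=n_hap
    )


def power_from_ncp(res: NoncentralityResult, alpha: float) -> float:
    """Power of a chi-square test with the given noncentrality at level alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    crit = stats.chi2.ppf(1.0 - alpha, res.df)
    if res.ncp == 0.0:
        return float(stats.chi2.sf(crit, res.df))
    return float(stats.ncx2.sf(crit, res.df, res.ncp))


def equivalent_sample_size(
    test: str, N_A: float, r: float, r2: float | None = None
) -> float:
    """Sample size at marker SNP(s) giving the same power as N_A at the causal SNP(s).

    trend: N_A / r**2; deviation: N_A / r**4; interaction: N_A / (r * r2)**2.
    """
    if test not in ("trend", "deviation", "interaction"):
        raise ValueError(f"unknown test {test!r}")
    if r == 0.0 or (test == "interaction" and not r2):
        raise ValueError("marker uninformative: r (and r' for interaction) must be nonzero")
    if test == "trend":
        return N_A / r**2
    if test == "deviation":
        return N_A / r**4
    return N_A / (r * r2) ** 2
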