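"""Finite-sample association tests on case-control genotype count tables.

The central object is :class:`CaseControlGenotypeModel`, a statsmodels-style
model built from a :class:`GenotypeCountTable`; ``fit()`` maximizes the
case-control logistic likelihood (via ``statsmodels`` GLM on binomial counts)
and returns a results object with estimates, standard errors and a
``summary()`` table.  On top of it sit the four tests used throughout:

trend test
    Cochran-Armitage test with scores (0, 1, 2); the score test of beta = 0
    under the multiplicative logistic model, computed in closed form.
deviation test
    1-df Wald test of the dominance parameter gamma; since the general model is
    saturated on a single-SNP table this too has a closed form.
general test
    2-df likelihood-ratio test of the general model against the null.
interaction test
    1-df Wald test of the product-term coefficient on a two-SNP (3x3) table.

Vectorized variants (`trend_stats`, `deviation_stats`) operate on stacked
count arrays and drive the genome-scan simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AssocFitError",
    "GenotypeCountTable",
    "TestResult",
    "CaseControlGenotypeModel",
    "trend_test",
    "deviation_test",
    "general_test",
    "interaction_test",
    "fit_model",
    "trend_stats",
    "deviation_stats",
]

_SINGLE_KINDS = ("multiplicative", "general")
_PAIR_KINDS = ("two_snp_mult", "interaction")


class AssocFitError(RuntimeError):
    """The requested fit is not possible (zero cells / separation).

    Callers running many replicates should treat the affected replicate as
    unfittable (e.g. non-significant) and log it; no continuity correction is
    applied, since that would change the size of the tests.
    """


@dataclass(frozen=True)
class GenotypeCountTable:
    """Case/control genotype counts at one SNP (length 3) or a SNP pair (3x3)."""

    case_counts: np.ndarray
    control_counts: np.ndarray

    def __post_init__(self) -> None:
        ca = np.asarray(self.case_counts, dtype=np.int64)
        co = np.asarray(self.control_counts, dtype=np.int64)
        if ca.shape != co.shape or ca.shape not in ((3,), (3, 3)):
            raise ValueError("counts must both be length-3 or 3x3 arrays")
        if np.any(ca < 0) or np.any(co < 0):
            raise ValueError("counts must be nonnegative")
        if ca.sum() == 0 or co.sum() == 0:
            raise ValueError("each phenotype needs at least one observation")
        object.__setattr__(self, "case_counts", ca)
        object.__setattr__(self, "control_counts", co)

    @property
    def is_pair(self) -> bool:
        return self.case_counts.ndim == 2

    @property
    def n_total(self) -> int:
        return int(self.case_counts.sum() + self.control_counts.sum())


@dataclass(frozen=True)
class TestResult:
    """A chi-square test outcome with the tested parameter's MLE where defined."""

    statistic: float
    df: int
    p_value: float
    estimate: float | None = None
    se: float | None = None


def _design(kind: str, pair: bool) -> tuple[np.ndarray, list[str]]:
    if pair:
        g1, g2 = np.meshgrid(np.arange(3.0), np.arange(3.0), indexing="ij")
        g1, g2 = g1.ravel(), g2.ravel()
        if kind == "two_snp_mult":
            return np.column_stack([np.ones(9), g1, g2]), [
                "intercept",
                "beta1",
                "beta2",
            ]
        if kind == "interaction":
            return (
                np.column_stack([np.ones(9), g1, g2, g1 * g2]),
                ["intercept", "beta1", "beta2", "tau"],
            )
        raise ValueError(f"kind {kind!r} needs a single-SNP table")
    g = np.arange(3.0)
    if kind == "multiplicative":
        return np.column_stack([np.ones(3), g]), ["intercept", "beta"]
    if kind == "general":
        return (
            np.column_stack([np.ones(3), g, (g == 1).astype(float)]),
            ["intercept", "beta", "gamma"],
        )
    raise ValueError(f"kind {kind!r} needs a two-SNP table")


class CaseControlGenotypeResults:
    """Estimates, uncertainty and diagnostics from a case-control logistic fit."""

    def __init__(self, model: "CaseControlGenotypeModel", glm_results):
        self.model = model
        self._res = glm_results
        self.param_names = model.param_names
        self.params = np.asarray(glm_results.params, dtype=float)
        self.bse = np.asarray(glm_results.bse, dtype=float)
        self.llf = float(glm_results.llf)

    def cov_params(self) -> np.ndarray:
        return np.asarray(self._res.cov_params(), dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.params[self.param_names.index(name)]

    def wald_test(self, name: str) -> TestResult:
        """1-df Wald chi-square test that the named coefficient is zero."""
        i = self.param_names.index(name)
        est, se = self.params[i], self.bse[i]
        if not np.isfinite(se) or se == 0.0:
            raise AssocFitError(f"standard error of {name!r} is not finite")
        stat = (est / se) ** 2
        return TestResult(
            statistic=float(stat),
            df=1,
            p_value=float(stats.chi2.sf(stat, 1)),
            estimate=float(est),
            se=float(se),
        )

    def summary(self):
        return self._res.summary(
            xname=self.param_names, title="Case-control genotype logistic fit"
        )


class CaseControlGenotypeModel:
    """Logistic disease-risk model on a genotype count table.

    Parameters
    ----------
    table
        Case/control genotype counts.
    kind
        One of ``multiplicative``, ``general`` (single SNP) or
        ``two_snp_mult``, ``interaction`` (SNP pair).
    """

    def __init__(self, table: GenotypeCountTable, kind: str = "general"):
        if kind not in _SINGLE_KINDS + _PAIR_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        if table.is_pair != (kind in _PAIR_KINDS):
            raise ValueError(f"model kind {kind!r} does not match table shape")
        self.table = table
        self.kind = kind
        self.exog, self.param_names = _design(kind, table.is_pair)

    @classmethod
    def from_counts(
        cls, case_counts, control_counts, kind: str = "general"
    ) -> "CaseControlGenotypeModel":
        return cls(GenotypeCountTable(case_counts, control_counts), kind)

    def fit(self) -> CaseControlGenotypeResults:
        import statsmodels.api as sm

        ca = self.table.case_counts.ravel().astype(float)
        co = self.table.control_counts.ravel().astype(float)
        self._check_fittable(ca, co)
        endog = np.column_stack([ca, co])
        keep = (ca + co) > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(endog[keep], self.exog[keep], family=sm.families.Binomial())
            try:
                res = glm.fit(maxiter=200, tol=1e-10)
            except Exception as exc:  # perfect separation and friends
                raise AssocFitError(str(exc)) from exc
        if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 30):
            raise AssocFitError(
                "fit did not yield finite estimates (zero cells or separation); "
                "treat this table as unfittable"
            )
        return CaseControlGenotypeResults(self, res)

    def _check_fittable(self, ca: np.ndarray, co: np.ndarray) -> None:
        if self.kind == "general":
            # saturated fit: every occupied genotype cell needs both phenotypes
            bad = (ca + co > 0) & ((ca == 0) | (co == 0))
            if np.any(bad):
                raise AssocFitError(
                    "general model is saturated and a genotype cell has cases "
                    "or controls only; the deviation test is undefined here"
                )


def fit_model(t: GenotypeCountTable, kind: str) -> CaseControlGenotypeResults:
    """Maximum-likelihood logistic fit of the requested model to a count table."""
    return CaseControlGenotypeModel(t, kind).fit()


# -- closed-form tests ------------------------------------------------------


def trend_stats(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Cochran-Armitage trend test over stacked (..., 3) count arrays.

    Returns (statistic, p_value); entries are NaN where the statistic is
    undefined (no genotype variation).
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    n = r + s
    g = np.arange(3.0)
    N = n.sum(axis=-1)
    R = r.sum(axis=-1)
    U = (g * r).sum(axis=-1) - (R / N) * (g * n).sum(axis=-1)
    pbar = R / N
    V = pbar * (1.0 - pbar) * ((g**2 * n).sum(axis=-1) - (g * n).sum(axis=-1) ** 2 / N)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(V > 0, U**2 / np.where(V > 0, V, 1.0), np.nan)
    return stat, stats.chi2.sf(stat, 1)


def deviation_stats(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized deviation (dominance) Wald test over stacked (..., 3) counts.

    The general model is saturated, so gamma_hat = logit of the heterozygote
    case fraction minus the mean of the homozygote logits, with variance the
    matching combination of 1/count terms.  Returns
    (statistic, p_value, gamma_hat, se); NaN where any cell is empty.
    """
    r = np.asarray(case_counts, dtype=float)
    s = np.asarray(control_counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        l = np.log(r) - np.log(s)  # per-genotype log odds
        v = 1.0 / r + 1.0 / s
        gamma = l[..., 1] - 0.5 * (l[..., 0] + l[..., 2])
        var = v[..., 1] + 0.25 * (v[..., 0] + v[..., 2])
        stat = gamma**2 / var
    ok = np.isfinite(stat)
    stat = np.where(ok, stat, np.nan)
    return stat, stats.chi2.sf(stat, 1), gamma, np.sqrt(var)


def trend_test(t: GenotypeCountTable) -> TestResult:
    """Cochran-Armitage trend test (score test of the multiplicative model)."""
    if t.is_pair:
        raise ValueError("trend test needs a single-SNP table")
    stat, p = trend_stats(t.case_counts, t.control_counts)
    if not np.isfinite(stat):
        raise AssocFitError("trend test undefined: no genotype variation")
    return TestResult(statistic=float(stat), df=1, p_value=float(p))


def deviation_test(t: GenotypeCountTable) -> TestResult:
    """1-df Wald test of the dominance parameter gamma (general vs multiplicative)."""
    if t.is_pair:
        raise ValueError("deviation test needs a single-SNP table")
    stat, p, gamma, se = deviation_stats(t.case_counts, t.control_counts)
    if not np.isfinite(stat):
        raise AssocFitError(
            "deviation test undefined: a genotype cell has no cases or no controls"
        )
    return TestResult(
        statistic=float(stat),
        df=1,
        p_value=float(p),
        estimate=float(gamma),
        se=float(se),
    )


def _binomial_llf(r: np.ndarray, s: np.ndarray, pi: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(r > 0, r * np.log(pi), 0.0) + np.where(
            s > 0, s * np.log1p(-pi), 0.0
        )
    return float(terms.sum())


def general_test(t: GenotypeCountTable) -> TestResult:
    """2-df likelihood-ratio test of the general model against the null.

    The general model is saturated on a single-SNP table, so its likelihood is
    evaluated at the empirical per-genotype case fractions.
    """
    if t.is_pair:
        raise ValueError("general test needs a single-SNP table")
    r = t.case_counts.astype(float)
    s = t.control_counts.astype(float)
    n = r + s
    occ = n > 0
    pi_hat = np.where(occ, r / np.where(occ, n, 1.0), 0.5)
    pi_null = r.sum() / n.sum()
    lr = 2.0 * (
        _binomial_llf(r[occ], s[occ], pi_hat[occ])
        - _binomial_llf(r[occ], s[occ], np.full(occ.sum(), pi_null))
    )
    lr = max(lr, 0.0)
    return TestResult(statistic=lr, df=2, p_value=float(stats.chi2.sf(lr, 2)))


def interaction_test(t: GenotypeCountTable) -> TestResult:
    """1-df Wald test of the interaction coefficient on a 3x3 genotype table."""
    if not t.is_pair:
        raise ValueError("interaction test needs a two-SNP (3x3) table")
    return fit_model(t, "interaction").wald_test("tau")
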