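"""Weighted logistic fits to theoretical cell frequencies.

Population-limit ("pretend the theoretical frequencies are sample counts")
logistic fits underpin both the effective additive parameter and the analytic
noncentrality parameters.  The designs involved have at most nine cells and a
handful of parameters, and downstream identity checks need the optimum to
machine precision, so a dedicated Newton-Raphson solver is used.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["weighted_logit_fit", "WeightedLogitFit"]


class SeparationError(RuntimeError):
    """The weighted likelihood has no finite maximum (degenerate frequencies)."""


class WeightedLogitFit:
    """Result of a weighted logistic fit.

    Attributes
    ----------
    params : ndarray
        Coefficient vector.
    info : ndarray
        Expected Fisher information per unit total weight, X' W X with
        W = diag(n_g * pi_g * (1 - pi_g)).
    """

    def __init__(self, params: np.ndarray, info: np.ndarray):
        self.params = params
        self.info = info

    def cov_per_unit(self) -> np.ndarray:
        return np.linalg.inv(self.info)


def weighted_logit_fit(
    X: np.ndarray,
    case_w: np.ndarray,
    ctrl_w: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 200,
) -> WeightedLogitFit:
    """Maximize sum_g [case_w_g log pi_g + ctrl_w_g log(1 - pi_g)], pi = expit(X b).

    Weights may be fractional; they are normalized to sum to 1 so the returned
    information matrix is per individual.
    """
    X = np.asarray(X, dtype=float)
    case_w = np.asarray(case_w, dtype=float)
    ctrl_w = np.asarray(ctrl_w, dtype=float)
    total = case_w.sum() + ctrl_w.sum()
    if total <= 0:
        raise ValueError("weights must have positive total")
    case_w = case_w / total
    ctrl_w = ctrl_w / total
    n_g = case_w + ctrl_w
    keep = n_g > 0
    if np.any(~keep):
        X, case_w, ctrl_w, n_g = X[keep], case_w[keep], ctrl_w[keep], n_g[keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SeparationError(
            "design matrix is rank-deficient at the observed cells "
            "(degenerate frequencies)"
        )

    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        pi = expit(eta)
        score = X.T @ (case_w - n_g * pi)
        w = n_g * pi * (1.0 - pi)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise SeparationError("singular information matrix") from exc
        # damped Newton for stability far from the optimum
        if np.max(np.abs(step)) > 5.0:
            step *= 5.0 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise SeparationError("weighted logistic fit did not converge")
    if np.max(np.abs(beta)) > 30.0:
        raise SeparationError("weighted logistic fit diverged (separation)")
    eta = X @ beta
    pi = expit(eta)
    w = n_g * pi * (1.0 - pi)
    info = X.T @ (X * w[:, None])
    return WeightedLogitFit(beta, info)
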