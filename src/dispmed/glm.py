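"""Maximum-likelihood logistic regression via Newton-Raphson.

A lean fitter sized for the package's inner loops (thousands of refits
inside the bootstrap and the chained-equations imputation cycle).  It is
cross-checked against statsmodels GLM in the test suite.  Separation and
non-convergence are reported through a flag, not an exception, so that
bootstrap replicates can be counted as failed rather than aborting a run;
an optional ridge penalty is available as a documented fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .design import DesignInfo
from .exceptions import CollinearityError, DegenerateDataError

_LP_CLIP = 35.0  # linear predictors beyond this are numerically 0/1
_BETA_SEPARATION = 50.0


def sigmoid(lp):
    """Numerically clipped inverse logit."""
    out = np.empty_like(lp, dtype=float)
    np.clip(lp, -_LP_CLIP, _LP_CLIP, out=out)
    np.negative(out, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming the dependent columns, if any."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = piv[np.flatnonzero(diag <= tol)]
    if diag.size < X.shape[1]:
        bad = np.concatenate([bad, piv[diag.size:]])
    if len(bad):
        raise CollinearityError([names[j] for j in sorted(bad)])


def fit_logistic_arrays(X: np.ndarray, y: np.ndarray, names: list[str] | None = None,
                        ridge: float = 0.0, max_iter: int = 60,
                        tol: float = 1e-10):
    """Newton-Raphson MLE for a binary response.

    Returns (beta, cov, converged, n_iter).  ``converged`` is False when the
    iteration limit is hit or the estimates drift to the separation region.
    """
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    if y.min() == y.max():
        raise DegenerateDataError("response is constant")
    if ridge == 0.0:
        check_rank(X, names)

    beta = np.zeros(p)
    dev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = X @ beta
        pr = sigmoid(lp)
        grad = X.T @ (y - pr)
        if ridge:
            grad -= ridge * beta
        w = pr * (1.0 - pr)
        H = (X * w[:, None]).T @ X
        if ridge:
            H[np.diag_indices_from(H)] += ridge
        try:
            step = scipy.linalg.solve(H, grad, assume_a="pos")
        except scipy.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8 * max(1.0, np.trace(H) / p)
            step = scipy.linalg.solve(H, grad, assume_a="pos")
        # step halving on the penalized deviance
        eps = 1e-12
        for half in range(25):
            cand = beta + step
            lp_c = np.clip(X @ cand, -_LP_CLIP, _LP_CLIP)
            dev_c = -2.0 * float(y @ lp_c - np.logaddexp(0.0, lp_c).sum())
            if ridge:
                dev_c += ridge * float(cand @ cand)
            if dev_c <= dev + 1e-9:
                break
            step *= 0.5
        beta = cand
        if abs(dev - dev_c) < tol * (abs(dev_c) + 1.0) and np.abs(grad).max() < 1e-6 * n:
            dev = dev_c
            converged = True
            break
        dev = dev_c

    if np.abs(beta).max() > _BETA_SEPARATION or (ridge == 0.0 and dev < 1e-6):
        converged = False  # separation: the MLE does not exist
    lp = X @ beta
    pr = sigmoid(lp)
    w = pr * (1.0 - pr)
    H = (X * w[:, None]).T @ X
    if ridge:
        H[np.diag_indices_from(H)] += ridge
    try:
        cov = scipy.linalg.inv(H)
    except scipy.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged, it


@dataclass
class FittedModel:
    """A logistic model: terms, log-odds coefficients and their covariance.

    Can also be constructed directly from coefficients (no data) to drive
    the mediation engine with externally specified models.
    """

    design_info: DesignInfo
    params: np.ndarray
    cov_params: np.ndarray | None = None
    converged: bool = True
    nobs: int = 0
    response: str = ""

    @property
    def term_names(self) -> list[str]:
        return self.design_info.term_names

    @property
    def bse(self) -> np.ndarray:
        if self.cov_params is None:
            return np.full(len(self.params), np.nan)
        return np.sqrt(np.diag(self.cov_params))

    def coef(self, name: str) -> float:
        return float(self.params[self.term_names.index(name)])

    def linear_predictor(self, encoded: dict[str, np.ndarray], n: int | None = None) -> np.ndarray:
        return self.design_info.matrix(encoded, n=n) @ self.params

    def predict(self, encoded: dict[str, np.ndarray], n: int | None = None) -> np.ndarray:
        """Predicted probabilities from encoded columns."""
        return sigmoid(self.linear_predictor(encoded, n=n))

    @classmethod
    def from_coefficients(cls, design_info: DesignInfo,
                          coefficients: dict[str, float]) -> "FittedModel":
        names = design_info.term_names
        unknown = set(coefficients) - set(names)
        if unknown:
            raise ValueError(f"coefficients for unknown terms: {sorted(unknown)}")
        params = np.array([coefficients.get(nm, 0.0) for nm in names], dtype=float)
        return cls(design_info=design_info, params=params, converged=True)


def fit_logistic(X: np.ndarray, y: np.ndarray, design_info: DesignInfo,
                 ridge: float = 0.0, response: str = "") -> FittedModel:
    beta, cov, converged, _ = fit_logistic_arrays(
        X, y, names=design_info.term_names, ridge=ridge)
    return FittedModel(design_info=design_info, params=beta, cov_params=cov,
                       converged=converged, nobs=len(y), response=response)
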