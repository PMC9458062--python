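"""Scikit-learn style estimator for sums of decaying exponentials.

The model is

    y(t) = Σᵢ cᵢ · exp(−λᵢ · t),    cᵢ ≥ 0, λᵢ > 0,

the first-order-kinetics washout form used for region time–activity
curves. Fitting minimises the (optionally weighted) sum of squared
residuals by curve peeling (log-linear fit of the terminal tail,
subtract, repeat) to initialise, followed by bounded nonlinear least
squares with a small deterministic multi-start.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["MultiExponentialDecay", "FitConvergenceError"]


class FitConvergenceError(RuntimeError):
    """Raised when no multi-start attempt converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _peel(t: np.ndarray, y: np.ndarray, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """Curve-peeling initial estimate: terminal log-linear segment first.

    Returns (coefficients, rates), slowest phase estimated first but
    returned unsorted. Falls back to crude spread-based guesses when a
    segment has too few positive residual points.
    """
    resid = y.astype(float).copy()
    coeffs = np.empty(n_terms)
    rates = np.empty(n_terms)
    n = len(t)
    t_span = max(t[-1] - t[0], 1e-12)
    # points per peeled segment, terminal segment first
    seg = max(2, n // n_terms)
    for i in range(n_terms):
        lo = max(0, n - seg * (i + 1))
        hi = n - seg * i if i > 0 else n
        tt, rr = t[lo:hi], resid[lo:hi]
        mask = rr > 0
        if mask.sum() >= 2 and (tt[mask][-1] - tt[mask][0]) > 0:
            slope, intercept = np.polyfit(tt[mask], np.log(rr[mask]), 1)
            lam = max(-slope, 1e-6 / t_span)
            c = math.exp(intercept)
        else:  # degenerate segment: geometric spread of rates over the span
            lam = (10.0 ** (i + 1)) / t_span
            c = max(resid.max(), y.max() * 0.1, 1e-6)
        rates[i] = lam
        coeffs[i] = c
        resid -= c * np.exp(-lam * t)
    return coeffs, rates


def _pack(coeffs: np.ndarray, rates: np.ndarray) -> np.ndarray:
    # coefficients stay linear (bounded at 0); rates are optimised in log
    return np.concatenate([coeffs, np.log(rates)])


def _unpack(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = len(params) // 2
    return params[:k], np.exp(params[k:])


class MultiExponentialDecay(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of ``Σ cᵢ·exp(−λᵢ t)``.

    Parameters
    ----------
    n_terms : int, default=2
        Number of exponential phases (1–3).
    weights : {"none", "inverse_variance"}, default="none"
        Residual weighting. ``"inverse_variance"`` requires ``sample_sd``
        passed to :meth:`fit`.
    n_starts : int, default=5
        Deterministic multi-start count; starts beyond the first jitter
        the peeled initial guess.
    constrain_sum : float or None, default=None
        If set, constrain Σ cᵢ (the t=0 value) to this number via an
        equality penalty much stiffer than the data residuals.
    random_state : int, default=0
        Seed for the start jitter.

    Attributes
    ----------
    coefficients_ : ndarray of shape (n_terms,)
        Amplitudes cᵢ ≥ 0, sorted by rate descending (fast phase first).
    rates_ : ndarray of shape (n_terms,)
        Decay rates λᵢ > 0, sorted descending.
    rss_ : float
        Residual sum of squares at the optimum (unweighted).
    aicc_ : float
        Small-sample corrected Akaike criterion (Gaussian likelihood).
    param_se_ : ndarray of shape (2*n_terms,) or None
        Asymptotic standard errors (coefficients then rates), from the
        Jacobian at the optimum; None when the normal matrix is singular.
    n_iter_ : int
        Optimizer function evaluations of the winning start.
    """

    def __init__(
        self,
        n_terms: int = 2,
        weights: str = "none",
        n_starts: int = 5,
        constrain_sum: float | None = None,
        random_state: int = 0,
    ):
        self.n_terms = n_terms
        self.weights = weights
        self.n_starts = n_starts
        self.constrain_sum = constrain_sum
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, sample_sd=None):
        """Fit to times ``X`` (shape (n,) or (n,1), hours) and values ``y``."""
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if not (1 <= self.n_terms <= 3):
            raise ValueError(f"n_terms must be 1–3, got {self.n_terms}")
        if len(t) < 2 * self.n_terms:
            raise ValueError(
                f"need at least {2 * self.n_terms} samples for a "
                f"{self.n_terms}-term fit, got {len(t)}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(t) <= 0):
            order = np.argsort(t)
            t, y = t[order], y[order]
            if sample_sd is not None:
                sample_sd = np.asarray(sample_sd, float).reshape(-1)[order]
        if self.weights == "inverse_variance":
            if sample_sd is None:
                raise ValueError("inverse_variance weighting requires sample_sd")
            sd = np.asarray(sample_sd, dtype=float).reshape(-1)
            if np.any(sd <= 0):
                raise ValueError("sample_sd must be positive for weighting")
            w = 1.0 / sd
        elif self.weights == "none":
            w = np.ones_like(y)
        else:
            raise ValueError(f"unknown weighting {self.weights!r}")

        scale = max(float(np.max(np.abs(y))), 1e-30)
        penalty = 1e6 * scale if self.constrain_sum is not None else None

        def residuals(params: np.ndarray) -> np.ndarray:
            c, lam = _unpack(params)
            r = (c[None, :] * np.exp(-np.outer(t, lam))).sum(axis=1) - y
            r = r * w
            if penalty is not None:
                r = np.append(r, penalty * (c.sum() - self.constrain_sum))
            return r

        c0, lam0 = _peel(t, y, self.n_terms)
        rng = np.random.default_rng(self.random_state)
        t_span = max(t[-1] - t[0], 1e-12)
        lo = np.concatenate(
            [np.zeros(self.n_terms), np.full(self.n_terms, math.log(1e-8 / t_span))]
        )
        hi = np.concatenate(
            [np.full(self.n_terms, np.inf), np.full(self.n_terms, math.log(1e8 / t_span))]
        )

        best = None
        attempts = []
        for start in range(max(1, self.n_starts)):
            if start == 0:
                c_i, lam_i = c0, lam0
            else:  # jitter the peeled guess multiplicatively
                c_i = c0 * rng.lognormal(0.0, 0.5, self.n_terms)
                lam_i = lam0 * rng.lognormal(0.0, 0.7, self.n_terms)
            x0 = np.clip(_pack(np.maximum(c_i, 0.0), np.maximum(lam_i, 1e-10)), lo, hi)
            try:
                sol = least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except Exception as exc:  # pragma: no cover - scipy internal failure
                attempts.append({"start": start, "error": str(exc)})
                continue
            attempts.append({"start": start, "cost": float(sol.cost),
                             "status": int(sol.status)})
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitConvergenceError(
                "multi-exponential fit failed to converge", {"attempts": attempts}
            )

        c, lam = _unpack(best.x)
        order = np.argsort(lam)[::-1]  # fast phase first
        self.coefficients_ = c[order]
        self.rates_ = lam[order]
        model_y = (self.coefficients_[None, :]
                   * np.exp(-np.outer(t, self.rates_))).sum(axis=1)
        self.rss_ = float(np.sum((model_y - y) ** 2))
        self.aicc_ = self._aicc(self.rss_, len(t), 2 * self.n_terms)
        self.param_se_ = self._asymptotic_se(best, order)
        self.n_iter_ = int(best.nfev)
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _aicc(rss: float, n: int, p: int) -> float:
        if n <= p + 1:
            return math.inf
        return n * math.log(max(rss, 1e-300) / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)

    def _asymptotic_se(self, sol, order: np.ndarray):
        n, p = sol.fun.size, sol.x.size
        if n <= p:
            return None
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (2 * sol.cost / (n - p))
        except np.linalg.LinAlgError:
            return None
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        k = p // 2
        # rate params were log-scale: delta method back to linear rates
        se_c = se[:k][order]
        se_lam = (se[k:] * np.exp(sol.x[k:]))[order]
        return np.concatenate([se_c, se_lam])

    # ------------------------------------------------------------------
    def predict(self, X):
        """Evaluate the fitted model at times ``X`` (hours)."""
        check_is_fitted(self, "coefficients_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return (self.coefficients_[None, :]
                * np.exp(-np.outer(t, self.rates_))).sum(axis=1)
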