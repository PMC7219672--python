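"""ARFIMA-based fractal analysis of accelerometer windows.

The offline, rigorous route to the fractal parameters: a non-stationary
signal a(n) is first-differenced to a stationary series s(n), an
ARFIMA(r, d, q) model is fitted with the fractional difference d in
[−0.5, 0.5], and the fractal parameters of the original non-stationary
signal follow from the conversion chain

    d̃ = d + 1,   β = 2 d̃,   H = (β − 1) / 2 = d̃ − 0.5,   fd = 2 − H.

Estimation is a two-stage profile-likelihood procedure: for each candidate
d the demeaned series is fractionally differenced by the truncated
binomial filter (1 − L)^d and an ARMA(r, q) model is fitted by exact
maximum likelihood (statsmodels state-space ARIMA); d is chosen by a
bounded line search maximising the profile log-likelihood.  Model orders
are selected over an (r, q) grid by minimum AIC with parameter count
k = r + q + 2 (d and the innovation variance are counted; AR/MA
coefficients add r + q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import lfilter


@dataclass
class ARFIMAModel:
    """A fitted ARFIMA(r, d, q) model for a stationary series.

    ``d`` is the fractional difference of the stationary series, in
    [−0.5, 0.5].  ``aic = 2k − 2·loglik`` with ``k = r + q + 2``.
    """

    r: int
    q: int
    d: float
    ar_coeffs: np.ndarray
    ma_coeffs: np.ndarray
    const: float
    mean: float
    innovation_variance: float
    loglik: float
    aic: float
    converged: bool = True

    @property
    def n_params(self) -> int:
        return self.r + self.q + 2

    def fractal_params(self) -> "FractalParams":
        """Fractal parameters of the original non-stationary signal."""
        return nonstationary_fractal_params(self.d)


@dataclass(frozen=True)
class FractalParams:
    """Fractal parameters of a non-stationary signal.

    The four fields satisfy d̃ = d + 1, β = 2d̃, H = (β − 1)/2, fd = 2 − H
    to machine precision, so fd = 1.5 − d is an affine function of d.
    """

    d_tilde: float
    beta: float
    hurst: float
    fd: float

    @classmethod
    def from_d(cls, d: float) -> "FractalParams":
        d_tilde = d + 1.0
        beta = 2.0 * d_tilde
        hurst = (beta - 1.0) / 2.0
        return cls(d_tilde=d_tilde, beta=beta, hurst=hurst, fd=2.0 - hurst)

    @classmethod
    def from_d_tilde(cls, d_tilde: float) -> "FractalParams":
        return cls.from_d(d_tilde - 1.0)


def nonstationary_fractal_params(d: float) -> FractalParams:
    """Convert a stationary-series fractional difference d to (d̃, β, H, fd)."""
    if not np.isfinite(d):
        raise ValueError(f"d must be finite, got {d}")
    return FractalParams.from_d(float(d))


def first_difference(x: np.ndarray) -> np.ndarray:
    """Δx with (Δx)[k] = x[k+1] − x[k]; output one sample shorter."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to difference")
    return np.diff(x)


def fracdiff_weights(d: float, n: int) -> np.ndarray:
    """First ``n`` binomial-expansion weights of (1 − L)^d.

    w0 = 1 and w_l = w_{l−1} · (l − 1 − d) / l, the recursive form of the
    Gamma-ratio coefficients Γ(d+1) / (Γ(l+1) Γ(d+1−l)) · (−1)^l.
    """
    w = np.empty(n)
    w[0] = 1.0
    for l in range(1, n):
        w[l] = w[l - 1] * (l - 1 - d) / l
    return w


def fractional_difference(
    x: np.ndarray, d: float, truncation: int | None = None
) -> np.ndarray:
    """Apply the fractional difference operator (1 − L)^d to ``x``.

    The binomial series is truncated at ``truncation`` lags (default: the
    series length, exact within machine precision for a finite sample).
    Output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if truncation is None:
        truncation = n
    if truncation < 1:
        raise ValueError("truncation must be >= 1")
    w = fracdiff_weights(float(d), min(truncation, n))
    return lfilter(w, [1.0], x)


def _arma_loglik(z: np.ndarray, r: int, q: int):
    """Exact-ML ARMA(r, q) fit on a demeaned series; returns statsmodels results."""
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(z, order=(r, 0, q), trend="n")
        return model.fit(method="statespace", low_memory=True)


def fit_arfima(
    s: np.ndarray,
    r: int,
    q: int,
    d_bounds: tuple[float, float] = (-0.49, 0.49),
    xatol: float = 5e-3,
) -> ARFIMAModel:
    """Fit an ARFIMA(r, d, q) model to a stationary series.

    Two-stage profile likelihood: line-search d on ``d_bounds``; at each
    candidate, fractionally difference the demeaned series and fit an
    ARMA(r, q) by exact maximum likelihood.  Raises on series shorter
    than 64 samples or orders outside [0, 4].
    """
    s = np.asarray(s, dtype=float)
    if len(s) < 64:
        raise ValueError(f"series too short for ARFIMA fitting: {len(s)} < 64")
    if not (0 <= r <= 4 and 0 <= q <= 4):
        raise ValueError(f"orders must be in [0, 4], got r={r}, q={q}")
    mu = float(np.mean(s))
    z0 = s - mu

    def neg_profile_ll(d: float) -> float:
        z = fractional_difference(z0, d)
        try:
            res = _arma_loglik(z, r, q)
        except Exception:
            return 1e12
        llf = float(res.llf)
        return -llf if np.isfinite(llf) else 1e12

    opt = minimize_scalar(
        neg_profile_ll,
        bounds=d_bounds,
        method="bounded",
        options={"xatol": xatol, "maxiter": 30},
    )
    d_hat = float(opt.x)
    z = fractional_difference(z0, d_hat)
    try:
        res = _arma_loglik(z, r, q)
    except Exception as exc:  # pragma: no cover - guarded by profile search
        raise RuntimeError(f"ARMA({r},{q}) fit failed at d={d_hat:.3f}") from exc
    llf = float(res.llf)
    if not np.isfinite(llf):
        raise RuntimeError(f"non-finite likelihood for ARFIMA({r},d,{q})")
    ar = np.asarray(res.arparams, dtype=float) if r > 0 else np.empty(0)
    ma = np.asarray(res.maparams, dtype=float) if q > 0 else np.empty(0)
    _check_roots(ar, ma)
    k = r + q + 2
    return ARFIMAModel(
        r=r,
        q=q,
        d=d_hat,
        ar_coeffs=ar,
        ma_coeffs=ma,
        const=mu,
        mean=mu,
        innovation_variance=float(res.params[-1]),
        loglik=llf,
        aic=2.0 * k - 2.0 * llf,
        converged=bool(getattr(res, "mle_retvals", {}).get("converged", True)),
    )


def _check_roots(ar: np.ndarray, ma: np.ndarray) -> None:
    """Warn when the fitted AR/MA polynomials sit on the unit circle."""
    for name, coeffs, sign in (("AR", ar, -1.0), ("MA", ma, 1.0)):
        if coeffs.size == 0:
            continue
        poly = np.concatenate([[1.0], sign * coeffs])
        roots = np.roots(poly[::-1])
        if roots.size and np.min(np.abs(roots)) < 1.0 + 1e-8:
            warnings.warn(
                f"fitted {name} polynomial has a root on or inside the unit "
                "circle; model is at the boundary of its admissible region",
                stacklevel=3,
            )


def select_model_grid(
    s: np.ndarray,
    r_max: int = 4,
    q_max: int = 4,
    d_bounds: tuple[float, float] = (-0.49, 0.49),
    xatol: float = 5e-3,
) -> ARFIMAModel:
    """Fit the (r, q) grid of ARFIMA models and return the minimum-AIC one.

    Failed fits are dropped; ties are broken by smaller r + q, then
    smaller r.  Raises when every model on the grid fails.
    """
    s = np.asarray(s, dtype=float)
    candidates: list[ARFIMAModel] = []
    for r in range(r_max + 1):
        for q in range(q_max + 1):
            try:
                candidates.append(fit_arfima(s, r, q, d_bounds=d_bounds, xatol=xatol))
            except ValueError:
                raise  # precondition violation, not a convergence failure
            except RuntimeError:
                continue
    if not candidates:
        raise RuntimeError("every ARFIMA model on the grid failed to fit")
    return min(candidates, key=lambda m: (m.aic, m.r + m.q, m.r))
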