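"""Wavelet-variance fractal-dimension features.

For a window a with variance σ²_a decomposed into detail coefficients
D1..DL, the power-law spectrum model S(ω) = σ²_a / ω^β gives, per level i,

    var(Di) = σ²_a / (2^i)^β
    β_i     = log2(σ²_a / var(Di)) / i
    H_i     = (β_i − 1) / 2
    fd_i    = 2 − H_i

The fractal dimension fd is an irregularity measure of the signal graph:
quiet windows dominated by a single smooth transient (falls) concentrate
their energy at low frequency, giving a large σ²_a / var(Di) ratio and a
small fd, while broadband, episodic activity (ADL) keeps var(Di) close to
σ²_a and fd high.  Each level yields an independent feature fd1..fd4; no
cross-level regression is performed.

Values of fd outside [1, 2] are reported as-is: the quantity is used as an
irregularity feature, not as a geometric dimension.  Levels with (near)
zero detail variance are flagged undefined (NaN) and replaced by a
sentinel only at feature-assembly time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fracfall.dwt import WaveletDecomposition

#: Detail variances below this are treated as degenerate (undefined level).
VAR_FLOOR = 1e-24


@dataclass
class FractalFeatures:
    """Per-level spectral exponent, Hurst exponent and fractal dimension.

    Undefined levels (zero detail variance) hold NaN in all three arrays.
    """

    beta: np.ndarray
    hurst: np.ndarray
    fd: np.ndarray
    var_details: np.ndarray
    var_signal: float
    levels: int

    def defined(self) -> np.ndarray:
        """Boolean mask of levels with a defined fractal dimension."""
        return np.isfinite(self.fd)


def spectral_exponent(var_signal: float, var_detail: float, level: int) -> float:
    """Power-spectrum exponent β = log2(σ²_a / var(Di)) / i.

    Both variances must be strictly positive and the level ≥ 1.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    if not (var_signal > 0 and var_detail > 0):
        raise ValueError(
            f"variances must be strictly positive, got "
            f"var_signal={var_signal}, var_detail={var_detail}"
        )
    return float(np.log2(var_signal / var_detail) / level)


def hurst_from_beta(beta: float) -> float:
    """Hurst exponent H = (β − 1) / 2."""
    return (beta - 1.0) / 2.0


def fd_from_hurst(h: float) -> float:
    """Fractal dimension fd = 2 − H."""
    return 2.0 - h


def wavelet_fractal_dimensions(
    dec: WaveletDecomposition, var_signal: float
) -> FractalFeatures:
    """Per-level β, H and fd from the detail variances of a decomposition.

    Detail variances subtract the level mean μ_Di and use the unbiased
    divisor (len − 1).  A level whose detail variance falls below
    ``VAR_FLOOR`` is returned as undefined (NaN) rather than ±inf.
    """
    if dec.levels < 1:
        raise ValueError("decomposition must have at least one level")
    if not var_signal > 0:
        raise ValueError(f"var_signal must be strictly positive, got {var_signal}")
    levels = dec.levels
    beta = np.full(levels, np.nan)
    hurst = np.full(levels, np.nan)
    fd = np.full(levels, np.nan)
    var_details = np.empty(levels)
    for i, detail in enumerate(dec.details, start=1):
        vd = float(np.var(detail, ddof=1))
        var_details[i - 1] = vd
        if vd < VAR_FLOOR:
            continue
        b = spectral_exponent(var_signal, vd, i)
        h = hurst_from_beta(b)
        beta[i - 1] = b
        hurst[i - 1] = h
        fd[i - 1] = fd_from_hurst(h)
    return FractalFeatures(
        beta=beta,
        hurst=hurst,
        fd=fd,
        var_details=var_details,
        var_signal=float(var_signal),
        levels=levels,
    )
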