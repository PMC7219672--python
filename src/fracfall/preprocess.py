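"""Windowed sum-vector preprocessing of triaxial accelerometer streams.

A triaxial stream (ax, ay, az, in units of g) is collapsed into its
per-sample Euclidean magnitude — the *sum vector* a' = sqrt(ax² + ay² + az²)
— which folds the orientation of the sensor into a single channel.  The
stream is then cut into fixed-length windows (default 128 samples with 50 %
overlap), and each window is zero-meaned, a = a' − μ_a'.  The window mean
μ_a' and unbiased variance σ²_a' (divisor N−1) are kept as features; the
variance of the zero-mean signal a feeds the fractal-dimension estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Full-scale range of the emulated sensor, in g.
SENSOR_RANGE_G = 8.0

#: Default sampling rate of the emulated sensor, in Hz.
DEFAULT_FS = 32.0

#: Default analysis window length, in samples.
DEFAULT_WINDOW = 128


@dataclass
class TriaxialSegment:
    """A segment of triaxial accelerometer data in units of g.

    Attributes
    ----------
    ax, ay, az : ndarray
        Equal-length acceleration channels along the x, y and z axes.
    fs : float
        Sampling rate in Hz (default 32).
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError(
                "axis channels must have equal lengths, got "
                f"{len(self.ax)}/{len(self.ay)}/{len(self.az)}"
            )
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in channel {name}")
        peak = max(
            (float(np.max(np.abs(a))) if a.size else 0.0)
            for a in (self.ax, self.ay, self.az)
        )
        if peak > SENSOR_RANGE_G:
            warnings.warn(
                f"|acceleration| reaches {peak:.2f} g, beyond the "
                f"±{SENSOR_RANGE_G:g} g range of the emulated sensor",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.ax)


@dataclass
class WindowedSignal:
    """One analysis window of the sum-vector signal with its statistics.

    Attributes
    ----------
    a_prime : ndarray
        The raw sum-vector window (g).
    mu_a_prime, var_a_prime : float
        Mean and unbiased variance (divisor N−1) of ``a_prime``.
    a : ndarray
        Zero-mean window, ``a_prime − mu_a_prime``.
    var_a : float
        Unbiased variance of ``a``; equals ``var_a_prime`` up to rounding.
    N : int
        Window length.
    start_index : int
        Offset of the window in the source stream.
    """

    a_prime: np.ndarray
    mu_a_prime: float
    var_a_prime: float
    a: np.ndarray
    var_a: float
    N: int
    start_index: int = 0


def sum_vector(seg: TriaxialSegment) -> np.ndarray:
    """Per-sample Euclidean magnitude sqrt(ax² + ay² + az²) of a segment."""
    return np.sqrt(seg.ax**2 + seg.ay**2 + seg.az**2)


def segment_windows(
    stream: np.ndarray,
    N: int = DEFAULT_WINDOW,
    overlap_fraction: float = 0.5,
) -> list[tuple[int, np.ndarray]]:
    """Cut a 1-D stream into overlapping fixed-length windows.

    Windows start at multiples of ``hop = floor(N * (1 − overlap_fraction))``;
    a trailing stretch that does not fill a whole window is discarded.

    Parameters
    ----------
    stream : array_like
        The input signal.
    N : int
        Window length; must be even and ≥ 16.
    overlap_fraction : float
        Fraction of overlap between consecutive windows, in [0, 1).

    Returns
    -------
    list of (start_index, window) pairs.  Empty (with a warning) when the
    stream is shorter than one window.
    """
    stream = np.asarray(stream, dtype=float)
    if N % 2 != 0 or N < 16:
        raise ValueError(f"window length must be even and >= 16, got {N}")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if len(stream) < N:
        warnings.warn(
            f"stream of length {len(stream)} is shorter than one "
            f"{N}-sample window; no windows produced",
            stacklevel=2,
        )
        return []
    hop = int(np.floor(N * (1.0 - overlap_fraction)))
    hop = max(hop, 1)
    count = (len(stream) - N) // hop + 1
    return [(k * hop, stream[k * hop : k * hop + N]) for k in range(count)]


def make_windowed_signal(window: np.ndarray, start_index: int = 0) -> WindowedSignal:
    """Zero-mean a sum-vector window and record its summary statistics.

    Variances use the unbiased divisor N−1.  Requires at least two samples.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1:
        raise ValueError("window must be one-dimensional")
    if len(window) < 2:
        raise ValueError("variance undefined for windows of fewer than 2 samples")
    if not np.all(np.isfinite(window)):
        raise ValueError("non-finite values in window")
    mu = float(np.mean(window))
    var_prime = float(np.var(window, ddof=1))
    a = window - mu
    var_a = float(np.var(a, ddof=1))
    return WindowedSignal(
        a_prime=window,
        mu_a_prime=mu,
        var_a_prime=var_prime,
        a=a,
        var_a=var_a,
        N=len(window),
        start_index=start_index,
    )
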