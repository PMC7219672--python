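"""Multi-level Daubechies-4 DWT with periodic boundary handling.

Two equivalent single-level implementations are provided:

* :func:`dwt_level_reference` — the textbook form: circular convolution of
  the signal with the analysis filters followed by dyadic downsampling.
  This is the ground-truth oracle.
* :func:`dwt_level_fused` — the optimised form used on embedded hardware:
  only the retained outputs are computed, by striding two samples at a
  time across a periodically extended signal with the filter taps stored
  in reverse.  It must agree with the reference to machine precision.

Conventions (frozen):

* "Daubechies-4" is the orthonormal 8-tap filter with 4 vanishing moments.
* Boundary mode is circular periodisation, so level ``i`` outputs have
  exactly ``N / 2**i`` coefficients.
* Downsampling keeps the odd-indexed circular-convolution outputs,
  ``A[k] = y[2k + 1]``.
* The highpass filter is the quadrature mirror ``g[k] = (−1)**k · h[7−k]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Orthonormal Daubechies decomposition lowpass filter, 8 taps
#: (4 vanishing moments).  sum(h) = sqrt(2), sum(h**2) = 1.
DB4_LOWPASS = np.array(
    [
        -0.010597401785069032,
        0.032883011666885197,
        0.030841381835560764,
        -0.18703481171909309,
        -0.027983769416859854,
        0.63088076792985892,
        0.71484657055291567,
        0.23037781330889651,
    ]
)


@dataclass(frozen=True)
class WaveletFilterPair:
    """An orthonormal analysis filter pair (lowpass h, highpass g)."""

    lowpass: np.ndarray
    highpass: np.ndarray
    name: str = "db4-8tap"

    @property
    def taps(self) -> int:
        return len(self.lowpass)


@dataclass
class WaveletDecomposition:
    """Per-level approximation and detail coefficients of a multi-level DWT.

    ``approximations[i]`` and ``details[i]`` hold level ``i+1`` coefficients;
    each level halves the length, so a 128-sample window decomposed to 4
    levels ends with 8 coefficients in each of A4 and D4.
    """

    approximations: list[np.ndarray]
    details: list[np.ndarray]
    levels: int
    input_length: int


def db4_filters() -> WaveletFilterPair:
    """The standard orthonormal Daubechies 8-tap decomposition pair."""
    h = DB4_LOWPASS.copy()
    k = np.arange(len(h))
    g = (-1.0) ** k * h[::-1]
    return WaveletFilterPair(lowpass=h, highpass=g)


def periodic_extend(x: np.ndarray, taps: int) -> np.ndarray:
    """Circularly extend ``x`` on the left by ``taps − 2`` samples.

    The extension is exactly the wrap-around copy needed so that every
    length-``taps`` filter placement whose output is retained by the fused
    transform reads only valid samples.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n % 2 != 0:
        raise ValueError(f"signal length must be even, got {n}")
    if n < taps:
        raise ValueError(f"signal length {n} shorter than filter ({taps} taps)")
    return np.concatenate([x[-(taps - 2):], x])


def dwt_level_reference(
    x: np.ndarray, filters: WaveletFilterPair | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One DWT level by circular convolution followed by downsampling.

    ``y[n] = Σ_m f[m] · x[(n − m) mod N]`` for each filter, retaining the
    odd-phase samples ``y[2k + 1]``.  Serves as the oracle for the fused
    implementation.
    """
    if filters is None:
        filters = db4_filters()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n % 2 != 0:
        raise ValueError(f"signal length must be even, got {n}")
    if n < filters.taps:
        raise ValueError(f"signal length {n} shorter than filter ({filters.taps} taps)")

    def circular(f: np.ndarray) -> np.ndarray:
        y = np.zeros(n)
        for m, fm in enumerate(f):
            y += fm * np.roll(x, m)
        return y[1::2]

    return circular(filters.lowpass), circular(filters.highpass)


def dwt_level_fused(
    x: np.ndarray, filters: WaveletFilterPair | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One DWT level computing only the retained outputs.

    Strides two samples at a time over the periodically extended signal
    with the filter taps reversed, so no discarded coefficient is ever
    computed.  Equals :func:`dwt_level_reference` to machine precision.
    """
    if filters is None:
        filters = db4_filters()
    x = np.asarray(x, dtype=float)
    taps = filters.taps
    ext = periodic_extend(x, taps)
    frames = np.lib.stride_tricks.sliding_window_view(ext, taps)[::2]
    return frames @ filters.lowpass[::-1], frames @ filters.highpass[::-1]


def multilevel_dwt(
    a: np.ndarray,
    levels: int = 4,
    filters: WaveletFilterPair | None = None,
    level_fn=dwt_level_fused,
) -> WaveletDecomposition:
    """Cascade the single-level DWT: level i+1 is computed from Ai.

    The input length must be divisible by ``2**levels``.  For the default
    128-sample window and 4 levels the final approximation and detail
    vectors each hold 8 coefficients.
    """
    a = np.asarray(a, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(a) % (2**levels) != 0:
        raise ValueError(
            f"signal length {len(a)} not divisible by 2**levels = {2**levels}"
        )
    approximations: list[np.ndarray] = []
    details: list[np.ndarray] = []
    current = a
    for _ in range(levels):
        approx, detail = level_fn(current, filters)
        approximations.append(approx)
        details.append(detail)
        current = approx
    return WaveletDecomposition(
        approximations=approximations,
        details=details,
        levels=levels,
        input_length=len(a),
    )
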