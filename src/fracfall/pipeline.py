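"""Glue: run the full feature-extraction chain on segments or streams."""

from __future__ import annotations

import numpy as np

from fracfall.classify import FeatureVector, assemble_features
from fracfall.dwt import multilevel_dwt
from fracfall.fractal import wavelet_fractal_dimensions
from fracfall.preprocess import (
    TriaxialSegment,
    make_windowed_signal,
    segment_windows,
    sum_vector,
)


def features_for_window(
    window: np.ndarray,
    start_index: int = 0,
    label: str | None = None,
    levels: int = 4,
    use_sd: bool = False,
) -> FeatureVector:
    """Feature vector of one sum-vector window."""
    win = make_windowed_signal(window, start_index=start_index)
    dec = multilevel_dwt(win.a, levels=levels)
    if win.var_a > 0:
        frac = wavelet_fractal_dimensions(dec, win.var_a)
        return assemble_features(win, dec, frac, label=label, use_sd=use_sd)
    # constant window: every fractal level is undefined
    from fracfall.fractal import FractalFeatures

    frac = FractalFeatures(
        beta=np.full(levels, np.nan),
        hurst=np.full(levels, np.nan),
        fd=np.full(levels, np.nan),
        var_details=np.zeros(levels),
        var_signal=0.0,
        levels=levels,
    )
    return assemble_features(win, dec, frac, label=label, use_sd=use_sd)


def extract_features(
    seg: TriaxialSegment,
    window: int = 128,
    overlap: float = 0.5,
    label: str | None = None,
    use_sd: bool = False,
) -> list[FeatureVector]:
    """Sum-vector, window, transform and assemble features for a segment."""
    stream = sum_vector(seg)
    out = []
    for start, win in segment_windows(stream, N=window, overlap_fraction=overlap):
        out.append(
            features_for_window(win, start_index=start, label=label, use_sd=use_sd)
        )
    return out
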