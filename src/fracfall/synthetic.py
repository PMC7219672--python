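"""Seeded synthetic-signal generators emulating the sensor front-end.

Three families of signals are produced, all fully determined by a seed:

* exact fractional Gaussian noise (fGn) with a chosen Hurst exponent via
  circulant embedding (Davies-Harte), used as the oracle process for the
  fractal estimators;
* ARFIMA(r, d, q) series with chosen coefficients, used for round-trip
  parameter-recovery tests; and
* triaxial accelerometer windows emulating a pelvis-worn sensor (32 Hz,
  ±8 g, optionally 12-bit quantised): *fall* windows are a quiet ~1 g
  gravity baseline with a brief free-fall dip followed by a short
  high-amplitude impact spike, *ADL* windows carry a few episodic,
  irregular band-limited oscillation bursts.

Fall/ADL morphology is calibrated so the two classes overlap slightly:
a linear discriminant on the default feature set separates them with
roughly 0.95-0.99 accuracy, not 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, lfilter

from fracfall.preprocess import TriaxialSegment

_TWO_PI = 2.0 * np.pi


@dataclass
class SimConfig:
    """Parameters of the synthetic accelerometer-window generators.

    Amplitudes are in g; the defaults emulate a 32 Hz, ±8 g pelvis-worn
    sensor.  Ranges are sampled uniformly per window/episode.
    """

    seed: int = 0
    n: int = 128
    fs: float = 32.0
    quantize_bits: int | None = None  # 12 emulates the sensor ADC
    baseline_g: float = 1.0
    noise_sd_g: float = 0.05
    drift_sd_g: float = 0.015  # per-step SD of the slow postural drift walk
    # fall morphology
    spike_amplitude_g: tuple[float, float] = (3.0, 7.0)
    spike_width_samples: tuple[int, int] = (3, 8)
    freefall_depth_g: tuple[float, float] = (0.5, 0.9)
    freefall_width_samples: tuple[int, int] = (8, 16)
    # ADL morphology
    episode_count: tuple[int, int] = (2, 5)
    episode_amplitude_g: tuple[float, float] = (0.3, 1.5)
    episode_frequency_hz: tuple[float, float] = (0.5, 3.0)
    episode_duration_samples: tuple[int, int] = (16, 48)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def fgn_autocovariance(h: float, lags: np.ndarray) -> np.ndarray:
    """Exact fGn autocovariance ρ(k) = ½(|k+1|^2H − 2|k|^2H + |k−1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * ((k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))


def gen_fgn(h: float, n: int, seed=0) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    The Davies-Harte construction embeds the length-n Toeplitz covariance
    in a circulant matrix diagonalised by the FFT; when an eigenvalue is
    (numerically) negative the exact Cholesky construction is used
    instead.  Unit innovation scale: var ≈ 1 at every H.
    """
    if not 0.0 < h < 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {h}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    rho = fgn_autocovariance(h, np.arange(n))
    circ = np.concatenate([rho, rho[-2:0:-1]]) if n > 1 else rho
    lam = np.fft.fft(circ).real
    if np.min(lam) < -1e-9 * np.max(lam):
        return _fgn_cholesky(rho, rng)
    lam = np.clip(lam, 0.0, None)
    m = len(circ)
    # Davies-Harte: weight independent normals by sqrt(λ/m) in frequency
    zr = rng.normal(size=m)
    zi = rng.normal(size=m)
    w = np.empty(m, dtype=complex)
    half = m // 2
    w[0] = zr[0] * np.sqrt(m)
    if m % 2 == 0:
        w[half] = zr[half] * np.sqrt(m)
        idx = np.arange(1, half)
    else:
        idx = np.arange(1, half + 1)
    w[idx] = (zr[idx] + 1j * zi[idx]) * np.sqrt(m / 2.0)
    w[m - idx] = np.conj(w[idx])
    x = np.fft.ifft(np.sqrt(lam) * w).real
    return x[:n]


def _fgn_cholesky(rho: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact fGn via Cholesky of the Toeplitz covariance (O(n³) fallback)."""
    from scipy.linalg import cholesky, toeplitz

    L = cholesky(toeplitz(rho), lower=True)
    return L @ rng.normal(size=len(rho))


def gen_arfima_series(
    r: int,
    d: float,
    q: int,
    ar=(),
    ma=(),
    n: int = 1024,
    seed=0,
    innovation_sd: float = 1.0,
) -> np.ndarray:
    """Simulate an ARFIMA(r, d, q) series with Gaussian innovations.

    The innovations are MA-filtered, fractionally integrated by the
    binomial weights of (1 − L)^(−d), then AR-recursed; a burn-in of
    max(500, n/4) samples is discarded.  The AR polynomial must be
    stationary (roots outside the unit circle) and |d| < 0.5.
    """
    ar = np.asarray(ar, dtype=float)
    ma = np.asarray(ma, dtype=float)
    if len(ar) != r or len(ma) != q:
        raise ValueError("ar/ma coefficient counts must match the orders r/q")
    if not abs(d) < 0.5:
        raise ValueError(f"|d| must be < 0.5, got {d}")
    if r > 0:
        roots = np.roots(np.concatenate([[1.0], -ar])[::-1])
        if roots.size and np.min(np.abs(roots)) <= 1.0:
            raise ValueError("AR polynomial is not stationary")
    rng = _as_rng(seed)
    burn = max(500, n // 4)
    m = n + burn
    eps = rng.normal(scale=innovation_sd, size=m)
    u = lfilter(np.concatenate([[1.0], ma]), [1.0], eps)
    # (1 − L)^{−d}: w0 = 1, w_l = w_{l−1}(l − 1 + d)/l
    w = np.empty(m)
    w[0] = 1.0
    for l in range(1, m):
        w[l] = w[l - 1] * (l - 1 + d) / l
    v = lfilter(w, [1.0], u)
    s = lfilter([1.0], np.concatenate([[1.0], -ar]), v)
    return s[burn:]


def _quantize(x: np.ndarray, bits: int, full_scale: float = 8.0) -> np.ndarray:
    """Quantise to a signed ``bits``-bit grid over ±``full_scale`` g."""
    step = 2.0 * full_scale / (2**bits)
    return np.clip(np.round(x / step) * step, -full_scale, full_scale)


def _finish(ax, ay, az, cfg: SimConfig) -> TriaxialSegment:
    if cfg.quantize_bits is not None:
        ax, ay, az = (_quantize(c, cfg.quantize_bits) for c in (ax, ay, az))
    else:
        ax, ay, az = (np.clip(c, -8.0, 8.0) for c in (ax, ay, az))
    return TriaxialSegment(ax=ax, ay=ay, az=az, fs=cfg.fs)


def _baseline(cfg: SimConfig, rng: np.random.Generator):
    """Quiet stance: gravity on z, sensor noise, and a slow postural drift.

    The drift is a small random walk on the vertical axis emulating slow
    body sway; it is what makes the windows read as unit-root processes
    in the ADF/KPSS battery, as real accelerometer windows do.
    """
    n = cfg.n
    ax = rng.normal(0.0, cfg.noise_sd_g, n)
    ay = rng.normal(0.0, cfg.noise_sd_g, n)
    az = cfg.baseline_g + rng.normal(0.0, cfg.noise_sd_g, n)
    if cfg.drift_sd_g > 0:
        az += np.cumsum(rng.normal(0.0, cfg.drift_sd_g, n))
    return ax, ay, az


def gen_fall_window(cfg: SimConfig, rng=None) -> tuple[TriaxialSegment, str]:
    """One synthetic fall window: quiet baseline, free-fall dip, impact spike.

    Gravity (1 g) sits on the z axis, emulating a static pelvis-worn
    orientation.  The impact is a half-sine pulse of 3-7 g lasting 3-8
    samples, preceded by a free-fall dip in which the magnitude drops by
    0.5-0.9 g for 8-16 samples.
    """
    rng = cfg.rng() if rng is None else _as_rng(rng)
    ax, ay, az = _baseline(cfg, rng)
    n = cfg.n
    c = int(rng.integers(24, n - 24))
    w = int(rng.integers(cfg.spike_width_samples[0], cfg.spike_width_samples[1] + 1))
    amp = rng.uniform(*cfg.spike_amplitude_g)
    dip_w = int(
        rng.integers(cfg.freefall_width_samples[0], cfg.freefall_width_samples[1] + 1)
    )
    depth = rng.uniform(*cfg.freefall_depth_g)
    s0 = max(0, c - dip_w)
    if c > s0:
        t = np.arange(c - s0)
        az[s0:c] -= depth * np.sin(np.pi * (t + 0.5) / (c - s0))
    t = np.arange(w)
    az[c : c + w] += amp * np.sin(np.pi * (t + 0.5) / w)
    return _finish(ax, ay, az, cfg), "fall"


def gen_adl_window(cfg: SimConfig, rng=None) -> tuple[TriaxialSegment, str]:
    """One synthetic ADL window: episodic irregular oscillation bursts.

    Each episode is band-limited Gaussian noise around a centre frequency
    of 0.5-3 Hz (band 0.5f to min(5f, 14) Hz, 2nd-order Butterworth),
    RMS-scaled to a 0.3-1.5 g amplitude, Hann-windowed and applied along
    a random direction with the vertical axis weighted double.
    """
    rng = cfg.rng() if rng is None else _as_rng(rng)
    ax, ay, az = _baseline(cfg, rng)
    n = cfg.n
    nyq = cfg.fs / 2.0
    n_ep = int(rng.integers(cfg.episode_count[0], cfg.episode_count[1] + 1))
    for _ in range(n_ep):
        dur = int(
            rng.integers(
                cfg.episode_duration_samples[0], cfg.episode_duration_samples[1] + 1
            )
        )
        dur = min(dur, n)
        start = int(rng.integers(0, n - dur + 1))
        f = rng.uniform(*cfg.episode_frequency_hz)
        amp = rng.uniform(*cfg.episode_amplitude_g)
        lo, hi = 0.5 * f, min(5.0 * f, 0.875 * nyq)
        b, a = butter(2, [lo / nyq, hi / nyq], btype="band")
        ep = lfilter(b, a, rng.normal(size=dur + 32))[32:]
        ep *= amp / max(1e-12, np.sqrt(2.0) * ep.std())
        ep *= np.hanning(dur)
        dirv = rng.normal(size=3)
        dirv[2] *= 2.0
        dirv /= np.linalg.norm(dirv)
        for sig, dcomp in zip((ax, ay, az), dirv):
            sig[start : start + dur] += dcomp * ep
    return _finish(ax, ay, az, cfg), "adl"


def gen_labelled_dataset(
    n_fall: int, n_adl: int, cfg: SimConfig | None = None
) -> tuple[list[TriaxialSegment], list[str]]:
    """A shuffled, seeded list of fall and ADL windows with labels."""
    if cfg is None:
        cfg = SimConfig()
    if n_fall < 0 or n_adl < 0:
        raise ValueError("window counts must be non-negative")
    rng = cfg.rng()
    items = [gen_fall_window(cfg, rng) for _ in range(n_fall)]
    items += [gen_adl_window(cfg, rng) for _ in range(n_adl)]
    order = rng.permutation(len(items))
    segs = [items[i][0] for i in order]
    labels = [items[i][1] for i in order]
    return segs, labels
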