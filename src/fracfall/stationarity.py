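"""ADF/KPSS stationarity battery for accelerometer windows.

The two tests have opposite null hypotheses, which yields a
double-validation verdict per window:

* ADF (augmented Dickey-Fuller, constant term, no trend) tests the
  unit-root null; rejection (p < α) means the series looks stationary.
* KPSS (level form) tests the stationarity null with a Newey-West
  long-run variance; rejection means the series looks non-stationary.

A window is classed "non-stationary" only when ADF fails to reject AND
KPSS rejects; "stationary" when ADF rejects AND KPSS fails to reject;
anything else is "inconclusive".

Lag selection follows the standard rules: the Schwert bound
floor(12 · (n/100)^(1/4)) for ADF, optionally refined by the sequential
procedure of Ng-Perron (start at the bound, keep the lag if the last
lag's |t|-statistic exceeds 1.6, else decrement), or chosen by AIC; and
floor(sqrt(n)) for the KPSS Newey-West bandwidth.

The regressions themselves are delegated to statsmodels; this module owns
the lag rules, the sequential procedure, the dual-test decision logic and
the per-window battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller, kpss

from fracfall.preprocess import WindowedSignal

#: |t|-statistic threshold of the sequential lag-selection procedure.
NG_PERRON_T = 1.6


@dataclass
class StationarityResult:
    """Outcome of a single ADF or KPSS test."""

    test_name: str  # "ADF" or "KPSS"
    lag_used: int
    statistic: float
    p_value: float
    reject_null: bool
    alpha: float = 0.05
    lag_rule: str = "schwert-ng"


def schwert_max_lag(n: int) -> int:
    """Schwert's maximum-lag bound floor(12 · (n/100)^(1/4)) for the ADF test."""
    if n < 8:
        raise ValueError(f"need n >= 8, got {n}")
    return int(np.floor(12.0 * (n / 100.0) ** 0.25))


def kpss_max_lag(n: int) -> int:
    """Newey-West bandwidth bound floor(sqrt(n)) for the KPSS test."""
    if n < 8:
        raise ValueError(f"need n >= 8, got {n}")
    return int(np.floor(np.sqrt(n)))


def _check_not_constant(x: np.ndarray) -> None:
    if np.ptp(x) == 0.0:
        raise ValueError("constant series: stationarity tests are degenerate")


def _sequential_lag(x: np.ndarray, p_max: int) -> int:
    """Ng-Perron sequential lag choice for the ADF regression.

    Starting at ``p_max``, the lag is kept when the last included lag's
    |t|-statistic exceeds 1.6, otherwise decremented; lag 0 is the floor.
    """
    for p in range(p_max, 0, -1):
        try:
            _, _, _, _, _, resstore = adfuller(
                x, maxlag=p, regression="c", autolag=None, store=True
            )
        except Exception:
            continue
        # regression columns: level lag, Δ-lags 1..p, constant
        t_last = float(resstore.resols.tvalues[p])
        if abs(t_last) > NG_PERRON_T:
            return p
    return 0


def adf_test(
    x: np.ndarray,
    lag_rule: str = "schwert-ng",
    alpha: float = 0.05,
    max_lag: int | None = None,
) -> StationarityResult:
    """Constant-only ADF unit-root test with the configured lag rule.

    ``lag_rule`` is one of ``"schwert-ng"`` (sequential Ng-Perron starting
    from the Schwert bound), ``"aic"`` (AIC over lags up to the Schwert
    bound) or ``"fixed"`` (``max_lag`` used as given).  Rejection of the
    unit-root null (p < α) reports the series as stationary.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 32:
        raise ValueError(f"need at least 32 samples, got {len(x)}")
    _check_not_constant(x)
    p_max = max_lag if max_lag is not None else schwert_max_lag(len(x))
    p_max = min(p_max, (len(x) - 8) // 2)
    if lag_rule == "schwert-ng":
        p = _sequential_lag(x, p_max)
        stat, pval, usedlag, *_ = adfuller(x, maxlag=p, regression="c", autolag=None)
    elif lag_rule == "aic":
        stat, pval, usedlag, *_ = adfuller(x, maxlag=p_max, regression="c", autolag="AIC")
        p = int(usedlag)
    elif lag_rule == "fixed":
        if max_lag is None:
            raise ValueError("lag_rule='fixed' requires max_lag")
        p = p_max
        stat, pval, usedlag, *_ = adfuller(x, maxlag=p, regression="c", autolag=None)
    else:
        raise ValueError(f"unknown lag_rule {lag_rule!r}")
    return StationarityResult(
        test_name="ADF",
        lag_used=int(p),
        statistic=float(stat),
        p_value=float(pval),
        reject_null=bool(pval < alpha),
        alpha=alpha,
        lag_rule=lag_rule,
    )


def kpss_test(
    x: np.ndarray,
    lags: int | None = None,
    alpha: float = 0.05,
    sensitivity: bool = False,
) -> StationarityResult | list[StationarityResult]:
    """Level-stationarity KPSS test at the given Newey-West lag.

    ``lags`` defaults to the data-driven Hobijn bandwidth capped at the
    floor(sqrt(n)) bound — the test is run with few lags, and more lags
    probe sensitivity.  With ``sensitivity=True`` the test is re-run at
    lags+2 and lags+4 and all three results returned.  Rejection of the
    stationarity null (p < α) reports the series as non-stationary.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 32:
        raise ValueError(f"need at least 32 samples, got {len(x)}")
    _check_not_constant(x)
    if lags is not None:
        base = lags
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, auto_lags, _ = kpss(x, regression="c", nlags="auto")
        base = min(int(auto_lags), kpss_max_lag(len(x)))

    def run(nlags: int) -> StationarityResult:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # p-value outside the lookup table
            stat, pval, used, _ = kpss(x, regression="c", nlags=nlags)
        return StationarityResult(
            test_name="KPSS",
            lag_used=int(used),
            statistic=float(stat),
            p_value=float(pval),
            reject_null=bool(pval < alpha),
            alpha=alpha,
            lag_rule="fixed",
        )

    if not sensitivity:
        return run(base)
    return [run(base + extra) for extra in (0, 2, 4)]


def joint_verdict(adf: StationarityResult, kp: StationarityResult) -> str:
    """Dual-test verdict: the tests must agree, otherwise 'inconclusive'."""
    if not adf.reject_null and kp.reject_null:
        return "non-stationary"
    if adf.reject_null and not kp.reject_null:
        return "stationary"
    return "inconclusive"


def stationarity_battery(
    windows: Iterable[WindowedSignal],
    lag_rule: str = "schwert-ng",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run ADF and KPSS on each window and on its first difference.

    Returns one row per window with test statistics, p-values and the
    joint verdicts for the raw zero-mean signal and its first difference.
    An empty window list yields an empty table.
    """
    rows = []
    for win in windows:
        x = win.a
        dx = np.diff(x)
        row: dict = {"start_index": win.start_index}
        for label, series in (("raw", x), ("diff", dx)):
            try:
                adf = adf_test(series, lag_rule=lag_rule, alpha=alpha)
                kp = kpss_test(series, alpha=alpha)
                row[f"adf_stat_{label}"] = adf.statistic
                row[f"adf_p_{label}"] = adf.p_value
                row[f"kpss_stat_{label}"] = kp.statistic
                row[f"kpss_p_{label}"] = kp.p_value
                row[f"verdict_{label}"] = joint_verdict(adf, kp)
            except ValueError:
                row[f"verdict_{label}"] = "degenerate"
        rows.append(row)
    return pd.DataFrame(rows)


def battery_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Fractions of each verdict for the raw and differenced signals."""
    if table.empty:
        return pd.DataFrame()
    out = {}
    for label in ("raw", "diff"):
        col = f"verdict_{label}"
        if col in table:
            out[label] = table[col].value_counts(normalize=True)
    return pd.DataFrame(out).fillna(0.0)
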