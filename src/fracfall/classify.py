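"""Feature assembly and two-class LDA fall/ADL classification.

The 14-dimensional feature vector of one window is, in fixed order,

    [A4(1..8), μ_a', σ²_a', fd1, fd2, fd3, fd4]

i.e. the level-4 wavelet approximations, the mean and unbiased variance
of the sum-vector window, and the four per-level fractal dimensions.
Undefined fractal dimensions (zero detail variance) are replaced by the
sentinel 2.0, the fractal dimension of an uncorrelated signal.

The classifier is the classical two-class linear discriminant: with
pooled within-class covariance Σ and class means μ_fall, μ_adl,

    w = Σ⁻¹ (μ_fall − μ_adl)
    b = −wᵀ (μ_fall + μ_adl) / 2 + ln(π_fall / π_adl)

and a window is declared a fall when wᵀx + b ≥ 0 (the boundary is
inclusive on the fall side).  Near-singular pooled covariances are ridge
regularised by λI with λ = 1e−6 · trace(Σ)/dim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from fracfall.dwt import WaveletDecomposition
from fracfall.fractal import FractalFeatures
from fracfall.preprocess import WindowedSignal

#: Substituted for an undefined per-level fractal dimension.
FD_SENTINEL = 2.0

FEATURE_NAMES = tuple(
    [f"a4_{i + 1}" for i in range(8)] + ["mu", "var", "fd1", "fd2", "fd3", "fd4"]
)

LABEL_FALL = "fall"
LABEL_ADL = "adl"


@dataclass
class FeatureVector:
    """One window's 14 features, with an optional class label."""

    a4: np.ndarray
    mu: float
    var: float
    fd: np.ndarray
    label: str | None = None
    start_index: int = 0
    fd_undefined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.a4 = np.asarray(self.a4, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.a4.shape != (8,):
            raise ValueError(f"a4 must have 8 entries, got {self.a4.shape}")
        if self.fd.shape != (4,):
            raise ValueError(f"fd must have 4 entries, got {self.fd.shape}")
        if self.fd_undefined is None:
            self.fd_undefined = np.zeros(4, dtype=bool)

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.a4, [self.mu, self.var], self.fd])


def assemble_features(
    win: WindowedSignal,
    dec: WaveletDecomposition,
    frac: FractalFeatures,
    label: str | None = None,
    use_sd: bool = False,
) -> FeatureVector:
    """Concatenate [A4, μ_a', σ²_a', fd1..fd4] for one window.

    ``use_sd=True`` substitutes the standard deviation for the variance
    feature.  Undefined fd levels are replaced by ``FD_SENTINEL`` and
    flagged in ``fd_undefined``.
    """
    if dec.levels != 4 or dec.input_length != win.N:
        raise ValueError(
            "expected a 4-level decomposition of the window "
            f"(got {dec.levels} levels of a {dec.input_length}-sample input "
            f"for a {win.N}-sample window)"
        )
    a4 = np.asarray(dec.approximations[-1], dtype=float)
    fd = frac.fd.copy()
    undefined = ~np.isfinite(fd)
    fd[undefined] = FD_SENTINEL
    spread = win.var_a_prime if not use_sd else float(np.sqrt(win.var_a_prime))
    return FeatureVector(
        a4=a4,
        mu=win.mu_a_prime,
        var=spread,
        fd=fd,
        label=label,
        start_index=win.start_index,
        fd_undefined=undefined,
    )


@dataclass
class LDAModel:
    """Two-class linear discriminant with pooled covariance."""

    weights: np.ndarray
    bias: float
    class_means: np.ndarray  # shape (2, dim): row 0 = ADL, row 1 = fall
    pooled_covariance: np.ndarray
    priors: np.ndarray  # (P(adl), P(fall))
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": "fracfall-lda",
            "version": 1,
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LDAModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "fracfall-lda":
            raise ValueError(f"{path}: not a fracfall LDA model document")
        return cls(
            weights=np.asarray(doc["weights"], dtype=float),
            bias=float(doc["bias"]),
            class_means=np.asarray(doc["class_means"], dtype=float),
            pooled_covariance=np.asarray(doc["pooled_covariance"], dtype=float),
            priors=np.asarray(doc["priors"], dtype=float),
            feature_names=tuple(doc["feature_names"]),
        )


def _as_matrix(X) -> np.ndarray:
    if len(X) and isinstance(X[0], FeatureVector):
        return np.array([fv.to_array() for fv in X])
    return np.asarray(X, dtype=float)


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        return (y == LABEL_FALL).astype(int)
    return y.astype(int)


def train_lda(X, y) -> LDAModel:
    """Fit the two-class pooled-covariance linear discriminant.

    ``y`` may be string labels ("fall"/"adl") or 0/1 integers with 1 =
    fall.  Both classes must be present.
    """
    Xm = _as_matrix(X)
    yb = _as_binary(y)
    if Xm.ndim != 2 or len(Xm) != len(yb):
        raise ValueError("X and y must be matching 2-D data and labels")
    classes = np.unique(yb)
    if len(classes) != 2:
        raise ValueError("both classes must be present for LDA training")
    X0, X1 = Xm[yb == 0], Xm[yb == 1]
    n0, n1 = len(X0), len(X1)
    dim = Xm.shape[1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n0 + n1 - 2)
    if np.linalg.cond(S) > 1e10:
        S = S + np.eye(dim) * (1e-6 * np.trace(S) / dim)
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance singular even after regularisation"
        ) from exc
    priors = np.array([n0, n1]) / (n0 + n1)
    bias = float(-w @ (mu0 + mu1) / 2.0 + np.log(priors[1] / priors[0]))
    return LDAModel(
        weights=w,
        bias=bias,
        class_means=np.vstack([mu0, mu1]),
        pooled_covariance=S,
        priors=priors,
        feature_names=FEATURE_NAMES if dim == len(FEATURE_NAMES) else tuple(
            f"x{i}" for i in range(dim)
        ),
    )


def discriminant(model: LDAModel, x) -> float | np.ndarray:
    """The linear score wᵀx + b; ≥ 0 means fall."""
    x = x.to_array() if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    if x.shape[-1] != model.weights.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[-1]} does not match model "
            f"({model.weights.shape[0]})"
        )
    return x @ model.weights + model.bias


def predict(model: LDAModel, X) -> np.ndarray:
    """Class predictions (1 = fall) with the inclusive ≥ 0 boundary."""
    Xm = _as_matrix(X) if not isinstance(X, np.ndarray) else X
    scores = np.atleast_1d(discriminant(model, Xm))
    return (scores >= 0.0).astype(int)


@dataclass
class EvalMetrics:
    """Confusion counts and the derived classification ratios.

    Ratios with a zero denominator are reported as None.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
        }


def evaluate(preds, truth) -> EvalMetrics:
    """Confusion counts and accuracy/sensitivity/specificity/precision."""
    p = _as_binary(preds)
    t = _as_binary(truth)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions, {len(t)} truths")
    if len(p) == 0:
        raise ValueError("empty prediction/truth vectors")
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return EvalMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
    )


def stratified_kfold_indices(
    y, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; returns (train, test) index pairs."""
    yb = _as_binary(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(yb):
        idx = np.flatnonzero(yb == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    out = []
    all_idx = set(range(len(yb)))
    for f in folds:
        test = np.array(sorted(f))
        train = np.array(sorted(all_idx - set(f)))
        out.append((train, test))
    return out


def cross_validate(X, y, k: int = 5, seed: int = 0) -> dict:
    """Stratified k-fold LDA cross-validation.

    Returns per-fold accuracies, their mean/SD, and pooled metrics over
    all held-out predictions.
    """
    Xm = _as_matrix(X)
    yb = _as_binary(y)
    accs = []
    all_pred = np.empty_like(yb)
    for train, test in stratified_kfold_indices(yb, k=k, seed=seed):
        model = train_lda(Xm[train], yb[train])
        pred = predict(model, Xm[test])
        all_pred[test] = pred
        accs.append(float(np.mean(pred == yb[test])))
    pooled = evaluate(all_pred, yb)
    return {
        "fold_accuracies": accs,
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)),
        "pooled": pooled,
    }
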