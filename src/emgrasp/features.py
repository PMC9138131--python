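"""Time-domain EMG features, IMU RMS, and the 66-D combined feature vector.

Per EMG channel and 150 ms window: mean absolute value (MAV), zero
crossings (ZC), waveform length (WL), slope sign changes (SSC) and the six
AR(6) coefficients — 10 features x 6 channels = 60.  Per IMU channel the
window RMS — 6 more — giving the fixed 66-D vector.

ZC counts strict sign products (u_i * u_{i+1} < 0, no amplitude deadband);
SSC counts strict slope-sign products ((u_i - u_{i+1})(u_i - u_{i-1}) > 0);
WL is the plain sum of absolute first differences.  AR coefficients follow
the standard convention u_i = sum_p a_p u_{i-p} + e_i and are estimated by
Burg's method, which is stable on the short 154-sample windows used here.

Normalization is symmetric min-max to [-1, 1] fitted on training data
only; test values are deliberately not clipped, so they may fall outside
the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.regression.linear_model import burg

from emgrasp.preprocess import SessionWindow

AR_ORDER = 6
EMG_FEATURE_NAMES = ["MAV", "ZC", "WL", "SSC"] + [f"AR{p}" for p in range(1, AR_ORDER + 1)]
IMU_CHANNEL_NAMES = ["ACCX", "ACCY", "ACCZ", "GYRX", "GYRY", "GYRZ"]
FEATURE_NAMES = tuple(
    [f"EMG{ch}_{name}" for ch in range(1, 7) for name in EMG_FEATURE_NAMES]
    + [f"{name}_RMS" for name in IMU_CHANNEL_NAMES]
)
N_FEATURES = len(FEATURE_NAMES)  # 66
LABEL_COLUMNS = ["subject", "grasp", "position", "rep", "window"]


def mav(u: np.ndarray) -> float:
    """Mean absolute value, (1/N) sum |u_i|."""
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("mav requires a non-empty window")
    return float(np.mean(np.abs(u)))


def zc(u: np.ndarray) -> int:
    """Zero crossings: count of i with u_i * u_{i+1} < 0 (strict)."""
    u = np.asarray(u, dtype=float)
    if u.size < 2:
        raise ValueError("zc requires at least 2 samples")
    return int(np.count_nonzero(u[:-1] * u[1:] < 0))


def wl(u: np.ndarray) -> float:
    """Waveform length: sum of |u_{i+1} - u_i|."""
    u = np.asarray(u, dtype=float)
    if u.size < 2:
        raise ValueError("wl requires at least 2 samples")
    return float(np.sum(np.abs(np.diff(u))))


def ssc(u: np.ndarray) -> int:
    """Slope sign changes: count of interior i with
    (u_i - u_{i+1})(u_i - u_{i-1}) > 0 (strict)."""
    u = np.asarray(u, dtype=float)
    if u.size < 3:
        raise ValueError("ssc requires at least 3 samples")
    d = (u[1:-1] - u[2:]) * (u[1:-1] - u[:-2])
    return int(np.count_nonzero(d > 0))


def ar_coeffs(u: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """AR(order) coefficients a_1..a_order by Burg's method.

    Convention: u_i = sum_{p=1..order} a_p u_{i-p} + e_i (a_1 is positive
    for a positively autocorrelated series).  Raises on windows that are
    too short or have (numerically) zero variance.
    """
    u = np.asarray(u, dtype=float)
    if u.size <= 2 * order:
        raise ValueError(
            f"ar_coeffs needs more than {2 * order} samples, got {u.size}")
    if not np.isfinite(u).all():
        raise ValueError("ar_coeffs requires finite input")
    if np.ptp(u) == 0.0:
        raise ValueError("ar_coeffs: constant window, autocovariance singular")
    coeffs, _sigma2 = burg(u, order=order, demean=True)
    return np.asarray(coeffs, dtype=float)


def rms(v: np.ndarray) -> float:
    """Root mean square, sqrt((1/M) sum v_i^2)."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("rms requires a non-empty window")
    return float(np.sqrt(np.mean(v * v)))


def window_features(window: SessionWindow) -> np.ndarray:
    """The 66-D feature vector of one window, in FEATURE_NAMES order.

    A constant (e.g. all-zero) EMG channel is degenerate for AR
    estimation; its six AR features are set to 0.
    """
    values = np.empty(N_FEATURES)
    pos = 0
    for ch in range(6):
        u = window.emg[ch]
        values[pos:pos + 4] = (mav(u), zc(u), wl(u), ssc(u))
        try:
            values[pos + 4:pos + 10] = ar_coeffs(u)
        except ValueError:
            values[pos + 4:pos + 10] = 0.0
        pos += 10
    for ch in range(6):
        values[pos] = rms(window.imu[ch])
        pos += 1
    return values


@dataclass
class FeatureDataset:
    """A feature matrix with per-row labels and an optional fold assignment.

    ``X`` is n x 66 after extraction, or n x k after projection (column
    names then become Y1..Yk).
    """

    X: np.ndarray
    labels: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES
    fold: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels must have one row per feature vector")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X's column count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def grasp(self) -> np.ndarray:
        return self.labels["grasp"].to_numpy()

    @property
    def position(self) -> np.ndarray:
        return self.labels["position"].to_numpy()

    def subset(self, mask: np.ndarray) -> "FeatureDataset":
        mask = np.asarray(mask)
        return FeatureDataset(
            X=self.X[mask],
            labels=self.labels.iloc[mask].reset_index(drop=True),
            feature_names=self.feature_names,
            fold=None if self.fold is None else self.fold[mask])

    def with_matrix(self, Y: np.ndarray,
                    names: tuple[str, ...] | None = None) -> "FeatureDataset":
        """Same rows/labels, new matrix (e.g. after projection)."""
        if names is None:
            names = tuple(f"Y{i}" for i in range(1, Y.shape[1] + 1))
        return FeatureDataset(X=Y, labels=self.labels.copy(),
                              feature_names=names, fold=self.fold)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.feature_names))
        for col in self.labels.columns:
            frame[col] = self.labels[col].to_numpy()
        if self.fold is not None:
            frame["fold"] = self.fold
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureDataset":
        frame = pd.read_csv(path)
        label_cols = [c for c in frame.columns if c in LABEL_COLUMNS]
        fold = frame.pop("fold").to_numpy() if "fold" in frame.columns else None
        feature_cols = [c for c in frame.columns if c not in label_cols]
        return cls(X=frame[feature_cols].to_numpy(dtype=float),
                   labels=frame[label_cols].copy(),
                   feature_names=tuple(feature_cols), fold=fold)


def extract(windows: list[SessionWindow]) -> FeatureDataset:
    """One 66-D feature vector per window, labels carried through."""
    if not windows:
        raise ValueError("extract requires at least one window")
    X = np.stack([window_features(w) for w in windows])
    labels = pd.DataFrame({
        "subject": [w.subject for w in windows],
        "grasp": [w.grasp for w in windows],
        "position": [w.position for w in windows],
        "rep": [w.rep for w in windows],
        "window": [w.index for w in windows],
    })
    return FeatureDataset(X=X, labels=labels)


class SymmetricMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-feature min-max mapping onto [-1, 1], fitted on training data.

    x -> 2 (x - min) / (max - min) - 1.  Values outside the training range
    map outside [-1, 1] (no clipping); a constant feature maps to 0.
    """

    def fit(self, X: np.ndarray, y=None) -> "SymmetricMinMaxScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("fit requires a non-empty 2-D array")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.data_max_ - self.data_min_
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (X - self.data_min_) / safe - 1.0
        return np.where(span == 0, 0.0, out)


def fit_normalizer(train: FeatureDataset) -> SymmetricMinMaxScaler:
    return SymmetricMinMaxScaler().fit(train.X)


def apply_normalizer(norm: SymmetricMinMaxScaler,
                     data: FeatureDataset) -> FeatureDataset:
    return FeatureDataset(X=norm.transform(data.X), labels=data.labels.copy(),
                          feature_names=data.feature_names, fold=data.fold)
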