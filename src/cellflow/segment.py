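"""Pixel-level cell/background classification and cell extraction.

A shallow (3-layer) feed-forward network classifies every pixel of an
8-bit colour micrograph as cell or background from its channel values.
The network — input features, one tanh hidden layer, one sigmoid output —
is trained full-batch by damped Levenberg–Marquardt on the mean squared
error, stopping when the training MSE reaches a target (default 1e-6) or
an epoch cap; a validation split is monitored for early stopping and a
held-out test split is scored but never used in fitting.  Thresholding
the network output yields a black-and-white mask from which connected
components give per-frame detections (centroid, area, moment-fitted
ellipse axes and orientation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "PixelClassifier",
    "Detection",
    "DetectionSet",
    "split_samples",
    "train_pixel_classifier",
    "classify_image",
    "extract_cells",
    "detections_to_frame",
]

# above this parameter count full-batch LM (dense J^T J solves) is wasteful;
# fall back to a quasi-Newton batch optimiser with the same stopping contract
LM_PARAM_CAP = 1000


def split_samples(
    X: np.ndarray,
    y: np.ndarray,
    proportions: Sequence[float] = (0.70, 0.15, 0.15),
    rng_seed: int = 0,
):
    """Randomly partition labelled samples into train/validation/test.

    The partition is disjoint and exhaustive, deterministic for a fixed
    seed.  A split whose proportion is zero may be empty; a split with a
    positive proportion that would receive no samples is an error.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n = len(y)
    if n == 0:
        raise ValueError("cannot split an empty sample set")
    if len(proportions) != 3 or abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must be three values summing to 1")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    b1 = int(round(proportions[0] * n))
    b2 = int(round((proportions[0] + proportions[1]) * n))
    parts = (perm[:b1], perm[b1:b2], perm[b2:])
    for prop, part, name in zip(proportions, parts, ("train", "validation", "test")):
        if prop > 0 and part.size == 0:
            raise ValueError(f"{name} split has proportion {prop} but received no samples")
    return tuple((X[p], y[p]) for p in parts)


@dataclass
class PixelClassifier:
    """3-layer feed-forward pixel classifier (tanh hidden, sigmoid out).

    ``feature_scale`` maps raw 8-bit channel values into [0, 1] before the
    network; weights are stored post-training and predictions are exactly
    reproducible after a save/load round trip.
    """

    W1: np.ndarray  # (hidden, n_features)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    feature_scale: float = 1.0 / 255.0
    features: str = "rgb"  # "rgb" | "luminance"
    report: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Network output in [0, 1] for raw feature rows (n, n_features)."""
        X = np.asarray(X, dtype=float) * self.feature_scale
        h = np.tanh(X @ self.W1.T + self.b1)
        z = h @ self.w2 + self.b2
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "cellflow-pixel-classifier-v1",
            "features": self.features,
            "feature_scale": self.feature_scale,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "report": self.report,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            W1=np.asarray(d["W1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            feature_scale=float(d["feature_scale"]),
            features=d.get("features", "rgb"),
            report=d.get("report", {}),
        )


def _unpack(p, n_feat, hidden):
    i = 0
    W1 = p[i : i + hidden * n_feat].reshape(hidden, n_feat)
    i += hidden * n_feat
    b1 = p[i : i + hidden]
    i += hidden
    w2 = p[i : i + hidden]
    i += hidden
    b2 = p[i]
    return W1, b1, w2, b2


def _forward(p, X, n_feat, hidden):
    W1, b1, w2, b2 = _unpack(p, n_feat, hidden)
    h = np.tanh(X @ W1.T + b1)
    z = h @ w2 + b2
    out = 1.0 / (1.0 + np.exp(-z))
    return out, h


def _residual_jacobian(p, X, y, n_feat, hidden):
    W1, b1, w2, b2 = _unpack(p, n_feat, hidden)
    out, h = _forward(p, X, n_feat, hidden)
    r = out - y
    s = out * (1.0 - out)  # d out / d z2
    n = X.shape[0]
    J = np.empty((n, p.size))
    # d r / d W1_{jk} = s * w2_j * (1 - h_j^2) * x_k
    g = s[:, None] * (w2 * (1.0 - h**2))  # (n, hidden)
    J[:, : hidden * n_feat] = (g[:, :, None] * X[:, None, :]).reshape(n, -1)
    J[:, hidden * n_feat : hidden * n_feat + hidden] = g
    J[:, hidden * n_feat + hidden : hidden * n_feat + 2 * hidden] = s[:, None] * h
    J[:, -1] = s
    return r, J


def _mse(p, X, y, n_feat, hidden):
    out, _ = _forward(p, X, n_feat, hidden)
    return float(np.mean((out - y) ** 2))


def train_pixel_classifier(
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    test: tuple[np.ndarray, np.ndarray] | None = None,
    hidden_size: int = 8,
    mse_target: float = 1e-6,
    max_epochs: int = 200,
    rng_seed: int = 0,
    features: str = "rgb",
    patience: int = 15,
) -> PixelClassifier:
    """Train the pixel network by full-batch Levenberg–Marquardt.

    Stops at the first of: training MSE ≤ ``mse_target``; ``max_epochs``
    accepted epochs; validation MSE not improving for ``patience`` epochs.
    The training report records final MSE per split, the epoch count and
    the stop reason.  Deterministic for a fixed seed.
    """
    Xtr_raw, ytr = np.asarray(train[0], float), np.asarray(train[1], float)
    if Xtr_raw.ndim != 2 or hidden_size < 1:
        raise ValueError("train features must be 2-D and hidden_size >= 1")
    classes = np.unique(ytr)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    scale = 1.0 / 255.0
    n_feat = Xtr_raw.shape[1]
    Xtr = Xtr_raw * scale
    rng = np.random.default_rng(rng_seed)
    n_params = hidden_size * n_feat + 2 * hidden_size + 1
    p = rng.normal(0.0, 0.5, size=n_params)

    def val_mse(pv):
        if validation is None or len(validation[1]) == 0:
            return None
        out, _ = _forward(pv, np.asarray(validation[0], float) * scale, n_feat, hidden_size)
        return float(np.mean((out - np.asarray(validation[1], float)) ** 2))

    stop_reason = "max_epochs"
    epochs = 0
    if n_params <= LM_PARAM_CAP:
        lam = 1e-2
        mse = _mse(p, Xtr, ytr, n_feat, hidden_size)
        best_val = np.inf
        stale = 0
        for epoch in range(1, max_epochs + 1):
            if not np.isfinite(mse):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            if mse <= mse_target:
                stop_reason = "mse_target"
                break
            r, J = _residual_jacobian(p, Xtr, ytr, n_feat, hidden_size)
            JtJ = J.T @ J
            Jtr = J.T @ r
            accepted = False
            for _ in range(12):
                try:
                    step = np.linalg.solve(JtJ + lam * np.eye(n_params), -Jtr)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = p + step
                cand_mse = _mse(cand, Xtr, ytr, n_feat, hidden_size)
                if np.isfinite(cand_mse) and cand_mse < mse:
                    p, mse = cand, cand_mse
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    break
                lam *= 10.0
            epochs = epoch
            if not accepted:
                stop_reason = "stalled"
                break
            vm = val_mse(p)
            if vm is not None:
                if vm < best_val - 1e-15:
                    best_val = vm
                    stale = 0
                else:
                    stale += 1
                    if stale >= patience:
                        stop_reason = "validation_early_stop"
                        break
        else:
            stop_reason = "max_epochs"
        if mse <= mse_target:
            stop_reason = "mse_target"
    else:
        # quasi-Newton fallback for larger networks; same stopping contract
        state = {"epochs": 0, "stop": "max_epochs"}

        def fun(pv):
            out, h = _forward(pv, Xtr, n_feat, hidden_size)
            r = out - ytr
            f = np.mean(r**2)
            rr, J = _residual_jacobian(pv, Xtr, ytr, n_feat, hidden_size)
            grad = 2.0 * (J.T @ rr) / len(ytr)
            return f, grad

        class _Converged(Exception):
            pass

        def cb(pv):
            state["epochs"] += 1
            if _mse(pv, Xtr, ytr, n_feat, hidden_size) <= mse_target:
                state["stop"] = "mse_target"
                raise _Converged

        try:
            res = minimize(fun, p, jac=True, method="L-BFGS-B",
                           options={"maxiter": max_epochs}, callback=cb)
            p = res.x
        except _Converged:
            pass
        epochs = state["epochs"]
        stop_reason = state["stop"]
        if not np.isfinite(_mse(p, Xtr, ytr, n_feat, hidden_size)):
            raise RuntimeError(f"non-finite training loss at epoch {epochs}")

    W1, b1, w2, b2 = _unpack(p, n_feat, hidden_size)
    clf = PixelClassifier(
        W1=W1.copy(), b1=b1.copy(), w2=w2.copy(), b2=float(b2),
        feature_scale=scale, features=features,
    )
    report = {
        "epochs": epochs,
        "stop_reason": stop_reason,
        "mse_train": _mse(p, Xtr, ytr, n_feat, hidden_size),
        "converged": stop_reason == "mse_target",
        "optimizer": "levenberg-marquardt" if n_params <= LM_PARAM_CAP else "l-bfgs-b",
    }
    report["mse_validation"] = val_mse(p)
    if test is not None and len(test[1]) > 0:
        out, _ = _forward(p, np.asarray(test[0], float) * scale, n_feat, hidden_size)
        report["mse_test"] = float(np.mean((out - np.asarray(test[1], float)) ** 2))
        report["test_error_rate"] = float(
            np.mean((out >= 0.5).astype(int) != np.asarray(test[1]).astype(int))
        )
    clf.report = report
    return clf


def _frame_features(image: np.ndarray, features: str) -> np.ndarray:
    if image.ndim == 2:
        image = image[..., None]
    if features == "luminance" and image.shape[-1] == 3:
        lum = image @ np.array([0.2126, 0.7152, 0.0722])
        return lum.reshape(-1, 1)
    return image.reshape(-1, image.shape[-1]).astype(float)


def classify_image(clf: PixelClassifier, frame, threshold: float = 0.5) -> np.ndarray:
    """Per-pixel cell/background decision: binary mask (1 = cell).

    ``frame`` is a :class:`cellflow.synth.RawFrame` or a (H, W[, C])
    array.  Pixels whose network output is ≥ ``threshold`` are cells.
    """
    image = frame.image if hasattr(frame, "image") else np.asarray(frame)
    X = _frame_features(image, clf.features)
    if X.shape[1] != clf.n_features:
        raise ValueError(
            f"frame has {X.shape[1]} channels but classifier expects {clf.n_features}"
        )
    proba = clf.predict_proba(X)
    shape = image.shape[:2]
    return (proba >= threshold).astype(np.uint8).reshape(shape)


@dataclass
class Detection:
    """One segmented object in one frame (pixel units)."""

    det_id: int
    centroid: tuple[float, float]  # (row, col)
    area_px2: float
    major_px: float  # fitted-ellipse major axis length
    minor_px: float
    orientation_rad: float
    volume_um3: float | None = None  # filled in by cellflow.measure


@dataclass
class DetectionSet:
    """All detections in one frame."""

    t_min: float
    detections: list[Detection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.detections)


def extract_cells(mask: np.ndarray, min_area: float = 5.0, frame_time: float = 0.0) -> DetectionSet:
    """8-connected components of a binary mask → per-frame detections.

    Components smaller than ``min_area`` (px²) are discarded as speckle.
    Ellipse axes and orientation come from the component's second moments.
    """
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    lab = sk_label(mask > 0, connectivity=2)
    dets = []
    for i, prop in enumerate(regionprops(lab), start=1):
        if prop.area < min_area:
            continue
        dets.append(
            Detection(
                det_id=len(dets) + 1,
                centroid=tuple(prop.centroid),
                area_px2=float(prop.area),
                major_px=float(prop.axis_major_length),
                minor_px=float(prop.axis_minor_length),
                orientation_rad=float(prop.orientation),
            )
        )
    return DetectionSet(t_min=frame_time, detections=dets)


def detections_to_frame(dsets: Sequence[DetectionSet]) -> pd.DataFrame:
    """Long-format table of detections across frames."""
    rows = []
    for ds in dsets:
        for d in ds.detections:
            rows.append(
                (ds.t_min, d.det_id, d.centroid[0], d.centroid[1],
                 d.area_px2, d.major_px, d.minor_px, d.orientation_rad, d.volume_um3)
            )
    return pd.DataFrame(
        rows,
        columns=["frame_t_min", "det_id", "centroid_row", "centroid_col",
                 "area_px2", "major_px", "minor_px", "orientation_rad", "volume_um3"],
    )
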