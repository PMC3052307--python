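"""Radial basis function network with an exact linear-system solve.

The hidden layer places one Gaussian unit on every training instance
(k = n centres) with a fixed shared bandwidth σ (default 5); each output
node j computes a linear combination of the hidden activations,

    y_j(x) = Σ_i w_ji · exp(−‖x − m_i‖² / (2σ²)),

and the output weights solve the regularised interpolation system
(Φ + ridge·I) W = Y against one-hot class targets.  On distinct centres
the Gaussian kernel matrix is symmetric positive definite, so at ridge=0
the network interpolates its training targets exactly.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

_MAGIC = b"UBILYS-RBFN-1\n"

#: Kernel conventions: exponent denominator 2σ² (default) or σ².
KERNELS = ("2sigma2", "sigma2")


@dataclass
class RBFNModel:
    """All-centres Gaussian RBF network with a linear output layer."""

    centers: np.ndarray  # (k, d)
    sigma: float
    weights: np.ndarray  # (k, c)
    class_order: list  # c labels, column order of the output layer
    ridge: float = 0.0
    kernel: str = "2sigma2"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValueError("centers must be a non-empty k×d matrix")
        if self.weights.shape[0] != self.centers.shape[0]:
            raise ValueError("weights rows must equal number of centers")
        if len(self.class_order) != self.weights.shape[1] or len(self.class_order) < 2:
            raise ValueError("need one weight column per class, ≥ 2 classes")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")

    @property
    def dim(self) -> int:
        return self.centers.shape[1]


def _kernel(A: np.ndarray, B: np.ndarray, sigma: float, kernel: str) -> np.ndarray:
    d2 = cdist(A, B, metric="sqeuclidean")
    denom = 2.0 * sigma**2 if kernel == "2sigma2" else sigma**2
    return np.exp(-d2 / denom)


def train(
    X: np.ndarray,
    labels: Sequence,
    sigma: float = 5.0,
    ridge: float = 1e-8,
    kernel: str = "2sigma2",
) -> RBFNModel:
    """Fit the output weights by solving (Φ + ridge·I) W = Y exactly.

    Deterministic; every training instance becomes a centre.  At ridge=0
    duplicate feature rows make the system singular and raise.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with ≥ 2 training instances")
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels must match rows of X")
    class_order = sorted(set(labels))
    if len(class_order) < 2:
        raise ValueError("training data must contain ≥ 2 classes")
    if ridge < 0:
        raise ValueError("ridge must be ≥ 0")
    if ridge == 0.0:
        uniq = np.unique(X, axis=0)
        if uniq.shape[0] != X.shape[0]:
            raise ValueError(
                "duplicate feature rows make the exact solve singular; "
                "use ridge > 0"
            )
    Y = np.zeros((X.shape[0], len(class_order)))
    idx = {c: j for j, c in enumerate(class_order)}
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    Phi = _kernel(X, X, sigma, kernel)
    if ridge > 0:
        Phi = Phi + ridge * np.eye(X.shape[0])
    try:
        W = np.linalg.solve(Phi, Y)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"kernel system singular ({exc}); use ridge > 0"
        ) from None
    return RBFNModel(
        centers=X.copy(),
        sigma=float(sigma),
        weights=W,
        class_order=class_order,
        ridge=float(ridge),
        kernel=kernel,
    )


def output(model: RBFNModel, x: np.ndarray) -> np.ndarray:
    """Raw output-node activations for one vector or a matrix of vectors."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.dim:
        raise ValueError(f"input dimension {x.shape[1]} != model dimension {model.dim}")
    act = _kernel(x, model.centers, model.sigma, model.kernel) @ model.weights
    return act[0] if single else act


def predict(
    model: RBFNModel,
    X: np.ndarray,
    threshold: Optional[float] = None,
) -> list:
    """Class labels by arg-max of the output nodes.

    With ``threshold`` set (binary positive/negative models only), predict
    positive iff y_pos − y_neg ≥ threshold; a tie at the default arg-max
    rule also resolves to the class sorted first (negative before positive).
    """
    act = output(model, np.atleast_2d(np.asarray(X, dtype=float)))
    if threshold is not None:
        if set(model.class_order) != {"positive", "negative"}:
            raise ValueError("threshold mode requires positive/negative classes")
        jp = model.class_order.index("positive")
        jn = model.class_order.index("negative")
        margin = act[:, jp] - act[:, jn]
        return ["positive" if m >= threshold else "negative" for m in margin]
    # np.argmax takes the first maximum -> sorted-first class wins ties
    return [model.class_order[j] for j in np.argmax(act, axis=1)]


def decision_margin(model: RBFNModel, X: np.ndarray) -> np.ndarray:
    """y_pos − y_neg for binary models (the threshold-mode score)."""
    act = output(model, np.atleast_2d(np.asarray(X, dtype=float)))
    jp = model.class_order.index("positive")
    jn = model.class_order.index("negative")
    return act[:, jp] - act[:, jn]


# ---------------------------------------------------------------------------
# Persistence: one JSON header line + little-endian float64 matrices

def save(model: RBFNModel, path: str | Path) -> None:
    header = {
        "sigma": model.sigma,
        "ridge": model.ridge,
        "kernel": model.kernel,
        "class_order": list(model.class_order),
        "k": int(model.centers.shape[0]),
        "d": int(model.centers.shape[1]),
        "c": int(model.weights.shape[1]),
    }
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(json.dumps(header, sort_keys=True).encode() + b"\n")
        fh.write(np.ascontiguousarray(model.centers, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(model.weights, dtype="<f8").tobytes())


def load(path: str | Path) -> RBFNModel:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a model file (bad magic)")
        header_line = fh.readline()
        try:
            header = json.loads(header_line.decode())
            k, d, c = header["k"], header["d"], header["c"]
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: corrupt model header ({exc})") from None
        body = fh.read()
    expected = 8 * (k * d + k * c)
    if len(body) != expected:
        raise ValueError(
            f"{path}: corrupt model file ({len(body)} body bytes, expected {expected})"
        )
    centers = np.frombuffer(body[: 8 * k * d], dtype="<f8").reshape(k, d).copy()
    weights = np.frombuffer(body[8 * k * d :], dtype="<f8").reshape(k, c).copy()
    return RBFNModel(
        centers=centers,
        sigma=header["sigma"],
        weights=weights,
        class_order=header["class_order"],
        ridge=header["ridge"],
        kernel=header["kernel"],
    )
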