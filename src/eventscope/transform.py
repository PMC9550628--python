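"""Widefield-to-scan coordinate registration.

The camera (widefield) space and the galvanometer scan space of a combined
widefield/point-scanning microscope are related by optical distortions that
a similarity or affine model cannot capture across a large field of view. A
general third-order 2-D polynomial, fitted to manually matched control
points from a bead sample imaged in both modalities, absorbs those
aberrations. The model is linear in its coefficients, so the damped
(Levenberg-Marquardt) fit used here must — and is tested to — agree with
the closed-form linear least-squares solution.

Inputs are normalised to [-1, 1] before the monomial design matrix is
built: third-order monomials on raw several-hundred-pixel coordinates are
catastrophically ill-conditioned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ControlPointSet",
    "PolynomialTransform2D",
    "AccuracyReport",
    "fit_transform",
    "apply_transform",
    "accuracy_report",
]

# Monomial exponents (i, j) for x^i * y^j with i + j <= 3, fixed order.
_EXPONENTS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for total in range(4) for i in range(total, -1, -1) for j in [total - i]
)
assert len(_EXPONENTS) == 10

MIN_CONTROL_POINTS = 10


@dataclass(frozen=True)
class ControlPointSet:
    """Matched point pairs: source (widefield) and target (scan) coordinates in px."""

    src: np.ndarray  # (N, 2)
    dst: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.src, dtype=float))
        dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ValueError("src and dst must both be (N, 2) arrays")
        if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
            raise ValueError("control points must be finite")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)

    def __len__(self) -> int:
        return self.src.shape[0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ControlPointSet":
        """Read matched pairs from a CSV with columns x_wf, y_wf, x_scan, y_scan."""
        df = pd.read_csv(path)
        required = ["x_wf", "y_wf", "x_scan", "y_scan"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"control point CSV missing columns: {missing}")
        return cls(df[["x_wf", "y_wf"]].to_numpy(), df[["x_scan", "y_scan"]].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x_wf": self.src[:, 0],
                "y_wf": self.src[:, 1],
                "x_scan": self.dst[:, 0],
                "y_scan": self.dst[:, 1],
            }
        ).to_csv(path, index=False)


def _design_matrix(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    return np.column_stack([x**i * y**j for i, j in _EXPONENTS])


@dataclass
class PolynomialTransform2D:
    """Third-order 2-D polynomial map between two image coordinate systems.

    ``coeffs`` holds 10 coefficients per output axis over the monomials
    x^i y^j, i + j <= 3, evaluated on inputs normalised by
    ``(p - offset) / scale``.
    """

    coeffs: np.ndarray  # (2, 10)
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    scale: np.ndarray = field(default_factory=lambda: np.ones(2))
    residual: float | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).reshape(2, 10)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        self.scale = np.asarray(self.scale, dtype=float).reshape(2)
        if np.any(self.scale == 0):
            raise ValueError("normalization scale must be nonzero")

    @classmethod
    def identity(cls) -> "PolynomialTransform2D":
        coeffs = np.zeros((2, 10))
        coeffs[0, _EXPONENTS.index((1, 0))] = 1.0
        coeffs[1, _EXPONENTS.index((0, 1))] = 1.0
        return cls(coeffs=coeffs)

    def __call__(self, coords) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        u = (coords - self.offset) / self.scale
        return _design_matrix(u) @ self.coeffs.T

    def transform_point(self, x: float, y: float) -> tuple[float, float]:
        out = self(np.array([[x, y]]))[0]
        return float(out[0]), float(out[1])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": "polynomial2d",
            "order": 3,
            "exponents": [list(e) for e in _EXPONENTS],
            "coeffs_x": self.coeffs[0].tolist(),
            "coeffs_y": self.coeffs[1].tolist(),
            "offset": self.offset.tolist(),
            "scale": self.scale.tolist(),
            "residual": self.residual,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialTransform2D":
        if d.get("model") != "polynomial2d":
            raise ValueError("not a polynomial2d transform document")
        return cls(
            coeffs=np.array([d["coeffs_x"], d["coeffs_y"]]),
            offset=np.array(d["offset"]),
            scale=np.array(d["scale"]),
            residual=d.get("residual"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PolynomialTransform2D":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_transform(points: ControlPointSet, method: str = "lm") -> PolynomialTransform2D:
    """Fit the third-order polynomial to matched control points.

    ``method`` is ``"lm"`` (damped iterative least squares, the default) or
    ``"linear"`` (closed-form normal solution via ``lstsq``). The model is
    linear in its coefficients, so the two agree to numerical precision;
    the linear route seeds the damped one.
    """
    n = len(points)
    if n < MIN_CONTROL_POINTS:
        raise ValueError(
            f"need at least {MIN_CONTROL_POINTS} control point pairs, got {n}"
        )
    src_unique = np.unique(points.src, axis=0)
    if src_unique.shape[0] != n:
        raise ValueError("duplicated source points in control point set")

    lo, hi = points.src.min(axis=0), points.src.max(axis=0)
    offset = (hi + lo) / 2.0
    scale = np.where((hi - lo) > 0, (hi - lo) / 2.0, 1.0)
    u = (points.src - offset) / scale
    design = _design_matrix(u)

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "control point design is rank-deficient (points collinear or "
            "clustered); add more spread-out points"
        )

    coeffs_lin, *_ = np.linalg.lstsq(design, points.dst, rcond=None)
    coeffs = coeffs_lin.T  # (2, 10)

    if method == "lm":
        def residuals(flat: np.ndarray) -> np.ndarray:
            c = flat.reshape(2, 10)
            return (design @ c.T - points.dst).ravel()

        sol = least_squares(residuals, coeffs.ravel(), method="lm")
        coeffs = sol.x.reshape(2, 10)
    elif method != "linear":
        raise ValueError(f"unknown fit method {method!r}")

    pred = design @ coeffs.T
    residual = float(np.sqrt(np.mean(np.sum((pred - points.dst) ** 2, axis=1))))
    return PolynomialTransform2D(coeffs=coeffs, offset=offset, scale=scale, residual=residual)


def apply_transform(t: PolynomialTransform2D, coords) -> np.ndarray:
    """Evaluate the transform on an (N, 2) array (or list) of (x, y) points."""
    return t(coords)


@dataclass
class AccuracyReport:
    """Per-point registration errors plus their mean, for accuracy mapping."""

    src: np.ndarray           # (N, 2) source (widefield) coordinates, px
    predicted: np.ndarray     # (N, 2) transformed coordinates, scan px
    detected: np.ndarray      # (N, 2) detected target coordinates, scan px
    distances_nm: np.ndarray  # (N,) per-point Euclidean error, nm
    mean_error_nm: float
    pixel_size_nm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_wf": self.src[:, 0],
                "y_wf": self.src[:, 1],
                "x_pred": self.predicted[:, 0],
                "y_pred": self.predicted[:, 1],
                "x_det": self.detected[:, 0],
                "y_det": self.detected[:, 1],
                "error_nm": self.distances_nm,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def accuracy_report(
    t: PolynomialTransform2D,
    validation: ControlPointSet,
    pixel_size_nm: float = 100.0,
) -> AccuracyReport:
    """Transform validation sources and measure distances to detected targets.

    Distances are reported in nm (scan-space px errors scaled by
    ``pixel_size_nm``); the per-point map supports inspection for spatial
    correlation of the residuals.
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    predicted = t(validation.src)
    d_px = np.sqrt(np.sum((predicted - validation.dst) ** 2, axis=1))
    d_nm = d_px * pixel_size_nm
    return AccuracyReport(
        src=validation.src.copy(),
        predicted=predicted,
        detected=validation.dst.copy(),
        distances_nm=d_nm,
        mean_error_nm=float(d_nm.mean()),
        pixel_size_nm=float(pixel_size_nm),
    )
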