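"""Fiducial-based planar affine registration between optical and thermal images.

Coordinate convention (used everywhere in the package): 0-based pixel
coordinates, ``x`` = column, ``y`` = row, both referring to pixel
*centers*.  A full 6-degree-of-freedom affine map is estimated by least
squares from labeled corner-point correspondences (identification card
or sticker corners visible in both modalities); the RMS residual is
reported so callers can reject poor registrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InvalidArgumentError

#: Registrations with RMS residual above this many pixels warrant a warning.
DEFAULT_RESIDUAL_WARN_PX = 2.0


@dataclass(frozen=True)
class AffineTransform2D:
    """Planar affine map ``p -> A @ p + b``.

    Parameters
    ----------
    matrix
        2x2 linear part ``A`` (must be invertible).
    offset
        length-2 translation ``b``.
    direction
        free-form tag recording which way the map goes, e.g.
        ``"optical->thermal"``.
    """

    matrix: np.ndarray
    offset: np.ndarray
    direction: str = "optical->thermal"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        b = np.asarray(self.offset, dtype=float).reshape(2)
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(b))):
            raise InvalidArgumentError("affine coefficients must be finite")
        if abs(np.linalg.det(m)) < 1e-12:
            raise DegenerateGeometryError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", b)

    @classmethod
    def identity(cls, direction: str = "optical->thermal") -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), direction)

    def __call__(self, points) -> np.ndarray:
        return apply_transform(self, points)

    def invert(self) -> "AffineTransform2D":
        """Inverse map, with the direction tag flipped if it contains '->'."""
        inv = np.linalg.inv(self.matrix)
        if "->" in self.direction:
            a, b = self.direction.split("->", 1)
            direction = f"{b}->{a}"
        else:
            direction = self.direction
        return AffineTransform2D(inv, -inv @ self.offset, direction)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return AffineTransform2D(
            self.matrix @ other.matrix,
            self.matrix @ other.offset + self.offset,
            self.direction,
        )

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))

    # -- JSON serialization (6 named coefficients + direction) ----------
    def to_dict(self) -> dict:
        a = self.matrix
        return {
            "a11": a[0, 0], "a12": a[0, 1], "a21": a[1, 0], "a22": a[1, 1],
            "tx": self.offset[0], "ty": self.offset[1],
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(
            np.array([[d["a11"], d["a12"]], [d["a21"], d["a22"]]], dtype=float),
            np.array([d["tx"], d["ty"]], dtype=float),
            d.get("direction", "optical->thermal"),
        )


@dataclass(frozen=True)
class EllipseSpec:
    """Ellipse in pixel coordinates, canonical form.

    ``semi_axes = (a, b)`` with ``a >= b > 0`` and ``rotation`` (radians,
    the angle of the ``a`` axis from +x, counter-clockwise in xy) in
    ``[0, pi)``.  Circles canonicalize to rotation 0.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        cx, cy = (float(v) for v in self.center)
        a, b = (float(v) for v in self.semi_axes)
        rot = float(self.rotation)
        if not all(np.isfinite([cx, cy, a, b, rot])):
            raise InvalidArgumentError("ellipse parameters must be finite")
        if a <= 0 or b <= 0:
            raise InvalidArgumentError(f"semi-axes must be positive, got {(a, b)}")
        if a < b:
            a, b = b, a
            rot += np.pi / 2
        rot = float(np.mod(rot, np.pi))
        if np.isclose(a, b):
            rot = 0.0
        object.__setattr__(self, "center", (cx, cy))
        object.__setattr__(self, "semi_axes", (a, b))
        object.__setattr__(self, "rotation", rot)

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def quadratic_form(self) -> np.ndarray:
        """Positive-definite matrix ``M`` with interior ``(p-c)^T M (p-c) < 1``."""
        a, b = self.semi_axes
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        r = np.array([[c, -s], [s, c]])
        return r @ np.diag([1.0 / a**2, 1.0 / b**2]) @ r.T

    def contains(self, points, strict: bool = True) -> np.ndarray:
        """Membership of points by the implicit quadratic form (strict '<' by default)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        q = np.einsum("ni,ij,nj->n", p, self.quadratic_form(), p)
        return q < 1.0 if strict else q <= 1.0

    def scaled(self, factor: float) -> "EllipseSpec":
        """Same center and rotation, semi-axes multiplied by ``factor``."""
        if factor <= 0:
            raise InvalidArgumentError("scale factor must be positive")
        a, b = self.semi_axes
        return EllipseSpec(self.center, (a * factor, b * factor), self.rotation)

    def boundary_points(self, n: int = 360) -> np.ndarray:
        """``n`` points on the boundary, for plotting and fit oracles."""
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        x = a * np.cos(t)
        y = b * np.sin(t)
        return np.column_stack([c * x - s * y, s * x + c * y]) + np.asarray(self.center)

    def to_dict(self, coordinate_system: str | None = None) -> dict:
        d = {
            "center": list(self.center),
            "semi_axes": list(self.semi_axes),
            "rotation": self.rotation,
        }
        if coordinate_system is not None:
            d["coordinate_system"] = coordinate_system
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseSpec":
        return cls(tuple(d["center"]), tuple(d["semi_axes"]), d.get("rotation", 0.0))


@dataclass(frozen=True)
class FiducialSet:
    """Labeled corresponding points in the optical and thermal images."""

    labels: tuple[str, ...]
    optical_points: np.ndarray
    thermal_points: np.ndarray

    def __post_init__(self) -> None:
        opt = np.asarray(self.optical_points, dtype=float).reshape(-1, 2)
        th = np.asarray(self.thermal_points, dtype=float).reshape(-1, 2)
        labels = tuple(str(x) for x in self.labels)
        if not (len(labels) == len(opt) == len(th)):
            raise InvalidArgumentError("labels, optical and thermal point lists must have equal length")
        if len(opt) < 3:
            raise DegenerateGeometryError("at least 3 fiducial points are required")
        if not (np.all(np.isfinite(opt)) and np.all(np.isfinite(th))):
            raise InvalidArgumentError("fiducial coordinates must be finite")
        if _collinear(opt):
            raise DegenerateGeometryError("optical fiducial points are collinear")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "optical_points", opt)
        object.__setattr__(self, "thermal_points", th)

    def __len__(self) -> int:
        return len(self.labels)

    def to_dict(self) -> dict:
        return {
            "coordinate_convention": "0-based x=column y=row, pixel centers",
            "points": [
                {
                    "label": lab,
                    "optical_xy": list(map(float, o)),
                    "thermal_xy": list(map(float, t)),
                }
                for lab, o, t in zip(self.labels, self.optical_points, self.thermal_points)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiducialSet":
        pts = d["points"]
        return cls(
            tuple(p["label"] for p in pts),
            np.array([p["optical_xy"] for p in pts], dtype=float),
            np.array([p["thermal_xy"] for p in pts], dtype=float),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FiducialSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    """True if all points lie on one line (rank of the centered cloud < 2)."""
    p = points - points.mean(axis=0)
    s = np.linalg.svd(p, compute_uv=False)
    return len(s) < 2 or s[1] <= tol * max(s[0], 1.0)


def estimate_affine(fiducials: FiducialSet) -> tuple[AffineTransform2D, float]:
    """Least-squares affine mapping optical fiducials onto thermal ones.

    Solves ``argmin sum_i || A p_i + b - q_i ||^2`` over the six affine
    coefficients via the linear system with design rows ``[x, y, 1]``.
    With exactly three non-collinear points the fit is exact.

    Returns
    -------
    (transform, rms_residual)
        The estimated optical->thermal transform and the RMS residual in
        thermal pixels over all fiducials.
    """
    src = fiducials.optical_points
    dst = fiducials.thermal_points
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    matrix = coef[:2].T
    offset = coef[2]
    t = AffineTransform2D(matrix, offset, "optical->thermal")
    resid = t(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return t, rms


def apply_transform(t: AffineTransform2D, points) -> np.ndarray:
    """Apply an affine map to an ``(n, 2)`` array (or a single point)."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if not np.all(np.isfinite(p)):
        raise InvalidArgumentError("points must be finite")
    out = p @ t.matrix.T + t.offset
    return out[0] if single else out


def map_ellipse(t: AffineTransform2D, e: EllipseSpec) -> EllipseSpec:
    """Exact analytic image of an ellipse under an affine map.

    The interior ``(p-c)^T M (p-c) < 1`` maps to an ellipse with center
    ``A c + b`` and quadratic form ``A^{-T} M A^{-1}``; the result is
    re-canonicalized (``a >= b``, rotation in ``[0, pi)``).  Area scales
    by ``|det A|``.
    """
    center = apply_transform(t, np.asarray(e.center))
    ainv = np.linalg.inv(t.matrix)
    m = ainv.T @ e.quadratic_form() @ ainv
    m = (m + m.T) / 2.0
    evals, evecs = np.linalg.eigh(m)
    if np.any(evals <= 0):
        raise DegenerateGeometryError("mapped conic is not an ellipse (singular transform?)")
    axes = 1.0 / np.sqrt(evals)  # ascending evals -> descending axes
    a, b = float(axes[0]), float(axes[1])  # a >= b since evals ascending
    v = evecs[:, 0]  # eigenvector of the smaller eigenvalue = major axis
    rotation = float(np.arctan2(v[1], v[0]))
    return EllipseSpec((float(center[0]), float(center[1])), (a, b), rotation)
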