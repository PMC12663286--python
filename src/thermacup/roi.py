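"""Concentric elliptical regions of interest around the cup imprint.

From the user-supplied outer ellipse (the 1x cup-imprint boundary) two
further ellipses are derived with the same center and rotation and
semi-axes scaled by 1.25 and 0.25.  The three nested ellipses bound the
three analysis regions:

* **Peri-ROI** — between the 1.25x and 1x ellipses (adjacent tissue not
  under pressure during cupping);
* **ROI Edge** — between the 1x and 0.25x ellipses (tissue under the
  cup rim);
* **ROI Center** — inside the 0.25x ellipse (tissue under most
  deformation).

Rasterization uses a strict pixel-center-inside test on each ellipse's
implicit quadratic form, so every pixel belongs to at most one region
and counts are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError, InvalidArgumentError
from .register import EllipseSpec

REGION_NAMES = ("Peri-ROI", "ROI Edge", "ROI Center")

DEFAULT_SCALE_OUT = 1.25
DEFAULT_SCALE_IN = 0.25


@dataclass(frozen=True)
class ConcentricROISet:
    """The outer cup-imprint ellipse plus its scaled companions."""

    outer: EllipseSpec
    peri_outer: EllipseSpec
    center: EllipseSpec

    @property
    def scale_out(self) -> float:
        return self.peri_outer.semi_axes[0] / self.outer.semi_axes[0]

    @property
    def scale_in(self) -> float:
        return self.center.semi_axes[0] / self.outer.semi_axes[0]


@dataclass(frozen=True)
class RegionMasks:
    """Disjoint boolean masks for the three regions on a pixel grid."""

    grid_shape: tuple[int, int]
    peri_mask: np.ndarray
    edge_mask: np.ndarray
    center_mask: np.ndarray

    def __iter__(self):
        yield from zip(REGION_NAMES, (self.peri_mask, self.edge_mask, self.center_mask))

    def as_dict(self) -> dict[str, np.ndarray]:
        return dict(self)

    @property
    def counts(self) -> dict[str, int]:
        return {name: int(mask.sum()) for name, mask in self}


def derive_concentric(
    outer: EllipseSpec,
    scale_out: float = DEFAULT_SCALE_OUT,
    scale_in: float = DEFAULT_SCALE_IN,
) -> ConcentricROISet:
    """Build the concentric ROI set by exact axis scaling of ``outer``."""
    if not (0 < scale_in < 1 < scale_out):
        raise InvalidArgumentError(
            f"require 0 < scale_in < 1 < scale_out, got scale_in={scale_in}, scale_out={scale_out}"
        )
    return ConcentricROISet(
        outer=outer,
        peri_outer=outer.scaled(scale_out),
        center=outer.scaled(scale_in),
    )


def _inside(e: EllipseSpec, grid_shape: tuple[int, int]) -> np.ndarray:
    rows, cols = grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    p = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float) - np.asarray(e.center)
    m = e.quadratic_form()
    # quadratic form expanded component-wise; avoids an (n,2,2) einsum
    q = m[0, 0] * p[:, 0] ** 2 + 2 * m[0, 1] * p[:, 0] * p[:, 1] + m[1, 1] * p[:, 1] ** 2
    return (q < 1.0).reshape(rows, cols)


def rasterize_masks(roi: ConcentricROISet, grid_shape: tuple[int, int]) -> RegionMasks:
    """Rasterize the three regions into disjoint boolean masks.

    Pixel-center membership is tested against each ellipse; because the
    ellipses are nested, peri/edge/center partition the interior of the
    1.25x ellipse by construction.  A peri ellipse extending beyond the
    grid is clipped with a warning; an empty ROI Center (smaller than
    the pixel spacing) is an error.
    """
    rows, cols = (int(v) for v in grid_shape)
    if rows <= 0 or cols <= 0:
        raise InvalidArgumentError(f"grid_shape must be positive, got {grid_shape}")
    cx, cy = roi.peri_outer.center
    a = roi.peri_outer.semi_axes[0]
    if cx - a < -0.5 or cy - a < -0.5 or cx + a > cols - 0.5 or cy + a > rows - 0.5:
        warnings.warn(
            "peri ellipse extends beyond the grid and is clipped", stacklevel=2
        )
    in_peri = _inside(roi.peri_outer, (rows, cols))
    in_outer = _inside(roi.outer, (rows, cols))
    in_center = _inside(roi.center, (rows, cols))
    masks = RegionMasks(
        grid_shape=(rows, cols),
        peri_mask=in_peri & ~in_outer,
        edge_mask=in_outer & ~in_center,
        center_mask=in_center,
    )
    for name, mask in masks:
        if not mask.any():
            raise EmptyRegionError(f"region {name!r} rasterized to zero pixels")
    return masks


def region_areas(roi: ConcentricROISet) -> dict[str, float]:
    """Analytic areas of the three regions (pixel^2); the rasterization oracle.

    With outer semi-axes ``(a, b)`` and scales ``s_out``/``s_in``:
    Peri = pi a b (s_out^2 - 1), Edge = pi a b (1 - s_in^2),
    Center = pi a b s_in^2.  At the default scales Center/outer = 1/16.
    """
    base = roi.outer.area
    s_out, s_in = roi.scale_out, roi.scale_in
    return {
        "Peri-ROI": base * (s_out**2 - 1.0),
        "ROI Edge": base * (1.0 - s_in**2),
        "ROI Center": base * s_in**2,
    }


def export_mask_png(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG for visual inspection."""
    from PIL import Image

    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)
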