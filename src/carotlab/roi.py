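"""Polygonal regions of interest and per-region colour statistics.

A disk outline is drawn once per sample as a polygon (list of ``[x, y]``
pixel vertices, 0-based, x rightward, y downward) and the same polygon is
reused across all images of that sample, mirroring a macro workflow where a
hand-drawn selection is applied to every light condition.  A pixel belongs
to the region iff its centre (``col + 0.5``, ``row + 0.5``) lies inside the
polygon under the even-odd fill rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as _MplPath
from shapely.geometry import Polygon as _ShPolygon

__all__ = ["RGBMeasurement", "rasterise_polygon", "roi_colour", "load_rois", "save_rois"]


@dataclass(frozen=True)
class RGBMeasurement:
    """Mean ± SD RGB over a region (population SD, 0–255 scale)."""

    mean_rgb: tuple
    sd_rgb: tuple
    n_pixels: int

    def __post_init__(self):
        if self.n_pixels < 1:
            raise ValueError("region must contain at least one pixel")
        if any(s < 0 for s in self.sd_rgb):
            raise ValueError("sd_rgb must be non-negative")


def rasterise_polygon(polygon, image_shape) -> np.ndarray:
    """Boolean interior mask of a simple polygon on a pixel grid.

    Parameters
    ----------
    polygon : sequence of (x, y)
        At least three vertices; must be simple (non-self-intersecting) and
        of non-zero area.
    image_shape : (rows, cols)
        Shape of the target image grid.

    Returns
    -------
    ndarray of bool, shape ``image_shape``
        True where the pixel centre is inside the polygon.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon must be a sequence of at least 3 (x, y) vertices")
    shp = _ShPolygon(verts)
    from shapely.validation import make_valid

    if make_valid(shp).area == 0.0:
        raise ValueError("degenerate polygon: zero area")
    if not shp.is_valid:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    rows, cols = int(image_shape[0]), int(image_shape[1])
    # restrict the centre test to the polygon's bounding box
    minx, miny, maxx, maxy = shp.bounds
    c0, c1 = max(int(np.floor(minx - 1)), 0), min(int(np.ceil(maxx + 1)), cols)
    r0, r1 = max(int(np.floor(miny - 1)), 0), min(int(np.ceil(maxy + 1)), rows)
    mask = np.zeros((rows, cols), dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    centres = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
    inside = _MplPath(verts).contains_points(centres, radius=0.0)
    mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    return mask


def roi_colour(image: np.ndarray, mask: np.ndarray) -> RGBMeasurement:
    """Per-channel arithmetic mean and population SD over masked pixels."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("image must be H x W x 3")
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape must match image")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region of interest")
    pixels = img[mask]
    return RGBMeasurement(
        mean_rgb=tuple(pixels.mean(axis=0)),
        sd_rgb=tuple(pixels.std(axis=0)),  # population SD
        n_pixels=n,
    )


def save_rois(rois: dict, path) -> None:
    """Write ROI polygons as JSON: ``{sample_id: [[x, y], ...]}``."""
    with open(path, "w") as fh:
        json.dump({k: np.asarray(v, dtype=float).tolist() for k, v in rois.items()}, fh)


def load_rois(path) -> dict:
    with open(path) as fh:
        return {k: np.asarray(v, dtype=float) for k, v in json.load(fh).items()}
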