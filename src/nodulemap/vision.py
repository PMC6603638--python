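"""Visual analysis: background subtraction, orientation, indentation grid.

Emulates the camera stage of the scanning platform.  The sample outline is
recovered by subtracting the background image from the sample image; the
resulting mask gives the shape, size and orientation of the specimen.  The
orientation is then normalized (software equivalent of the physical
rotation stage) and an axis-aligned lattice of indentation points at a
fixed step (2 mm by default) is laid over the mask, keeping only points
whose probe footprint lies safely inside the sample.

Conventions: pixel centers sit at integer (row, col) coordinates; mask
membership is by center inclusion; the in-plane angle is measured from the
x (column) axis toward increasing rows, reported in (-90, 90] degrees.
Grid coordinates are millimetres relative to the minimum corner of the
mask bounding box, x along columns and y along rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "SampleMask",
    "IndentationGrid",
    "NoSampleError",
    "subtract_background",
    "normalize_orientation",
    "build_indentation_grid",
    "save_grid",
    "load_grid",
]


class NoSampleError(ValueError):
    """Raised when no usable sample silhouette can be extracted."""


@dataclass
class SampleMask:
    """Binary sample silhouette with scale and orientation metadata.

    ``soft`` keeps the continuous (anti-aliased) difference image from
    which the binary mask was thresholded; it is carried along so that
    rotations interpolate the underlying coverage rather than a hard mask.
    """

    mask: np.ndarray
    mm_per_pixel: float
    principal_angle_deg: float
    centroid_px: tuple[float, float]  # (col, row)
    soft: np.ndarray | None = None

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.mm_per_pixel**2


@dataclass
class IndentationGrid:
    """Ordered (row-major) lattice of indentation points, mm, at a fixed step."""

    points: np.ndarray  # (n, 2) -> (x, y) mm
    step_mm: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")

    def __len__(self) -> int:
        return len(self.points)


def _mask_moments(mask_or_weights: np.ndarray) -> tuple[tuple[float, float], float]:
    """Centroid (col, row) and principal angle (deg) from second-order moments."""
    w = np.asarray(mask_or_weights, dtype=float)
    total = w.sum()
    rows, cols = np.nonzero(w > 0)
    vals = w[rows, cols]
    cr = float((rows * vals).sum() / total)
    cc = float((cols * vals).sum() / total)
    x = cols - cc
    y = rows - cr
    mu20 = float((vals * x * x).sum())
    mu02 = float((vals * y * y).sum())
    mu11 = float((vals * x * y).sum())
    angle = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    # Canonical range (-90, 90]; ties at +-90 resolved toward the longer
    # bounding-box side by preferring the representative closest to zero.
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return (cc, cr), angle


def subtract_background(
    sample_image: np.ndarray,
    background_image: np.ndarray,
    mm_per_pixel: float,
    threshold: float = 0.1,
) -> SampleMask:
    """Extract the sample silhouette as |sample - background| thresholding.

    ``threshold`` is a fraction of the difference image's dynamic range, so
    the operation is intensity-scale free.  The binary mask is cleaned by
    filling holes and keeping the largest connected component.  Raises
    :class:`NoSampleError` when nothing remains.
    """
    sample_image = np.asarray(sample_image, dtype=float)
    background_image = np.asarray(background_image, dtype=float)
    if sample_image.shape != background_image.shape:
        raise ValueError("sample and background images must share a shape")

    diff = np.abs(sample_image - background_image)
    span = diff.max()
    if span == 0:
        raise NoSampleError("no sample detected: images are identical")
    soft = diff / span
    binary = soft > threshold
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise NoSampleError("no sample detected after cleanup")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    binary = labels == (1 + int(np.argmax(sizes)))

    soft = np.where(binary | (soft > threshold), soft, 0.0)
    centroid, angle = _mask_moments(binary)
    return SampleMask(
        mask=binary,
        mm_per_pixel=mm_per_pixel,
        principal_angle_deg=angle,
        centroid_px=centroid,
        soft=soft,
    )


def normalize_orientation(mask: SampleMask, threshold: float = 0.5) -> SampleMask:
    """Rotate the mask about its centroid so its long axis aligns with x.

    Interpolates the continuous coverage image when available (bilinear),
    then re-thresholds, so the aligned outline is sub-pixel accurate.
    """
    if mask.mask.sum() == 0:
        raise NoSampleError("empty mask")
    source = mask.soft if mask.soft is not None else mask.mask.astype(float)
    rotated = _sk_rotate(
        source,
        angle=mask.principal_angle_deg,
        resize=True,
        center=None,
        order=1,
        mode="constant",
        cval=0.0,
    )
    binary = rotated > threshold
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        raise NoSampleError("mask vanished during rotation")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    binary = labels == (1 + int(np.argmax(sizes)))
    centroid, angle = _mask_moments(binary)
    return SampleMask(
        mask=binary,
        mm_per_pixel=mask.mm_per_pixel,
        principal_angle_deg=angle,
        centroid_px=centroid,
        soft=np.where(binary | (rotated > threshold), rotated, 0.0),
    )


def build_indentation_grid(
    mask: SampleMask,
    step_mm: float = 2.0,
    margin_mm: float = 1.5,
) -> IndentationGrid:
    """Lay an axis-aligned lattice over the mask bounding box.

    Points are kept when they fall on the mask and at least ``margin_mm``
    from its border (distance-transform test, with half a pixel of slack to
    absorb rasterization), so the full probe footprint stays on the sample
    when ``margin_mm`` is the probe radius.  Coordinates are mm relative to
    the bounding-box minimum corner; ordering is row-major (y outer).
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise NoSampleError("empty mask")
    r0, c0 = int(rows.min()), int(cols.min())
    r1, c1 = int(rows.max()), int(cols.max())
    mmpp = mask.mm_per_pixel

    edt_mm = ndimage.distance_transform_edt(mask.mask) * mmpp
    min_dist = max(margin_mm - 0.5 * mmpp, 0.0)

    eps = 1e-9
    xs = np.arange(0.0, (c1 - c0) * mmpp + eps + 1e-12, step_mm)
    ys = np.arange(0.0, (r1 - r0) * mmpp + eps + 1e-12, step_mm)
    points = []
    for y in ys:
        rr = r0 + int(round(y / mmpp))
        for x in xs:
            cc = c0 + int(round(x / mmpp))
            if rr > r1 or cc > c1:
                continue
            if mask.mask[rr, cc] and edt_mm[rr, cc] >= min_dist:
                points.append((x, y))
    if not points:
        raise NoSampleError("sample too small for the requested step/margin")
    return IndentationGrid(points=np.array(points), step_mm=step_mm)


def save_grid(grid: IndentationGrid, path) -> None:
    """Write the grid as delimited text with a unit/step header."""
    with open(path, "w") as fh:
        fh.write(f"# units: mm\n# step_mm: {grid.step_mm}\n")
        fh.write("x_mm\ty_mm\n")
        for x, y in grid.points:
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")


def load_grid(path) -> IndentationGrid:
    step = None
    with open(path) as fh:
        lines = fh.readlines()
    data = []
    for line in lines:
        if line.startswith("#"):
            if "step_mm:" in line:
                step = float(line.split(":", 1)[1])
            continue
        if line.strip() and not line[0].isalpha():
            x, y = line.split("\t")
            data.append((float(x), float(y)))
    if step is None:
        raise ValueError("grid file missing step header")
    return IndentationGrid(points=np.array(data), step_mm=step)
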