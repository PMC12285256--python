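"""Cell-occupancy measurement inside water-in-oil droplets from micrographs.

A droplet micrograph shows a bright oil background, a dark circular
interface ring at the droplet boundary, and dark microbial cells inside the
lumen. Occupancy is the percentage of the lumen area covered by cells:

    A_occup(%) = (A_droplet - A_ex) / A_droplet * 100

where ``A_droplet`` is the lumen area and ``A_ex`` the area excluding cells,
both in pixels. The pipeline is: circular-Hough droplet detection,
interface-ring extraction, Otsu binarization of the lumen, and the formula
above. The interface ring itself is excluded from ``A_droplet`` (whether the
rim belongs to the droplet area is an imaging convention; we measure the
lumen only).

Coordinates are 0-based with a pixel-center convention; areas are in px^2
and convert to um^2 via ``um_per_px**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, morphology, transform

__all__ = [
    "DropletImage",
    "DropletGeometry",
    "OccupancyMeasurement",
    "DropletDetectionError",
    "detect_droplet",
    "segment_cells",
    "compute_occupancy",
    "measure_image",
    "summarize_replicates",
    "read_droplet_image",
    "write_droplet_image",
]


class DropletDetectionError(RuntimeError):
    """No acceptable droplet could be located in the frame."""


@dataclass(frozen=True)
class DropletImage:
    """A grayscale droplet micrograph with its pixel scale."""

    pixels: np.ndarray  # 2-D float array, intensities in [0, 1]
    um_per_px: float

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 32:
            raise ValueError("image must be 2-D with both dimensions >= 32 px")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class DropletGeometry:
    """Detected droplet outline: center, radius and circle area in px."""

    center_xy: tuple[float, float]
    radius_px: float
    area_px: float

    def __post_init__(self):
        if self.radius_px <= 0:
            raise ValueError("radius must be positive")
        if abs(self.area_px - math.pi * self.radius_px**2) > 0.005 * self.area_px:
            raise ValueError("area_px inconsistent with radius (pi r^2 within 0.5%)")


@dataclass(frozen=True)
class OccupancyMeasurement:
    """Areas and occupancy for a single droplet (pixel units)."""

    a_droplet_px: float
    a_ex_px: float
    occupancy_pct: float


def compute_occupancy(a_droplet_px: float, a_ex_px: float) -> float:
    """Occupancy (%) from droplet area and cell-excluded area."""
    if a_droplet_px <= 0:
        raise ValueError(f"A_droplet must be positive, got {a_droplet_px}")
    if not 0 <= a_ex_px <= a_droplet_px:
        raise ValueError(
            f"A_ex must lie in [0, A_droplet], got {a_ex_px} vs {a_droplet_px}"
        )
    return (a_droplet_px - a_ex_px) / a_droplet_px * 100.0


def detect_droplet(
    img: DropletImage,
    diameter_prior_um: float = 120.0,
    radius_tolerance: float = 0.20,
    min_accumulator: float = 0.25,
) -> DropletGeometry:
    """Locate the dominant droplet by circular Hough transform.

    The radius search window is the expected droplet radius (from
    ``diameter_prior_um`` and the image scale) +/- ``radius_tolerance``.
    Droplets touching the frame edge are rejected: a partial droplet has no
    valid occupancy.
    """
    px = img.pixels
    r_prior = 0.5 * diameter_prior_um / img.um_per_px
    r_lo = max(4, int(math.floor(r_prior * (1 - radius_tolerance))))
    r_hi = int(math.ceil(r_prior * (1 + radius_tolerance)))
    edges = feature.canny(px, sigma=1.5)
    if not edges.any():
        raise DropletDetectionError("no edges found: frame appears blank")
    radii = np.arange(r_lo, r_hi + 1)
    accum = transform.hough_circle(edges, radii)
    _, cx, cy, rad = transform.hough_circle_peaks(accum, radii, total_num_peaks=8)
    if len(rad) == 0:
        raise DropletDetectionError("no circular object found in radius window")
    peak_vals = np.array(
        [accum[np.searchsorted(radii, r), y, x] for x, y, r in zip(cx, cy, rad)]
    )
    if peak_vals.max() < min_accumulator:
        raise DropletDetectionError(
            f"best circle accumulator {peak_vals.max():.2f} below "
            f"{min_accumulator}: no droplet outline"
        )
    # prefer the outer interface edge: largest radius among near-best peaks
    good = peak_vals >= 0.9 * peak_vals.max()
    i = int(np.flatnonzero(good)[np.argmax(rad[good])])
    x0, y0, r = float(cx[i]), float(cy[i]), float(rad[i])
    h, w = px.shape
    if x0 - r < 0 or y0 - r < 0 or x0 + r > w - 1 or y0 + r > h - 1:
        raise DropletDetectionError(
            "droplet touches the frame edge; partial droplets are rejected"
        )
    return DropletGeometry(center_xy=(x0, y0), radius_px=r, area_px=math.pi * r**2)


def _background_stats(px: np.ndarray, geom: DropletGeometry):
    h, w = px.shape
    yy, xx = np.mgrid[0:h, 0:w]
    x0, y0 = geom.center_xy
    dist2 = (xx - x0) ** 2 + (yy - y0) ** 2
    outside = dist2 > (1.1 * geom.radius_px) ** 2
    roi = dist2 <= (1.05 * geom.radius_px) ** 2
    bg = float(np.median(px[outside])) if outside.any() else float(np.median(px))
    sigma_bg = float(px[outside].std()) if outside.any() else 0.0
    p_dark = float(np.percentile(px[roi], 0.5))
    return bg, sigma_bg, p_dark, roi


def _lumen_mask(px, geom, bg, p_dark, roi):
    """Extract the droplet lumen: interior of the dark interface ring."""
    contrast = bg - p_dark
    if contrast <= 0:
        raise DropletDetectionError("no dark structure inside the detected circle")
    dark = (px < bg - 0.3 * contrast) & roi
    labels, n = ndimage.label(dark)
    if n == 0:
        raise DropletDetectionError("interface ring not found inside detected circle")
    # the interface ring is the dark component with the largest filled area;
    # a few-pixel size floor discards isolated noise specks
    sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n + 1))
    best_fill, ring = None, None
    for lab in np.flatnonzero(sizes >= 5) + 1:
        comp = labels == lab
        fill = ndimage.binary_fill_holes(comp)
        if best_fill is None or fill.sum() > best_fill.sum():
            best_fill, ring = fill, comp
    if ring is None:
        raise DropletDetectionError("interface ring not found inside detected circle")
    lumen = best_fill & ~ring
    # near-full droplets: cells merge with the ring, leaving no open lumen;
    # fall back to eroding the filled disk by the nominal ring width
    if lumen.sum() < 0.5 * best_fill.sum():
        lumen = morphology.erosion(best_fill, morphology.disk(2))
    return lumen


def segment_cells(
    img: DropletImage,
    geom: DropletGeometry,
    cells_darker: bool = True,
    open_radius: int = 1,
) -> tuple[float, float]:
    """Binarize the droplet lumen into cell / non-cell pixels.

    Returns ``(a_droplet_px, a_ex_px)``: the lumen area and the non-cell
    area within it. Thresholding (Otsu) is confined to the lumen. A lumen
    statistically indistinguishable from the oil background is reported as
    cell-free; a uniformly dark lumen as fully occupied.
    """
    px = img.pixels if cells_darker else 1.0 - img.pixels
    bg, sigma_bg, p_dark, roi = _background_stats(px, geom)
    lumen = _lumen_mask(px, geom, bg, p_dark, roi)
    a_droplet = float(lumen.sum())
    if a_droplet == 0:
        raise DropletDetectionError("empty lumen after ring extraction")
    vals = px[lumen]
    # degenerate (near-uniform) lumen: no Otsu split is meaningful
    uniform = np.ptp(vals) < 1e-12
    if not uniform:
        thresh = filters.threshold_otsu(vals)
        lo, hi = vals[vals <= thresh], vals[vals > thresh]
        separation = (hi.mean() - lo.mean()) if len(lo) and len(hi) else 0.0
        uniform = separation < max(6 * sigma_bg, 0.1 * (bg - p_dark))
    if uniform:
        if abs(float(np.median(vals)) - bg) <= 3 * sigma_bg + 1e-3:
            return a_droplet, a_droplet  # matches background: no cells
        return a_droplet, 0.0  # uniformly dark: fully occupied
    cell_mask = lumen & (px < thresh)
    if open_radius > 0:
        cell_mask = morphology.opening(cell_mask, morphology.disk(open_radius))
        cell_mask &= lumen
    a_cells = float(cell_mask.sum())
    return a_droplet, a_droplet - a_cells


def measure_image(
    img: DropletImage,
    geometry: DropletGeometry | None = None,
    diameter_prior_um: float = 120.0,
    cells_darker: bool = True,
    open_radius: int = 1,
) -> OccupancyMeasurement:
    """Full occupancy pipeline: detect -> segment -> occupancy formula.

    A user-supplied ``geometry`` (e.g. manual delineation) bypasses the
    Hough detection step.
    """
    if geometry is None:
        geometry = detect_droplet(img, diameter_prior_um=diameter_prior_um)
    a_droplet, a_ex = segment_cells(
        img, geometry, cells_darker=cells_darker, open_radius=open_radius
    )
    return OccupancyMeasurement(
        a_droplet_px=a_droplet,
        a_ex_px=a_ex,
        occupancy_pct=compute_occupancy(a_droplet, a_ex),
    )


def summarize_replicates(measurements) -> dict[str, float]:
    """Mean and SD of occupancy over replicate droplets (ddof=1)."""
    occ = np.array([m.occupancy_pct for m in measurements], dtype=float)
    if occ.size == 0:
        raise ValueError("no measurements to summarize")
    return {
        "n": int(occ.size),
        "mean_occupancy_pct": float(occ.mean()),
        "sd_occupancy_pct": float(occ.std(ddof=1)) if occ.size > 1 else 0.0,
    }


def write_droplet_image(path, img: DropletImage) -> None:
    """Write a droplet image as 16-bit grayscale TIFF (PNG by extension)."""
    data = np.clip(img.pixels, 0.0, 1.0)
    scaled = np.round(data * 65535).astype(np.uint16)
    path = str(path)
    if path.lower().endswith((".png",)):
        import imageio.v3 as iio

        iio.imwrite(path, scaled)
    else:
        import tifffile

        tifffile.imwrite(path, scaled)


def read_droplet_image(path, um_per_px: float) -> DropletImage:
    """Read a TIFF/PNG micrograph and normalize intensities to [0, 1]."""
    path = str(path)
    if path.lower().endswith(".png"):
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path))
    else:
        import tifffile

        raw = tifffile.imread(path)
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 3:  # collapse RGB(A) to grayscale
        raw = raw[..., :3].mean(axis=-1)
    if raw.max() > 1.0:
        raw = raw / (65535.0 if raw.max() > 255 else 255.0)
    return DropletImage(pixels=raw, um_per_px=um_per_px)
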