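"""Synthetic micrograph rendering and droplet detection.

The coarsening readout of the physical platform is real-time image
analysis of a droplet monolayer: detect the droplets in each frame,
convert pixel radii to µm, and track mean radius and polydispersity s/d
over time.  This module re-creates that readout against *synthetic*
frames rendered from simulated populations, with exact ground truth, so
the detector can be benchmarked and the whole simulation→imaging→metrics
chain checked end to end.

Rendering convention: droplets sit on a mid-grey background and are drawn
as a dark ring at the water/oil interface (the dominant feature of
bright-field droplet micrographs) with an interior slightly lighter than
the background.  The ring is drawn inward from the true radius so that the
filled detection mask has the droplet's true area.  This is a fixture
convention, not a claim about any particular optical setup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .dynamics import Population

__all__ = [
    "SyntheticFrame",
    "FramePlacementError",
    "render_frame",
    "detect_droplets",
    "track_coarsening",
    "write_frame",
    "read_frame",
]

BACKGROUND = 128
RING = 32
INTERIOR = 140
RING_WIDTH_PX = 2.0
MIN_RENDER_RADIUS_PX = 2.0


class FramePlacementError(RuntimeError):
    """The frame is too small to place all droplets without overlap."""


@dataclass
class SyntheticFrame:
    """A rendered monolayer image with ground-truth geometry.

    ``pixels`` is an 8-bit grayscale array; ``scale`` converts pixels to
    µm; ``ground_truth`` lists (center_x, center_y, radius) in pixels for
    every rendered droplet.
    """

    pixels: np.ndarray
    scale: float
    ground_truth: list[tuple[float, float, float]] = field(default_factory=list)
    time_stamp: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D uint8 array")
        if self.scale <= 0:
            raise ValueError("scale must be > 0 µm/px")


def render_frame(
    population: Population,
    scale: float,
    frame_size: int | tuple[int, int],
    noise_sd: float,
    rng: np.random.Generator,
    min_gap_px: float = 6.0,
    max_tries: int = 2000,
) -> SyntheticFrame:
    """Render a population as one synthetic monolayer frame.

    Droplets are placed by greedy dart throwing (largest first, seeded by
    ``rng``): random non-overlapping positions with at least ``min_gap_px``
    between interfaces and a full-droplet margin to the frame border, so
    every ground-truth circle lies fully inside the frame.  Additive
    Gaussian pixel noise of standard deviation ``noise_sd`` (intensity
    units) is applied and the result clipped to 8 bits.

    Raises
    ------
    FramePlacementError
        If placement fails; the message reports how many droplets did not
        fit.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0 µm/px")
    if isinstance(frame_size, int):
        shape = (frame_size, frame_size)
    else:
        shape = (int(frame_size[0]), int(frame_size[1]))
    radii_px = np.asarray(population.radius, dtype=float) / scale
    if population.n and radii_px.min() < MIN_RENDER_RADIUS_PX:
        raise FramePlacementError(
            f"smallest droplet renders below {MIN_RENDER_RADIUS_PX} px; "
            "decrease the µm/px scale"
        )
    order = np.argsort(radii_px)[::-1]
    placed: list[tuple[float, float, float]] = []
    overflow = 0
    h, w = shape
    for i in order:
        r = radii_px[i]
        margin = r + 2.0
        if 2 * margin >= min(h, w):
            overflow += 1
            continue
        ok = False
        for _ in range(max_tries):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 >= (r + pr + min_gap_px) ** 2
                for px, py, pr in placed
            ):
                placed.append((cx, cy, r))
                ok = True
                break
        if not ok:
            overflow += 1
    if overflow:
        raise FramePlacementError(
            f"frame {shape} too small: {overflow} of {population.n} droplets "
            "could not be placed without overlap"
        )

    img = np.full(shape, float(BACKGROUND))
    for cx, cy, r in placed:
        x0, x1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 2))
        y0, y1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx, yy - cy)
        tile = img[y0:y1, x0:x1]
        inner = max(r - RING_WIDTH_PX, 0.0)
        tile[dist <= r] = INTERIOR
        tile[(dist <= r) & (dist > inner)] = RING
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticFrame(
        pixels=pixels,
        scale=scale,
        ground_truth=placed,
        time_stamp=population.time,
    )


def detect_droplets(
    frame: SyntheticFrame,
    smooth_sigma: float = 0.5,
    min_area_px: float = 20.0,
) -> list[tuple[float, float, float]]:
    """Detect droplets in a frame; returns (center_x, center_y, radius) in px.

    Pipeline: Gaussian smoothing → global threshold by between-class
    variance maximisation (Otsu) isolating the dark interface rings →
    fill enclosed regions → connected components → discard components
    touching the border or smaller than ``min_area_px`` → report each
    component's centroid and equivalent-circle radius sqrt(area/π).
    Results are sorted by descending radius.  An empty frame yields an
    empty list.
    """
    img = frame.pixels.astype(float)
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    if img.max() == img.min():  # blank frame: no threshold exists
        return []
    thresh = filters.threshold_otsu(img)
    mask = img < thresh
    if not mask.any():
        return []
    mask = ndimage.binary_fill_holes(mask)
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        return []
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border & mask]))
    out = []
    for region in measure.regionprops(labels):
        if region.label in border_labels:
            continue
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        r = float(np.sqrt(region.area / np.pi))
        out.append((float(cx), float(cy), r))
    out.sort(key=lambda c: -c[2])
    return out


def track_coarsening(frames, smooth_sigma: float = 0.5, min_area_px: float = 20.0,
                     ddof: int = 1):
    """Track mean droplet radius and polydispersity across a frame series.

    Frames must be time-ordered and share one µm/px scale.  Each frame is
    detected independently; radii are converted to µm and summarised as
    (t, n_detected, mean radius, s/d).  A frame with fewer than two
    detections contributes missing statistics but does not stop the run.

    Returns a :class:`pandas.DataFrame` with columns ``t_s``,
    ``n_detected``, ``mean_radius_um``, ``s_over_d``.
    """
    import pandas as pd

    from . import metrics

    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")
    scales = {f.scale for f in frames}
    if len(scales) != 1:
        raise ValueError("all frames must share the same µm/px scale")
    rows = []
    for f in frames:
        detections = detect_droplets(f, smooth_sigma=smooth_sigma,
                                     min_area_px=min_area_px)
        radii_um = np.array([r for _, _, r in detections]) * f.scale
        if radii_um.size >= 2:
            stat = metrics.polydispersity(radii_um, ddof=ddof)
            mean_r, s_over_d = stat.d, stat.ratio
        elif radii_um.size == 1:
            mean_r, s_over_d = float(radii_um[0]), float("nan")
        else:
            mean_r, s_over_d = float("nan"), float("nan")
        rows.append(
            {
                "t_s": f.time_stamp,
                "n_detected": int(radii_um.size),
                "mean_radius_um": mean_r,
                "s_over_d": s_over_d,
            }
        )
    return pd.DataFrame(rows)


def write_frame(frame: SyntheticFrame, path) -> None:
    """Write a frame as 8-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(str(path), frame.pixels)


def read_frame(path, scale: float, time_stamp: float = 0.0) -> SyntheticFrame:
    """Read an 8-bit grayscale TIFF as a frame (no ground truth)."""
    import tifffile

    pixels = tifffile.imread(str(path))
    return SyntheticFrame(pixels=np.asarray(pixels, dtype=np.uint8), scale=scale,
                          time_stamp=time_stamp)
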