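"""AFM height-image volumetrics and oligomer-state assignment.

The processing chain mirrors standard AFM practice for single-molecule
volumetry: three-point plane levelling (with patch averaging around the
anchors), Gaussian smoothing, masking of structures above half the maximum
height of the raw image, per-particle volume integration with local
background subtraction, a fixed-kernel experimental pdf over the volumes,
multi-Gaussian decomposition, and classification of each particle into the
oligomeric state whose segment (bounded by midpoints between adjacent fitted
peak means) contains its volume.

Note on integration support: the half-height mask cuts a smooth particle
profile well inside its tails (for a 2D Gaussian of peak height A cut at
height c*A, the mask holds only a (1-c) fraction of the volume). Volumes are
therefore integrated over a dilated copy of each mask component, with the
local background taken as the median of a ring outside the dilation; the
dilation radius is configurable and the mask itself still defines particle
identity, pixel counts and border contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.ndimage import binary_dilation
from skimage.filters import gaussian as _gaussian_filter
from skimage.measure import label as _label, regionprops
from skimage.morphology import disk

from .densities import EventPdf, MixtureFit, build_pdf, fit_multi_gaussian
from .errors import InvalidInputError

DEFAULT_VOLUME_KERNEL_SD = 4.0  # nm^3, instrument error of one volume measurement


@dataclass
class HeightMap:
    """2D height image in nm with a square pixel size in nm."""

    heights: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise InvalidInputError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise InvalidInputError("heights must be finite")
        if not self.pixel_size > 0:
            raise InvalidInputError("pixel_size must be > 0")

    @property
    def shape(self):
        return self.heights.shape


@dataclass
class ParticleRecord:
    label: int
    pixel_count: int
    volume: float  # nm^3
    centroid: tuple  # (row, col) in pixels
    touches_border: bool


@dataclass
class OligomerModel:
    """Oligomer-state decomposition of a particle-volume distribution."""

    peak_means: np.ndarray  # nm^3, ascending
    boundaries: np.ndarray  # nm^3, midpoints between adjacent peaks
    counts: np.ndarray
    fractions: np.ndarray
    n_total: int
    mixture: MixtureFit | None = None
    assignments: np.ndarray | None = None  # state index (0-based) per volume


def _patch_mean(img: np.ndarray, point, patch: int) -> float:
    r, c = int(point[0]), int(point[1])
    h = patch // 2
    r0, r1 = max(0, r - h), min(img.shape[0], r + h + 1)
    c0, c1 = max(0, c - h), min(img.shape[1], c + h + 1)
    return float(img[r0:r1, c0:c1].mean())


def level_plane(img: HeightMap, anchors: Sequence, patch: int = 5) -> HeightMap:
    """Subtract the plane through three patch-averaged anchor points.

    ``anchors`` are three (row, col) pixel positions; the plane is fixed by
    the mean height of a ``patch`` x ``patch`` neighbourhood around each.
    Collinear anchors are rejected.
    """
    if len(anchors) != 3:
        raise InvalidInputError("exactly three anchor points are required")
    pts = np.asarray(anchors, dtype=float)
    for r, c in pts:
        if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
            raise InvalidInputError(f"anchor ({r}, {c}) outside the image")
    area2 = abs((pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1])
                - (pts[2, 0] - pts[0, 0]) * (pts[1, 1] - pts[0, 1]))
    if area2 < 1e-9:
        raise InvalidInputError("anchor points are collinear")
    z = np.array([_patch_mean(img.heights, p, patch) for p in pts])
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(3)])
    a, b, c0 = np.linalg.solve(A, z)
    rows, cols = np.mgrid[0: img.shape[0], 0: img.shape[1]]
    plane = a * rows + b * cols + c0
    return HeightMap(heights=img.heights - plane, pixel_size=img.pixel_size,
                     metadata={**img.metadata, "leveled": True})


def smooth(img: HeightMap, sigma_px: float) -> HeightMap:
    """Gaussian smoothing with reflective borders; ``sigma_px = 0`` is the
    identity."""
    if sigma_px < 0:
        raise InvalidInputError("sigma_px must be >= 0")
    if sigma_px == 0:
        out = img.heights.copy()
    else:
        out = _gaussian_filter(img.heights, sigma=sigma_px, mode="reflect",
                               preserve_range=True)
    return HeightMap(heights=out, pixel_size=img.pixel_size,
                     metadata={**img.metadata, "smoothed_sigma_px": sigma_px})


def mask_particles(raw: HeightMap, processed: HeightMap,
                   min_pixels: int = 4) -> np.ndarray:
    """Label particles above half the maximum height of the raw image.

    The threshold is 0.5 x max(raw heights) but is applied to the
    levelled-and-smoothed image; components are 8-connected and those with
    fewer than ``min_pixels`` pixels are dropped. Returns the labelled mask
    (all zeros when nothing survives).
    """
    if raw.shape != processed.shape:
        raise InvalidInputError("raw and processed images must be congruent")
    threshold = 0.5 * float(raw.heights.max())
    bw = processed.heights > threshold
    labels = _label(bw, connectivity=2)
    for region in regionprops(labels):
        if region.num_pixels < min_pixels:
            labels[labels == region.label] = 0
    # relabel compactly
    return _label(labels > 0, connectivity=2)


def particle_volumes(labels: np.ndarray, leveled: HeightMap,
                     integration_dilation: int = 8,
                     ring_width: int = 2,
                     min_pixels: int = 4) -> list[ParticleRecord]:
    """Integrate each labelled particle's volume (nm^3).

    volume = sum(height - local background) * pixel_size^2 over the
    component dilated by ``integration_dilation`` pixels (capturing the
    profile tails the half-height mask cuts off); the local background is
    the median height of a ``ring_width``-pixel ring outside the dilated
    support, excluding any other particle's support.
    """
    if labels.shape != leveled.shape:
        raise InvalidInputError("labels and image must be congruent")
    px2 = leveled.pixel_size**2
    h = leveled.heights
    any_support = binary_dilation(labels > 0, structure=disk(integration_dilation))
    records = []
    for region in regionprops(labels):
        core = labels == region.label
        support = binary_dilation(core, structure=disk(integration_dilation))
        ring = binary_dilation(support, structure=disk(ring_width)) & ~support & ~any_support
        if not ring.any():
            ring = binary_dilation(support, structure=disk(ring_width)) & ~support
        bg = float(np.median(h[ring])) if ring.any() else 0.0
        volume = float(np.sum(h[support] - bg) * px2)
        rr = region.bbox
        touches = (rr[0] == 0 or rr[1] == 0
                   or rr[2] == labels.shape[0] or rr[3] == labels.shape[1])
        if volume <= 0 or region.num_pixels < min_pixels:
            continue
        records.append(ParticleRecord(
            label=int(region.label), pixel_count=int(region.num_pixels),
            volume=volume, centroid=tuple(float(c) for c in region.centroid),
            touches_border=bool(touches)))
    return records


def volume_pdf(volumes: Sequence[float],
               kernel_sd: float = DEFAULT_VOLUME_KERNEL_SD) -> EventPdf:
    """Experimental pdf over particle volumes with a constant kernel width
    (the instrument's volume measurement error)."""
    v = np.asarray(volumes, dtype=float)
    return build_pdf(v, np.full(v.shape, float(kernel_sd)))


def count_states(pdf: EventPdf, prominence_fraction: float = 0.05) -> int:
    """Number of local maxima of the pdf above a prominence floor."""
    peaks, _ = find_peaks(pdf.density, prominence=prominence_fraction * pdf.density.max())
    return max(1, int(peaks.size))


def assign_oligomer_states(pdf: EventPdf, volumes: Sequence[float],
                           n_states: int | None = None) -> OligomerModel:
    """Decompose the volume pdf into oligomer states and classify particles.

    The pdf is fitted with ``n_states`` Gaussians (default: the number of
    local maxima above a 5% prominence floor); classification boundaries sit
    at the midpoints between adjacent fitted peak means (equidistant
    segments), and each volume is assigned to the state whose segment
    contains it. Peaks closer than one kernel width are merged with a
    warning.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise InvalidInputError("no volumes to classify")
    if n_states is None:
        n_states = count_states(pdf)
    if n_states < 1:
        raise InvalidInputError("n_states must be >= 1")

    if n_states == 1:
        mixture = fit_multi_gaussian(pdf, 1)
        means = mixture.means
    else:
        mixture = fit_multi_gaussian(pdf, n_states)
        means = mixture.means
        kernel = float(np.median(pdf.kernel_sigmas))
        merged = [means[0]]
        for mu in means[1:]:
            if mu - merged[-1] < kernel:
                warnings.warn(
                    f"oligomer peaks at {merged[-1]:.1f} and {mu:.1f} nm^3 are "
                    "closer than one kernel width; merging", stacklevel=2)
                merged[-1] = 0.5 * (merged[-1] + mu)
            else:
                merged.append(mu)
        means = np.asarray(merged)

    boundaries = 0.5 * (means[:-1] + means[1:]) if means.size > 1 else np.array([])
    assignments = np.searchsorted(boundaries, v)
    counts = np.bincount(assignments, minlength=means.size)
    fractions = counts / v.size
    return OligomerModel(peak_means=np.asarray(means), boundaries=boundaries,
                         counts=counts, fractions=fractions, n_total=int(v.size),
                         mixture=mixture, assignments=assignments)


def synth_afm_image(
    volumes: Sequence[float],
    rng: np.random.Generator,
    positions: Sequence | None = None,
    shape: tuple = (256, 256),
    pixel_size: float = 0.5,
    peak_height: float = 2.0,
    tilt: tuple = (0.002, 0.004),
    noise_sigma: float = 0.05,
    min_separation: float = 14.0,
) -> tuple[HeightMap, dict]:
    """Render a synthetic height image of Gaussian-profile particles.

    Each particle has the requested integrated volume (nm^3) and a common
    peak height (nm), so its lateral width scales with sqrt(volume) -- the
    behaviour of compact molecules lying on the support imaged with a finite
    tip. Particles sit on a tilted plane (``tilt`` in nm per nm along
    rows/cols) with additive white Gaussian height noise. When ``positions``
    (in nm) is omitted, particles are placed uniformly with a minimum
    centre-to-centre separation. Returns the raw image and a ground-truth
    dict.
    """
    vols = np.asarray(volumes, dtype=float)
    if np.any(vols <= 0):
        raise InvalidInputError("volumes must be > 0")
    ny, nx = shape
    extent = (ny * pixel_size, nx * pixel_size)
    if positions is None:
        positions = []
        margin = 8.0
        for _ in range(vols.size):
            for _try in range(20000):
                cand = (rng.uniform(margin, extent[0] - margin),
                        rng.uniform(margin, extent[1] - margin))
                if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_separation**2
                       for p in positions):
                    positions.append(cand)
                    break
            else:
                raise InvalidInputError(
                    "could not place particles at the requested density; "
                    "reduce their number or min_separation")
    positions = np.asarray(positions, dtype=float)

    rows = (np.arange(ny) + 0.5) * pixel_size
    cols = (np.arange(nx) + 0.5) * pixel_size
    R, C = np.meshgrid(rows, cols, indexing="ij")
    img = tilt[0] * R + tilt[1] * C
    for (r0, c0), vol in zip(positions, vols):
        sigma2 = vol / (2.0 * np.pi * peak_height)  # nm^2
        img += peak_height * np.exp(-((R - r0) ** 2 + (C - c0) ** 2) / (2.0 * sigma2))
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    truth = {"positions_nm": positions, "volumes_nm3": vols,
             "peak_height_nm": peak_height, "tilt": tilt,
             "noise_sigma_nm": noise_sigma}
    return HeightMap(heights=img, pixel_size=pixel_size,
                     metadata={"synthetic": True}), truth
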