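"""Experimental probability density functions and their decomposition.

An "experimental pdf" is the continuous-histogram equivalent used throughout
force spectroscopy: each measured value contributes a unit-area Gaussian
whose width is that measurement's own error (the per-curve force-noise
amplitude for rupture forces, a fixed instrument error for AFM volumes).
Summing the Gaussians and dividing by the number of events gives a density
free of binning artefacts, at the price of convolution broadening: a peak
built from samples of SD s with kernel width k appears with SD
sqrt(s^2 + k^2).

Multi-Gaussian decomposition is performed on the density curve itself
(nonlinear least squares), not by expectation-maximization on the raw
samples, to stay in register with how such pdfs are analysed in the
dynamic-force-spectroscopy literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from lmfit.models import GaussianModel
from scipy.signal import find_peaks

from .curves import RuptureEvent
from .errors import InsufficientDataError, InvalidInputError, NumericsError

logger = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class EventPdf:
    """Heteroscedastic Gaussian-sum density on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    kernel_sigmas: np.ndarray
    n_events: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


@dataclass
class MixtureFit:
    """Multi-Gaussian decomposition of an :class:`EventPdf`.

    ``components`` is a list of ``(weight, mean, sd)`` sorted by ascending
    mean; weights are component areas (fractions of the unit-area pdf).
    ``flagged`` marks surplus components whose weight fell below the floor.
    """

    components: list[tuple[float, float, float]]
    residual_norm: float
    flagged: list[int]

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])


@dataclass
class LoadingRateSegment:
    """Events falling between two half-decade loading-rate boundaries."""

    log10_lo: float
    log10_hi: float
    events: list[RuptureEvent]
    representative_rate: float  # geometric mean of member loading rates, pN/s
    peak_mean: float | None = None  # pN
    peak_sd: float | None = None  # pN

    @property
    def n_events(self) -> int:
        return len(self.events)


def build_pdf(values: Sequence[float], sigmas: Sequence[float],
              grid_step: float | None = None) -> EventPdf:
    """Sum unit-area Gaussians centred at ``values`` with widths ``sigmas``.

    The grid spans [min - 4 sigma_max, max + 4 sigma_max] with step
    ``grid_step`` (default: min(sigmas)/4, resolving the narrowest kernel).
    The tabulated density is renormalized by its trapezoidal integral so the
    stored curve integrates to one despite the 4-sigma tail truncation.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if v.size == 0 or v.shape != s.shape:
        raise InvalidInputError("values and sigmas must be equal-length, non-empty")
    if np.any(s <= 0) or not np.all(np.isfinite(s)) or not np.all(np.isfinite(v)):
        raise InvalidInputError("sigmas must be finite and > 0, values finite")
    if grid_step is None:
        grid_step = float(np.min(s)) / 4.0
    smax = float(np.max(s))
    lo, hi = float(np.min(v)) - 4.0 * smax, float(np.max(v)) + 4.0 * smax
    grid = np.arange(lo, hi + grid_step, grid_step)
    z = (grid[None, :] - v[:, None]) / s[:, None]
    density = np.sum(np.exp(-0.5 * z**2) / (s[:, None] * _SQRT2PI), axis=0) / v.size
    density /= np.trapezoid(density, grid)
    return EventPdf(grid=grid, density=density, kernel_sigmas=s, n_events=int(v.size))


def _initial_centers(pdf: EventPdf, n_components: int) -> list[int]:
    """Indices of initial component centres: the tallest local maxima,
    padded with quantile positions if the density has too few peaks."""
    peaks, props = find_peaks(pdf.density, prominence=0.01 * pdf.density.max())
    order = np.argsort(pdf.density[peaks])[::-1]
    centers = list(peaks[order][:n_components])
    if len(centers) < n_components:
        cdf = np.cumsum(pdf.density)
        cdf /= cdf[-1]
        for q in np.linspace(0.15, 0.85, n_components):
            if len(centers) >= n_components:
                break
            i = int(np.searchsorted(cdf, q))
            if all(abs(i - c) > 2 for c in centers):
                centers.append(i)
    return centers[:n_components]


def fit_multi_gaussian(pdf: EventPdf, n_components: int,
                       weight_floor: float = 0.02) -> MixtureFit:
    """Least-squares fit of a sum of ``n_components`` Gaussians to the
    density curve, initialized from its largest local maxima.

    Components are returned sorted by mean; those with area below
    ``weight_floor`` are flagged as surplus.
    """
    if n_components < 1:
        raise InvalidInputError("n_components must be >= 1")
    centers = _initial_centers(pdf, n_components)
    width0 = max(float(np.median(pdf.kernel_sigmas)), 2.0 * (pdf.grid[1] - pdf.grid[0]))
    span = pdf.grid[-1] - pdf.grid[0]

    model, params = None, None
    for i, c in enumerate(centers):
        g = GaussianModel(prefix=f"g{i}_")
        p = g.make_params(
            center=float(pdf.grid[c]),
            sigma=width0,
            amplitude=float(pdf.density[c]) * width0 * _SQRT2PI,
        )
        p[f"g{i}_sigma"].set(min=0.2 * width0, max=span)
        p[f"g{i}_center"].set(min=float(pdf.grid[0]), max=float(pdf.grid[-1]))
        p[f"g{i}_amplitude"].set(min=0.0)
        if model is None:
            model, params = g, p
        else:
            model = model + g
            params.update(p)

    result = model.fit(pdf.density, params, x=pdf.grid)
    if not result.success:
        raise NumericsError(
            "multi-Gaussian fit did not converge",
            diagnostics={"initial_centers": [float(pdf.grid[c]) for c in centers],
                         "message": result.message},
        )
    comps = []
    for i in range(n_components):
        w = float(result.params[f"g{i}_amplitude"].value)
        mu = float(result.params[f"g{i}_center"].value)
        sd = float(result.params[f"g{i}_sigma"].value)
        comps.append((w, mu, sd))
    comps.sort(key=lambda c: c[1])
    flagged = [i for i, c in enumerate(comps) if c[0] < weight_floor]
    resid = float(np.sqrt(np.mean(result.residual**2)))
    return MixtureFit(components=comps, residual_norm=resid, flagged=flagged)


def segment_by_loading_rate(events: Sequence[RuptureEvent],
                            min_count: int = 20) -> list[LoadingRateSegment]:
    """Partition events into half-decade loading-rate segments.

    Boundaries sit at 10^(k/2), i.e. two segments per decade with
    equidistant boundaries on the log axis. Segments with fewer than
    ``min_count`` events are excluded (and logged). The representative
    loading rate of a segment is the geometric mean of its members' rates.
    """
    if len(events) == 0:
        raise InsufficientDataError("no events to segment")
    rates = np.array([e.loading_rate for e in events])
    if np.any(rates <= 0):
        raise InvalidInputError("all loading rates must be > 0")
    bin_index = np.floor(2.0 * np.log10(rates)).astype(int)
    segments = []
    for b in np.unique(bin_index):
        members = [e for e, k in zip(events, bin_index) if k == b]
        if len(members) < min_count:
            logger.info("excluding loading-rate segment [10^%.1f, 10^%.1f) with %d < %d events",
                        b / 2.0, (b + 1) / 2.0, len(members), min_count)
            continue
        rep = float(np.exp(np.mean(np.log([e.loading_rate for e in members]))))
        segments.append(LoadingRateSegment(
            log10_lo=b / 2.0, log10_hi=(b + 1) / 2.0,
            events=members, representative_rate=rep,
        ))
    if not segments:
        raise InsufficientDataError(
            f"no loading-rate segment holds >= {min_count} events")
    return segments


def segment_peak_stats(segment: LoadingRateSegment) -> LoadingRateSegment:
    """Fit a single Gaussian to the maximum peak of the segment's force pdf.

    The pdf is built from member forces with their per-event noise widths;
    the fit window is +/- 2x the median kernel width around the highest local
    maximum. Returns a copy of the segment with ``peak_mean``/``peak_sd``
    filled in.
    """
    if segment.n_events < 20:
        raise InsufficientDataError("segment peak statistics require >= 20 events")
    forces = [e.unbinding_force for e in segment.events]
    sigmas = [e.noise_sigma for e in segment.events]
    pdf = build_pdf(forces, sigmas)
    peaks, _ = find_peaks(pdf.density)
    i0 = int(peaks[np.argmax(pdf.density[peaks])]) if peaks.size else int(np.argmax(pdf.density))
    med = float(np.median(pdf.kernel_sigmas))
    window = (pdf.grid >= pdf.grid[i0] - 2 * med) & (pdf.grid <= pdf.grid[i0] + 2 * med)

    g = GaussianModel()
    params = g.make_params(center=float(pdf.grid[i0]), sigma=med,
                           amplitude=float(pdf.density[i0]) * med * _SQRT2PI)
    params["sigma"].set(min=pdf.grid[1] - pdf.grid[0])
    result = g.fit(pdf.density[window], params, x=pdf.grid[window])
    if not result.success:
        raise NumericsError("segment peak fit failed",
                            diagnostics={"message": result.message})
    return replace(segment,
                   peak_mean=float(result.params["center"].value),
                   peak_sd=float(result.params["sigma"].value))
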