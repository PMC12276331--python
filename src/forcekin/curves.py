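"""Rupture-event extraction from force-distance retract traces.

A retract trace is stored with the pulling force positive: the adhesive
tether load rises nonlinearly with tip-sample distance and collapses to the
baseline in one or more abrupt drops when bonds rupture. Event detection is
threshold-based on the per-curve noise amplitude: a drop of at least
``min_drop_sigma`` noise standard deviations completed within
``max_drop_width`` nm of tip travel, preceded by an adhesive rise, is an
unbinding event. For each event the unbinding force, the effective spring
constant (local slope of the force-distance curve before the drop), the
unbinding length and the loading rate (slope times pulling speed) are
recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidInputError


@dataclass
class ForceCurve:
    """One retract trace.

    ``distance`` (nm, strictly increasing, zero at the start of retraction)
    and ``force`` (pN, pulling positive) of equal length, with acquisition
    metadata.
    """

    distance: np.ndarray
    force: np.ndarray
    pulling_speed: float  # um/s
    contact_time: float  # s
    curve_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.distance.shape != self.force.shape or self.distance.ndim != 1:
            raise InvalidInputError("distance and force must be equal-length 1-D arrays")
        if np.any(np.diff(self.distance) <= 0):
            raise InvalidInputError("distance must be strictly increasing")
        if not self.pulling_speed > 0:
            raise InvalidInputError("pulling_speed must be > 0")

    def __len__(self):
        return len(self.distance)


@dataclass
class RuptureEvent:
    """One unbinding event extracted from a curve."""

    unbinding_force: float  # pN
    effective_spring_constant: float  # pN/nm
    loading_rate: float  # pN/s
    unbinding_length: float  # nm
    noise_sigma: float  # pN
    rank: int  # 1-based order within its curve
    curve_id: str = ""

    def __post_init__(self):
        if not self.unbinding_force > 0:
            raise InvalidInputError("unbinding_force must be > 0")
        if not self.loading_rate > 0:
            raise InvalidInputError("loading_rate must be > 0")


def estimate_noise(curve: ForceCurve, baseline_fraction: float = 0.2,
                   min_points: int = 50) -> float:
    """Force-noise amplitude (pN): SD of the trailing post-detachment baseline
    after linear detrending.

    The baseline window is the trailing ``baseline_fraction`` of the trace.
    If it holds fewer than ``min_points`` samples, fall back to a robust MAD
    estimate over the whole linearly-detrended trace (with a warning).
    """
    n = len(curve)
    nb = int(round(n * baseline_fraction))
    if nb >= min_points:
        d = curve.distance[-nb:]
        f = curve.force[-nb:]
        trend = np.polyval(np.polyfit(d, f, 1), d)
        return float(np.std(f - trend, ddof=1))
    warnings.warn(
        f"baseline window has {nb} < {min_points} points; "
        "falling back to whole-trace MAD estimate",
        stacklevel=2,
    )
    trend = np.polyval(np.polyfit(curve.distance, curve.force, 1), curve.distance)
    resid = curve.force - trend
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def _find_contact_point(force_s: np.ndarray, distance: np.ndarray, first_event: int) -> float:
    """Last zero-crossing of the smoothed force before the adhesive rise."""
    seg = force_s[: first_event + 1]
    below = np.nonzero(seg <= 0)[0]
    if below.size == 0:
        return float(distance[0])
    return float(distance[below[-1]])


def detect_ruptures(
    curve: ForceCurve,
    min_drop_sigma: float = 4.0,
    max_drop_width: float = 2.0,
    slope_window: float = 10.0,
    sigma: float | None = None,
    smooth_points: int = 3,
    min_drop_abs: float = 2.0,
) -> list[RuptureEvent]:
    """Detect unbinding events in one retract trace.

    An event is a force drop of at least ``max(min_drop_sigma * sigma,
    min_drop_abs)`` pN completed within ``max_drop_width`` nm of tip travel,
    whose pre-drop force itself clears the same threshold (which suppresses
    pure-noise excursions) and which is preceded by a rising adhesive load.
    The effective spring constant is the absolute slope of a linear fit over
    the ``slope_window`` nm preceding the drop (truncated at the previous
    event), and the loading rate is that slope times the pulling speed.

    Returns events ordered by distance with 1-based ranks (empty list when
    nothing is found).
    """
    if sigma is None:
        sigma = estimate_noise(curve)
    d, f = curve.distance, curve.force
    n = len(curve)
    dx = float(np.median(np.diff(d)))
    fs = uniform_filter1d(f, size=max(1, smooth_points), mode="nearest")

    threshold = max(min_drop_sigma * sigma, min_drop_abs)
    w = max(1, int(round(max_drop_width / dx)))
    if n <= w + 2:
        return []

    # drop[i]: largest force decrease from i completed within the next w samples
    future = np.lib.stride_tricks.sliding_window_view(fs[1:], w).min(axis=1)
    drop = fs[: n - w] - future
    candidate = (drop >= threshold) & (fs[: n - w] >= threshold)

    events: list[RuptureEvent] = []
    idx = np.nonzero(candidate)[0]
    if idx.size == 0:
        return []
    # group contiguous candidate runs; each run is one putative event
    splits = np.nonzero(np.diff(idx) > 1)[0] + 1
    groups = np.split(idx, splits)

    prev_end = 0
    for g in groups:
        i_peak = int(g[np.argmax(fs[g])])
        # smoothing drags the argmax one sample early; step to the raw peak
        for _ in range(2):
            if i_peak + 1 < n and f[i_peak + 1] > f[i_peak]:
                i_peak += 1
        # require an adhesive rise before the drop
        w0 = max(prev_end, int(np.searchsorted(d, d[i_peak] - slope_window)))
        if i_peak - w0 < 3:
            w0 = max(prev_end, i_peak - 3)
        if i_peak - w0 < 2:
            continue
        slope = np.polyfit(d[w0 : i_peak + 1], f[w0 : i_peak + 1], 1)[0]
        if slope <= 0:
            continue
        # backward mean avoids averaging post-drop samples into the force;
        # the fitted slope corrects its one-sample lag on the rising flank
        f_pre = float(np.mean(f[max(i_peak - 2, 0) : i_peak + 1])) + abs(float(slope)) * dx
        events.append((i_peak, f_pre, abs(float(slope))))
        prev_end = i_peak + w

    if not events:
        return []
    first_event = events[0][0]
    d_contact = _find_contact_point(fs, d, first_event)

    speed_nm_s = curve.pulling_speed * 1e3
    out = []
    for rank, (i_peak, force, k) in enumerate(events, start=1):
        out.append(
            RuptureEvent(
                unbinding_force=force,
                effective_spring_constant=k,
                loading_rate=k * speed_nm_s,
                unbinding_length=float(d[i_peak] - d_contact),
                noise_sigma=sigma,
                rank=rank,
                curve_id=curve.curve_id,
            )
        )
    return out


def binding_probability(events_per_curve: Sequence[int]) -> tuple[float, tuple[float, float]]:
    """Fraction of curves with at least one unbinding event, with a 95%
    Wilson score interval.

    ``events_per_curve`` holds the event count of every recorded curve
    (zeros included).
    """
    counts = np.asarray(events_per_curve)
    if counts.size == 0:
        raise InvalidInputError("binding_probability requires at least one curve")
    k = int(np.count_nonzero(counts > 0))
    n = counts.size
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(lo), float(hi))


def classify_pattern(
    events: Sequence[RuptureEvent],
    single_force_ref: float,
    tolerance: float = 0.25,
) -> str:
    """Classify the rupture pattern of one curve.

    ``single_force_ref`` is the monovalent peak force from the mixture
    decomposition. No event: ``"none"``; two or more events:
    ``"sequential"``; one event within ``tolerance`` (relative) of twice the
    reference: ``"simultaneous"``; otherwise ``"single"``.
    """
    if not single_force_ref > 0:
        raise InvalidInputError("single_force_ref must be > 0")
    if len(events) == 0:
        return "none"
    if len(events) >= 2:
        return "sequential"
    f = events[0].unbinding_force
    if abs(f - 2.0 * single_force_ref) <= tolerance * 2.0 * single_force_ref:
        return "simultaneous"
    return "single"
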