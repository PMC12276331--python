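"""Kinetic-rate inference from force-spectroscopy observables.

Two independent experiments feed this module. The dynamic force spectrum
(most-probable rupture force vs. loading rate across half-decade segments)
yields the dissociation rate ``k_off`` and barrier width ``x_beta`` through a
weighted linear Bell-Evans fit in semi-log coordinates; the Williams
parallel-bond model then predicts the double-bond branch of the force
spectrum and the effective double-bond off-rate ``k_off,2 = (2/3) k_off``
with no extra free parameters. The binding probability vs. contact time
curve, P(t) = A (1 - exp(-(t - t0)/tau)), yields the interaction time tau of
pseudo-first-order association; with the effective concentration of the
single tethered ligand (hemispherical reach volume) this becomes a
bimolecular ``k_on = 1/(tau c_eff)``, while the second-bond curve gives the
unimolecular ``k_2 = 1/tau_2`` directly.

Standard errors are carried in log10 decades throughout, matching the
"mantissa x 10^(exponent +/- error)" convention of kinetic summary tables;
derived quantities combine errors in log-domain quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

from .bond_physics import (
    DEFAULT_KBT,
    BellParams,
    ParallelBondSpec,
    effective_concentration,
    koff_parallel,
    williams_force,
)
from .densities import LoadingRateSegment
from .errors import InsufficientDataError, InvalidInputError, NumericsError

LN10 = math.log(10.0)

__all__ = [
    "BellEvansFit", "KineticsFit", "RateTable", "fit_bell_evans",
    "predict_double_bond_overlay", "binding_probability_curve",
    "fit_binding_kinetics", "effective_concentration", "compute_kon",
    "compute_k2", "compute_affinity", "bond_lifetime", "summarize_rates",
    "compare_binding_probabilities", "GroupComparison",
]


@dataclass
class BellEvansFit:
    """Result of the weighted Bell-Evans fit of a dynamic force spectrum."""

    params: BellParams
    se_log10_koff: float  # decades
    se_xbeta: float  # nm
    n_segments: int
    weighted_residual: float

    def __post_init__(self):
        if self.se_log10_koff < 0 or self.se_xbeta < 0:
            raise InvalidInputError("standard errors must be >= 0")
        if self.n_segments < 3:
            raise InsufficientDataError("a reported Bell-Evans fit requires >= 3 segments")


@dataclass
class KineticsFit:
    """Pseudo-first-order binding-probability fit P(t) = A(1-exp(-(t-t0)/tau))."""

    A: float
    t0: float  # s
    tau: float  # s
    se_log10_A: float
    se_log10_t0: float
    se_log10_tau: float
    bond_order: int = 1

    def __post_init__(self):
        if not (0 < self.A <= 1):
            raise InvalidInputError(f"A must lie in (0, 1], got {self.A}")
        if not self.tau > 0:
            raise InvalidInputError("tau must be > 0")


def fit_bell_evans(segments: Sequence[LoadingRateSegment],
                   kBT: float = DEFAULT_KBT) -> BellEvansFit:
    """Weighted least squares of segment peak force vs. ln(loading rate).

    The Bell-Evans relation F* = (kBT/x_beta) ln(r_f x_beta / (k_off kBT)) is
    linear in ln r_f with slope m = kBT/x_beta and intercept
    b = m ln(x_beta/(k_off kBT)), so x_beta = kBT/m and
    k_off = exp(-b/m)/m. Weights are 1/peak_sd^2 taken as absolute
    measurement errors: the parameter covariance is (X' W X)^-1 without
    residual-variance rescaling, so scaling every peak_sd by c scales every
    standard error by c while leaving the point estimates untouched.
    """
    segs = [s for s in segments if s.peak_mean is not None and s.peak_sd is not None]
    if len(segs) < 3:
        raise InsufficientDataError(
            f"Bell-Evans fit requires >= 3 segments with peak statistics, got {len(segs)}")
    x = np.array([math.log(s.representative_rate) for s in segs])
    y = np.array([s.peak_mean for s in segs])
    w = np.array([1.0 / s.peak_sd**2 for s in segs])

    X = np.column_stack([x, np.ones_like(x)])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    m, b = float(beta[0]), float(beta[1])
    if m <= 0:
        raise NumericsError("Bell-Evans slope is non-positive; force spectrum "
                            "does not increase with loading rate",
                            diagnostics={"slope": m, "intercept": b})
    x_beta = kBT / m
    k_off = math.exp(-b / m) / m

    # delta method on ln k_off = -ln m - b/m and x_beta = kBT/m
    g = np.array([-1.0 / m + b / m**2, -1.0 / m])
    var_ln_koff = float(g @ cov @ g)
    se_log10_koff = math.sqrt(max(var_ln_koff, 0.0)) / LN10
    se_xbeta = kBT / m**2 * math.sqrt(cov[0, 0])
    resid = float(np.sum(w * (y - X @ beta) ** 2))
    return BellEvansFit(
        params=BellParams(k_off=k_off, x_beta=x_beta, kBT=kBT),
        se_log10_koff=se_log10_koff,
        se_xbeta=se_xbeta,
        n_segments=len(segs),
        weighted_residual=resid,
    )


def predict_double_bond_overlay(fit: BellEvansFit, rates) -> np.ndarray:
    """Zero-free-parameter Williams (N=2) force-vs-loading-rate overlay."""
    spec = ParallelBondSpec(n_bonds=2, params=fit.params)
    return np.asarray(williams_force(np.asarray(rates, dtype=float), spec))


def binding_probability_curve(t, A: float, t0: float, tau: float):
    """P(t) = A (1 - exp(-(t - t0)/tau)), clamped to [0, 1] and 0 for t <= t0."""
    t = np.asarray(t, dtype=float)
    p = A * -np.expm1(-(t - t0) / tau)
    return np.clip(np.where(t <= t0, 0.0, p), 0.0, 1.0)


def fit_binding_kinetics(
    contact_times: Sequence[float],
    probabilities: Sequence[float],
    uncertainties: Sequence[float] | None = None,
    bond_order: int = 1,
    fix_t0: float | None = None,
) -> KineticsFit:
    """Least-squares fit of the pseudo-first-order binding-probability curve.

    ``uncertainties`` (binomial SEs of the measured probabilities) enter as
    weights when given. For ``bond_order == 2`` the lag time is fixed at 0
    unless ``fix_t0`` overrides it. Requires >= 4 contact times; a flat,
    nonzero probability profile is rejected as unidentifiable rather than
    silently fitted.
    """
    t = np.asarray(contact_times, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("binding-kinetics fit requires >= 4 contact times")
    if t.shape != p.shape:
        raise InvalidInputError("contact_times and probabilities must match in length")
    if np.ptp(p) < 1e-12 and p.max() > 0:
        raise InsufficientDataError(
            "binding probability is constant and nonzero across contact times; "
            "tau is unidentifiable")

    model = Model(binding_probability_curve)
    pmax = float(np.max(p))
    above = np.nonzero(p >= 0.63 * pmax)[0]
    tau0 = float(t[above[0]]) if (pmax > 0 and above.size) else float(np.median(t))
    tau0 = max(tau0, 1e-3)

    weights = None
    if uncertainties is not None:
        u = np.asarray(uncertainties, dtype=float)
        weights = 1.0 / np.clip(u, 1e-6, None)

    # small multi-start over tau: the (A, t0, tau) surface has shallow
    # valleys and a bounded solver can stall on a poor initialization
    result = None
    for tau_init in (tau0, tau0 / 3.0, 3.0 * tau0):
        params = model.make_params(A=min(max(pmax, 0.05), 1.0),
                                   t0=float(t.min()) / 4.0, tau=tau_init)
        params["A"].set(min=1e-6, max=1.0)
        params["tau"].set(min=1e-6)
        if bond_order == 2 and fix_t0 is None:
            fix_t0 = 0.0
        if fix_t0 is not None:
            params["t0"].set(value=fix_t0, vary=False)
        else:
            # keep the initial value strictly inside the bounds: lmfit's
            # bound transform has zero gradient exactly on a bound
            params["t0"].set(min=-float(t.max()), max=float(t.max()))
        r = model.fit(p, params, t=t, weights=weights)
        if r.success and (result is None or r.chisqr < result.chisqr):
            result = r
    if result is None or not np.isfinite(result.params["tau"].value):
        # grid-search fallback over tau before giving up
        best = None
        for tau_try in np.geomspace(t.min() / 4 + 1e-6, t.max() * 4, 40):
            params["tau"].set(value=tau_try)
            r = model.fit(p, params, t=t, weights=weights)
            if best is None or r.chisqr < best.chisqr:
                best = r
        result = best
        if result is None or not result.success:
            raise NumericsError("binding-kinetics fit did not converge",
                                diagnostics={"grid_search": "tau in [tmin/4, 4*tmax]"})

    def se_log10(name):
        par = result.params[name]
        if not par.vary or par.stderr is None or par.value <= 0:
            return 0.0
        return par.stderr / (par.value * LN10)

    return KineticsFit(
        A=float(np.clip(result.params["A"].value, 1e-9, 1.0)),
        t0=float(result.params["t0"].value),
        tau=float(result.params["tau"].value),
        se_log10_A=se_log10("A"),
        se_log10_t0=se_log10("t0"),
        se_log10_tau=se_log10("tau"),
        bond_order=bond_order,
    )


def compute_kon(tau: float, c_eff: float,
                se_log10_tau: float = 0.0) -> tuple[float, float]:
    """Bimolecular association rate k_on = 1/(tau c_eff) in 1/(M s).

    The effective concentration is treated as exact, so the log10 error of
    k_on equals that of tau.
    """
    if not (tau > 0 and c_eff > 0):
        raise InvalidInputError("tau and c_eff must be > 0")
    return 1.0 / (tau * c_eff), se_log10_tau


def compute_k2(tau2: float, se_log10_tau2: float = 0.0) -> tuple[float, float]:
    """Association rate of the second (or third) bond, k_2 = 1/tau_2 in 1/s."""
    if not tau2 > 0:
        raise InvalidInputError("tau2 must be > 0")
    return 1.0 / tau2, se_log10_tau2


def compute_affinity(k_off: float, k_on: float,
                     se_log10_koff: float = 0.0,
                     se_log10_kon: float = 0.0) -> tuple[float, float]:
    """Equilibrium dissociation constant K_D = k_off/k_on (M) with its
    log10 error from log-domain quadrature."""
    if not (k_off > 0 and k_on > 0):
        raise InvalidInputError("rates must be > 0")
    return k_off / k_on, math.hypot(se_log10_koff, se_log10_kon)


def bond_lifetime(k_off: float) -> float:
    """Mean single-bond lifetime tau = 1/k_off in s."""
    if not k_off > 0:
        raise InvalidInputError("k_off must be > 0")
    return 1.0 / k_off


def format_rate(value: float, se_log10: float) -> str:
    """Render ``value`` as 'mantissa x 10^exponent +/- log10-error'."""
    if value <= 0:
        return "n/a"
    exponent = math.floor(math.log10(value))
    mantissa = value / 10**exponent
    return f"{mantissa:.1f} x 10^{exponent} +/- {se_log10:.2f}"


@dataclass
class RateTable:
    """Per-construct kinetic summary with internal-consistency guarantees.

    Every row is derived from (k_off, k_on, k_2) with log10 errors; the
    derived columns obey k_off,2 = koff_parallel(k_off, 2), K_D = k_off/k_on,
    K_D,2 = k_off,2/k_on, tau = 1/k_off and tau_2 = 1/k_off,2 exactly.
    """

    frame: pd.DataFrame
    _derived = ("k_off_2", "K_D", "K_D_2", "lifetime", "lifetime_2",
                "se_log10_k_off_2", "se_log10_K_D", "se_log10_K_D_2")

    def to_csv(self, path):
        self.frame.to_csv(path, index=True, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        return cls(frame=pd.read_csv(path, index_col=0, float_precision="round_trip"))

    def to_text(self) -> str:
        """Formatted table mirroring the mantissa x 10^exponent convention."""
        lines = [f"{'construct':<12} {'k_off [1/s]':<22} {'k_off,2 [1/s]':<22} "
                 f"{'k_on [1/(M s)]':<22} {'k_2 [1/s]':<22} {'K_D [M]':<22} {'K_D,2 [M]':<22}"]
        for name, row in self.frame.iterrows():
            lines.append(
                f"{name:<12} "
                f"{format_rate(row['k_off'], row['se_log10_k_off']):<22} "
                f"{format_rate(row['k_off_2'], row['se_log10_k_off_2']):<22} "
                f"{format_rate(row['k_on'], row['se_log10_k_on']):<22} "
                f"{format_rate(row['k_2'], row['se_log10_k_2']):<22} "
                f"{format_rate(row['K_D'], row['se_log10_K_D']):<22} "
                f"{format_rate(row['K_D_2'], row['se_log10_K_D_2']):<22}"
            )
        return "\n".join(lines)


def summarize_rates(constructs: Mapping[str, Mapping[str, float]]) -> RateTable:
    """Assemble a :class:`RateTable` from per-construct primary rates.

    Each construct maps to a dict with keys ``k_off``, ``k_on``, ``k_2`` and
    optional ``se_log10_k_off``, ``se_log10_k_on``, ``se_log10_k_2``
    (decades; default 0). All derived columns are computed here so the
    table's internal identities hold exactly.
    """
    rows = {}
    for name, d in constructs.items():
        k_off, k_on, k_2 = d["k_off"], d["k_on"], d["k_2"]
        se_koff = d.get("se_log10_k_off", 0.0)
        se_kon = d.get("se_log10_k_on", 0.0)
        se_k2 = d.get("se_log10_k_2", 0.0)
        k_off_2 = koff_parallel(k_off, 2)
        kd, se_kd = compute_affinity(k_off, k_on, se_koff, se_kon)
        kd2, se_kd2 = compute_affinity(k_off_2, k_on, se_koff, se_kon)
        rows[name] = {
            "k_off": k_off, "se_log10_k_off": se_koff,
            "k_off_2": k_off_2, "se_log10_k_off_2": se_koff,
            "k_on": k_on, "se_log10_k_on": se_kon,
            "k_2": k_2, "se_log10_k_2": se_k2,
            "K_D": kd, "se_log10_K_D": se_kd,
            "K_D_2": kd2, "se_log10_K_D_2": se_kd2,
            "lifetime": bond_lifetime(k_off),
            "lifetime_2": bond_lifetime(k_off_2),
        }
    return RateTable(frame=pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class GroupComparison:
    """Welch comparison of per-cell binding probabilities between two groups."""

    effect: float  # difference of group means (A - B)
    ci_low: float
    ci_high: float
    p_value: float
    statistic: float
    df: float


def compare_binding_probabilities(group_a: Sequence[float],
                                  group_b: Sequence[float],
                                  alpha: float = 0.05) -> GroupComparison:
    """Two-sided unequal-variance (Welch) t-test on per-cell binding
    probabilities, with the difference of means and its CI as the effect."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            "comparison requires >= 3 cells per group "
            f"(got {a.size} and {b.size})")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    se = math.sqrt(va + vb)
    if se == 0:
        df = float(a.size + b.size - 2)
        p_value, statistic = 1.0, 0.0
    else:
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_value, statistic = float(res.pvalue), float(res.statistic)
    effect = float(a.mean() - b.mean())
    tcrit = stats.t.ppf(1 - alpha / 2, df) if se > 0 else 0.0
    return GroupComparison(effect=effect, ci_low=effect - tcrit * se,
                           ci_high=effect + tcrit * se,
                           p_value=p_value, statistic=statistic, df=float(df))
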