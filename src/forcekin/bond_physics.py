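"""Single- and parallel-bond rupture models under a force ramp.

Units are fixed package-wide: forces in pN, lengths in nm, times in s,
loading rates in pN/s, thermal energy kBT in pN*nm.

The single-bond description is the Bell-Evans picture: a bond with intrinsic
dissociation rate ``k_off`` and energy-barrier width ``x_beta`` loaded at a
constant rate ``r_f`` ruptures most probably at

    F* = (kBT/x_beta) * ln(r_f * x_beta / (k_off * kBT)),

floored at zero (a negative most-probable force is unphysical; it simply
means the ramp is slower than spontaneous dissociation).

For ``N`` identical, uncorrelated bonds sharing the load equally, the Markov
chain over the number of surviving bonds gives the loading rate at which a
given force ``F`` is the most probable final-rupture force:

    r_f = k_off * (kBT/x_beta) * [ sum_{l=1}^{N} (1/l^2) exp(-F x_beta / (l kBT)) ]^-1

and the effective dissociation rate for simultaneous parallel rupture:

    k_off,N = k_off / sum_{l=1}^{N} (1/l).

Both reduce to the single-bond expressions at N = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidInputError, NumericsError

#: Boltzmann constant in pN*nm per kelvin.
BOLTZMANN_PN_NM = 1.380649e-2

#: Default thermal energy (pN*nm) at room temperature.
DEFAULT_KBT = 4.114
DEFAULT_TEMPERATURE = 298.15

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class BellParams:
    """Bell-model bond parameters.

    Parameters
    ----------
    k_off : float
        Intrinsic dissociation rate at zero force, 1/s.
    x_beta : float
        Width of the energy barrier along the pulling direction, nm.
    kBT : float
        Thermal energy, pN*nm.
    temperature : float
        Absolute temperature (metadata; must be consistent with ``kBT``
        through the Boltzmann constant to within 0.1%).
    """

    k_off: float
    x_beta: float
    kBT: float = DEFAULT_KBT
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        for name in ("k_off", "x_beta", "kBT", "temperature"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"BellParams.{name} must be finite and > 0, got {v!r}")
        implied = BOLTZMANN_PN_NM * self.temperature
        if abs(implied - self.kBT) / implied > 1e-3:
            raise InvalidInputError(
                f"kBT={self.kBT} pN*nm inconsistent with T={self.temperature} K "
                f"(k_B*T = {implied:.4f} pN*nm; tolerance 0.1%)"
            )

    @property
    def thermal_force(self) -> float:
        """kBT / x_beta, the force scale of the rupture-force distribution (pN)."""
        return self.kBT / self.x_beta


@dataclass(frozen=True)
class ParallelBondSpec:
    """``n_bonds`` identical bonds sharing load equally."""

    n_bonds: int
    params: BellParams

    def __post_init__(self):
        if not (isinstance(self.n_bonds, (int, np.integer)) and self.n_bonds >= 1):
            raise InvalidInputError(f"n_bonds must be an integer >= 1, got {self.n_bonds!r}")


def _check_rate(r_f) -> np.ndarray:
    r = np.asarray(r_f, dtype=float)
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise InvalidInputError(f"loading rate must be finite and > 0, got {r_f!r}")
    return r


def bell_evans_force(r_f, p: BellParams):
    """Most probable rupture force (pN) of a single bond at loading rate ``r_f``.

    Returns 0 where the logarithm is non-positive (force floor). Accepts a
    scalar or array loading rate.
    """
    r = _check_rate(r_f)
    f = p.thermal_force * np.log(r * p.x_beta / (p.k_off * p.kBT))
    out = np.maximum(f, 0.0)
    return float(out) if np.isscalar(r_f) else out


def koff_parallel(k_off: float, n_bonds: int) -> float:
    """Effective dissociation rate for simultaneous rupture of ``n_bonds`` bonds.

    k_off,N = k_off / sum_{l=1}^{N} 1/l; for N=2 this is (2/3) k_off.
    """
    if not (np.isfinite(k_off) and k_off > 0):
        raise InvalidInputError(f"k_off must be finite and > 0, got {k_off!r}")
    if not (isinstance(n_bonds, (int, np.integer)) and n_bonds >= 1):
        raise InvalidInputError(f"n_bonds must be an integer >= 1, got {n_bonds!r}")
    harmonic = sum(1.0 / l for l in range(1, n_bonds + 1))
    return k_off / harmonic


def williams_loading_rate(F, spec: ParallelBondSpec):
    """Loading rate (pN/s) at which ``F`` is the most probable rupture force
    of ``spec.n_bonds`` parallel bonds. Accepts scalar or array ``F``."""
    f = np.asarray(F, dtype=float)
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise InvalidInputError(f"force must be finite and >= 0, got {F!r}")
    p = spec.params
    s = np.zeros_like(f)
    for l in range(1, spec.n_bonds + 1):
        s += (1.0 / l**2) * np.exp(-f * p.x_beta / (l * p.kBT))
    r = p.k_off * p.thermal_force / s
    return float(r) if np.isscalar(F) else r


def williams_force(r_f, spec: ParallelBondSpec, rtol: float = 1e-10):
    """Invert the Williams relation: most probable rupture force at ``r_f``.

    Bracketed root finding on the (strictly increasing) loading-rate curve;
    relative residual |delta r_f| / r_f <= 1e-8 guaranteed by much tighter
    solver tolerances. For ``n_bonds == 1`` this equals ``bell_evans_force``.
    """
    if not np.isscalar(r_f):
        return np.array([williams_force(r, spec, rtol) for r in np.asarray(r_f, dtype=float)])
    r = float(_check_rate(r_f))
    p = spec.params
    if spec.n_bonds == 1:
        return bell_evans_force(r, p)
    if williams_loading_rate(0.0, spec) >= r:
        return 0.0  # ramp slower than spontaneous multi-bond dissociation
    f_single = max(bell_evans_force(r, p), p.thermal_force)
    hi = f_single
    cap = 10.0 * spec.n_bonds * f_single
    while williams_loading_rate(hi, spec) < r:
        hi *= 2.0
        if hi > cap:
            raise NumericsError(
                "could not bracket the Williams force",
                diagnostics={"r_f": r, "upper_bound_tried": hi, "cap": cap},
            )
    root = brentq(lambda f: williams_loading_rate(f, spec) - r, 0.0, hi,
                  xtol=1e-12, rtol=8.882e-16)
    return float(root)


class RuptureForceDistribution:
    """Rupture-force distribution of a single Bell bond under a constant ramp.

    With k(F) = k_off exp(F x_beta / kBT) and F = r_f t,

        pdf(F) = (k(F)/r_f) exp( -(k_off kBT)/(x_beta r_f) (exp(F x_beta/kBT) - 1) )

    on F >= 0. The CDF and quantile function are closed-form, which makes
    exact inverse-CDF sampling possible.
    """

    def __init__(self, r_f: float, params: BellParams):
        self.r_f = float(_check_rate(r_f))
        self.params = params
        self._phi = params.x_beta / params.kBT
        self._a = params.k_off * params.kBT / (params.x_beta * self.r_f)

    def pdf(self, F):
        f = np.asarray(F, dtype=float)
        k = self.params.k_off * np.exp(f * self._phi)
        out = (k / self.r_f) * np.exp(-self._a * np.expm1(f * self._phi))
        out = np.where(f < 0, 0.0, out)
        return float(out) if np.isscalar(F) else out

    __call__ = pdf

    def cdf(self, F):
        f = np.asarray(F, dtype=float)
        out = -np.expm1(-self._a * np.expm1(f * self._phi))
        out = np.where(f < 0, 0.0, out)
        return float(out) if np.isscalar(F) else out

    def ppf(self, q):
        u = np.asarray(q, dtype=float)
        if np.any((u < 0) | (u >= 1)):
            raise InvalidInputError("quantile must lie in [0, 1)")
        out = np.log1p(-np.log1p(-u) / self._a) / self._phi
        return float(out) if np.isscalar(q) else out

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size))

    @property
    def mode(self) -> float:
        """Most probable force; equals the Bell-Evans force when positive."""
        return bell_evans_force(self.r_f, self.params)


def rupture_force_density(r_f: float, p: BellParams) -> RuptureForceDistribution:
    """Rupture-force density under a constant ramp (callable; also exposes
    ``cdf``/``ppf``/``sample`` for exact inverse-CDF sampling)."""
    return RuptureForceDistribution(r_f, p)


def effective_concentration(radius: float, n_ligands: int = 1) -> float:
    """Effective molar concentration of ``n_ligands`` tethered molecules
    confined to a hemisphere of the given radius (nm).

    V = (2/3) pi r^3 (in litres; 1 nm^3 = 1e-24 L); c_eff = N / (N_A V).
    """
    if not (np.isfinite(radius) and radius > 0):
        raise InvalidInputError(f"radius must be finite and > 0, got {radius!r}")
    if not n_ligands >= 1:
        raise InvalidInputError(f"n_ligands must be >= 1, got {n_ligands!r}")
    volume_litre = (2.0 / 3.0) * math.pi * radius**3 * 1e-24
    return n_ligands / (AVOGADRO * volume_litre)
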