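"""Monte-Carlo generator of force-distance retract traces with ground truth.

The generator emulates the statistical structure a tether-mediated
force-spectroscopy experiment presents to the analysis pipeline:

* whether a curve carries zero, one or two bonds follows the
  pseudo-first-order binding-probability law P(t_c) = A(1-exp(-(t_c-t0)/tau))
  in the tip-surface contact time, with the second bond forming with
  probability P2(t_c) = A2(1-exp(-t_c/tau2));
* rupture forces follow Bell kinetics under the ramp set by the pulling
  speed through the series compliance of cantilever, worm-like-chain tether
  and surface; double bonds rupture through the exact two-state Markov
  cascade with equal load sharing (each surviving bond carries F/l), sampled
  by inverse CDF within each state -- no time discretization error;
* the rendered trace shows the nonlinear worm-like-chain rise, instantaneous
  force drops at the rupture positions, and additive white Gaussian noise
  with a per-curve amplitude drawn from a configured range.

A double rupture whose two failures fall within ``resolution_nm`` of tip
travel is tagged "simultaneous" (a single double-height step in the trace,
mimicking the instrument's inability to resolve near-coincident drops);
otherwise it is "sequential" and rendered as two separate drops. Because the
total tether force is continuous through the first failure in the idealized
equal-sharing picture, the rendered first drop releases the load the failed
bond was carrying (half the pre-rupture force) -- the signature sequential
traces show in practice.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
import numpy as np
from scipy.optimize import brentq

from .bond_physics import BellParams, ParallelBondSpec, bell_evans_force, rupture_force_density
from .curves import ForceCurve
from .errors import InvalidInputError, SimulationError
from .kinetics import binding_probability_curve


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated dataset.

    Defaults follow a cell-surface receptor-antibody experiment probed
    through a short PEG tether: pulling speeds spanning 0.75-12 um/s, a soft
    cantilever (0.01 N/m = 10 pN/nm), an 8 nm contour / 0.38 nm persistence
    length tether, a compliant surface, and per-curve force noise of about
    5 pN.
    """

    pulling_speeds: tuple = (0.75, 1.5, 3.0, 5.0, 8.0, 12.0)  # um/s
    cantilever_k: float = 10.0  # pN/nm
    tether_contour_length: float = 8.0  # nm
    tether_persistence_length: float = 0.38  # nm
    surface_stiffness: float = 5.0  # pN/nm
    bond: BellParams = field(default_factory=lambda: BellParams(k_off=0.03, x_beta=0.5))
    binding_A: float = 0.4
    binding_t0: float = 0.01  # s
    binding_tau: float = 0.2  # s
    second_bond_A: float = 0.3
    second_bond_tau: float = 0.25  # s
    noise_sigma_range: tuple = (4.0, 6.0)  # pN
    sample_rate: float = 10.0  # points per nm
    curves_per_condition: int = 600
    contact_times: tuple = (0.25,)  # s
    seed: int = 0
    tether_slack: float = 2.0  # nm of slack before the tether engages
    retract_length: float = 120.0  # nm
    resolution_nm: float = 0.5  # sequential/simultaneous resolution threshold

    def __post_init__(self):
        if not (0 < self.binding_A <= 1):
            raise InvalidInputError("binding_A must lie in (0, 1]")
        if not (0 <= self.second_bond_A <= 1):
            raise InvalidInputError("second_bond_A must lie in [0, 1]")
        for name in ("cantilever_k", "tether_contour_length", "tether_persistence_length",
                     "surface_stiffness", "binding_tau", "second_bond_tau",
                     "sample_rate", "retract_length"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        if any(v <= 0 or v > 50 for v in self.pulling_speeds):
            raise InvalidInputError("pulling speeds must lie in (0, 50] um/s")
        if self.noise_sigma_range[0] < 0 or self.noise_sigma_range[1] < self.noise_sigma_range[0]:
            raise InvalidInputError("noise_sigma_range must be a non-decreasing pair >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bond"] = {"k_off": self.bond.k_off, "x_beta": self.bond.x_beta,
                     "kBT": self.bond.kBT, "temperature": self.bond.temperature}
        return d


@dataclass
class GroundTruth:
    """Per-curve labels for acceptance testing."""

    curve_id: str
    bound: bool
    n_bonds: int  # 0, 1 or 2
    pattern: str  # none | single | sequential | simultaneous
    rupture_forces: tuple = ()  # pN, in rupture order
    rupture_positions: tuple = ()  # nm, sorted ascending
    spring_constants: tuple = ()  # pN/nm at each rupture
    loading_rate: float = 0.0  # pN/s of the sampling ramp
    noise_sigma: float = 0.0  # pN
    pulling_speed: float = 0.0  # um/s
    contact_time: float = 0.0  # s


@dataclass
class RuptureSample:
    forces: tuple
    pattern: str

    @property
    def final_force(self) -> float:
        return self.forces[-1]


# ---------------------------------------------------------------------------
# worm-like chain tether mechanics

def wlc_force(x, Lp: float, Lc: float, kBT: float):
    """Worm-like-chain interpolation force (pN) at extension ``x`` (nm)."""
    z = np.asarray(x, dtype=float) / Lc
    if np.any(z < 0) or np.any(z >= 1):
        raise InvalidInputError("extension must lie in [0, contour length)")
    out = (kBT / Lp) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return float(out) if np.isscalar(x) else out


def wlc_stiffness(x, Lp: float, Lc: float, kBT: float):
    """dF/dx (pN/nm) of the interpolation formula."""
    z = np.asarray(x, dtype=float) / Lc
    out = (kBT / (Lp * Lc)) * (0.5 / (1.0 - z) ** 3 + 1.0)
    return float(out) if np.isscalar(x) else out


def series_stiffness(force: float, scenario: SimScenario) -> float:
    """Effective spring constant of cantilever + tether + surface at ``force``."""
    p = scenario.bond
    Lp, Lc = scenario.tether_persistence_length, scenario.tether_contour_length
    x = brentq(lambda e: wlc_force(e, Lp, Lc, p.kBT) - force, 0.0, Lc * (1 - 1e-9))
    k_t = wlc_stiffness(x, Lp, Lc, p.kBT)
    return 1.0 / (1.0 / scenario.cantilever_k + 1.0 / scenario.surface_stiffness + 1.0 / k_t)


def condition_loading_rate(scenario: SimScenario, speed: float) -> tuple[float, float]:
    """Self-consistent (loading rate pN/s, effective stiffness pN/nm) for one
    pulling speed: the stiffness is evaluated at the most probable rupture
    force of the ramp it itself defines (fixed-point iteration; the coupling
    is logarithmic and converges in a few steps)."""
    v = speed * 1e3  # nm/s
    force = 40.0
    for _ in range(60):
        k = series_stiffness(max(force, 1.0), scenario)
        new = bell_evans_force(k * v, scenario.bond)
        if abs(new - force) < 1e-10:
            force = new
            break
        force = new
    k = series_stiffness(max(force, 1.0), scenario)
    return k * v, k


# ---------------------------------------------------------------------------
# stochastic draws

def draw_binding_state(t_c: float, scenario: SimScenario, rng: np.random.Generator) -> int:
    """Number of bonds formed during a contact of duration ``t_c`` (0, 1 or 2).

    P(bound) follows the scenario's pseudo-first-order law; conditional on
    binding, a second bond forms with probability
    A2 (1 - exp(-t_c / tau2)).
    """
    if t_c < 0:
        raise InvalidInputError("contact time must be >= 0")
    p1 = float(binding_probability_curve(t_c, scenario.binding_A,
                                         scenario.binding_t0, scenario.binding_tau))
    if rng.random() >= p1:
        return 0
    p2 = float(binding_probability_curve(t_c, scenario.second_bond_A,
                                         0.0, scenario.second_bond_tau))
    return 2 if rng.random() < p2 else 1


def sample_rupture(r_f: float, spec: ParallelBondSpec, rng: np.random.Generator,
                   force_resolution: float = 0.0) -> RuptureSample:
    """Sample the rupture cascade of ``spec.n_bonds`` equal-sharing bonds
    under a constant ramp ``r_f``.

    With ``l`` surviving bonds each carries F/l, so the state hazard is
    l k_off exp(F x_beta / (l kBT)); within each state the rupture force is
    drawn by exact inversion of the cumulative hazard. A multi-bond cascade
    whose force gap between first and last failure is at most
    ``force_resolution`` (pN) is tagged "simultaneous"."""
    if not r_f > 0:
        raise InvalidInputError("loading rate must be > 0")
    p = spec.params
    if spec.n_bonds == 1:
        f = float(rupture_force_density(r_f, p).sample(rng))
        return RuptureSample(forces=(f,), pattern="single")
    phi = p.x_beta / p.kBT
    forces = []
    f_prev = 0.0
    for l in range(spec.n_bonds, 0, -1):
        # cumulative hazard in state l from f_prev:
        #   (l^2 k_off / (r_f phi)) (exp(phi F / l) - exp(phi f_prev / l))
        a = l * l * p.k_off / (r_f * phi)
        e1 = rng.exponential()
        f_prev = (np.log(np.exp(phi * f_prev / l) + e1 / a)) * l / phi
        forces.append(float(f_prev))
    gap = forces[-1] - forces[0]
    pattern = "simultaneous" if gap <= force_resolution else "sequential"
    return RuptureSample(forces=tuple(forces), pattern=pattern)


# ---------------------------------------------------------------------------
# trace rendering

def _tether_curve(scenario: SimScenario):
    """Force vs tip-sample distance of the series compliance (monotone)."""
    p = scenario.bond
    Lp, Lc = scenario.tether_persistence_length, scenario.tether_contour_length
    x = np.linspace(0.0, Lc * (1 - 1e-6), 4000)
    f = wlc_force(x, Lp, Lc, p.kBT)
    compliance = 1.0 / scenario.cantilever_k + 1.0 / scenario.surface_stiffness
    d = scenario.tether_slack + x + f * compliance
    return d, f


def render_curve(truth: GroundTruth, scenario: SimScenario, speed: float,
                 rng: np.random.Generator, sigma: float | None = None) -> ForceCurve:
    """Render one retract trace for ``truth`` and fill in its geometric
    fields (rupture positions, local spring constants, noise sigma)."""
    n = int(round(scenario.retract_length * scenario.sample_rate))
    d = np.arange(n) / scenario.sample_rate
    if sigma is None:
        sigma = float(rng.uniform(*scenario.noise_sigma_range))
    force = np.zeros(n)

    if truth.n_bonds > 0:
        d_t, f_t = _tether_curve(scenario)
        forces = truth.rupture_forces
        f_final = forces[-1]
        if f_final > f_t[-1]:
            raise SimulationError(
                f"rupture force {f_final:.1f} pN requires tether extension beyond "
                "the contour length; scenario parameters are inconsistent")
        positions, springs = [], []
        if truth.pattern in ("single", "simultaneous"):
            d_rupt = float(np.interp(f_final, f_t, d_t))
            if d_rupt >= scenario.retract_length * 0.75:
                raise SimulationError("rupture position leaves no baseline; "
                                      "increase retract_length")
            rise = d <= d_rupt
            force[rise] = np.interp(d[rise], d_t, f_t)
            k_eff = series_stiffness(max(f_final, 1.0), scenario)
            positions, springs = [d_rupt], [k_eff]
        else:  # sequential: two rendered drops
            f1, f2 = forces[0], forces[-1]
            d1 = float(np.interp(f1, f_t, d_t))
            k1 = series_stiffness(max(f1, 1.0), scenario)
            d2 = d1 + (f2 - 0.5 * f1) / k1
            if d2 >= scenario.retract_length * 0.75:
                raise SimulationError("rupture position leaves no baseline; "
                                      "increase retract_length")
            rise = d <= d1
            force[rise] = np.interp(d[rise], d_t, f_t)
            ramp = (d > d1) & (d <= d2)
            force[ramp] = 0.5 * f1 + k1 * (d[ramp] - d1)
            positions, springs = [d1, d2], [k1, k1]
        truth.rupture_positions = tuple(positions)
        truth.spring_constants = tuple(springs)

    if sigma > 0:
        force = force + rng.normal(0.0, sigma, size=n)
    truth.noise_sigma = sigma
    return ForceCurve(distance=d, force=force, pulling_speed=speed,
                      contact_time=truth.contact_time, curve_id=truth.curve_id,
                      metadata={"noise_sigma": sigma})


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass
class SimulatedDataset:
    curves: list
    truths: list
    manifest: dict

    def __iter__(self):
        return iter(zip(self.curves, self.truths))


def _scenario_digest(scenario: SimScenario) -> str:
    return hashlib.sha256(
        json.dumps(scenario.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def simulate_dataset(scenario: SimScenario) -> SimulatedDataset:
    """Generate the full (speed x contact time) grid of curves with labels.

    Deterministic for a fixed scenario seed: each curve draws from its own
    counter-derived substream, so curve ``k`` of condition ``c`` is identical
    regardless of how many other conditions are simulated.
    """
    if len(scenario.pulling_speeds) == 0:
        warnings.warn("scenario has no pulling speeds; returning an empty dataset",
                      stacklevel=2)
        return SimulatedDataset(curves=[], truths=[], manifest={
            "scenario": scenario.to_dict(), "n_curves": 0,
            "scenario_digest": _scenario_digest(scenario)})

    curves, truths = [], []
    conditions = [(s, t) for s in scenario.pulling_speeds for t in scenario.contact_times]
    for ci, (speed, t_c) in enumerate(conditions):
        r_f, k_eff = condition_loading_rate(scenario, speed)
        force_resolution = k_eff * scenario.resolution_nm
        for k in range(scenario.curves_per_condition):
            rng = np.random.default_rng([scenario.seed, ci, k])
            n_bonds = draw_binding_state(t_c, scenario, rng)
            cid = f"c{ci:03d}_{k:05d}"
            if n_bonds == 0:
                truth = GroundTruth(curve_id=cid, bound=False, n_bonds=0,
                                    pattern="none", pulling_speed=speed,
                                    contact_time=t_c, loading_rate=r_f)
            else:
                spec = ParallelBondSpec(n_bonds=n_bonds, params=scenario.bond)
                samp = sample_rupture(r_f, spec, rng, force_resolution=force_resolution)
                truth = GroundTruth(curve_id=cid, bound=True, n_bonds=n_bonds,
                                    pattern=samp.pattern,
                                    rupture_forces=samp.forces,
                                    pulling_speed=speed, contact_time=t_c,
                                    loading_rate=r_f)
            curves.append(render_curve(truth, scenario, speed, rng))
            truths.append(truth)

    manifest = {
        "schema_version": 1,
        "scenario": scenario.to_dict(),
        "scenario_digest": _scenario_digest(scenario),
        "n_curves": len(curves),
        "conditions": [{"pulling_speed": s, "contact_time": t} for s, t in conditions],
        "units": {"distance": "nm", "force": "pN", "pulling_speed": "um/s",
                  "contact_time": "s", "loading_rate": "pN/s"},
    }
    return SimulatedDataset(curves=curves, truths=truths, manifest=manifest)
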