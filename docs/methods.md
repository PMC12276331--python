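# Methods

This note describes the models implemented in `forcekin`, the assumptions
behind the synthetic-data generators, the numerical choices that matter, and
the limits of what the simulation-based tests can show about real
instrument data.

## Single-bond rupture under a force ramp

A receptor-ligand bond pulled at constant loading rate `r_f` (pN/s) is
modelled with Bell kinetics: the force-dependent off-rate is
`k(F) = k_off exp(F x_beta / kBT)`, where `k_off` (1/s) is the dissociation
rate at zero force and `x_beta` (nm) the distance to the transition state.
The rupture-force density under the ramp is

    p(F) = (k(F)/r_f) exp( -(k_off kBT)/(x_beta r_f) (exp(F x_beta/kBT) - 1) ),

whose mode is the Bell-Evans most-probable rupture force

    F* = (kBT/x_beta) ln( r_f x_beta / (k_off kBT) ).

`F*` is floored at zero: a negative value only signals that the ramp is
slower than spontaneous dissociation, and the loading rates of interest sit
two or more decades above that floor. The CDF and quantile function are
closed-form, so the simulator samples rupture forces by exact inverse-CDF
transformation with no discretization error.

Default thermal energy is `kBT = 4.114 pN nm` (room temperature,
`T = 298.15 K`); `BellParams` refuses a `kBT`/temperature pair inconsistent
with the Boltzmann constant beyond 0.1%. Units are fixed package-wide:
pN, nm, s, M, loading rates in pN/s.

## Parallel bonds: the Markov load-sharing model

For `N` identical, uncorrelated bonds sharing the load equally (each of `l`
surviving bonds carries `F/l`), the Markov chain over the number of intact
bonds yields the loading rate at which `F` is the most probable final
rupture force:

    r_f = k_off (kBT/x_beta) [ sum_{l=1}^{N} (1/l^2) exp(-F x_beta/(l kBT)) ]^-1,

and the effective off-rate of the fully loaded parallel cluster:

    k_off,N = k_off / sum_{l=1}^{N} 1/l      (k_off,2 = (2/3) k_off).

`williams_force` inverts the rate relation by bracketed bisection/Brent
iteration (deterministic, relative residual far below 1e-8); at `N = 1` both
relations reduce exactly to Bell-Evans. The two-bond force branch predicted
from a fitted single-bond spectrum carries **zero** additional free
parameters, which is what makes the overlay a meaningful consistency check.
Note that the two-bond/one-bond force ratio approaches 2 only
logarithmically: `F2 = 2 F1 - (2 kBT/x_beta) ln 4` at large rates, giving a
ratio near 1.9 at 1e8 pN/s.

## Force-curve simulator

The simulator (`forcekin.simulate`) emulates the statistical structure a
tether-mediated cell-surface experiment presents to the analysis pipeline.

**Binding states.** Whether a tip-surface contact of duration `t_c` forms
0, 1 or 2 bonds follows pseudo-first-order association:
`P(t_c) = A (1 - exp(-(t_c - t0)/tau))` for the first bond (clamped to
[0, 1], zero below the lag time `t0`), and
`P2(t_c) = A2 (1 - exp(-t_c/tau2))` for the second bond conditional on the
first. Defaults: `A = 0.4`, `t0 = 0.01 s`, `tau = 0.2 s`, `A2 = 0.3`,
`tau2 = 0.25 s`. The second-bond amplitude `A2` is a required parameter of
the saturating form; it is exposed in the scenario alongside `tau2`.

**Mechanics.** The tether is a worm-like chain (interpolation formula) with
contour length 8 nm and persistence length 0.38 nm — typical for a short
PEG crosslinker — in series with the cantilever (10 pN/nm, i.e. the 0.01 N/m
class of soft levers) and a compliant surface (5 pN/nm, representing cell
membrane give). Because the WLC stiffens steeply near full extension, the
series stiffness at rupture-level forces is dominated by the cantilever and
surface terms and varies by <10% across 0.75-12 um/s pulling speeds, so the
ramp is nearly constant near rupture. Each (speed, contact-time) condition
uses the self-consistent fixed point `F* = BellEvans(k_eff(F*) v)` to set
its sampling loading rate.

**Double-bond cascades.** With two bonds the pair hazard is
`2 k_off exp(F x_beta/(2 kBT))`; after the first failure the survivor
carries the full force with hazard `k_off exp(F x_beta/kBT)`. Both states
are sampled by exact inversion of their cumulative hazards. A cascade whose
two failures fall within 0.5 nm of tip travel (configurable) is tagged
"simultaneous" — a single double-height step, mimicking the instrument's
inability to resolve near-coincident drops — otherwise "sequential".

**Rendering.** In the idealized equal-sharing picture the *total* tether
force is continuous through the first failure, which would make sequential
ruptures invisible in the trace; measured sequential curves nevertheless
show two drops because the load path rearranges. The renderer therefore
drops the trace to half the pre-rupture force at the first failure (the
load the broken bond was carrying) and resumes the ramp at the local
effective stiffness until the survivor fails. Noise is white Gaussian per
point with a per-curve amplitude drawn uniformly from 4-6 pN (no 1/f
component). The retract range is 120 nm at 10 points/nm so that sequential
cascades retain a post-detachment baseline.

**Determinism.** Every curve draws from a counter-derived substream
(`default_rng([seed, condition, curve])`), so datasets are bit-reproducible
and individual curves do not depend on how many conditions are simulated.

What the generator does **not** emulate: approach-phase contact mechanics,
cell viscoelasticity and drift, 1/f force noise, multiple tethers,
rebinding during retraction, and unequal load sharing. Passing
parameter-recovery tests therefore demonstrates the correctness of the
inference chain under the stated statistical model, not robustness to every
artefact of live-cell data.

## Event detection

Per-curve noise is the SD of the trailing 20% of the trace after linear
detrending (falling back to a whole-trace MAD with a warning when the
baseline is shorter than 50 points). An event is a force drop of at least
`max(4 sigma, 2 pN)` completed within 2 nm of tip travel, whose pre-drop
force clears the same threshold and which is preceded by a rising adhesive
load. The absolute 2 pN floor exists because a purely sigma-relative
threshold degenerates on noiseless synthetic curves. The unbinding force is
a three-sample backward mean corrected by one sample of the fitted slope
(a centred mean would average post-drop samples into the estimate); the
effective spring constant is the absolute slope of a linear fit over the
10 nm before the drop, truncated at the previous event; the loading rate is
slope x pulling speed. On the default simulator conditions this detector
reaches >= 98% sensitivity with no false events on unbound curves.

## Densities, segmentation and fits

**Experimental pdfs.** Each measured value contributes a unit-area Gaussian
whose width is its own measurement error (per-curve noise for forces, a
fixed 4 nm^3 instrument error for volumes); the average of these kernels is
tabulated on a grid with step `min(sigma)/4` spanning +/-4 sigma beyond the
data. Because a 4-sigma truncation already forfeits 6e-5 of mass, the
tabulated curve is renormalized by its trapezoidal integral. A peak built
from samples of SD `s` appears with SD `sqrt(s^2 + kernel^2)` — the fits
report this broadened width and do not deconvolve it.

**Mixture fits** are nonlinear least squares of a Gaussian sum to the
density curve (not EM on raw samples), initialized at the tallest local
maxima; components are sorted by ascending mean, the lowest-mean component
is the monovalent branch, and components with area below 0.02 are flagged
as surplus.

**Loading-rate segments** have boundaries at `10^(k/2)` (two per decade,
equidistant in log), segments with fewer than 20 events are excluded and
logged, and each segment is represented by the geometric mean of its
members' rates — the log-domain centroid matching the semi-log fit
abscissa. The segment peak is a single Gaussian fitted in a window of +/-2
median kernel widths around the highest local pdf maximum.

**Bell-Evans fit.** Weighted least squares of peak force vs `ln r_f` with
weights `1/peak_sd^2` treated as absolute errors: the parameter covariance
is `(X' W X)^-1` without residual rescaling, so scaling all peak SDs by `c`
scales the standard errors by `c` and leaves point estimates unchanged.
Slope and intercept map to `x_beta = kBT/m` and `k_off = exp(-b/m)/m`;
errors propagate by the delta method and are reported as log10 decades,
matching the `mantissa x 10^(exponent +/- error)` table convention used
throughout.

**Binding kinetics.** `P(t)` is fitted by weighted least squares with a
three-point tau multi-start; the lag time is initialized strictly inside
its bounds because a bounded Levenberg-Marquardt stalls when started
exactly on a bound. For second-bond fits the lag is fixed at zero. A flat,
nonzero probability profile is rejected as unidentifiable rather than
silently fitted. Note a statistical limit: from 8 contact times x 300
binary outcomes the information bound (Cramer-Rao) on the interaction time
is ~12% relative SD even with the lag fixed, so single-dataset tau
estimates carry that floor irrespective of the estimator.

**Derived rates.** `k_on = 1/(tau c_eff)` with
`c_eff = N/(N_A (2/3) pi r^3)` — one tethered ligand confined to a
hemisphere whose default radius (12 nm) is the tether contour length plus
the size of the coupled molecule, configurable because neither is uniquely
fixed by the hardware; `k_2 = 1/tau2`; `K_D = k_off/k_on` with log-domain
quadrature of errors; lifetimes `1/k_off`. Rate tables recompute every
derived column from the primary rates so the internal identities
(`k_off,2 = (2/3) k_off`, `K_D = k_off/k_on`, `tau = 1/k_off`) hold exactly.
The competitive-assay comparison is a two-sided Welch t-test on per-cell
binding probabilities (the field reports per-cell fractions; the test is
configurable in principle but Welch is the default for unequal variances).

## AFM volumetrics

Images are levelled by subtracting the plane through three patch-averaged
anchor points, Gaussian-smoothed, and masked at half the maximum height of
the **raw** image (the threshold is computed on the raw image, applied to
the levelled-and-smoothed one; "half the height" is read as half the
maximum, and the ambiguity with half the height *range* is noted —
for tilt amplitudes small against particle heights the two nearly
coincide). Components are 8-connected with a 4-pixel minimum;
border-touching particles are flagged and excluded from statistics.

A half-height cut leaves a large part of a smooth particle profile outside
the mask (for a 2D Gaussian of peak height `A` cut at `cA`, the mask holds
a fraction `1-c` of the volume — half, at `c = 0.5`). Volumes are therefore
integrated over each component dilated by 8 pixels, with the local
background taken as the median of a 2-pixel ring outside the dilation and
outside every other particle's support. With the default synthetic-image
geometry this recovers Gaussian-blob volumes to within ~4% for
monomer/dimer sizes (~10% by trimer size); the mask itself still defines
particle identity, pixel count and border contact.

The synthetic image generator places Gaussian-profile particles of
specified integrated volume and **constant peak height** (2 nm): compact
molecules lying on the support imaged with a finite tip grow laterally, not
vertically, with oligomer order — and a constant height is also what keeps
a half-of-maximum threshold meaningful across states. Particles sit on a
tilted plane (default ~0.002-0.004 nm/nm) with 0.05 nm white height noise,
placed with a minimum separation of 14 nm.

Oligomer states are the Gaussian components of the volume pdf (state count
defaulting to the number of local maxima above a 5% prominence floor);
classification boundaries sit at the midpoints between adjacent fitted peak
means, each particle is assigned to the segment containing its volume, and
peaks closer than one kernel width are merged with a warning.

## Problem sizes used in the reference runs

The bundled analyses run on one CPU in well under a minute each: the
dynamic-force-spectrum recovery uses 6 pulling speeds x 600 curves
(~1000 events, 4 half-decade segments); the two-bond overlay uses the same
grid with ~30% bivalent curves; the contact-time study uses 100 replicates
of 8 contact times x 300 binary draws; the volume study uses 400 particles
across ten 128 x 128 nm images. These sizes were chosen to keep Monte-Carlo
error comfortably inside the tolerances being tested while remaining
desk-scale.

## Known limitations

- The Bell-Evans abscissa uses per-segment geometric-mean loading rates;
  within-segment rate spread is not propagated into the fit errors.
- Mixture decomposition on the density curve inherits kernel broadening;
  component SDs are convolved widths, not intrinsic force spreads.
- No alternative dynamic-force-spectroscopy models (Friddle-Noy-De Yoreo,
  Dudko-Hummer-Szabo), no catch bonds, no rebinding.
- Volume integration assumes approximately radially symmetric particles
  with tails captured by a fixed dilation; strongly elongated or
  overlapping particles will bias volumes.
- The simulator's per-condition loading rate is a single fixed point;
  biological stiffness heterogeneity (cell-to-cell compliance variation)
  is not modelled.
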