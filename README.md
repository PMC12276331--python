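# forcekin

Single-molecule force spectroscopy (SMFS) and high-speed AFM volumetrics in
one tested toolkit: forward models for bond rupture under load, a
Monte-Carlo force-curve and height-image simulator with ground truth, and
the full inference chain that turns raw retract traces into kinetic rates
and AFM images into oligomer-state distributions.

It is written for single-molecule biophysicists who probe receptor-ligand
bonds — e.g. antibodies or trimeric ligands engaging cell-surface receptors
of the TNF-receptor family — with an AFM tip functionalized through a PEG
tether, and who additionally image molecular self-assembly by high-speed
AFM.

## The models

**Bell-Evans.** A bond loaded at rate `r_f` ruptures most probably at

    F* = (k_B T / x_beta) * ln( r_f * x_beta / (k_off * k_B T) ),

so plotting segment peak forces against log loading rate and fitting the
line yields the dissociation rate `k_off` and barrier width `x_beta`.

**Williams parallel-bond model.** For N identical bonds sharing load
equally and failing independently,

    r_f = k_off (k_B T/x_beta) [ sum_{l=1}^{N} (1/l^2) exp(-F* x_beta/(l k_B T)) ]^-1,
    k_off,N = k_off / sum_{l=1}^{N} (1/l),

which predicts the bivalent branch of the force spectrum (and the two-bond
off-rate `k_off,2 = (2/3) k_off`) with no extra free parameters.

**Binding kinetics.** The binding probability grows with tip-surface
contact time as `P(t) = A (1 - exp(-(t - t0)/tau))`; the interaction time
`tau` converts to a bimolecular on-rate through the effective concentration
of the single tethered ligand, `k_on = 1/(tau c_eff)` with
`c_eff = N/(N_A (2/3) pi r^3)`, and the second bond forms at `k_2 = 1/tau_2`.
Affinities follow as `K_D = k_off/k_on`, lifetimes as `tau = 1/k_off`, with
errors carried in log10 decades.

**AFM volumetrics.** Height images are plane-levelled (three anchor
points), smoothed, masked at half the raw maximum height; per-particle
volumes feed a kernel density (4 nm^3 measurement error) whose
multi-Gaussian decomposition defines oligomer states, with classification
boundaries at the midpoints between adjacent peaks.

Every inference stage is exercised against simulators that generate force
curves (worm-like-chain tether, exact inverse-CDF rupture sampling, Markov
two-bond cascades, per-curve Gaussian noise) and height images (tilted
noisy background, volume-calibrated particles) with full ground truth.

## Worked example

Run the bundled quickstart (a small simulated dataset: 5 pulling speeds
from 0.75 to 12 um/s x 6 contact times x 120 curves, generated with
`k_off = 0.03/s`, `x_beta = 0.5 nm`, `A = 0.4`, `tau = 0.2 s`,
`tau_2 = 0.25 s`, ~5 pN noise):

```bash
forcekin report --out results_quickstart
```

which detects rupture events, segments them by loading rate, fits the
Bell-Evans line and the contact-time kinetics, and prints the rate table:

```
construct    k_off [1/s]            k_off,2 [1/s]          k_on [1/(M s)]         k_2 [1/s]              K_D [M]                K_D,2 [M]
quickstart   1.7 x 10^-2 +/- 2.93   1.1 x 10^-2 +/- 2.93   1.3 x 10^4 +/- 0.04    4.1 x 10^0 +/- 0.10    1.3 x 10^-6 +/- 2.93   8.7 x 10^-7 +/- 2.93
```

Reading the columns: the fitted dissociation rate `1.7e-2 /s` sits 0.25
decades from the generating 3e-2 /s (the quoted +/-2.93 is the log10
standard error under the convention that segment peak SDs — here ~10 pN —
are absolute force errors); the second-bond association rate `4.1 /s`
recovers the generating `1/tau_2 = 4 /s`; the two-bond column is exactly
2/3 of the first; and the affinity `K_D = k_off/k_on ~ 1.3 uM` is in the
micromolar range typical of antibody:receptor bonds. The bundle also
contains `overlay.png` (force vs loading rate with the one- and two-bond
curves), the events table, and a reproducibility record. A larger run
(6 speeds x 600 curves, `forcekin kinetics` with a custom config) recovers
`k_off` to within ~0.06 decades and `x_beta` to within ~2%.

The AFM side has its own subcommand:

```bash
forcekin volumes --out results_volumes --seed 0
```

which synthesizes images of a 27/54 nm^3 monomer/dimer mixture, runs the
levelling/masking/volumetry chain and prints the fitted peaks,
classification boundary (~40 nm^3) and state fractions.

## Layout

| module | contents |
| --- | --- |
| `forcekin.bond_physics` | Bell-Evans and Williams models, rupture-force distribution, effective concentration |
| `forcekin.simulate` | force-curve simulator: scenarios, binding-state draws, rupture cascades, WLC rendering |
| `forcekin.curves` | noise estimation, rupture-event detection, binding probability, pattern classification |
| `forcekin.densities` | heteroscedastic Gaussian-sum pdfs, mixture fits, loading-rate segmentation |
| `forcekin.kinetics` | Bell-Evans fit, P(t) fit, derived rates, rate tables, group comparison |
| `forcekin.afm` | image levelling/smoothing/masking, particle volumes, oligomer assignment, image synthesis |
| `forcekin.archive` / `config` / `pipeline` / `cli` | HDF5/CSV/TIFF/JSONL formats, YAML config, end-to-end pipeline, subcommand CLI |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
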