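"""End-to-end orchestration: simulate -> detect -> segment -> fit -> summarize.

`run_smfs_pipeline` drives the full force-spectroscopy chain on a simulated
dataset and writes a reproducible result bundle; `run_volume_pipeline` does
the same for the AFM volumetrics chain on synthetic height images. Both are
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from pathlib import Path

import numpy as np

from . import afm
from .archive import events_to_frame, write_curve_archive
from .config import PipelineConfig
from .curves import binding_probability, classify_pattern, detect_ruptures
from .densities import build_pdf, fit_multi_gaussian, segment_by_loading_rate, segment_peak_stats
from .errors import InsufficientDataError
from .kinetics import (
    compute_k2,
    compute_kon,
    effective_concentration,
    fit_bell_evans,
    fit_binding_kinetics,
    predict_double_bond_overlay,
    summarize_rates,
)
from .simulate import simulate_dataset


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def analyze_curves(curves, detection) -> tuple[list, list[int]]:
    """Detect rupture events on every curve; returns (events, events-per-curve)."""
    all_events, counts = [], []
    for curve in curves:
        events = detect_ruptures(
            curve,
            min_drop_sigma=detection.min_drop_sigma,
            max_drop_width=detection.max_drop_width_nm,
            slope_window=detection.slope_window_nm,
            min_drop_abs=detection.min_drop_abs_pN,
        )
        all_events.extend(events)
        counts.append(len(events))
    return all_events, counts


def dynamic_force_spectrum(events):
    """Loading-rate segmentation with per-segment peak statistics and the
    Bell-Evans fit of the monovalent branch."""
    segments = [segment_peak_stats(s) for s in segment_by_loading_rate(events)]
    fit = fit_bell_evans(segments)
    return segments, fit


def run_smfs_pipeline(config: PipelineConfig, output_dir=None, seed: int | None = None) -> dict:
    """Execute the full simulated-SMFS analysis chain.

    Returns the result dictionary; when ``output_dir`` is given, also writes
    the curve archive, events table, rate table (CSV + formatted text), the
    force-vs-loading-rate overlay plot and a reproducibility record.
    """
    scenario = config.scenario.to_scenario(seed=seed)
    dataset = simulate_dataset(scenario)
    events, counts = analyze_curves(dataset.curves, config.detection)
    if not events:
        raise InsufficientDataError("no rupture events detected in the dataset")

    # dynamic force spectrum and Bell-Evans fit
    segments, be_fit = dynamic_force_spectrum(events)
    rate_grid = np.geomspace(min(s.representative_rate for s in segments) / 2,
                             max(s.representative_rate for s in segments) * 2, 50)
    overlay = predict_double_bond_overlay(be_fit, rate_grid)

    # mixture decomposition of the pooled force pdf -> monovalent reference
    pdf = build_pdf([e.unbinding_force for e in events],
                    [e.noise_sigma for e in events])
    mixture = fit_multi_gaussian(pdf, config.n_mixture_components)
    single_ref = float(mixture.means[0])

    # per-curve event bookkeeping
    by_curve = defaultdict(list)
    for e in events:
        by_curve[e.curve_id].append(e)

    # binding probability vs contact time (pooled over speeds)
    by_tc_counts = defaultdict(list)
    by_tc_double = defaultdict(lambda: [0, 0])  # bound, double
    for curve in dataset.curves:
        evs = by_curve.get(curve.curve_id, [])
        by_tc_counts[curve.contact_time].append(len(evs))
        if evs:
            pattern = classify_pattern(evs, single_ref)
            by_tc_double[curve.contact_time][0] += 1
            if pattern in ("sequential", "simultaneous"):
                by_tc_double[curve.contact_time][1] += 1

    tc = sorted(by_tc_counts)
    p_binding, p_se = [], []
    for t in tc:
        frac, (lo, hi) = binding_probability(by_tc_counts[t])
        p_binding.append(frac)
        p_se.append(max((hi - lo) / 4.0, 1e-3))

    results = {
        "n_curves": len(dataset.curves),
        "n_events": len(events),
        "binding_probability": {str(t): p for t, p in zip(tc, p_binding)},
        "segments": [{
            "log10_range": [s.log10_lo, s.log10_hi],
            "n_events": s.n_events,
            "representative_rate_pN_s": s.representative_rate,
            "peak_mean_pN": s.peak_mean,
            "peak_sd_pN": s.peak_sd,
        } for s in segments],
        "bell_evans": {
            "k_off_per_s": be_fit.params.k_off,
            "x_beta_nm": be_fit.params.x_beta,
            "se_log10_k_off": be_fit.se_log10_koff,
            "se_xbeta_nm": be_fit.se_xbeta,
            "n_segments": be_fit.n_segments,
        },
        "mixture_components": [list(c) for c in mixture.components],
        "overlay": {"rates_pN_s": rate_grid.tolist(), "forces_pN": overlay.tolist()},
    }

    # binding kinetics (needs a spread of contact times)
    if len(tc) >= 4:
        kin1 = fit_binding_kinetics(tc, p_binding, uncertainties=p_se, bond_order=1)
        c_eff = effective_concentration(config.kinetics.tether_radius_nm,
                                        config.kinetics.n_ligands)
        k_on, se_kon = compute_kon(kin1.tau, c_eff, kin1.se_log10_tau)
        results["binding_kinetics"] = {
            "A": kin1.A, "t0_s": kin1.t0, "tau_s": kin1.tau,
            "se_log10_tau": kin1.se_log10_tau,
            "c_eff_M": c_eff, "k_on_per_M_s": k_on,
        }
        p2 = [by_tc_double[t][1] / by_tc_double[t][0] if by_tc_double[t][0] else 0.0
              for t in tc]
        k_2 = None
        try:
            kin2 = fit_binding_kinetics(tc, p2, bond_order=2)
            k_2, se_k2 = compute_k2(kin2.tau, kin2.se_log10_tau)
            results["second_bond_kinetics"] = {
                "A2": kin2.A, "tau2_s": kin2.tau, "k_2_per_s": k_2,
            }
        except Exception:
            se_k2 = 0.0
        table = summarize_rates({config.kinetics.construct_name: {
            "k_off": be_fit.params.k_off, "se_log10_k_off": be_fit.se_log10_koff,
            "k_on": k_on, "se_log10_k_on": se_kon,
            "k_2": k_2 if k_2 is not None else float("nan"),
            "se_log10_k_2": se_k2,
        }})
        results["rate_table"] = json.loads(table.frame.to_json(orient="index"))
    else:
        table = None

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_curve_archive(dataset, out / "curves.h5", out / "truth.jsonl",
                            out / "manifest.json")
        events_to_frame(events).to_csv(out / "events.csv", index=False)
        (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        if table is not None:
            table.to_csv(out / "rate_table.csv")
            (out / "rate_table.txt").write_text(table.to_text() + "\n")
        _plot_overlay(segments, be_fit, rate_grid, overlay, out / "overlay.png")
        (out / "reproducibility.json").write_text(json.dumps({
            "config_hash": _config_hash(config),
            "seed": scenario.seed,
            "config": config.model_dump(),
        }, indent=2, sort_keys=True, default=str))
    return results


def _plot_overlay(segments, be_fit, rate_grid, overlay, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .bond_physics import bell_evans_force

    fig, ax = plt.subplots(figsize=(5, 4))
    rates = [s.representative_rate for s in segments]
    means = [s.peak_mean for s in segments]
    sds = [s.peak_sd for s in segments]
    ax.errorbar(rates, means, yerr=sds, fmt="o", color="crimson",
                label="segment peak (monovalent)")
    ax.semilogx(rate_grid, bell_evans_force(rate_grid, be_fit.params),
                "-", color="crimson", label="Bell-Evans fit")
    ax.semilogx(rate_grid, overlay, "-", color="royalblue",
                label="parallel 2-bond prediction")
    ax.set_xlabel("loading rate (pN/s)")
    ax.set_ylabel("most probable rupture force (pN)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_volume_pipeline(
    volumes_truth,
    rng: np.random.Generator,
    n_images: int = 10,
    n_states: int | None = None,
    noise_sigma: float = 0.05,
    smoothing_sigma_px: float = 1.0,
    output_dir=None,
) -> dict:
    """Synthesize height images for the given ground-truth particle volumes,
    run the full volumetrics chain and return the oligomer model summary.

    ``volumes_truth`` is the flat list of particle volumes (nm^3); it is
    split across ``n_images`` images.
    """
    vols = np.asarray(volumes_truth, dtype=float)
    chunks = np.array_split(vols, n_images)
    measured = []
    for chunk in chunks:
        if chunk.size == 0:
            continue
        img, _truth = afm.synth_afm_image(chunk, rng, noise_sigma=noise_sigma)
        ny, nx = img.shape
        anchors = [(5, 5), (5, nx - 6), (ny - 6, nx // 2)]
        leveled = afm.level_plane(img, anchors)
        smoothed = afm.smooth(leveled, smoothing_sigma_px)
        labels = afm.mask_particles(img, smoothed)
        records = afm.particle_volumes(labels, leveled)
        measured.extend(r.volume for r in records if not r.touches_border)

    pdf = afm.volume_pdf(measured)
    model = afm.assign_oligomer_states(pdf, measured, n_states=n_states)
    results = {
        "n_particles_truth": int(vols.size),
        "n_particles_measured": len(measured),
        "peak_means_nm3": model.peak_means.tolist(),
        "boundaries_nm3": model.boundaries.tolist(),
        "fractions": model.fractions.tolist(),
        "counts": model.counts.tolist(),
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "oligomer_model.json").write_text(json.dumps(results, indent=2))
    return results
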