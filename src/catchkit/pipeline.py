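"""End-to-end workflow: simulate -> analyze -> fit -> report.

The pipeline streams curves (simulate, analyze, optionally write, discard)
so memory stays bounded for thousand-curve batches, then runs the kinetics
stack on the pooled per-curve records: pathway fractions per speed,
Bell--Evans fits per pathway, the XMod censoring-bias correction, the
combined P1/P2 off-rate transformation with its catch-bond crossover, and
DHS fits. All outputs are plain-text CSV/TSV plus a run log recording the
package version, config hash and root seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .curves import analyze_curve
from .elasticity import Environment
from .kinetics import (
    BiasCorrectionResult,
    FitResult,
    ForceHistogram,
    OffRateCurve,
    average_offrates_across_speeds,
    correct_xmod_bias,
    fit_bell_evans,
    fit_dhs,
    histogram_to_offrates,
    most_probable_force_per_speed,
)
from .simulate import curve_seed_sequences, simulate_constant_speed
from .io import write_curve_tsv

logger = logging.getLogger("catchkit")

__all__ = [
    "simulate_and_analyze",
    "pathway_fractions",
    "rupture_groups",
    "fit_pathway_bell_evans",
    "xmod_observed_fractions",
    "combined_offrate_curves",
    "crossover_force",
    "run_pipeline",
]


def _analysis_kwargs(config: RunConfig) -> dict:
    a = config.analysis
    return dict(
        frc=a.frc_params(),
        env=config.environment(),
        force_floor=a.force_floor,
        bin_width=a.contour_bin_width,
        smooth_sigma_nm=a.smooth_sigma_nm,
        min_separation_nm=a.min_separation_nm,
        fingerprint_total=a.fingerprint_total,
        fingerprint_tol=a.fingerprint_tol,
        substep_window=a.substep_window,
        xmod_window=a.xmod_window,
        p1_threshold=a.p1_threshold,
    )


def simulate_and_analyze(config: RunConfig,
                         outdir: Optional[Path] = None,
                         speeds: Optional[Sequence[float]] = None,
                         n_curves: Optional[int] = None,
                         seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate the configured batch and analyze each curve on the fly.

    Returns one row per simulated curve with both the simulator truth
    (binding mode, true pathway, event list summary) and the analysis
    outcome (classification, rupture force, loading rate, increments).
    When ``outdir`` is given and ``config.save_curves`` is set, curves are
    written as TSV + JSON sidecars with a manifest CSV.
    """
    speeds = tuple(speeds if speeds is not None else config.protocol.speeds)
    n_curves = int(n_curves if n_curves is not None else config.protocol.n_curves)
    seed = int(seed if seed is not None else config.seed)
    env = config.environment()
    network = config.network.to_network()
    kwargs = _analysis_kwargs(config)

    curve_dir = None
    manifest = []
    if outdir is not None and config.save_curves:
        curve_dir = Path(outdir) / "curves"
        curve_dir.mkdir(parents=True, exist_ok=True)

    children = curve_seed_sequences(seed, len(speeds) * n_curves)
    rows = []
    idx = 0
    for speed in speeds:
        protocol = config.protocol.to_protocol(speed)
        for j in range(n_curves):
            rng = np.random.default_rng(children[idx])
            curve = simulate_constant_speed(network, protocol, rng, env)
            source_id = f"v{int(speed)}_{j:05d}"
            rec = analyze_curve(curve, source_id=source_id, **kwargs)
            rows.append({
                "source_id": source_id,
                "speed": speed,
                "binding_mode": curve.binding_mode,
                "true_pathway": curve.true_pathway,
                "ruptured": curve.ruptured,
                "true_rupture_force": (curve.rupture_event.force
                                       if curve.rupture_event else np.nan),
                "true_xmod_unfolded": any(ev.name == "xmod_unfold"
                                          for ev in curve.events),
                "pathway": rec.pathway,
                "rupture_force": rec.rupture_force,
                "loading_rate": rec.loading_rate,
                "fingerprint_ok": rec.fingerprint_ok,
                "xmod_step_present": rec.xmod_step_present,
                "xmod_unfold_force": rec.xmod_unfold_force,
                "xmod_unfold_rate": rec.xmod_unfold_rate,
                "n_increments": len(rec.increments),
                "fp_total": sum(i.size for i in rec.increments
                                if kwargs["substep_window"][0] <= i.size
                                <= kwargs["substep_window"][1]),
            })
            if curve_dir is not None:
                fname = f"curve_{source_id}.tsv"
                write_curve_tsv(curve, curve_dir / fname)
                manifest.append({"file": fname, "speed": speed,
                                 "source_id": source_id})
            idx += 1
    df = pd.DataFrame(rows)
    if curve_dir is not None and manifest:
        pd.DataFrame(manifest).to_csv(curve_dir / "manifest.csv", index=False)
    return df


def pathway_fractions(df: pd.DataFrame) -> pd.DataFrame:
    """Percentage of P1/P2/P3 among classified curves, per pulling speed."""
    rows = []
    for speed, grp in df.groupby("speed"):
        cls = grp[grp["pathway"].isin(["P1", "P2", "P3"])]
        n = len(cls)
        row = {"speed": speed, "n_classified": n}
        for p in ("P1", "P2", "P3"):
            row[f"{p}_pct"] = 100.0 * (cls["pathway"] == p).sum() / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("speed").reset_index(drop=True)


def rupture_groups(df: pd.DataFrame, pathways: Sequence[str]) -> dict:
    """speed -> (rupture forces, loading rates) for the given pathways."""
    out = {}
    sel = df[df["pathway"].isin(list(pathways))].dropna(
        subset=["rupture_force", "loading_rate"])
    for speed, grp in sel.groupby("speed"):
        out[float(speed)] = (grp["rupture_force"].to_numpy(),
                             grp["loading_rate"].to_numpy())
    return out


def fit_pathway_bell_evans(df: pd.DataFrame, config: RunConfig) -> dict:
    """Bell--Evans fits of most-probable force vs. log loading rate for the
    P1/P2/P3 rupture events and the observed XMod unfolding events."""
    env = config.environment()
    min_ev = config.analysis.min_events_per_speed
    fits: dict[str, FitResult] = {}
    for tag, paths in (("P1", ["P1"]), ("P2", ["P2"]), ("P3", ["P3"])):
        groups = rupture_groups(df, paths)
        pts = most_probable_force_per_speed(groups, min_events=min_ev)
        if len(pts) >= 2:
            fits[tag] = fit_bell_evans(list(pts.values()), env)
    xm = df.dropna(subset=["xmod_unfold_force", "xmod_unfold_rate"])
    groups = {
        float(s): (g["xmod_unfold_force"].to_numpy(),
                   g["xmod_unfold_rate"].to_numpy())
        for s, g in xm.groupby("speed")
    }
    pts = most_probable_force_per_speed(groups, min_events=min_ev)
    if len(pts) >= 2:
        fits["xmod_measured"] = fit_bell_evans(list(pts.values()), env)
    return fits


def xmod_observed_fractions(df: pd.DataFrame) -> dict:
    """speed -> observed fraction of strong-mode (P1 or P2) curves showing
    the XMod unfolding step."""
    out = {}
    strong = df[df["pathway"].isin(["P1", "P2"])]
    for speed, grp in strong.groupby("speed"):
        if len(grp):
            out[float(speed)] = float((grp["pathway"] == "P2").mean())
    return out


def combined_offrate_curves(df: pd.DataFrame, config: RunConfig,
                            pathways: Sequence[str] = ("P1", "P2")
                            ) -> tuple[dict, OffRateCurve]:
    """Histogram-transform off-rate curves of the pooled rupture events of
    the given pathways, one per speed, plus their across-speed average."""
    groups = rupture_groups(df, pathways)
    curves = {}
    for speed, (forces, rates) in groups.items():
        if forces.size < config.analysis.min_events_per_speed:
            continue
        hist = ForceHistogram.from_events(
            forces, rates, bin_width=config.analysis.force_bin_width)
        curves[speed] = histogram_to_offrates(hist)
    if len(curves) < 2:
        raise ValueError("need off-rate curves from at least two speeds")
    averaged = average_offrates_across_speeds(
        curves, bin_width=config.analysis.force_bin_width)
    return curves, averaged


def crossover_force(curve: OffRateCurve,
                    drop_factor: float = 2.0) -> float:
    """Force at the catch-bond crossover: the first local maximum of the
    off-rate curve that is followed by a decrease of at least
    ``drop_factor`` before the off-rate exceeds the maximum again.
    Returns NaN when the curve is monotone (no crossover).
    """
    f, k = curve.force, curve.k_off
    n = k.size
    for i in range(1, n - 1):
        if not (k[i] >= k[i - 1] and k[i] > k[i + 1]):
            continue
        fell = False
        for j in range(i + 1, n):
            if k[j] <= k[i] / drop_factor:
                fell = True
                break
            if k[j] > k[i]:
                break
        if fell:
            return float(f[i])
    return float("nan")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full workflow and write the report bundle to ``outdir``.

    Emits: frozen effective config, per-curve records CSV, pathway-fraction
    table, Bell--Evans parameter table (with measured and bias-corrected
    XMod rows), off-rate CSVs (per speed and averaged) with the crossover
    force, DHS fits of the weak-mode and combined curves, and a run log.
    Returns a summary dict with the main results in memory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        config.to_yaml(outdir / "effective_config.yaml")
        logger.info("catchkit %s | config %s | seed %d",
                    __version__, config.config_hash(), config.seed)

        df = simulate_and_analyze(config, outdir=outdir)
        df.to_csv(outdir / "records.csv", index=False, float_format="%.17g")
        logger.info("simulated and analyzed %d curves", len(df))

        fractions = pathway_fractions(df)
        fractions.to_csv(outdir / "pathway_fractions.csv", index=False)

        fits = fit_pathway_bell_evans(df, config)
        correction: Optional[BiasCorrectionResult] = None
        if config.analysis.correct_xmod and "P1" in fits and "xmod_measured" in fits:
            obs = xmod_observed_fractions(df)
            if len(obs) >= 3:
                # competition plays out on the fully fingerprint-unfolded
                # polymer with XMod still intact
                lc_ext = config.network.base_Lc + config.network.n_fingerprints * (
                    config.network.fingerprint_step1.delta_Lc
                    + config.network.fingerprint_step2.delta_Lc)
                correction = correct_xmod_bias(
                    obs,
                    rupture_params=fits["P1"].bell_evans,
                    initial_unfold_params=fits["xmod_measured"].bell_evans,
                    contour_length=lc_ext,
                    env=config.environment(),
                    persistence=config.network.persistence,
                    spring_constant=config.protocol.spring_constant,
                )
                logger.info("xmod bias correction converged=%s nfev=%d",
                            correction.converged, correction.n_eval)

        rows = []
        for tag, fit in fits.items():
            rows.append({"process": tag, "model": fit.model,
                         "k0_per_s": fit.params["k0"],
                         "dx_nm": fit.params["dx"],
                         "dG_kBT": fit.params.get("dG", np.nan)})
        if correction is not None:
            rows.append({"process": "xmod_corrected", "model": "BE",
                         "k0_per_s": correction.corrected.k0,
                         "dx_nm": correction.corrected.dx,
                         "dG_kBT": np.nan})

        from .io import write_offrate_csv

        speed_curves, averaged = combined_offrate_curves(df, config)
        for speed, curve in speed_curves.items():
            write_offrate_csv(curve, outdir / f"offrates_p1p2_v{int(speed)}.csv")
        write_offrate_csv(averaged, outdir / "offrates_p1p2_averaged.csv")
        xover = crossover_force(averaged)
        logger.info("combined P1/P2 off-rate crossover at %.1f pN", xover)

        p3_groups = rupture_groups(df, ["P3"])
        dhs_fits = {}
        try:
            p3_curves = {}
            for speed, (forces, rates) in p3_groups.items():
                if forces.size < config.analysis.min_events_per_speed:
                    continue
                hist = ForceHistogram.from_events(
                    forces, rates, bin_width=config.analysis.force_bin_width)
                p3_curves[speed] = histogram_to_offrates(hist)
            if len(p3_curves) >= 2:
                p3_avg = average_offrates_across_speeds(
                    p3_curves, bin_width=config.analysis.force_bin_width)
                write_offrate_csv(p3_avg, outdir / "offrates_p3_averaged.csv")
                for nu in (0.5, 2.0 / 3.0):
                    fit = fit_dhs(p3_avg, nu=nu, env=config.environment())
                    dhs_fits[f"P3_nu{nu:.3g}"] = fit
                    rows.append({"process": "P3", "model": fit.model,
                                 "k0_per_s": fit.params["k0"],
                                 "dx_nm": fit.params["dx"],
                                 "dG_kBT": fit.params["dG"]})
        except (ValueError, RuntimeError) as exc:
            logger.warning("P3 DHS fitting skipped: %s", exc)

        params_df = pd.DataFrame(rows)
        params_df.to_csv(outdir / "parameter_table.csv", index=False,
                         float_format="%.6g")

        summary = {
            "records": df,
            "pathway_fractions": fractions,
            "bell_evans_fits": fits,
            "xmod_correction": correction,
            "dhs_fits": dhs_fits,
            "offrates_averaged": averaged,
            "crossover_force_pN": xover,
            "elapsed_s": time.time() - t0,
        }
        logger.info("pipeline finished in %.1f s", summary["elapsed_s"])
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
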