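"""Recompute the headline quantities of the modelled study from scratch.

Each function runs the package end to end — simulation, curve analysis,
fitting — under the default study conditions and returns the measured
quantity. :func:`reproduce_all` bundles them for the acceptance script and
the ``reproduce-paper`` CLI subcommand.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import RunConfig
from .curves import analyze_curve
from .elasticity import be_most_probable_force
from .fret import (
    FRETCorrections,
    compute_efficiency,
    fit_efficiency_mixture,
    generate_synthetic_bursts,
    stoichiometry_filter,
)
from .pipeline import (
    _analysis_kwargs,
    combined_offrate_curves,
    crossover_force,
    fit_pathway_bell_evans,
    pathway_fractions,
    simulate_and_analyze,
)
from .simulate import curve_seed_sequences, simulate_constant_speed

__all__ = [
    "strong_mode_rupture_force",
    "weak_mode_rupture_force",
    "fingerprint_total_on_simulated_curve",
    "reproduce_all",
]

LOADING_RATE_REFERENCE = 1.0e4  # pN/s (10 nN/s)


def strong_mode_rupture_force(config: RunConfig | None = None,
                              loading_rate: float = LOADING_RATE_REFERENCE) -> float:
    """Closed-form most probable rupture force of the strong binding mode
    (pathway 1 parameters) at the reference loading rate."""
    config = config or RunConfig()
    p = config.network.rupture_p1
    from .elasticity import BellEvansParams
    return be_most_probable_force(
        loading_rate, BellEvansParams(k0=p.k0, dx=p.dx), config.environment())


def weak_mode_rupture_force(config: RunConfig | None = None,
                            loading_rate: float = LOADING_RATE_REFERENCE) -> float:
    """Closed-form most probable rupture force of the weak binding mode
    (pathway 3 parameters) at the reference loading rate."""
    config = config or RunConfig()
    p = config.network.rupture_p3
    from .elasticity import BellEvansParams
    return be_most_probable_force(
        loading_rate, BellEvansParams(k0=p.k0, dx=p.dx), config.environment())


def fingerprint_total_on_simulated_curve(config: RunConfig | None = None,
                                         seed: int = 0,
                                         speed: float = 400.0,
                                         max_tries: int = 50) -> float:
    """Simulate one constant-speed curve containing both double-sub-step
    fingerprint unfoldings, run the contour-length transformation and
    increment detection, and sum the fingerprint-attributed increments."""
    config = config or RunConfig()
    env = config.environment()
    network = config.network.to_network()
    protocol = config.protocol.to_protocol(speed)
    kwargs = _analysis_kwargs(config)
    n_steps = 2 * config.network.n_fingerprints
    children = curve_seed_sequences(seed, max_tries)
    for child in children:
        rng = np.random.default_rng(child)
        curve = simulate_constant_speed(network, protocol, rng, env)
        fp_events = sum(ev.name.startswith("ddfln4") for ev in curve.events)
        if not curve.ruptured or fp_events < n_steps:
            continue
        rec = analyze_curve(curve, **kwargs)
        if rec.fingerprint_ok:
            lo, hi = kwargs["substep_window"]
            return float(sum(i.size for i in rec.increments if lo <= i.size <= hi))
    raise RuntimeError("no analyzable curve with both fingerprints found")


def fret_lower_mean(config: RunConfig | None = None, seed: int = 0,
                    n_bursts: int = 2000,
                    populations=((0.34, 0.2), (0.71, 0.8)),
                    mean_burst_size: float = 80.0) -> float:
    """Generate a synthetic two-population burst dataset, run stoichiometry
    filtering and corrected-efficiency calculation, fit a two-Gaussian
    mixture and return the lower component mean."""
    config = config or RunConfig()
    corr = FRETCorrections(alpha=config.fret.alpha, delta=config.fret.delta,
                           gamma_f=config.fret.gamma_f)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    bursts = generate_synthetic_bursts(list(populations), n_bursts, corr, rng,
                                       mean_burst_size=mean_burst_size)
    kept = stoichiometry_filter(bursts, corr, config.fret.stoichiometry_bounds)
    eff = [e for e in (compute_efficiency(b, corr) for b in kept)
           if e is not None]
    fit = fit_efficiency_mixture(eff, n_components=2,
                                 bin_width=config.fret.efficiency_bin_width)
    return float(fit.means[0])


def reproduce_all(seed: int = 0, n_curves: int = 1000,
                  config: RunConfig | None = None) -> dict:
    """All headline quantities, as {name: {"value": float, "n": int}}.

    The multi-speed Monte Carlo dataset (``n_curves`` per speed at
    {100, 400, 1600, 6400} nm/s) is simulated once and reused for the
    pathway fractions, the off-rate crossover and the loading-rate fit.
    """
    config = config or RunConfig()
    config = replace(config, seed=seed, save_curves=False)

    results: dict[str, dict] = {}
    results["strong_mode_rupture_force_pN"] = {
        "value": strong_mode_rupture_force(config), "n": 1}
    results["weak_mode_rupture_force_pN"] = {
        "value": weak_mode_rupture_force(config), "n": 1}
    results["fingerprint_total_nm"] = {
        "value": fingerprint_total_on_simulated_curve(config, seed=seed), "n": 1}

    df = simulate_and_analyze(config, n_curves=n_curves)

    frac = pathway_fractions(df)
    at_400 = frac[frac["speed"] == 400.0]
    results["p3_percent_400nm_s"] = {
        "value": float(at_400["P3_pct"].iloc[0]),
        "n": int(at_400["n_classified"].iloc[0]),
    }

    _, averaged = combined_offrate_curves(df, config)
    results["offrate_crossover_pN"] = {
        "value": crossover_force(averaged),
        "n": int(df["pathway"].isin(["P1", "P2"]).sum()),
    }

    fits = fit_pathway_bell_evans(df, config)
    results["p1_dx_nm"] = {
        "value": float(fits["P1"].params["dx"]),
        "n": int((df["pathway"] == "P1").sum()),
    }

    results["fret_lower_mean_efficiency"] = {
        "value": fret_lower_mean(config, seed=seed), "n": 2000}

    return results
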