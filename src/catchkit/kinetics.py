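"""Energy-landscape parameter estimation from rupture/unfolding force data.

Implements the dynamic force spectroscopy fitting stack:

* most-probable force extraction per pulling speed (Gaussian fit of the
  force histogram, KDE-mode fallback) and the linear Bell--Evans fit of
  most-probable force against log loading rate;
* the histogram transformation of rupture-force histograms into
  force-dependent off-rates, and its continuous (KDE) form;
* weighted nonlinear Dudko--Hummer--Szabo fits of off-rate curves;
* the censoring-bias correction of XMod unfolding parameters: observed
  unfolding statistics are biased because complex rupture terminates the
  observation, so the unfolding parameters are re-estimated by matching the
  predicted fraction of curves showing unfolding to the observed fraction
  across pulling speeds, with the complex-rupture parameters held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .elasticity import (
    BellEvansParams,
    DHSParams,
    Environment,
    WLCParams,
    be_rate,
    dhs_max_force,
    dhs_rate,
    wlc_force,
)

__all__ = [
    "ForceHistogram",
    "OffRateCurve",
    "FitResult",
    "BiasCorrectionResult",
    "most_probable_force_per_speed",
    "fit_bell_evans",
    "histogram_to_offrates",
    "kde_to_offrates",
    "average_offrates_across_speeds",
    "fit_dhs",
    "unfolding_probability_ramp",
    "correct_xmod_bias",
]

DEFAULT_BIN_WIDTH_PN = 40.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ForceHistogram:
    """Equal-width rupture/unfolding force histogram with per-bin loading
    rates.

    ``heights`` are normalized as h_k = C_k / (C_tot dF), so that
    sum(h_k dF) = 1.
    """

    edges: np.ndarray          # length N+1, starting at F0
    counts: np.ndarray         # length N
    mean_force: np.ndarray     # per-bin mean event force (NaN if empty)
    mean_loading_rate: np.ndarray  # per-bin mean loading rate (NaN if empty)

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def heights(self) -> np.ndarray:
        return self.counts / (self.total * self.bin_width)

    @classmethod
    def from_events(cls, forces, loading_rates,
                    bin_width: float = DEFAULT_BIN_WIDTH_PN,
                    f0: float = 0.0) -> "ForceHistogram":
        forces = np.asarray(forces, dtype=float)
        rates = np.asarray(loading_rates, dtype=float)
        if forces.size == 0:
            raise ValueError("no events")
        n_bins = int(np.ceil((forces.max() - f0) / bin_width)) + 1
        edges = f0 + bin_width * np.arange(n_bins + 1)
        idx = np.clip(((forces - f0) // bin_width).astype(int), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        mean_f = np.full(n_bins, np.nan)
        mean_r = np.full(n_bins, np.nan)
        for k in range(n_bins):
            sel = idx == k
            if sel.any():
                mean_f[k] = forces[sel].mean()
                mean_r[k] = rates[sel].mean()
        return cls(edges=edges, counts=counts, mean_force=mean_f,
                   mean_loading_rate=mean_r)


@dataclass
class OffRateCurve:
    """Force-dependent off-rate points, optionally with dispersion."""

    force: np.ndarray
    k_off: np.ndarray
    k_off_std: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.k_off = np.asarray(self.k_off, dtype=float)
        if np.any(self.k_off <= 0):
            raise ValueError("off-rates must be positive")


@dataclass
class FitResult:
    model: str                      # "BE" | "DHS-0.5" | "DHS-0.667" | "DHS-1"
    params: dict
    residual_norm: float
    covariance: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def bell_evans(self) -> BellEvansParams:
        return BellEvansParams(k0=self.params["k0"], dx=self.params["dx"])


@dataclass
class BiasCorrectionResult:
    measured: BellEvansParams
    corrected: BellEvansParams
    converged: bool
    objective: float
    n_eval: int


# ---------------------------------------------------------------------------
# Most probable force and Bell-Evans fit
# ---------------------------------------------------------------------------

def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _most_probable_force(forces: np.ndarray) -> float:
    """Mode of a force sample: Gaussian fit of its histogram, KDE fallback."""
    iqr = np.subtract(*np.percentile(forces, [75, 25]))
    width = max(2.0 * iqr * forces.size ** (-1 / 3), 5.0)
    edges = np.arange(forces.min() - width, forces.max() + 2 * width, width)
    counts, edges = np.histogram(forces, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        p0 = (counts.max(), float(centers[np.argmax(counts)]), max(forces.std(), width))
        popt, _ = optimize.curve_fit(_gaussian, centers, counts, p0=p0, maxfev=5000)
        mu = float(popt[1])
        if forces.min() - width <= mu <= forces.max() + width:
            return mu
    except RuntimeError:
        pass
    kde = stats.gaussian_kde(forces)
    grid = np.linspace(forces.min(), forces.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def most_probable_force_per_speed(groups: dict,
                                  min_events: int = 20) -> dict:
    """Most probable force and mean loading rate per pulling speed.

    ``groups`` maps speed -> (forces, loading_rates). Speeds with fewer
    than ``min_events`` events are excluded. Returns speed -> (F*, r_mean).
    """
    out = {}
    for speed, (forces, rates) in groups.items():
        forces = np.asarray(forces, dtype=float)
        rates = np.asarray(rates, dtype=float)
        ok = np.isfinite(forces) & np.isfinite(rates) & (rates > 0)
        forces, rates = forces[ok], rates[ok]
        if forces.size < min_events:
            continue
        out[speed] = (_most_probable_force(forces), float(rates.mean()))
    return out


def fit_bell_evans(points: Sequence[tuple[float, float]],
                   env: Environment = Environment()) -> FitResult:
    """Linear Bell--Evans fit of most-probable force vs. log loading rate.

    ``points`` are (F*, loading rate) pairs, one per speed. The slope of
    F* on ln r gives dx = kBT/slope and the intercept gives k0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two speeds for a Bell-Evans fit")
    fstar, r = pts[:, 0], pts[:, 1]
    lnr = np.log(r)
    res = stats.linregress(lnr, fstar)
    if res.slope <= 0:
        raise ValueError("inverted loading-rate dependence: non-positive slope")
    dx = env.kBT / res.slope
    # intercept = slope * ln(dx / (k0 kBT))
    k0 = dx / (env.kBT * math.exp(res.intercept / res.slope))
    pred = res.intercept + res.slope * lnr
    return FitResult(
        model="BE",
        params={"k0": k0, "dx": dx},
        residual_norm=float(np.sqrt(np.sum((fstar - pred) ** 2))),
        diagnostics={"slope": res.slope, "intercept": res.intercept,
                     "stderr": res.stderr, "r_value": res.rvalue,
                     "n_speeds": len(points)},
    )


# ---------------------------------------------------------------------------
# Histogram / KDE transformation to off-rates
# ---------------------------------------------------------------------------

def histogram_to_offrates(hist: ForceHistogram) -> OffRateCurve:
    """Transform a rupture-force histogram into force-dependent off-rates:

        k_off(F_k) = h_k r(F_k) / ( (h_k/2 + sum_{i>k} h_i) dF )

    Zero-count bins are skipped; for the last occupied bin the denominator
    reduces to (h_k/2) dF.
    """
    if hist.total <= 0:
        raise ValueError("empty histogram")
    h = hist.heights
    dF = hist.bin_width
    forces, rates, counts = [], [], []
    for k in range(len(h)):
        if hist.counts[k] == 0 or not hist.mean_loading_rate[k] > 0:
            continue
        denom = (h[k] / 2.0 + h[k + 1:].sum()) * dF
        forces.append(hist.mean_force[k])
        rates.append(h[k] * hist.mean_loading_rate[k] / denom)
        counts.append(hist.counts[k])
    return OffRateCurve(force=np.array(forces), k_off=np.array(rates),
                        counts=np.array(counts), source="histogram")


def kde_to_offrates(forces, loading_rates,
                    bandwidth: Optional[float] = None,
                    n_grid: int = 256,
                    survival_floor: float = 1e-3) -> OffRateCurve:
    """Continuous form of the histogram transformation:

        k_off(F) = P(F) r(F) / (1 - int_0^F P)

    with P(F) a Gaussian KDE of the rupture-force distribution and r(F) the
    loading rate interpolated against force. The curve is truncated where
    the survival drops below ``survival_floor`` (tail instability).
    """
    forces = np.asarray(forces, dtype=float)
    rates = np.asarray(loading_rates, dtype=float)
    if forces.size < 50:
        raise ValueError("need at least 50 events for the KDE transform")
    kde = stats.gaussian_kde(forces, bw_method=bandwidth)
    grid = np.linspace(forces.min(), forces.max(), n_grid)
    dens = kde(grid)
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(grid))))
    cdf += kde.integrate_box_1d(-np.inf, grid[0])
    survival = np.clip(1.0 - cdf, 0.0, None)

    order = np.argsort(forces)
    r_of_f = np.interp(grid, forces[order], rates[order])

    keep = survival > survival_floor
    k = dens[keep] * r_of_f[keep] / survival[keep]
    pos = k > 0
    return OffRateCurve(force=grid[keep][pos], k_off=k[pos], source="kde")


def average_offrates_across_speeds(curves: dict,
                                   bin_width: float = DEFAULT_BIN_WIDTH_PN,
                                   f0: float = 0.0,
                                   min_speeds: int = 2) -> OffRateCurve:
    """Per-force-bin mean and standard deviation of off-rate curves from
    different pulling speeds. Bins covered by fewer than ``min_speeds``
    speeds are excluded."""
    if len(curves) < min_speeds:
        raise ValueError(f"need curves from at least {min_speeds} speeds")
    per_bin: dict[int, list[float]] = {}
    per_bin_f: dict[int, list[float]] = {}
    for curve in curves.values():
        seen = {}
        for f, k in zip(curve.force, curve.k_off):
            b = int((f - f0) // bin_width)
            seen.setdefault(b, []).append((f, k))
        for b, pts in seen.items():
            fs, ks = zip(*pts)
            per_bin.setdefault(b, []).append(float(np.mean(ks)))
            per_bin_f.setdefault(b, []).append(float(np.mean(fs)))
    bins = sorted(b for b, ks in per_bin.items() if len(ks) >= min_speeds)
    if not bins:
        raise ValueError("no force bin is covered by enough speeds")
    force = np.array([np.mean(per_bin_f[b]) for b in bins])
    kmean = np.array([np.mean(per_bin[b]) for b in bins])
    kstd = np.array([np.std(per_bin[b], ddof=1) for b in bins])
    n = np.array([len(per_bin[b]) for b in bins])
    return OffRateCurve(force=force, k_off=kmean, k_off_std=kstd,
                        counts=n, source="averaged")


# ---------------------------------------------------------------------------
# DHS fitting
# ---------------------------------------------------------------------------

def _dhs_log_rate(F, log10_k0, dx, dG, nu, kBT):
    inner = 1.0 - nu * F * dx / (dG * kBT)
    inner = np.clip(inner, 1e-12, None)
    return (log10_k0 * np.log(10.0)
            + (1.0 / nu - 1.0) * np.log(inner)
            + dG * (1.0 - inner ** (1.0 / nu)))


def fit_dhs(curve: OffRateCurve, nu: float = 0.5,
            env: Environment = Environment(),
            p0: Optional[tuple[float, float, float]] = None) -> FitResult:
    """Weighted nonlinear least squares of the DHS off-rate law in log
    space. Off-rates span decades, so residuals are taken on log k with
    inverse-variance weights derived from the per-bin dispersion when the
    curve carries one (unit weights otherwise). Raises on non-convergence
    with the last iterate in the message.
    """
    F = curve.force
    logk = np.log(curve.k_off)
    if curve.k_off_std is not None:
        rel = np.clip(curve.k_off_std / curve.k_off, 1e-2, None)
        w = 1.0 / np.log1p(rel)
    else:
        w = np.ones_like(logk)

    if p0 is None:
        # Bell-Evans initialisation from the log-linear trend
        slope, intercept = np.polyfit(F, logk, 1)
        slope = max(slope, 1e-6)
        dx0 = min(max(slope * env.kBT, 1e-3), 1.0)
        k00 = math.exp(intercept)
        p0 = (math.log10(max(k00, 1e-30)), dx0, 10.0)

    def resid(theta):
        log10_k0, dx, dG = theta
        return w * (_dhs_log_rate(F, log10_k0, dx, dG, nu, env.kBT) - logk)

    # make the initial barrier compatible with the data's force range
    log10_k0, dx0, dG0 = p0
    dG_min = 1.05 * nu * F.max() * dx0 / env.kBT
    p0 = (log10_k0, dx0, max(dG0, dG_min))

    sol = optimize.least_squares(
        resid, p0, bounds=([-30.0, 1e-4, 0.1], [10.0, 5.0, 200.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
    )
    if not sol.success:
        raise RuntimeError(
            f"DHS fit did not converge: {sol.message}; last iterate "
            f"log10_k0={sol.x[0]:.3f}, dx={sol.x[1]:.4f}, dG={sol.x[2]:.3f}"
        )
    log10_k0, dx, dG = sol.x
    params = DHSParams(k0=10.0 ** log10_k0, dx=dx, dG=dG, nu=_snap_nu(nu))
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * 2 * sol.cost / max(F.size - 3, 1)
    except np.linalg.LinAlgError:
        cov = None
    return FitResult(
        model=f"DHS-{nu:.3g}",
        params={"k0": params.k0, "dx": params.dx, "dG": params.dG, "nu": nu},
        residual_norm=float(np.sqrt(2 * sol.cost)),
        covariance=cov,
        diagnostics={"nfev": sol.nfev, "status": sol.status,
                     "max_admissible_force": dhs_max_force(params, env)},
    )


def _snap_nu(nu: float) -> float:
    for v in (0.5, 2.0 / 3.0, 1.0):
        if abs(nu - v) < 1e-9:
            return v
    return nu


# ---------------------------------------------------------------------------
# Censoring-bias correction of XMod unfolding
# ---------------------------------------------------------------------------

def unfolding_probability_ramp(unfold: BellEvansParams,
                               rupture: BellEvansParams,
                               speed: float,
                               contour_length: float,
                               env: Environment = Environment(),
                               persistence: float = 0.4,
                               spring_constant: float = 100.0,
                               grid_step: float = 0.05,
                               force_floor: float = 1.0,
                               force_cap: float = 1500.0) -> float:
    """Probability that unfolding fires before rupture under a force ramp.

    Deterministically integrates the two competing hazards along the same
    WLC loading path the pulling simulator uses (even extension grid, head
    height H = X + F/k, time from the constant head speed). With rates held
    constant within each slice, the slice-exact allocation is

        P(unfold first) = sum_i S_i (1 - e^{-(k_u+k_r) dt_i}) k_u/(k_u+k_r),
        S_{i+1} = S_i e^{-(k_u+k_r) dt_i},

    which is probability-conserving for arbitrarily large per-slice hazards
    and is the exact expectation of the event fraction a Monte Carlo
    estimate would converge to, with no sampling noise.
    """
    wlc = WLCParams(Lc=contour_length, p=persistence)
    z_cap = 1.0 - math.sqrt(env.kBT / (4.0 * persistence * force_cap))
    x = np.arange(grid_step, contour_length * z_cap, grid_step)
    F = wlc_force(x, wlc, env)
    keep = F >= force_floor
    x, F = x[keep], F[keep]
    H = x + F / spring_constant
    dt = np.diff(H, prepend=H[0] - grid_step) / speed
    ku = be_rate(F, unfold, env)
    kr = be_rate(F, rupture, env)
    total = ku + kr
    p_slice = -np.expm1(-total * dt)
    log_surv = np.concatenate(([0.0], -np.cumsum(total * dt)))[:-1]
    survival = np.exp(log_surv)
    return float(np.sum(survival * p_slice * ku / total))


def correct_xmod_bias(observed_fractions: dict,
                      rupture_params: BellEvansParams,
                      initial_unfold_params: BellEvansParams,
                      contour_length: float = 244.0,
                      env: Environment = Environment(),
                      persistence: float = 0.4,
                      spring_constant: float = 100.0,
                      grid_step: float = 0.05,
                      maxiter: int = 200) -> BiasCorrectionResult:
    """Censoring-bias correction of the XMod unfolding parameters.

    ``observed_fractions`` maps pulling speed -> observed fraction of
    strong-binding-mode curves showing XMod unfolding. With the complex
    rupture parameters held fixed, (k0, dx) of the unfolding process are
    adjusted by least squares so the predicted unfolding-before-rupture
    fraction under the forced pulling process matches the observations at
    every speed. A Nelder--Mead simplex searches (log k0, dx); the inner
    objective is deterministic, so the result is reproducible. The initial
    guess is the naive ("measured") fit, which is reported alongside.

    ``contour_length`` is the polymer contour length over which the
    competition plays out (the fully extended system after fingerprint
    unfolding but with XMod intact).
    """
    if len(observed_fractions) < 3:
        raise ValueError("need observed fractions at >= 3 speeds")
    speeds = sorted(observed_fractions)
    obs = np.array([observed_fractions[s] for s in speeds])

    def objective(theta):
        log_k0, dx = theta
        if dx <= 1e-4 or dx > 5.0 or not np.isfinite(log_k0):
            return 1e6
        p = BellEvansParams(k0=math.exp(log_k0), dx=dx)
        pred = np.array([
            unfolding_probability_ramp(
                p, rupture_params, s, contour_length, env,
                persistence, spring_constant, grid_step)
            for s in speeds
        ])
        return float(np.sum((pred - obs) ** 2))

    x0 = np.array([math.log(initial_unfold_params.k0), initial_unfold_params.dx])
    f0 = objective(x0)
    if f0 < 1e-10:
        # the initial (naive) parameters already reproduce the observed
        # fractions -- nothing for the correction to move
        return BiasCorrectionResult(
            measured=initial_unfold_params,
            corrected=initial_unfold_params,
            converged=True, objective=f0, n_eval=1,
        )
    sol = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-10},
    )
    corrected = BellEvansParams(k0=math.exp(sol.x[0]), dx=float(sol.x[1]))
    return BiasCorrectionResult(
        measured=initial_unfold_params,
        corrected=corrected,
        converged=bool(sol.success),
        objective=float(sol.fun),
        n_eval=int(sol.nfev),
    )
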