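"""Burst selection and corrected FRET efficiency analysis.

Confocal single-molecule FRET with alternating-laser excitation (ALEX)
yields a photon stream in three channels: DD (donor excitation, donor
emission), DA (donor excitation, acceptor emission) and AA (acceptor
excitation, acceptor emission). Bursts from single diffusing complexes are
found with a sliding time-window search, doubly labeled complexes are
selected by stoichiometry, and accurate FRET efficiencies are computed with
spectral cross-talk (alpha), direct-excitation (delta) and detection/quantum
yield (gamma) corrections:

    E = (I_DA - a I_DD - d I_AA) / (g I_DD + I_DA - a I_DD - d I_AA)
    S = (g I_DD + I_DA - a I_DD - d I_AA + ...) -- standard ALEX convention

Efficiency histograms are fitted with one- or two-component Gaussian
mixtures; two populations evidence two binding modes with different
donor-acceptor distances. A synthetic burst generator provides test data
with known population structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "PhotonRecord",
    "PhotonStream",
    "Burst",
    "FRETCorrections",
    "BurstFilter",
    "sliding_window_burst_search",
    "compute_efficiency",
    "compute_stoichiometry",
    "stoichiometry_filter",
    "MixtureFit",
    "fit_efficiency_mixture",
    "generate_synthetic_bursts",
    "distance_to_efficiency",
]

CHANNELS = ("DD", "DA", "AA")


@dataclass(frozen=True)
class PhotonRecord:
    timestamp: float  # s
    channel: str      # DD | DA | AA


@dataclass
class PhotonStream:
    """Sorted photon arrival times with channel labels (0=DD, 1=DA, 2=AA)."""

    timestamps: np.ndarray
    channels: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = np.asarray(self.channels)
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    @classmethod
    def from_records(cls, records: Sequence[PhotonRecord]) -> "PhotonStream":
        ts = np.array([r.timestamp for r in records])
        ch = np.array([CHANNELS.index(r.channel) for r in records])
        order = np.argsort(ts, kind="stable")
        return cls(timestamps=ts[order], channels=ch[order])


@dataclass
class Burst:
    """Background-corrected photon counts of one burst."""

    I_DD: float
    I_DA: float
    I_AA: float
    start_time: float = 0.0
    duration: float = 0.0

    @property
    def total(self) -> float:
        return self.I_DD + self.I_DA + self.I_AA


@dataclass(frozen=True)
class FRETCorrections:
    """Correction factors of the accurate-FRET formula.

    alpha: donor spectral cross-talk into the acceptor channel;
    delta: direct excitation of the acceptor by the donor laser;
    gamma_f: detection-efficiency/quantum-yield ratio (named ``gamma_f`` to
    keep it distinct from the FRC bond angle).
    """

    alpha: float = 0.0
    delta: float = 0.0
    gamma_f: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be non-negative")
        if self.gamma_f <= 0:
            raise ValueError("gamma_f must be positive")


#: A pluggable burst filter: bursts -> retained bursts. Additional
#: photobleaching/blinking filters (e.g. ALEX-2CDE-style kinetics filters)
#: can be chained through this interface.
BurstFilter = Callable[[list[Burst]], list[Burst]]


# ---------------------------------------------------------------------------
# Burst search
# ---------------------------------------------------------------------------

def sliding_window_burst_search(stream: PhotonStream,
                                window: float = 500e-6,
                                min_photons_per_window: int = 4,
                                burst_threshold: int = 40,
                                background_rates: tuple[float, float, float]
                                = (0.0, 0.0, 0.0)) -> list[Burst]:
    """Sliding time-window burst search.

    A photon qualifies when at least ``min_photons_per_window`` photons
    (itself included) fall inside the ``window`` centered on it; contiguous
    runs of qualifying photons form candidate bursts, and candidates with at
    least ``burst_threshold`` photons are returned. Per-channel background
    (rates in Hz) is subtracted from the counts over each burst's duration,
    clipped at zero.
    """
    ts = stream.timestamps
    if ts.size == 0:
        return []
    half = window / 2.0
    left = np.searchsorted(ts, ts - half, side="left")
    right = np.searchsorted(ts, ts + half, side="right")
    qualifies = (right - left) >= min_photons_per_window

    bursts: list[Burst] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], qualifies.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        n = stop - start
        if n < burst_threshold:
            continue
        ch = stream.channels[start:stop]
        t0 = float(ts[start])
        dur = float(ts[stop - 1] - ts[start])
        counts = [float(np.count_nonzero(ch == c)) for c in range(3)]
        corrected = [max(c - bg * dur, 0.0)
                     for c, bg in zip(counts, background_rates)]
        bursts.append(Burst(I_DD=corrected[0], I_DA=corrected[1],
                            I_AA=corrected[2], start_time=t0, duration=dur))
    return bursts


# ---------------------------------------------------------------------------
# Efficiency and stoichiometry
# ---------------------------------------------------------------------------

def compute_efficiency(burst: Burst,
                       corrections: FRETCorrections = FRETCorrections()
                       ) -> Optional[float]:
    """Accurate FRET efficiency of one burst; None when the denominator
    vanishes (the burst is discarded and counted by callers)."""
    f_da = burst.I_DA - corrections.alpha * burst.I_DD - corrections.delta * burst.I_AA
    denom = corrections.gamma_f * burst.I_DD + f_da
    if denom == 0:
        return None
    return f_da / denom


def compute_stoichiometry(burst: Burst,
                          corrections: FRETCorrections = FRETCorrections()
                          ) -> Optional[float]:
    """ALEX stoichiometry S = (g I_DD + F_DA) / (g I_DD + F_DA + I_AA),
    with F_DA the fully corrected acceptor signal after donor excitation.
    S ~ 1 for donor-only and S ~ 0 for acceptor-only species."""
    f_da = burst.I_DA - corrections.alpha * burst.I_DD - corrections.delta * burst.I_AA
    num = corrections.gamma_f * burst.I_DD + f_da
    denom = num + burst.I_AA
    if denom == 0:
        return None
    return num / denom


def stoichiometry_filter(bursts: Sequence[Burst],
                         corrections: FRETCorrections = FRETCorrections(),
                         bounds: tuple[float, float] = (0.2, 0.8)
                         ) -> list[Burst]:
    """Keep doubly labeled bursts: stoichiometry within ``bounds``."""
    lo, hi = bounds
    out = []
    for b in bursts:
        s = compute_stoichiometry(b, corrections)
        if s is not None and lo <= s <= hi:
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# Mixture fitting
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    means: np.ndarray      # ascending
    sigmas: np.ndarray
    weights: np.ndarray    # area fractions, sum 1
    n_components: int
    residual_norm: float
    bin_width: float


def _gauss_mix(x, *theta):
    n = len(theta) // 3
    out = np.zeros_like(x)
    for i in range(n):
        amp, mu, sig = theta[3 * i: 3 * i + 3]
        out = out + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def fit_efficiency_mixture(efficiencies, n_components: int = 2,
                           bin_width: float = 0.025,
                           min_bursts: int = 100) -> MixtureFit:
    """Least-squares Gaussian (or two-Gaussian) fit of the binned FRET
    efficiency histogram. Component means are returned in ascending order;
    weights are the relative component areas."""
    e = np.asarray(efficiencies, dtype=float)
    if e.size < min_bursts:
        raise ValueError(f"need at least {min_bursts} bursts, got {e.size}")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    lo = math.floor(e.min() / bin_width) * bin_width
    hi = math.ceil(e.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(e, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    amp0 = counts.max()
    if n_components == 1:
        p0 = [amp0, float(np.median(e)), max(float(e.std()), bin_width)]
        lower = [0.0, lo - 0.5, bin_width / 4]
        upper = [np.inf, hi + 0.5, 2.0]
    else:
        q25, q75 = np.percentile(e, [25, 75])
        sig0 = max(float(e.std()) / 2, bin_width)
        p0 = [amp0, float(q25), sig0, amp0, float(q75), sig0]
        lower = [0.0, lo - 0.5, bin_width / 4] * 2
        upper = [np.inf, hi + 0.5, 2.0] * 2
    try:
        popt, _ = optimize.curve_fit(_gauss_mix, centers, counts, p0=p0,
                                     bounds=(lower, upper), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"efficiency mixture fit did not converge: {exc}")
    theta = np.asarray(popt).reshape(n_components, 3)
    areas = theta[:, 0] * theta[:, 2]  # ~ amp * sigma
    order = np.argsort(theta[:, 1])
    theta = theta[order]
    areas = areas[order]
    resid = counts - _gauss_mix(centers, *popt)
    return MixtureFit(
        means=theta[:, 1].copy(),
        sigmas=theta[:, 2].copy(),
        weights=areas / areas.sum(),
        n_components=n_components,
        residual_norm=float(np.sqrt(np.sum(resid ** 2))),
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# Synthetic burst generation
# ---------------------------------------------------------------------------

def distance_to_efficiency(distance_nm: float, r0_nm: float) -> float:
    """Foerster relation E = 1 / (1 + (d/R0)^6) (generator use only)."""
    return 1.0 / (1.0 + (distance_nm / r0_nm) ** 6)


def generate_synthetic_bursts(populations: Sequence[tuple[float, float]],
                              n: int,
                              corrections: FRETCorrections = FRETCorrections(),
                              rng: Optional[np.random.Generator] = None,
                              mean_burst_size: float = 80.0,
                              min_burst_size: int = 40,
                              stoichiometry: float = 0.5) -> list[Burst]:
    """Synthetic doubly labeled bursts from a FRET population mixture.

    ``populations`` is a list of (mean efficiency, fraction) with fractions
    summing to 1. Burst sizes are ``min_burst_size`` plus a Poisson excess
    with the requested mean. Photon counts are split multinomially across
    the three channels so that the corrected efficiency and stoichiometry
    recover the targets in expectation after inverse application of the
    corrections (a round trip through :func:`compute_efficiency`).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    fracs = np.array([f for _, f in populations], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("population fractions must sum to 1")
    if not (0.0 < stoichiometry < 1.0):
        raise ValueError("stoichiometry target must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng

    pop_idx = rng.choice(len(populations), size=n, p=fracs)
    sizes = min_burst_size + rng.poisson(
        max(mean_burst_size - min_burst_size, 0.0), size=n
    )
    bursts: list[Burst] = []
    a, d, g = corrections.alpha, corrections.delta, corrections.gamma_f
    s = stoichiometry
    for i in range(n):
        e = populations[pop_idx[i]][0]
        # expected raw channel intensities realizing (E, S) after correction
        i_dd = (1.0 - e) / g
        f_da = e
        i_aa = (g * i_dd + f_da) * (1.0 - s) / s
        i_da = f_da + a * i_dd + d * i_aa
        w = np.array([i_dd, i_da, i_aa])
        counts = rng.multinomial(sizes[i], w / w.sum())
        bursts.append(Burst(I_DD=float(counts[0]), I_DA=float(counts[1]),
                            I_AA=float(counts[2]),
                            start_time=float(i) * 1e-2,
                            duration=1e-3))
    return bursts
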