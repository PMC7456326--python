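"""Kinetic Monte Carlo simulation of constant-speed and force-clamp pulling.

Implements the multi-state kinetic network of the Rc XMod-Doc:Coh complex:
upon tip-surface contact the complex forms the strong binding mode A with
probability ``p_mode_a`` (default 0.8) or the weak mode B otherwise, with no
interconversion. Mode A competes between high-force complex rupture (pathway
P1) and XMod unfolding, which gates a weakened state that ruptures at low
force (pathway P2). Mode B ruptures at low force with XMod intact (pathway
P3). Two ddFLN4 fingerprint domains, each unfolding in two sequential
sub-steps totalling 32 nm, certify single-molecule tethers.

Constant-speed pulling builds the force ramp on an even molecular-extension
grid from the current worm-like chain, converts extension to AFM head height
through the cantilever bending correction H = X + F/k, derives time from the
constant head speed, and fires transitions per time slice with probability
1 - exp(-k_off(F) dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .elasticity import (
    BellEvansParams,
    DHSParams,
    Environment,
    WLCParams,
    force_dependent_rate,
    wlc_force,
    wlc_stiffness,
)

__all__ = [
    "TransitionSpec",
    "NetworkSpec",
    "PullingProtocol",
    "SimEvent",
    "SimCurve",
    "ClampResult",
    "default_network",
    "assign_binding_mode",
    "simulate_constant_speed",
    "simulate_force_clamp",
    "simulate_dataset",
    "curve_seed_sequences",
    "P1_RUPTURE_BE",
    "XMOD_UNFOLD_BE_CORRECTED",
    "XMOD_UNFOLD_BE_MEASURED",
    "P2_RUPTURE_BE",
    "P3_RUPTURE_BE",
    "P1_RUPTURE_DHS",
    "P3_RUPTURE_DHS",
]

# Published AFM-SMFS Bell-Evans parameters for the Rc XMod-Doc:Coh system
# (k0 in 1/s, dx in nm). The XMod unfolding process ships in two variants:
# the raw ("measured") fit and the censoring-bias corrected fit; the
# corrected set is the default because it is the best estimate of the
# intrinsic process.
P1_RUPTURE_BE = BellEvansParams(k0=4.70e-8, dx=0.178)
XMOD_UNFOLD_BE_MEASURED = BellEvansParams(k0=9.94e-6, dx=0.139)
XMOD_UNFOLD_BE_CORRECTED = BellEvansParams(k0=4.53e-5, dx=0.116)
P2_RUPTURE_BE = BellEvansParams(k0=7.43e-4, dx=0.277)
P3_RUPTURE_BE = BellEvansParams(k0=2.79e-5, dx=0.366)

# DHS fits (cusp surface, nu = 0.5) of the same rupture processes; dG in kBT.
P1_RUPTURE_DHS = DHSParams(k0=9.39e-5, dx=0.146, dG=22.8, nu=0.5)
P3_RUPTURE_DHS = DHSParams(k0=0.831, dx=0.131, dG=8.46, nu=0.5)

#: Contour-length increment of one full ddFLN4 unfolding (nm).
DDFLN4_TOTAL_NM = 32.0
#: Contour-length increment of XMod unfolding (116 aa x 0.365 nm - 5.3 nm).
XMOD_INCREMENT_NM = 37.0

_FORCE_CAP_PN = 2500.0  # safety truncation; far above any modelled event


@dataclass(frozen=True)
class TransitionSpec:
    """One barrier-crossing process of the network.

    ``kind`` is ``"unfolding"`` (adds ``delta_Lc`` nm of contour length and
    the trajectory continues) or ``"rupture"`` (terminates the trajectory,
    ``delta_Lc`` must be 0).
    """

    name: str
    rate_model: BellEvansParams | DHSParams
    delta_Lc: float = 0.0
    kind: str = "unfolding"

    def __post_init__(self) -> None:
        if self.kind not in ("unfolding", "rupture"):
            raise ValueError(f"kind must be 'unfolding' or 'rupture', got {self.kind!r}")
        if self.delta_Lc < 0:
            raise ValueError("delta_Lc must be non-negative")
        if self.kind == "rupture" and self.delta_Lc != 0:
            raise ValueError("rupture transitions must have delta_Lc = 0")


def _default_fingerprints() -> tuple[tuple[TransitionSpec, ...], ...]:
    """Two ddFLN4 fingerprint domains, each two sequential sub-steps.

    The sub-step kinetics are chosen so that unfolding happens between
    roughly 60 and 120 pN at the simulated pulling speeds; increments
    15 nm + 17 nm sum to the 32 nm signature of one domain.
    """
    def domain(tag: str) -> tuple[TransitionSpec, ...]:
        return (
            TransitionSpec(f"{tag}_step1", BellEvansParams(k0=3.0e-3, dx=0.45),
                           delta_Lc=15.0, kind="unfolding"),
            TransitionSpec(f"{tag}_step2", BellEvansParams(k0=1.0e-3, dx=0.50),
                           delta_Lc=17.0, kind="unfolding"),
        )

    return (domain("ddfln4_a"), domain("ddfln4_b"))


@dataclass(frozen=True)
class NetworkSpec:
    """The binding-mode / pathway state machine plus the polymer backbone.

    ``base_Lc`` is the contour length of the fully folded tethered system
    (ELP linkers plus folded domains); unfolding events extend it.
    """

    rupture_p1: TransitionSpec
    xmod_unfold: TransitionSpec
    rupture_p2: TransitionSpec
    rupture_p3: TransitionSpec
    fingerprints: tuple[tuple[TransitionSpec, ...], ...] = field(
        default_factory=_default_fingerprints
    )
    p_mode_a: float = 0.8
    base_Lc: float = 180.0
    persistence: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_mode_a <= 1.0):
            raise ValueError(f"p_mode_a must lie in [0, 1], got {self.p_mode_a}")
        if self.base_Lc <= 0:
            raise ValueError("base_Lc must be positive")
        for t, kind in ((self.rupture_p1, "rupture"), (self.rupture_p2, "rupture"),
                        (self.rupture_p3, "rupture"), (self.xmod_unfold, "unfolding")):
            if t.kind != kind:
                raise ValueError(f"{t.name}: expected kind {kind!r}, got {t.kind!r}")


def default_network(xmod: str = "corrected", p_mode_a: float = 0.8,
                    base_Lc: float = 180.0) -> NetworkSpec:
    """Network with the published kinetic parameters as defaults.

    ``xmod`` selects the XMod unfolding parameter set: ``"corrected"``
    (censoring-bias corrected, default) or ``"measured"``.
    """
    xmod_params = {
        "corrected": XMOD_UNFOLD_BE_CORRECTED,
        "measured": XMOD_UNFOLD_BE_MEASURED,
    }[xmod]
    return NetworkSpec(
        rupture_p1=TransitionSpec("rupture_P1", P1_RUPTURE_BE, kind="rupture"),
        xmod_unfold=TransitionSpec("xmod_unfold", xmod_params,
                                   delta_Lc=XMOD_INCREMENT_NM, kind="unfolding"),
        rupture_p2=TransitionSpec("rupture_P2", P2_RUPTURE_BE, kind="rupture"),
        rupture_p3=TransitionSpec("rupture_P3", P3_RUPTURE_BE, kind="rupture"),
        p_mode_a=p_mode_a,
        base_Lc=base_Lc,
    )


@dataclass(frozen=True)
class PullingProtocol:
    """Constant-speed pulling protocol.

    speed: head retraction speed V (nm/s); spring_constant: cantilever k
    (pN/nm, default 100 = 0.1 N/m); extension_grid_step: even molecular
    extension grid spacing (nm); max_head_height: truncation height (nm).
    """

    speed: float
    spring_constant: float = 100.0
    extension_grid_step: float = 0.05
    max_head_height: float = 400.0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.extension_grid_step <= 0:
            raise ValueError("grid step must be positive")


@dataclass
class SimEvent:
    name: str
    kind: str
    time: float
    force: float
    loading_rate: float
    delta_Lc: float


@dataclass
class SimCurve:
    """A simulated force-extension trace with annotated events."""

    time: np.ndarray
    head_height: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    events: list[SimEvent]
    binding_mode: str
    true_pathway: Optional[str]
    speed: float
    ruptured: bool
    no_rupture_reason: Optional[str] = None

    @property
    def rupture_event(self) -> Optional[SimEvent]:
        for ev in self.events:
            if ev.kind == "rupture":
                return ev
        return None


@dataclass
class ClampResult:
    lifetime: float
    pathway: str
    binding_mode: str
    events: list[str]


def assign_binding_mode(rng: np.random.Generator, p_mode_a: float) -> str:
    """Bernoulli draw of the binding mode: 'A' with probability p_mode_a."""
    if not (0.0 <= p_mode_a <= 1.0):
        raise ValueError(f"p_mode_a must lie in [0, 1], got {p_mode_a}")
    return "A" if rng.random() < p_mode_a else "B"


class _NetworkState:
    """Mutable per-trajectory pathway state."""

    def __init__(self, network: NetworkSpec, mode: str):
        self.network = network
        self.mode = mode
        self.xmod_unfolded = False
        self.fp_progress = [0] * len(network.fingerprints)

    def active_transitions(self) -> list[TransitionSpec]:
        active: list[TransitionSpec] = []
        for i, domain in enumerate(self.network.fingerprints):
            j = self.fp_progress[i]
            if j < len(domain):
                active.append(domain[j])
        if self.mode == "A":
            if self.xmod_unfolded:
                active.append(self.network.rupture_p2)
            else:
                active.append(self.network.rupture_p1)
                active.append(self.network.xmod_unfold)
        else:
            active.append(self.network.rupture_p3)
        return active

    def apply(self, transition: TransitionSpec) -> None:
        if transition is self.network.xmod_unfold:
            self.xmod_unfolded = True
            return
        for i, domain in enumerate(self.network.fingerprints):
            j = self.fp_progress[i]
            if j < len(domain) and domain[j] is transition:
                self.fp_progress[i] = j + 1
                return

    def pathway(self) -> str:
        if self.mode == "B":
            return "P3"
        return "P2" if self.xmod_unfolded else "P1"


def _loading_rate(x: float, wlc: WLCParams, protocol: PullingProtocol,
                  env: Environment) -> float:
    """dF/dt at extension x under constant head speed with cantilever
    compliance: r = S V / (1 + S/k), S = dF/dx of the WLC."""
    s = wlc_stiffness(x, wlc, env)
    return s * protocol.speed / (1.0 + s / protocol.spring_constant)


def simulate_constant_speed(network: NetworkSpec, protocol: PullingProtocol,
                            rng: np.random.Generator,
                            env: Environment = Environment(),
                            tail_samples: int = 40) -> SimCurve:
    """Simulate one constant-speed pulling curve on the kinetic network.

    Per time slice each active transition fires with probability
    1 - exp(-k_off(F) dt) against an independent uniform draw; when several
    fire in the same slice the winner is chosen with probability
    proportional to its instantaneous rate. Unfolding extends the polymer
    (the extension jumps forward at fixed head height); rupture drops the
    force to baseline and terminates the curve. A short zero-force tail is
    appended after rupture so downstream rupture detection sees the drop.
    """
    mode = assign_binding_mode(rng, network.p_mode_a)
    state = _NetworkState(network, mode)

    dx = protocol.extension_grid_step
    k_spring = protocol.spring_constant
    V = protocol.speed

    Lc = network.base_Lc
    x_cur = 0.0
    H_prev = 0.0
    t_prev = 0.0

    times = [0.0]
    heads = [0.0]
    exts = [0.0]
    forces = [0.0]
    events: list[SimEvent] = []
    ruptured = False
    no_rupture_reason: Optional[str] = None

    while True:
        wlc = WLCParams(Lc=Lc, p=network.persistence)
        # segment extension grid, truncated by the force cap
        z_cap = 1.0 - np.sqrt(env.kBT / (4.0 * network.persistence * _FORCE_CAP_PN))
        x_hi = min(Lc * min(z_cap, 0.999), x_cur + 1e7)
        n_pts = int(np.floor((x_hi - x_cur) / dx))
        if n_pts < 1:
            no_rupture_reason = "force-cap"
            break
        x_seg = x_cur + dx * np.arange(1, n_pts + 1)
        F_seg = wlc_force(x_seg, wlc, env)
        H_seg = x_seg + F_seg / k_spring
        # truncate at the maximum head height
        over = np.searchsorted(H_seg, protocol.max_head_height)
        capped = over < H_seg.size
        if capped:
            x_seg, F_seg, H_seg = x_seg[:over], F_seg[:over], H_seg[:over]
        if H_seg.size == 0:
            no_rupture_reason = "max-head-height"
            break
        dH = np.diff(H_seg, prepend=H_prev)
        dt = dH / V
        t_seg = t_prev + np.cumsum(dt)

        active = state.active_transitions()
        rates = np.vstack([
            np.asarray(force_dependent_rate(tr.rate_model, F_seg, env))
            for tr in active
        ])
        p_fire = -np.expm1(-rates * dt)
        u = rng.random(size=p_fire.shape)
        fired = u < p_fire
        any_fired = fired.any(axis=0)

        if not any_fired.any():
            times.append(t_seg)
            heads.append(H_seg)
            exts.append(x_seg)
            forces.append(F_seg)
            no_rupture_reason = "max-head-height" if capped else "force-cap"
            break

        j = int(np.argmax(any_fired))
        winners = np.flatnonzero(fired[:, j])
        if winners.size == 1:
            w = int(winners[0])
        else:
            wr = rates[winners, j]
            w = int(rng.choice(winners, p=wr / wr.sum()))
        chosen = active[w]

        times.append(t_seg[: j + 1])
        heads.append(H_seg[: j + 1])
        exts.append(x_seg[: j + 1])
        forces.append(F_seg[: j + 1])

        ev = SimEvent(
            name=chosen.name,
            kind=chosen.kind,
            time=float(t_seg[j]),
            force=float(F_seg[j]),
            loading_rate=_loading_rate(float(x_seg[j]), wlc, protocol, env),
            delta_Lc=chosen.delta_Lc,
        )
        events.append(ev)
        t_prev = float(t_seg[j])
        H_prev = float(H_seg[j])

        if chosen.kind == "rupture":
            ruptured = True
            # zero-force tail: the head keeps moving, the tether is gone
            H_tail = H_prev + dx * np.arange(1, tail_samples + 1)
            t_tail = t_prev + (H_tail - H_prev) / V
            times.append(t_tail)
            heads.append(H_tail)
            exts.append(H_tail.copy())  # F = 0 so X = H
            forces.append(np.zeros(tail_samples))
            break

        state.apply(chosen)
        Lc_new = Lc + chosen.delta_Lc
        wlc_new = WLCParams(Lc=Lc_new, p=network.persistence)
        # the head is fixed during the (instantaneous) unfolding: solve
        # x + F(x; Lc_new)/k = H for the relaxed extension
        x_hi_b = min(H_prev, Lc_new * (1.0 - 1e-9))
        x_cur = brentq(
            lambda xx: xx + wlc_force(xx, wlc_new, env) / k_spring - H_prev,
            min(float(x_seg[j]), x_hi_b - 1e-9),
            x_hi_b,
            xtol=1e-10,
        )
        Lc = Lc_new

    time = np.concatenate([np.atleast_1d(a) for a in times])
    head = np.concatenate([np.atleast_1d(a) for a in heads])
    ext = np.concatenate([np.atleast_1d(a) for a in exts])
    force = np.concatenate([np.atleast_1d(a) for a in forces])

    return SimCurve(
        time=time,
        head_height=head,
        extension=ext,
        force=force,
        events=events,
        binding_mode=mode,
        true_pathway=state.pathway() if ruptured else None,
        speed=V,
        ruptured=ruptured,
        no_rupture_reason=no_rupture_reason,
    )


def simulate_force_clamp(network: NetworkSpec, clamp_force: float,
                         rng: np.random.Generator,
                         env: Environment = Environment()) -> ClampResult:
    """Fixed-force competing-hazard (Gillespie) simulation of the network.

    Returns the time to rupture and the pathway taken. At constant force the
    rates are constant between events, so waiting times are exponential with
    the summed rate of the active transitions and the firing transition is
    chosen proportionally to its rate.
    """
    if clamp_force < 0:
        raise ValueError("clamp force must be non-negative")
    mode = assign_binding_mode(rng, network.p_mode_a)
    state = _NetworkState(network, mode)
    t = 0.0
    fired: list[str] = []
    while True:
        active = state.active_transitions()
        rates = np.array([
            float(force_dependent_rate(tr.rate_model, clamp_force, env))
            for tr in active
        ])
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        chosen = active[int(rng.choice(len(active), p=rates / total))]
        fired.append(chosen.name)
        if chosen.kind == "rupture":
            return ClampResult(lifetime=t, pathway=state.pathway(),
                               binding_mode=mode, events=fired)
        state.apply(chosen)


def curve_seed_sequences(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Deterministic per-curve child seed sequences from one root seed."""
    return list(np.random.SeedSequence(seed).spawn(n))


def simulate_dataset(network: NetworkSpec,
                     speeds: Sequence[float] = (100.0, 400.0, 1600.0, 6400.0),
                     n_curves: int = 1000,
                     seed: int = 0,
                     protocol_template: Optional[PullingProtocol] = None,
                     env: Environment = Environment()) -> list[SimCurve]:
    """Reproducible batch of constant-speed curves, ``n_curves`` per speed.

    One root seed spawns an independent child stream per curve, so the
    batch is byte-identical across runs with the same seed. Per-curve true
    pathway labels are retained on the returned :class:`SimCurve` objects.
    For large batches prefer iterating :func:`iter_dataset` to keep memory
    bounded.
    """
    return list(iter_dataset(network, speeds, n_curves, seed,
                             protocol_template, env))


def iter_dataset(network: NetworkSpec,
                 speeds: Sequence[float] = (100.0, 400.0, 1600.0, 6400.0),
                 n_curves: int = 1000,
                 seed: int = 0,
                 protocol_template: Optional[PullingProtocol] = None,
                 env: Environment = Environment()):
    """Generator form of :func:`simulate_dataset` (same seeding scheme)."""
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    children = curve_seed_sequences(seed, len(speeds) * n_curves)
    idx = 0
    for speed in speeds:
        if protocol_template is None:
            protocol = PullingProtocol(speed=speed)
        else:
            protocol = replace(protocol_template, speed=speed)
        for _ in range(n_curves):
            rng = np.random.default_rng(children[idx])
            idx += 1
            yield simulate_constant_speed(network, protocol, rng, env)
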