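"""Polymer elasticity and force-dependent rate laws.

Closed-form models shared by the pulling simulator and the fitting stages:

* worm-like chain (WLC) force-extension interpolation (Marko--Siggia), used to
  build simulated force ramps;
* freely rotating chain (FRC) contour-length transformation, used to map
  recorded force-extension data into contour-length space;
* Bell--Evans (BE) force-accelerated escape rate and its most-probable
  rupture force at constant loading rate;
* Dudko--Hummer--Szabo (DHS) off-rate law with barrier height and shape
  parameter, which reduces to BE at nu = 1.

All forces are in pN, lengths in nm, energies in pN nm, rates in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Environment",
    "WLCParams",
    "FRCParams",
    "BellEvansParams",
    "DHSParams",
    "DomainError",
    "wlc_force",
    "wlc_stiffness",
    "wlc_extension",
    "frc_contour_length",
    "be_rate",
    "be_most_probable_force",
    "dhs_rate",
    "dhs_max_force",
    "force_dependent_rate",
]

BOLTZMANN_PN_NM_PER_K = 0.0138064852  # k_B in pN nm / K


class DomainError(ValueError):
    """Raised when an input lies outside a model's physical domain."""


@dataclass(frozen=True)
class Environment:
    """Thermal environment of the experiment.

    Parameters
    ----------
    kBT : float
        Thermal energy in pN nm. The default 4.114 pN nm corresponds to 298 K.
    temperature : float
        Absolute temperature in K (bookkeeping only; ``kBT`` is authoritative).
    """

    kBT: float = 4.114
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ValueError(f"kBT must be positive, got {self.kBT}")

    @classmethod
    def from_temperature(cls, temperature: float) -> "Environment":
        return cls(kBT=BOLTZMANN_PN_NM_PER_K * temperature, temperature=temperature)

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kBT in 1/(pN nm)."""
        return 1.0 / self.kBT


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters: contour length ``Lc`` and persistence
    length ``p`` (defaults to 0.4 nm, typical for an unfolded polypeptide)."""

    Lc: float
    p: float = 0.4

    def __post_init__(self) -> None:
        if self.Lc <= 0:
            raise ValueError(f"contour length must be positive, got {self.Lc}")
        if self.p <= 0:
            raise ValueError(f"persistence length must be positive, got {self.p}")


@dataclass(frozen=True)
class FRCParams:
    """Freely rotating chain parameters.

    Bonds of length ``b`` joined at a fixed angle ``gamma`` (degrees). The
    Kuhn length ``a`` and FRC persistence length ``l`` are derived:

        a = b (1 + cos g) / ((1 - cos g) cos(g/2))
        l = b cos(g/2) / |ln(cos g)|

    Defaults b = 0.11 nm, gamma = 41 deg, the standard polypeptide values.
    """

    b: float = 0.11
    gamma: float = 41.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 90.0):
            raise ValueError(f"bond angle must lie in (0, 90) deg, got {self.gamma}")
        if self.b <= 0:
            raise ValueError(f"bond length must be positive, got {self.b}")

    @property
    def kuhn_length(self) -> float:
        g = math.radians(self.gamma)
        return self.b * (1.0 + math.cos(g)) / ((1.0 - math.cos(g)) * math.cos(g / 2.0))

    @property
    def frc_persistence(self) -> float:
        g = math.radians(self.gamma)
        return self.b * math.cos(g / 2.0) / abs(math.log(math.cos(g)))


@dataclass(frozen=True)
class BellEvansParams:
    """Bell--Evans barrier parameters: intrinsic rate ``k0`` (1/s) and
    distance to the transition state ``dx`` (nm)."""

    k0: float
    dx: float

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")


@dataclass(frozen=True)
class DHSParams:
    """Dudko--Hummer--Szabo parameters.

    ``dG`` is the barrier height in units of kBT; ``nu`` selects the assumed
    free-energy surface: 0.5 (cusp), 2/3 (linear-cubic) or 1 (Bell limit).
    """

    k0: float
    dx: float
    dG: float
    nu: float = 0.5

    _ALLOWED_NU = (0.5, 2.0 / 3.0, 1.0)

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")
        if self.dG <= 0:
            raise ValueError(f"dG must be positive, got {self.dG}")
        if not any(abs(self.nu - v) < 1e-9 for v in self._ALLOWED_NU):
            raise ValueError(f"nu must be one of {self._ALLOWED_NU}, got {self.nu}")


# ---------------------------------------------------------------------------
# Worm-like chain
# ---------------------------------------------------------------------------

def wlc_force(x, params: WLCParams, env: Environment = Environment()):
    """Marko--Siggia interpolation force of a WLC at extension ``x`` (nm).

        F(x) = (kBT/p) [ 1/4 (1 - x/Lc)^-2 - 1/4 + x/Lc ]

    Strictly increasing in x, F(0) = 0, diverging as x -> Lc.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise DomainError("extension must be non-negative")
    if np.any(x_arr >= params.Lc):
        raise DomainError(
            f"extension must be below the contour length Lc={params.Lc} nm"
        )
    z = x_arr / params.Lc
    f = (env.kBT / params.p) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return float(f) if np.isscalar(x) else f


def wlc_stiffness(x, params: WLCParams, env: Environment = Environment()):
    """Derivative dF/dx (pN/nm) of the Marko--Siggia force."""
    x_arr = np.asarray(x, dtype=float)
    z = x_arr / params.Lc
    s = (env.kBT / params.p) * (0.5 / (1.0 - z) ** 3 + 1.0) / params.Lc
    return float(s) if np.isscalar(x) else s


def wlc_extension(F, params: WLCParams, env: Environment = Environment()):
    """Numeric inverse of :func:`wlc_force`: extension at force ``F`` (pN)."""

    def _one(f: float) -> float:
        if f < 0:
            raise DomainError("force must be non-negative")
        if f == 0.0:
            return 0.0
        return brentq(
            lambda xx: wlc_force(xx, params, env) - f,
            0.0,
            params.Lc * (1.0 - 1e-12),
            xtol=1e-12,
            rtol=1e-14,
        )

    if np.isscalar(F):
        return _one(float(F))
    return np.array([_one(float(f)) for f in np.asarray(F, dtype=float)])


# ---------------------------------------------------------------------------
# Freely rotating chain contour-length transform
# ---------------------------------------------------------------------------

def frc_contour_length(F, x, params: FRCParams = FRCParams(),
                       env: Environment = Environment()):
    """Contour length ``L`` (nm) of an FRC observed at force ``F`` and
    extension ``x``.

    Three asymptotic regimes, selected by the reduced force f = F b / kBT
    against the boundaries b/l and l/b (a: Kuhn length, l: FRC persistence
    length):

        f <  b/l        L = 3 kBT x / (F a)          (linear, low force)
        b/l <= f < l/b  L = x / (1 - (4 F l / kBT)^-1/2)   (WLC-like)
        f >= l/b        L = x / (1 - (2 F b / kBT)^-1)     (discrete FRC)

    The two upper branches join continuously at f = l/b. Points whose
    transform is non-finite or non-positive are returned as NaN so callers
    can drop them.
    """
    F_arr = np.asarray(F, dtype=float)
    x_arr = np.asarray(x, dtype=float)
    F_b, x_b = np.broadcast_arrays(F_arr, x_arr)
    out = np.full(F_b.shape, np.nan)

    a = params.kuhn_length
    l = params.frc_persistence
    b = params.b
    with np.errstate(divide="ignore", invalid="ignore"):
        f_red = F_b * b / env.kBT
        low = f_red < b / l
        high = f_red >= l / b
        mid = ~(low | high)

        out[low] = 3.0 * env.kBT * x_b[low] / (F_b[low] * a)
        denom_mid = 1.0 - (4.0 * F_b[mid] * l / env.kBT) ** -0.5
        out[mid] = x_b[mid] / denom_mid
        denom_high = 1.0 - (2.0 * F_b[high] * b / env.kBT) ** -1.0
        out[high] = x_b[high] / denom_high

    bad = ~np.isfinite(out) | (out <= 0) | (F_b <= 0) | (x_b <= 0)
    out[bad] = np.nan
    if np.isscalar(F) and np.isscalar(x):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def be_rate(F, params: BellEvansParams, env: Environment = Environment()):
    """Bell--Evans off-rate k(F) = k0 exp(beta F dx)."""
    F_arr = np.asarray(F, dtype=float)
    if np.any(F_arr < 0):
        raise DomainError("force must be non-negative")
    k = params.k0 * np.exp(env.beta * F_arr * params.dx)
    return float(k) if np.isscalar(F) else k


def be_most_probable_force(loading_rate, params: BellEvansParams,
                           env: Environment = Environment()):
    """Most probable rupture force under a constant loading rate r (pN/s):

        F* = (kBT/dx) ln( r dx / (k0 kBT) )

    clipped at zero when the logarithm is negative.
    """
    r = np.asarray(loading_rate, dtype=float)
    if np.any(r <= 0):
        raise DomainError("loading rate must be positive")
    fstar = (env.kBT / params.dx) * np.log(r * params.dx / (params.k0 * env.kBT))
    fstar = np.clip(fstar, 0.0, None)
    return float(fstar) if np.isscalar(loading_rate) else fstar


def dhs_max_force(params: DHSParams, env: Environment = Environment()) -> float:
    """Largest admissible force of the DHS expression: F < dG kBT/(nu dx)."""
    return params.dG * env.kBT / (params.nu * params.dx)


def dhs_rate(F, params: DHSParams, env: Environment = Environment()):
    """Dudko--Hummer--Szabo off-rate (dG in units of kBT):

        k(F) = k0 (1 - nu F dx / (dG kBT))^(1/nu - 1)
                  * exp( dG [1 - (1 - nu F dx/(dG kBT))^(1/nu)] )

    Raises :class:`DomainError` outside the admissible force range rather
    than clamping, so fitting code must bound its own search region.
    """
    F_arr = np.asarray(F, dtype=float)
    if np.any(F_arr < 0):
        raise DomainError("force must be non-negative")
    fmax = dhs_max_force(params, env)
    if np.any(F_arr >= fmax):
        raise DomainError(
            f"force out of the DHS domain: requires F < {fmax:.1f} pN for "
            f"nu={params.nu:g}, dx={params.dx:g} nm, dG={params.dG:g} kBT"
        )
    inner = 1.0 - params.nu * F_arr * params.dx / (params.dG * env.kBT)
    k = (
        params.k0
        * inner ** (1.0 / params.nu - 1.0)
        * np.exp(params.dG * (1.0 - inner ** (1.0 / params.nu)))
    )
    return float(k) if np.isscalar(F) else k


def force_dependent_rate(model, F, env: Environment = Environment()):
    """Evaluate either a Bell--Evans or a DHS rate model at force ``F``."""
    if isinstance(model, BellEvansParams):
        return be_rate(F, model, env)
    if isinstance(model, DHSParams):
        return dhs_rate(F, model, env)
    raise TypeError(f"unsupported rate model: {type(model).__name__}")
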