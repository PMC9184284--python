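"""Confined-diffusion hydrodynamics.

A sphere of radius R_s diffusing in a channel of equivalent circular radius
r is slowed relative to free solution by wall drag and steric restriction.
The hindrance factor K(lambda), lambda = R_s/r, is the ratio of confined to
free diffusivity, given by the Dechadilok–Deen phenomenological correlation:

    K = (1 + (9/8) lam ln lam - 1.56 lam + 0.53 lam^2 + 1.92 lam^3
         - 2.81 lam^4 + 0.27 lam^5 + 1.1 lam^6 - 0.44 lam^7) / (1 - lam)^2

so the hindered Stokes–Einstein relation reads

    D = K(R_s / r) * k_B T / (6 pi eta R_s).

The inverse problem — R_s from a measured D — is an implicit equation in
R_s (K depends on it) and is solved by bracketed root finding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants
from scipy.optimize import brentq

__all__ = [
    "HydroContext",
    "EmpiricalScaling",
    "hindrance_factor",
    "hindered_diffusivity",
    "stokes_radius_from_diffusivity",
    "globular_radius_from_mw",
    "expected_count",
    "LAMBDA_MAX",
    "LAMBDA_WARN",
]

#: validity cap of the hindrance correlation; it diverges toward lambda -> 1
LAMBDA_MAX = 0.8
#: above this confinement the correlation is extrapolated; warn
LAMBDA_WARN = 0.6


@dataclass(frozen=True)
class HydroContext:
    """Solvent and confinement context for Stokes–Einstein conversions.

    temperature in K (default 294.15 = 21 C), viscosity in Pa s (water at
    21 C), ``equivalent_radius_nm`` the channel's circular-equivalent radius
    r = sqrt(A/pi); ``None`` or ``inf`` means unconfined (K = 1).
    """

    temperature: float = 294.15
    viscosity: float = 9.78e-4
    equivalent_radius_nm: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.equivalent_radius_nm is not None and not (
            self.equivalent_radius_nm > 0
        ):
            raise ValueError("equivalent_radius_nm must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_B T in joules."""
        return constants.k * self.temperature

    @property
    def r_nm(self) -> float:
        r = self.equivalent_radius_nm
        return math.inf if r is None else r


def _K(lam: float) -> float:
    """Hindrance correlation without domain policing (internal)."""
    if lam == 0.0:
        return 1.0
    num = (
        1.0
        + 9.0 * lam * math.log(lam) / 8.0
        - 1.56 * lam
        + 0.53 * lam**2
        + 1.92 * lam**3
        - 2.81 * lam**4
        + 0.27 * lam**5
        + 1.1 * lam**6
        - 0.44 * lam**7
    )
    return num / (1.0 - lam) ** 2


def hindrance_factor(lam: float) -> float:
    """Hindered/free diffusivity ratio K(lambda) for a sphere in a pore.

    K(0) = 1 exactly (the lam*ln(lam) term vanishes in the limit); K is
    strictly decreasing and lies in (0, 1] on the domain exercised here.

    Raises
    ------
    ValueError
        For lam < 0, or lam >= 0.8 where the correlation (whose (1-lam)^-2
        prefactor diverges) is outside its validity.

    Warns
    -----
    UserWarning
        For 0.6 < lam < 0.8, where the correlation is an extrapolation.
    """
    if lam < 0:
        raise ValueError("confinement ratio lambda must be non-negative")
    if lam >= LAMBDA_MAX:
        raise ValueError(
            f"lambda={lam:.3g} outside correlation validity (>= {LAMBDA_MAX})"
        )
    if lam > LAMBDA_WARN:
        warnings.warn(
            f"lambda={lam:.3g} > {LAMBDA_WARN}: hindrance correlation extrapolated",
            stacklevel=2,
        )
    return _K(lam)


def hindered_diffusivity(r_s: float, ctx: HydroContext | None = None) -> float:
    """Diffusivity (m^2/s) of a sphere of radius ``r_s`` nm in the channel.

    D = K(r_s/r) * k_B T / (6 pi eta r_s); reduces to free Stokes–Einstein
    for an unconfined context (r -> inf).
    """
    ctx = ctx if ctx is not None else HydroContext()
    if r_s <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    lam = 0.0 if math.isinf(ctx.r_nm) else r_s / ctx.r_nm
    K = hindrance_factor(lam)
    return K * ctx.kT / (6 * math.pi * ctx.viscosity * r_s * 1e-9)


def stokes_radius_from_diffusivity(
    D: float, ctx: HydroContext | None = None, xtol_nm: float = 1e-6
) -> float:
    """Hydrodynamic radius (nm) from a measured diffusivity (m^2/s).

    Solves R = K(R/r) k_B T / (6 pi eta D) for R by bracketed root finding
    on (0, lambda_max * r); exact inverse of :func:`hindered_diffusivity`
    on the validity domain.

    Raises
    ------
    ValueError
        If D <= 0, or if no root exists below the correlation's validity
        cap ("unresolvable confinement": D is too small for this channel).
    """
    ctx = ctx if ctx is not None else HydroContext()
    if D <= 0:
        raise ValueError("diffusivity must be positive for radius conversion")
    stokes_nm = ctx.kT / (6 * math.pi * ctx.viscosity * D) * 1e9  # K=1 radius
    if math.isinf(ctx.r_nm):
        return stokes_nm

    r = ctx.r_nm

    def f(R_nm: float) -> float:
        return R_nm - _K(R_nm / r) * stokes_nm

    hi = LAMBDA_MAX * r * (1.0 - 1e-12)
    lo = min(1e-9, hi / 2)
    if f(hi) < 0:
        raise ValueError(
            "unresolvable confinement: no hydrodynamic radius below the "
            f"hindrance-correlation validity cap (D={D:.3g} m^2/s too small "
            f"for equivalent radius {r:.3g} nm)"
        )
    root = brentq(f, lo, hi, xtol=xtol_nm)
    if root / r > LAMBDA_WARN:
        warnings.warn(
            f"recovered lambda={root / r:.3g} > {LAMBDA_WARN}: hindrance "
            "correlation extrapolated",
            stacklevel=2,
        )
    return float(root)


@dataclass(frozen=True)
class EmpiricalScaling:
    """Globular-protein size scaling R_s = b * MW^(1/3), MW in kDa, b in nm."""

    b: float = 0.88

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("scaling prefactor b must be positive")


def globular_radius_from_mw(
    mw_kda: float, scaling: EmpiricalScaling | None = None
) -> float:
    """Empirical globular radius (nm) for a protein of ``mw_kda`` kilodaltons."""
    if mw_kda < 0:
        raise ValueError("molecular weight must be non-negative")
    b = (scaling or EmpiricalScaling()).b
    return b * mw_kda ** (1.0 / 3.0)


def expected_count(concentration: float, area_nm2: float, fov_length_nm: float) -> float:
    """Mean number of molecules inside the field of view at a concentration.

    ``concentration`` in mol/L, channel cross-section in nm^2, FOV length in
    nm.  count = c * N_A * V with V = A * L converted to liters
    (1 nm^3 = 1e-24 L).
    """
    if concentration < 0 or area_nm2 < 0 or fov_length_nm < 0:
        raise ValueError("inputs must be non-negative")
    volume_L = area_nm2 * fov_length_nm * 1e-24
    return concentration * constants.N_A * volume_L
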