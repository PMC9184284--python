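"""Interference-contrast optics of a molecule inside a nanochannel.

A nano-object inside a water-filled channel etched in silica is detected
through the interference between the light scattered by the channel and by
the object.  Because the channel sits in a higher-index matrix its
polarizability per length is negative while the molecule's is positive, so
the interference term is negative: molecules appear as dark dips on the
channel background.

The quantitative readout is the integrated optical contrast (iOC): the
differential relative contrast of the dip integrated along the channel
axis, carrying units of length.  iOC relates linearly to molecular weight,

    MW = iOC * A / (nbar * a),

with ``A`` the channel cross-sectional area, ``a`` the mass polarizability
of protein (0.46 A^3/Da), and ``nbar`` a signed refractive-index factor of
the water/silica pair.  All signed quantities are kept signed here (nbar < 0
and iOC < 0 in the default configuration), so positive mass emerges
naturally from the product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalModel",
    "IntensityModel",
    "contrast_factor",
    "polarizability_from_mw",
    "mw_from_ioc",
    "ioc_from_mw",
    "interference_intensities",
]

#: mass polarizability of protein, nm^3 per Da (0.46 A^3/Da)
MASS_POLARIZABILITY_NM3_PER_DA = 4.6e-4


def contrast_factor(n_medium: float, n_wall: float) -> float:
    """Signed refractive-index contrast factor nbar of the channel/medium pair.

    nbar = (1.5 n_medium^2 + 0.5 n_wall^2) / (n_medium^2 - n_wall^2)

    Negative when the wall index exceeds the medium index (water in silica),
    which is what makes molecules appear as *dark* dips.

    Raises
    ------
    ValueError
        If either index is non-positive, or the indices are equal
        ("degenerate contrast": the denominator vanishes).
    """
    if n_medium <= 0 or n_wall <= 0:
        raise ValueError("refractive indices must be positive")
    num = 1.5 * n_medium**2 + 0.5 * n_wall**2
    den = n_medium**2 - n_wall**2
    if den == 0.0:
        raise ValueError("degenerate contrast: n_medium == n_wall")
    return num / den


@dataclass(frozen=True)
class OpticalModel:
    """Optical parameters of the imaging system and contrast model.

    Attributes
    ----------
    n_medium, n_wall : float
        Refractive indices of the liquid in the channel and the channel
        matrix (water 1.33, silica 1.46).
    a : float
        Mass polarizability in nm^3/Da (default 4.6e-4, i.e. 0.46 A^3/Da).
    psf_sigma : float
        Standard deviation of the 1-D Gaussian line-spread function, nm.
    pixel_pitch : float
        Kymograph pixel size along the channel, nm.
    noise_rel : float
        Per-pixel relative contrast noise (s.d.), dimensionless.
        Default 5e-5 = 0.005%, the processed-kymograph level at 200 fps.
    frame_rate : float
        Frames per second.
    """

    n_medium: float = 1.33
    n_wall: float = 1.46
    a: float = MASS_POLARIZABILITY_NM3_PER_DA
    psf_sigma: float = 100.0
    pixel_pitch: float = 30.0
    noise_rel: float = 5e-5
    frame_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("mass polarizability a must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        # validates indices (positivity, degeneracy)
        contrast_factor(self.n_medium, self.n_wall)

    @property
    def nbar(self) -> float:
        """Signed contrast factor of the configured index pair."""
        return contrast_factor(self.n_medium, self.n_wall)

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate


def polarizability_from_mw(mw: float, model: OpticalModel | None = None) -> float:
    """Molecular polarizability alpha_m = a * MW, in nm^3 (MW in Da)."""
    if mw < 0:
        raise ValueError("molecular weight must be non-negative")
    a = model.a if model is not None else MASS_POLARIZABILITY_NM3_PER_DA
    return a * mw


def ioc_from_mw(mw: float, area: float, model: OpticalModel | None = None) -> float:
    """Integrated optical contrast (nm, signed) of a molecule of mass ``mw`` Da.

    iOC = MW * nbar * a / A.  Negative in the default water/silica
    configuration (dark dips).
    """
    if mw < 0:
        raise ValueError("molecular weight must be non-negative")
    if area <= 0:
        raise ValueError("channel cross-sectional area must be positive")
    model = model if model is not None else OpticalModel()
    return mw * model.nbar * model.a / area


def mw_from_ioc(ioc: float, area: float, model: OpticalModel | None = None) -> float:
    """Molecular weight in Da from integrated optical contrast (nm).

    MW = |iOC| * A / (|nbar| * a).  Magnitudes are taken so that either the
    signed (negative) or the absolute contrast convention yields the same
    non-negative mass; exact inverse of :func:`ioc_from_mw`.
    """
    if area <= 0:
        raise ValueError("channel cross-sectional area must be positive")
    model = model if model is not None else OpticalModel()
    return abs(ioc) * area / (abs(model.nbar) * model.a)


@dataclass(frozen=True)
class IntensityModel:
    """Absolute-scale interference model (pedagogical; analysis never uses it).

    The analysis pipeline works entirely in relative contrast; this model
    exists to check the interference identities (I_c >> I_m, the -2 sqrt
    cross term) at plausible magnitudes.  ``alpha_c`` defaults to a
    slab-contrast surrogate of magnitude A |n_wall^2 - n_medium^2| /
    (n_wall^2 + n_medium^2), negative for a water channel in silica.
    """

    incident_intensity: float = 1.0
    collection_efficiency: float = 1.0
    wavenumber: float = 2 * math.pi / 600.0  # nm^-1, 600 nm central wavelength
    segment_length: float | None = None  # nm, default 3*pi/(2k)
    alpha_channel: float | None = None  # nm^2 per length, signed (negative)
    alpha_molecule: float = 30.36  # nm^3, ~66 kDa protein
    channel_area: float = 2700.0  # nm^2, used only for the alpha_c surrogate
    n_medium: float = 1.33
    n_wall: float = 1.46

    def __post_init__(self) -> None:
        if self.incident_intensity <= 0 or self.collection_efficiency <= 0:
            raise ValueError("intensity scale parameters must be positive")
        if self.wavenumber <= 0:
            raise ValueError("wavenumber must be positive")
        if self.segment_length is not None and self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.alpha_molecule < 0:
            raise ValueError("alpha_molecule must be non-negative")
        if self.alpha_channel is not None and self.alpha_channel >= 0:
            raise ValueError("alpha_channel must be negative (water in silica)")

    @property
    def L(self) -> float:
        return (
            self.segment_length
            if self.segment_length is not None
            else 3 * math.pi / (2 * self.wavenumber)
        )

    @property
    def alpha_c(self) -> float:
        if self.alpha_channel is not None:
            return self.alpha_channel
        nm2, nw2 = self.n_medium**2, self.n_wall**2
        return -self.channel_area * abs(nw2 - nm2) / (nw2 + nm2)


def interference_intensities(im: IntensityModel) -> tuple[float, float, float]:
    """Scattering intensities (I_c, I_m, dI_t) of channel, molecule, interference.

    I_c = c I0 L |alpha_c|^2 k^3 / 4
    I_m = c I0 |alpha_m|^2 k^4 / (6 pi)
    dI_t = -2 sqrt(I_c I_m)   (the detectable, negative interference term)
    """
    c, i0, k, L = im.collection_efficiency, im.incident_intensity, im.wavenumber, im.L
    i_c = c * i0 * L * im.alpha_c**2 * k**3 / 4.0
    i_m = c * i0 * im.alpha_molecule**2 * k**4 / (6 * math.pi)
    d_it = -2.0 * math.sqrt(i_c * i_m)
    return i_c, i_m, d_it
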