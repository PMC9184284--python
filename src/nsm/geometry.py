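"""Nanochannel geometry.

The channel cross-section sets both the optical contrast (through the
cross-sectional area ``A`` in the mass–contrast relation) and the
hydrodynamic confinement (through the equivalent circular radius
``r = sqrt(A / pi)`` entering the hindrance factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular nanochannel cross-section and imaged length.

    Parameters
    ----------
    width_nm, height_nm : float
        Cross-sectional dimensions in nm. Only their product (the area)
        enters the physics; the width/height split is kept for bookkeeping.
    fov_length_nm : float
        Length of the imaged portion of the channel (field of view).
    name : str
        Optional label, e.g. ``"I"`` for the named channels below.
    """

    width_nm: float
    height_nm: float
    fov_length_nm: float = 15_000.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.width_nm <= 0 or self.height_nm <= 0:
            raise ValueError("channel cross-section dimensions must be positive")
        if self.fov_length_nm <= 0:
            raise ValueError("fov_length_nm must be positive")

    @property
    def area_nm2(self) -> float:
        """Cross-sectional area A in nm^2."""
        return self.width_nm * self.height_nm

    @property
    def equivalent_radius_nm(self) -> float:
        """Radius of the circle with the same area, r = sqrt(A/pi), in nm."""
        return math.sqrt(self.area_nm2 / math.pi)


#: Named channel cross-sections (width x height, nm) of the reference chips.
CHANNELS: dict[str, ChannelGeometry] = {
    "I": ChannelGeometry(100.0, 27.0, name="I"),
    "II": ChannelGeometry(110.0, 72.0, name="II"),
    "III": ChannelGeometry(100.0, 15.0, name="III"),
    "IV": ChannelGeometry(145.0, 27.0, name="IV"),
    "V": ChannelGeometry(225.0, 200.0, name="V"),
    "VI": ChannelGeometry(82.0, 40.0, name="VI"),
}


def get_channel(name: str, fov_length_nm: float = 15_000.0) -> ChannelGeometry:
    """Look up a named channel, optionally overriding the FOV length."""
    try:
        base = CHANNELS[name]
    except KeyError:
        raise KeyError(
            f"unknown channel {name!r}; known channels: {sorted(CHANNELS)}"
        ) from None
    return ChannelGeometry(base.width_nm, base.height_nm, fov_length_nm, base.name)
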