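"""Optical model of blood-vs-tissue contrast.

Blood strongly absorbs visible light below ~600 nm (hemoglobin bands), while
the surrounding tissue autofluoresces under laser excitation.  A vessel
therefore appears dark against a bright background, and the vessel/tissue
contrast of an excitation/emission channel is governed by Beer-Lambert
attenuation of the light that must traverse the vessel.  This module holds the
channel and spectrum types, the whole-blood absorption table, and the
closed-form contrast prediction used both to rank candidate channels and to
drive phantom rendering.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpectralBand",
    "ChannelSpec",
    "AbsorptionSpectrum",
    "TissueOptics",
    "WHOLE_BLOOD",
    "DEFAULT_CHANNELS",
    "absorption_at",
    "beer_lambert_transmission",
    "effective_attenuation",
    "predicted_contrast",
    "rank_channel_predictions",
]


@dataclass(frozen=True, order=True)
class SpectralBand:
    """A laser line or emission filter band; ``width_nm = 0`` is a pure line."""

    center_nm: float
    width_nm: float = 0.0

    def __post_init__(self) -> None:
        if not 300.0 <= self.center_nm <= 900.0:
            raise ValueError(
                f"band center {self.center_nm} nm outside the supported 300-900 nm range"
            )
        if self.width_nm < 0:
            raise ValueError("band width must be >= 0")


_CHANNEL_RE = re.compile(r"^ex(\d+)_em(\d+|none)$")


@dataclass(frozen=True)
class ChannelSpec:
    """One excitation/emission pair identifying an image in the library.

    ``emission is None`` means no emission filter: only excitation light is
    collected (reflection-mode imaging at the laser wavelength).
    """

    excitation: SpectralBand
    emission: Optional[SpectralBand] = None

    def __post_init__(self) -> None:
        if self.emission is not None and not (
            self.emission.center_nm > self.excitation.center_nm
        ):
            raise ValueError(
                "emission must be red-shifted from excitation (Stokes shift); "
                f"got ex {self.excitation.center_nm} / em {self.emission.center_nm}"
            )

    @property
    def label(self) -> str:
        em = "none" if self.emission is None else f"{self.emission.center_nm:.0f}"
        return f"ex{self.excitation.center_nm:.0f}_em{em}"

    @classmethod
    def parse(cls, text: str) -> "ChannelSpec":
        """Parse a channel label such as ``ex488_em550`` or ``ex635_emnone``."""
        m = _CHANNEL_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse channel label {text!r}")
        ex = SpectralBand(float(m.group(1)))
        em = None if m.group(2) == "none" else SpectralBand(float(m.group(2)))
        return cls(ex, em)

    def sort_key(self) -> tuple[float, float]:
        # no-filter channels sort before any filtered channel at the same laser
        em = -1.0 if self.emission is None else self.emission.center_nm
        return (self.excitation.center_nm, em)


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Absorption coefficient mu_a (per mm) tabulated at increasing wavelengths."""

    wavelengths_nm: tuple[float, ...]
    mu_a_per_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        mu = np.asarray(self.mu_a_per_mm, dtype=float)
        if wl.size < 2 or wl.size != mu.size:
            raise ValueError("spectrum needs >= 2 (wavelength, mu_a) knots")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("knot wavelengths must be strictly increasing")
        if np.any(mu < 0):
            raise ValueError("mu_a values must be >= 0")

    @property
    def min_nm(self) -> float:
        return self.wavelengths_nm[0]

    @property
    def max_nm(self) -> float:
        return self.wavelengths_nm[-1]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["wavelength_nm,mu_a_per_mm"]
        lines += [
            f"{w:g},{m:g}" for w, m in zip(self.wavelengths_nm, self.mu_a_per_mm)
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbsorptionSpectrum":
        rows = Path(path).read_text().strip().splitlines()
        header = rows[0].strip().lower().replace(" ", "")
        if header != "wavelength_nm,mu_a_per_mm":
            raise ValueError(
                f"expected header 'wavelength_nm,mu_a_per_mm', got {rows[0]!r}"
            )
        pairs = [tuple(float(v) for v in r.split(",")) for r in rows[1:] if r.strip()]
        return cls(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


# Whole-blood absorption, per mm, at the laser/filter wavelengths of interest.
# Coarse table from standard oxyhemoglobin extinction tabulations assuming
# ~150 g/L total hemoglobin: strong absorption through the 450-550 nm bands,
# the steep drop past 600 nm, and near-transparency at 635-700 nm.
WHOLE_BLOOD = AbsorptionSpectrum(
    wavelengths_nm=(450.0, 488.0, 530.0, 550.0, 590.0, 635.0, 700.0),
    mu_a_per_mm=(35.0, 14.0, 22.0, 28.0, 4.2, 0.33, 0.09),
)

# The documented acquisition subset: lasers at 488/590/635 nm, each collected
# either through a 550 nm emission filter (where Stokes-valid) or unfiltered.
DEFAULT_CHANNELS: tuple[ChannelSpec, ...] = (
    ChannelSpec(SpectralBand(488.0), SpectralBand(550.0)),
    ChannelSpec(SpectralBand(488.0), None),
    ChannelSpec(SpectralBand(590.0), None),
    ChannelSpec(SpectralBand(635.0), None),
)


@dataclass(frozen=True)
class TissueOptics:
    """Background-emission and vessel-geometry parameters for prediction/rendering.

    autofluorescence_yield
        Normalized tissue intensity collected through an emission filter.
    reflectance_background
        Normalized tissue intensity for no-filter channels (backscattered
        excitation light).
    vessel_diameter_mm
        Default optical path through blood used by :func:`predicted_contrast`;
        0.05 mm corresponds to a 50 um vessel.
    """

    autofluorescence_yield: float = 0.8
    reflectance_background: float = 0.9
    vessel_diameter_mm: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "autofluorescence_yield",
            "reflectance_background",
            "vessel_diameter_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def background_for(self, channel: ChannelSpec) -> float:
        if channel.emission is None:
            return self.reflectance_background
        return self.autofluorescence_yield


def absorption_at(spectrum: AbsorptionSpectrum, band: SpectralBand) -> float:
    """Linearly interpolate mu_a (per mm) at the band center.

    The band width is ignored (center-wavelength evaluation).  Wavelengths
    outside the tabulated knot range raise rather than extrapolate.
    """
    wl = band.center_nm
    if not spectrum.min_nm <= wl <= spectrum.max_nm:
        raise ValueError(
            f"{wl} nm outside the tabulated range "
            f"[{spectrum.min_nm}, {spectrum.max_nm}] nm (no extrapolation)"
        )
    return float(np.interp(wl, spectrum.wavelengths_nm, spectrum.mu_a_per_mm))


def beer_lambert_transmission(mu_a: float, path_mm: float) -> float:
    """Fractional transmission exp(-mu_a * path) through a homogeneous absorber."""
    if mu_a < 0 or path_mm < 0:
        raise ValueError("mu_a and path_mm must be >= 0")
    return math.exp(-mu_a * path_mm)


def effective_attenuation(
    channel: ChannelSpec, blood: AbsorptionSpectrum
) -> float:
    """Per-mm attenuation of a channel through blood for one vessel crossing.

    Light traverses the vessel on the way in at the excitation wavelength and
    on the way out at the collection wavelength, so the round-trip exponent is
    mu_a(ex) + mu_a(em) for filtered channels and 2 * mu_a(ex) when only
    excitation light is collected.
    """
    mu_ex = absorption_at(blood, channel.excitation)
    if channel.emission is None:
        return 2.0 * mu_ex
    return mu_ex + absorption_at(blood, channel.emission)


def predicted_contrast(
    channel: ChannelSpec,
    optics: TissueOptics = TissueOptics(),
    blood: AbsorptionSpectrum = WHOLE_BLOOD,
) -> float:
    """Predicted vessel/tissue contrast, in percent, for one channel.

    C = 100 * (1 - T) with T the round-trip Beer-Lambert transmission through
    one vessel diameter of blood.  Lies in [0, 100]; channels where blood is
    nearly transparent (e.g. 635 nm) predict only a few percent.
    """
    mu = effective_attenuation(channel, blood)
    t = beer_lambert_transmission(mu, optics.vessel_diameter_mm)
    return 100.0 * (1.0 - t)


def rank_channel_predictions(
    channels: Sequence[ChannelSpec],
    optics: TissueOptics = TissueOptics(),
    blood: AbsorptionSpectrum = WHOLE_BLOOD,
) -> list[ChannelSpec]:
    """Channels ordered by descending predicted contrast.

    Ties are broken by ascending (excitation, emission) wavelength, with
    no-filter channels ordering before filtered ones at the same laser line.
    """
    if len(channels) == 0:
        raise ValueError("channel list must be non-empty")
    return sorted(
        channels,
        key=lambda ch: (-predicted_contrast(ch, optics, blood), ch.sort_key()),
    )
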