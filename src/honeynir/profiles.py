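"""Instrument profiles for the three NIR acquisition setups.

Each profile describes a complete analytical configuration — wavelength
range, sampling resolution, acquisition geometry and a noise model — rather
than a bare instrument. The three defaults mirror a benchtop scanning
monochromator (850–2500 nm at 0.5 nm, transflectance), a portable wide-range
spectrometer (1350–2500 nm at 16 nm, transflectance) and a portable
narrow-range spectrometer (1102–1600 nm at 2 nm, transmittance through a
thicker cuvette, which is what drives its saturation artefact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InstrumentProfile",
    "BENCHTOP",
    "WIDE_PORTABLE",
    "NARROW_PORTABLE",
    "PROFILES",
    "get_profile",
]


@dataclass(frozen=True)
class InstrumentProfile:
    """Wavelength grid plus acquisition/noise parameters of one setup.

    Parameters
    ----------
    name : str
        One of ``benchtop``, ``wide_portable``, ``narrow_portable`` for the
        built-in profiles; arbitrary names are allowed for custom setups.
    lambda_min, lambda_max : float
        Inclusive wavelength bounds in nm. The grid is the arithmetic
        sequence ``lambda_min, lambda_min + resolution, ...`` truncated at
        ``lambda_max`` (the last point may fall short of ``lambda_max`` when
        the span is not a multiple of the resolution).
    resolution : float
        Grid step in nm.
    mode : str
        ``transflectance`` or ``transmittance``; metadata only.
    pathlength : float
        Effective optical path in arbitrary path units (1.0 for the
        transflectance cells); scales the chemical absorbance term.
    noise_sd : float
        Additive detector noise, absorbance units.
    saturation_threshold : float or None
        Absorbance level above which detector noise is inflated (None
        disables the saturation artefact).
    """

    name: str
    lambda_min: float
    lambda_max: float
    resolution: float
    mode: str = "transflectance"
    pathlength: float = 1.0
    noise_sd: float = 0.002
    saturation_threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.lambda_min < self.lambda_max:
            raise ValueError("lambda_min must be < lambda_max")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.mode not in ("transflectance", "transmittance"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")

    def grid(self) -> np.ndarray:
        """Wavelength grid in nm (strictly increasing, 1-D float array)."""
        n = int(np.floor((self.lambda_max - self.lambda_min) / self.resolution + 1e-9)) + 1
        return self.lambda_min + self.resolution * np.arange(n)


BENCHTOP = InstrumentProfile(
    name="benchtop",
    lambda_min=850.0,
    lambda_max=2500.0,
    resolution=0.5,
    mode="transflectance",
    pathlength=1.0,
    noise_sd=0.002,
    saturation_threshold=None,
)

WIDE_PORTABLE = InstrumentProfile(
    name="wide_portable",
    lambda_min=1350.0,
    lambda_max=2500.0,
    resolution=16.0,
    mode="transflectance",
    pathlength=1.0,
    noise_sd=0.010,
    saturation_threshold=None,
)

# The narrow-range unit measures in transmittance through an 8 mm cuvette;
# the longer path pushes the strong 1400-1600 nm bands past the detector's
# linear range, hence the saturation threshold.
NARROW_PORTABLE = InstrumentProfile(
    name="narrow_portable",
    lambda_min=1102.0,
    lambda_max=1600.0,
    resolution=2.0,
    mode="transmittance",
    pathlength=1.4,
    noise_sd=0.005,
    saturation_threshold=2.0,
)

PROFILES = {p.name: p for p in (BENCHTOP, WIDE_PORTABLE, NARROW_PORTABLE)}


def get_profile(name: str) -> InstrumentProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown instrument profile {name!r}; valid: {sorted(PROFILES)}"
        ) from None
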