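"""Ground-truth absorption bands used by the spectral simulator.

Each analyte is assigned a small set of Gaussian absorption bands
(center, sigma, amplitude per unit concentration). The defaults place the
dominant honey NIR features where they are observed in practice:

* the first O-H/C-H overtone cluster at 1420-1470 nm (water + sugars),
* the O-H combination band near 1900-1940 nm (water),
* the C-H combination region at 2050-2150 nm (carbohydrates).

HMF carries a single tiny-amplitude band (2150 nm) and diastatic activity
carries no band at all, so both are poorly predictable from spectra by
construction. The mineral latent behind conductivity/pH contributes only a
weak, very broad feature — conductivity is spectrally indirect.

The set of grid points within +/-2 sigma of any band center is the
"informative set" that band-selection recovery tests score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .profiles import InstrumentProfile

__all__ = ["BandTruth", "DEFAULT_BAND_TRUTHS", "band_truths_for", "informative_mask"]


@dataclass(frozen=True)
class BandTruth:
    """Gaussian absorption bands of one analyte.

    ``amplitudes`` are absorbance per unit concentration per unit path at
    the band center.
    """

    analyte: str
    centers: tuple[float, ...] = field(default_factory=tuple)
    widths: tuple[float, ...] = field(default_factory=tuple)  # Gaussian sigma, nm
    amplitudes: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("centers, widths, amplitudes must have equal length")
        for c in self.centers:
            if not 850.0 <= c <= 2500.0:
                raise ValueError(f"band center {c} nm outside [850, 2500]")
        for s in self.widths:
            if s <= 0:
                raise ValueError("band widths (sigma) must be > 0")
        for a in self.amplitudes:
            if a < 0:
                raise ValueError("band amplitudes must be >= 0")

    def response(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-concentration absorbance of this analyte on a grid."""
        out = np.zeros_like(wavelengths, dtype=float)
        for c, s, a in zip(self.centers, self.widths, self.amplitudes):
            out += a * np.exp(-0.5 * ((wavelengths - c) / s) ** 2)
        return out


DEFAULT_BAND_TRUTHS: tuple[BandTruth, ...] = (
    BandTruth("moisture", (1440.0, 1920.0), (18.0, 14.0), (0.050, 0.040)),
    BandTruth("glucose", (1450.0, 2100.0), (15.0, 25.0), (0.020, 0.020)),
    # Fructose carries combination bands shifted from glucose's (a lower
    # first-overtone shoulder and a higher C-H combination band): the two
    # sugars are NIR-distinguishable precisely because their band positions
    # are offset, not because either has an exclusive spectral window.
    BandTruth("fructose", (1390.0, 2270.0), (15.0, 25.0), (0.015, 0.015)),
    BandTruth("hmf", (2150.0,), (20.0,), (0.0004,)),
    BandTruth("diastase"),
    # Mineral/organic-acid load behind conductivity and pH: a very weak,
    # very broad feature (sub-noise per column) — conductivity is
    # spectrally indirect.
    BandTruth("conductivity", (1650.0,), (150.0,), (0.0015,)),
)


def band_truths_for(analytes: Iterable[str]) -> tuple[BandTruth, ...]:
    """Subset of the default truths for the named analytes (order preserved)."""
    wanted = set(analytes)
    unknown = wanted - {t.analyte for t in DEFAULT_BAND_TRUTHS}
    if unknown:
        raise ValueError(f"no default band truth for analytes {sorted(unknown)}")
    return tuple(t for t in DEFAULT_BAND_TRUTHS if t.analyte in wanted)


def informative_mask(
    truths: Sequence[BandTruth], profile: InstrumentProfile
) -> np.ndarray:
    """Boolean mask over the profile grid: within +/-2 sigma of any band.

    Only bands with amplitude > 0 count. Bands entirely outside the grid
    contribute nothing (e.g. a 2100 nm band on a 1102-1600 nm instrument).
    """
    if not truths:
        raise ValueError("truths must be non-empty")
    grid = profile.grid()
    mask = np.zeros(grid.shape, dtype=bool)
    for truth in truths:
        for c, s, a in zip(truth.centers, truth.widths, truth.amplitudes):
            if a > 0:
                mask |= np.abs(grid - c) <= 2.0 * s
    return mask
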