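"""Forward simulation of multi-instrument honey NIR spectra.

The signal model is additive Beer-Lambert-style chemistry plus an
instrument/presentation layer:

    clean(lambda) = pathlength * sum_analyte conc_a * response_a(lambda)
                    + alpha + beta * lambda + class_offset
    row(lambda)   = clean(lambda) * scatter + eps(lambda)

where ``response_a`` is the analyte's Gaussian band profile, ``scatter`` is
a per-scan multiplicative factor ~ Normal(1, s_scatter) emulating
particle-size/presentation effects, and ``eps`` is additive detector noise
~ Normal(0, noise_sd). For instruments with a saturation threshold the
noise SD is inflated wherever the clean absorbance exceeds the threshold,
reproducing the elevated-noise artefact of an over-long optical path.

Class-dependent baseline offsets (PF > MF > CH) encode the consistently
higher mean absorbance of polyfloral samples — a scattering/crystallisation
effect that rides on top of the compositional differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bands import DEFAULT_BAND_TRUTHS, BandTruth
from .composition import CompositionRecord
from .io import SpectrumSet
from .profiles import InstrumentProfile

__all__ = ["SimulationConfig", "DEFAULT_SIMULATION", "simulate_spectra"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator constants for the instrument/presentation layer.

    All values are in absorbance units (per nm for the baseline slope).
    """

    baseline_intercept: float = 0.2
    baseline_slope: float = 2.0e-4  # gentle upward drift with wavelength
    class_offsets: tuple[tuple[str, float], ...] = (
        ("CH", -0.06),
        ("MF", 0.0),
        ("PF", 0.06),
    )
    scatter_sd: float = 0.02
    saturation_noise_inflation: float = 5.0

    def offset_for(self, botanical_class: str) -> float:
        return dict(self.class_offsets).get(botanical_class, 0.0)


DEFAULT_SIMULATION = SimulationConfig()


def simulate_spectra(
    records: Sequence[CompositionRecord],
    profile: InstrumentProfile,
    truths: Sequence[BandTruth] = DEFAULT_BAND_TRUTHS,
    replicates: int = 2,
    seed: int = 0,
    config: SimulationConfig = DEFAULT_SIMULATION,
) -> SpectrumSet:
    """Simulate replicate scans of each sample on one instrument.

    Parameters
    ----------
    records : sequence of CompositionRecord
        Reference chemistry; each analyte named by a BandTruth must be a
        record attribute (concentration >= 0).
    profile : InstrumentProfile
        Wavelength grid, pathlength and noise model.
    truths : sequence of BandTruth
        Analyte band profiles (defaults to the full generator truth set).
    replicates : int
        Independent-aliquot scans per sample (the reference protocol uses 2).
    seed : int
        Seed for the dedicated random generator.

    Returns
    -------
    SpectrumSet
        ``len(records) * replicates`` rows on the profile grid, annotated
        with sample ids, replicate ids and botanical classes.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = profile.grid()
    if grid.size == 0:
        raise ValueError("instrument profile has an empty wavelength grid")
    responses = np.stack([t.response(grid) for t in truths])  # analytes x p
    conc = np.empty((len(records), len(truths)))
    for i, rec in enumerate(records):
        for j, t in enumerate(truths):
            c = float(getattr(rec, t.analyte))
            if c < 0:
                raise ValueError(
                    f"negative concentration {c} for analyte {t.analyte!r} "
                    f"in sample {rec.sample_id!r}"
                )
            conc[i, j] = c

    rng = np.random.default_rng(seed)
    n_rows = len(records) * replicates
    absorbance = np.empty((n_rows, grid.size))
    sample_ids = np.empty(n_rows, dtype=object)
    replicate_ids = np.empty(n_rows, dtype=object)
    classes = np.empty(n_rows, dtype=object)

    chem = conc @ responses * profile.pathlength  # samples x p
    baseline = config.baseline_intercept + config.baseline_slope * grid
    row = 0
    for i, rec in enumerate(records):
        clean = chem[i] + baseline + config.offset_for(rec.botanical_class)
        noise_sd = np.full(grid.size, profile.noise_sd)
        if profile.saturation_threshold is not None:
            noise_sd[clean > profile.saturation_threshold] *= (
                config.saturation_noise_inflation
            )
        for r in range(replicates):
            scatter = 1.0 + config.scatter_sd * rng.standard_normal()
            eps = noise_sd * rng.standard_normal(grid.size)
            absorbance[row] = clean * scatter + eps
            sample_ids[row] = rec.sample_id
            replicate_ids[row] = f"r{r + 1}"
            classes[row] = rec.botanical_class
            row += 1
    return SpectrumSet(
        wavelengths=grid,
        absorbance=absorbance,
        sample_ids=sample_ids,
        replicate_ids=replicate_ids,
        class_labels=classes,
        instrument=profile,
    )
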