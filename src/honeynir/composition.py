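"""Synthetic wet-chemistry reference values for honey samples.

Draws per-sample physicochemical records (moisture, HMF, diastatic
activity, electrical conductivity, glucose, fructose, reducing sugars, pH)
for three botanical classes:

* ``CH`` — chestnut,
* ``PF`` — polyfloral,
* ``MF`` — a pooled multifloral class.

CH and PF parameters are the published group means of a 30+30 sample
reference study; per-class SDs are reconstructed from the printed pooled
SEM as ``SD = SEM * sqrt(30)``. The MF class has no published composition
table and is modelled as a 50/50 mixture of the CH and PF parameter sets
with 1.5x inflated SDs, giving it intermediate means and wider spread.

Generator conventions
---------------------
* ``reducing_sugars = glucose + fructose`` holds exactly for every record
  (consistent with the reference means: 20.4 + 38.5 = 58.9 for CH and
  30.2 + 38.4 = 68.6 for PF).
* Electrical conductivity and pH are deterministic monotone functions of a
  latent "mineral" concentration (conductivity is the latent itself; pH is
  an affine map of it), reflecting that both trace the mineral / organic
  acid load rather than a specific NIR-active constituent.
* All draws are truncated normals, clipped at +/-4 SD and at physical
  bounds (moisture within the 13-25 % refractometer operating range, all
  quantities positive).
* Every stochastic operation takes an explicit seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "CompositionRecord",
    "TABLE_STATS",
    "GROUP_N",
    "CLASSES",
    "PH_SLOPE",
    "PH_INTERCEPT",
    "class_sd",
    "sample_composition",
    "records_to_frame",
    "RESPONSE_COLUMNS",
]

CLASSES = ("CH", "PF", "MF")

#: Reference per-class means and pooled SEM for the eight responses.
#: Keys: variable -> {"CH": mean, "PF": mean, "sem": pooled SEM}.
TABLE_STATS: dict[str, dict[str, float]] = {
    "moisture": {"CH": 17.1, "PF": 17.7, "sem": 0.18},
    "hmf": {"CH": 5.87, "PF": 12.7, "sem": 1.01},
    "diastase": {"CH": 29.3, "PF": 26.9, "sem": 1.39},
    "conductivity": {"CH": 1.92, "PF": 0.79, "sem": 0.06},
    "glucose": {"CH": 20.4, "PF": 30.2, "sem": 0.46},
    "fructose": {"CH": 38.5, "PF": 38.4, "sem": 0.51},
    "reducing_sugars": {"CH": 58.9, "PF": 68.6, "sem": 0.72},
    "ph": {"CH": 5.11, "PF": 4.10, "sem": 0.06},
}

#: Per-group sample size behind the SEMs above (SD = SEM * sqrt(GROUP_N)).
GROUP_N = 30

#: Inflation applied to SDs when drawing the pooled multifloral class.
MF_SD_INFLATION = 1.5

#: Variables drawn directly (reducing sugars and pH are derived).
_DRAWN = ("moisture", "hmf", "diastase", "conductivity", "glucose", "fructose")

#: Physical bounds per drawn variable (refractometer range for moisture,
#: positivity floors elsewhere).
_BOUNDS = {
    "moisture": (13.0, 25.0),
    "hmf": (0.1, np.inf),
    "diastase": (0.5, np.inf),
    "conductivity": (0.05, np.inf),
    "glucose": (5.0, 60.0),
    "fructose": (5.0, 60.0),
}

# pH as an affine, strictly increasing function of the mineral latent
# (= conductivity), calibrated so both class means reproduce the reference
# table: CH (1.92 mS/cm, pH 5.11) and PF (0.79 mS/cm, pH 4.10).
PH_SLOPE = (5.11 - 4.10) / (1.92 - 0.79)
PH_INTERCEPT = 5.11 - PH_SLOPE * 1.92

RESPONSE_COLUMNS = [
    "moisture",
    "hmf",
    "diastase",
    "conductivity",
    "glucose",
    "fructose",
    "reducing_sugars",
    "ph",
]


@dataclass(frozen=True)
class CompositionRecord:
    """Wet-chemistry reference values for one honey sample."""

    sample_id: str
    botanical_class: str
    moisture: float  # %
    hmf: float  # mg/kg
    diastase: float  # Schade units
    conductivity: float  # mS/cm
    glucose: float  # %
    fructose: float  # %
    reducing_sugars: float  # %
    ph: float

    def __post_init__(self) -> None:
        if self.botanical_class not in CLASSES:
            raise ValueError(
                f"unknown botanical class {self.botanical_class!r}; "
                f"valid classes: {list(CLASSES)}"
            )


def class_sd(variable: str) -> float:
    """Per-class SD reconstructed from the pooled SEM (SD = SEM * sqrt(n))."""
    return TABLE_STATS[variable]["sem"] * float(np.sqrt(GROUP_N))


def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    lo = max(lo, mean - 4.0 * sd)
    hi = min(hi, mean + 4.0 * sd)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_record(rng: np.random.Generator, sample_id: str, cls: str) -> CompositionRecord:
    if cls == "MF":
        # 50/50 CH/PF mixture with inflated spread; one parent pick per
        # sample so sugar/mineral patterns stay internally coherent.
        parent = "CH" if rng.random() < 0.5 else "PF"
        sd_factor = MF_SD_INFLATION
    else:
        parent = cls
        sd_factor = 1.0
    values: dict[str, float] = {}
    for var in _DRAWN:
        mean = TABLE_STATS[var][parent]
        sd = class_sd(var) * sd_factor
        lo, hi = _BOUNDS[var]
        values[var] = _draw_truncnorm(rng, mean, sd, lo, hi)
    mineral = values["conductivity"]
    return CompositionRecord(
        sample_id=sample_id,
        botanical_class=cls,
        moisture=values["moisture"],
        hmf=values["hmf"],
        diastase=values["diastase"],
        conductivity=mineral,
        glucose=values["glucose"],
        fructose=values["fructose"],
        reducing_sugars=values["glucose"] + values["fructose"],
        ph=PH_INTERCEPT + PH_SLOPE * mineral,
    )


def sample_composition(
    n_per_class: Mapping[str, int], seed: int
) -> list[CompositionRecord]:
    """Draw composition records per botanical class.

    Parameters
    ----------
    n_per_class : mapping
        Class name -> number of samples, e.g. ``{"CH": 30, "PF": 30, "MF": 18}``.
    seed : int
        Seed for the dedicated random generator.

    Returns
    -------
    list of CompositionRecord
        Records in class order as given, ids ``{class}{index:03d}``.
    """
    for cls, n in n_per_class.items():
        if cls not in CLASSES:
            raise ValueError(
                f"unknown botanical class {cls!r}; valid classes: {list(CLASSES)}"
            )
        if n < 1:
            raise ValueError(f"n_per_class[{cls!r}] must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    records = []
    for cls, n in n_per_class.items():
        for i in range(n):
            records.append(_draw_record(rng, f"{cls}{i:03d}", cls))
    return records


def records_to_frame(records: list[CompositionRecord]):
    """Reference table (one row per sample) as a pandas DataFrame."""
    import pandas as pd

    rows = [
        {
            "sample_id": r.sample_id,
            "botanical_class": r.botanical_class,
            **{c: getattr(r, c) for c in RESPONSE_COLUMNS},
        }
        for r in records
    ]
    return pd.DataFrame(rows)
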