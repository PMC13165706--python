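"""Spectral matrix container and plain-CSV persistence.

The wide CSV dialect: one row per scan; columns ``sample_id``,
``replicate_id``, optionally ``class``, then one column per wavelength with
the wavelength in nm (up to 2 decimals) as the header. Comma separated,
UTF-8. Reference chemistry tables are ordinary CSV with a ``sample_id``
column, a ``botanical_class`` column and one column per response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .profiles import InstrumentProfile

__all__ = [
    "SpectrumSet",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "write_reference_csv",
    "average_replicates",
    "align",
]

log = logging.getLogger(__name__)

#: replicate id used after averaging
AVERAGED = "avg"


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV violates the wide-format contract."""


@dataclass
class SpectrumSet:
    """Absorbance matrix on a wavelength grid with per-row annotations.

    Rows are individual scans; ``sample_ids`` and ``replicate_ids`` have one
    entry per row, ``wavelengths`` one entry per column. ``class_labels`` is
    optional (None when unknown). Absorbance is stored in log(1/R) or
    log(1/T) units; the acquisition mode lives on the instrument profile and
    is metadata only.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    replicate_ids: np.ndarray
    class_labels: Optional[np.ndarray] = None
    instrument: Optional[InstrumentProfile] = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.replicate_ids = np.asarray(self.replicate_ids, dtype=object)
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels, dtype=object)
        self.validate()

    def validate(self) -> None:
        n, p = self.absorbance.shape
        if self.wavelengths.ndim != 1 or self.wavelengths.size != p:
            raise ValueError("wavelengths length must equal column count")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.sample_ids.size != n or self.replicate_ids.size != n:
            raise ValueError("sample_ids/replicate_ids length must equal row count")
        if self.class_labels is not None and self.class_labels.size != n:
            raise ValueError("class_labels length must equal row count")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains missing/non-finite values")

    @property
    def n_rows(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]


def _format_wavelength(w: float) -> str:
    s = f"{w:.2f}".rstrip("0").rstrip(".")
    return s


def write_spectra_csv(s: SpectrumSet, path) -> None:
    """Write a SpectrumSet in the wide CSV dialect.

    Wavelength headers are printed with up to 2 decimals (a 0.5 nm grid
    needs one); absorbance values at 17 significant digits so a read/write
    round trip is exact to well below 1e-12.
    """
    cols = {"sample_id": s.sample_ids, "replicate_id": s.replicate_ids}
    if s.class_labels is not None:
        cols["class"] = s.class_labels
    df = pd.DataFrame(cols)
    spec = pd.DataFrame(
        s.absorbance, columns=[_format_wavelength(w) for w in s.wavelengths]
    )
    pd.concat([df, spec.set_index(df.index)], axis=1).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_spectra_csv(path, instrument: Optional[InstrumentProfile] = None) -> SpectrumSet:
    """Read a wide-format spectra CSV.

    The first header row holds wavelengths in decimal nm after the
    ``sample_id``/``replicate_id`` (and optional ``class``) columns.
    Wavelengths must parse as numbers and be strictly increasing; ragged or
    incomplete rows are rejected naming the offending row.
    """
    df = pd.read_csv(path)
    meta_cols = ["sample_id", "replicate_id"]
    for c in meta_cols:
        if c not in df.columns:
            raise SpectraFormatError(f"missing required column {c!r}")
    has_class = "class" in df.columns
    if has_class:
        meta_cols.append("class")
    wl_cols = [c for c in df.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from None
    if wavelengths.size < 1:
        raise SpectraFormatError("no wavelength columns found")
    if not np.all(np.diff(wavelengths) > 0):
        raise SpectraFormatError(
            "wavelength header not strictly increasing (duplicated or unordered columns)"
        )
    values = df[wl_cols].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(values).all(axis=1))[0]
    if bad.size:
        raise SpectraFormatError(
            f"row {bad[0]} (sample_id={df['sample_id'].iloc[bad[0]]!r}) "
            "has missing or non-numeric absorbance values"
        )
    return SpectrumSet(
        wavelengths=wavelengths,
        absorbance=values,
        sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
        replicate_ids=df["replicate_id"].astype(str).to_numpy(dtype=object),
        class_labels=(
            df["class"].astype(str).to_numpy(dtype=object) if has_class else None
        ),
        instrument=instrument,
    )


def write_reference_csv(ref: pd.DataFrame, path) -> None:
    ref.to_csv(path, index=False, float_format="%.17g")


def read_reference_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SpectraFormatError("reference table missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise SpectraFormatError("reference table sample_id values must be unique")
    return df


def average_replicates(s: SpectrumSet) -> SpectrumSet:
    """Average replicate scans per sample (duplicate-aliquot convention).

    One output row per sample_id, in first-appearance order; the arithmetic
    mean over that sample's replicate rows. Replicate ids collapse to
    ``"avg"``; class labels are preserved and must agree within a sample.
    Idempotent: averaging an averaged set returns it unchanged.
    """
    ids = s.sample_ids
    order: list[str] = []
    seen = set()
    for sid in ids:
        if sid not in seen:
            seen.add(sid)
            order.append(sid)
    rows = np.empty((len(order), s.n_wavelengths))
    labels = [] if s.class_labels is not None else None
    for i, sid in enumerate(order):
        idx = np.where(ids == sid)[0]
        rows[i] = s.absorbance[idx].mean(axis=0)
        if labels is not None:
            lab = set(s.class_labels[idx])
            if len(lab) > 1:
                raise ValueError(
                    f"conflicting class labels {sorted(lab)} within sample {sid!r}"
                )
            labels.append(lab.pop())
    return SpectrumSet(
        wavelengths=s.wavelengths.copy(),
        absorbance=rows,
        sample_ids=np.array(order, dtype=object),
        replicate_ids=np.array([AVERAGED] * len(order), dtype=object),
        class_labels=np.array(labels, dtype=object) if labels is not None else None,
        instrument=s.instrument,
    )


def align(
    s: SpectrumSet, ref: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame, Optional[np.ndarray]]:
    """Match averaged spectra with a reference chemistry table.

    Returns ``(X, Y, labels)`` with rows in sorted sample-id order (the
    result depends only on the id sets, not on input row order). Samples
    present on one side only are dropped with a logged count.

    ``labels`` come from the spectra's class annotation when present,
    otherwise from the reference table's ``botanical_class`` column.
    """
    if np.unique(s.sample_ids).size != s.sample_ids.size:
        raise ValueError("spectra must be replicate-averaged before alignment")
    spec_ids = set(map(str, s.sample_ids))
    ref_ids = set(map(str, ref["sample_id"]))
    common = sorted(spec_ids & ref_ids)
    if not common:
        raise ValueError("no overlapping sample_ids between spectra and reference")
    dropped = len(spec_ids - ref_ids) + len(ref_ids - spec_ids)
    if dropped:
        log.info("align: dropped %d unmatched sample(s)", dropped)
    pos = {str(sid): i for i, sid in enumerate(s.sample_ids)}
    row_idx = [pos[sid] for sid in common]
    X = s.absorbance[row_idx]
    Y = ref.set_index(ref["sample_id"].astype(str)).loc[common].reset_index(drop=True)
    if s.class_labels is not None:
        labels = s.class_labels[row_idx]
    elif "botanical_class" in Y.columns:
        labels = Y["botanical_class"].to_numpy(dtype=object)
    else:
        labels = None
    return X, Y, labels


def subset_rows(s: SpectrumSet, idx: np.ndarray) -> SpectrumSet:
    """Row subset helper preserving annotations."""
    return replace(
        s,
        absorbance=s.absorbance[idx],
        sample_ids=s.sample_ids[idx],
        replicate_ids=s.replicate_ids[idx],
        class_labels=None if s.class_labels is None else s.class_labels[idx],
    )
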