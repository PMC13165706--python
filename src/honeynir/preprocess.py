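"""Spectral pre-processing operators and the calibration/validation contract.

Operators are applied in a fixed order: scatter correction (SNV or MSC) ->
linear detrending -> Savitzky-Golay filtering (smoothing or derivative) ->
column scaling (mean centring or autoscaling). Row-wise operators (SNV,
MSC, detrend, SG) are stateless; the MSC reference spectrum and scaling
statistics are estimated on calibration rows only and reused verbatim on
validation rows, so validation never leaks into the fit.

The enumeration grid mirrors standard chemometric practice: SG window
lengths 3-21 points (odd), polynomial order 2 or 3, derivative order 0-2,
with window length 1 meaning "no Savitzky-Golay filtering".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "PreprocessSpec",
    "FittedPreprocessor",
    "snv",
    "msc",
    "detrend_linear",
    "savitzky_golay",
    "fit_apply",
    "enumerate_grid",
    "IDENTITY_SPEC",
]

SG_WINDOWS = tuple(range(3, 22, 2))
SG_POLYORDERS = (2, 3)
SG_DERIVS = (0, 1, 2)
SCATTERS = ("none", "snv", "msc")
SCALINGS = ("none", "mean_center", "autoscale")

_ORDINAL = {0: "smoothing", 1: "1st derivative", 2: "2nd derivative"}


@dataclass(frozen=True)
class PreprocessSpec:
    """One point of the pre-processing grid.

    ``sg_window == 1`` means no SG filtering (and requires ``sg_deriv == 0``);
    otherwise the window must be odd and exceed the polynomial order.
    """

    scatter: str = "none"
    detrend: bool = False
    sg_window: int = 1
    sg_polyorder: int = 2
    sg_deriv: int = 0
    scaling: str = "none"

    def __post_init__(self) -> None:
        if self.scatter not in SCATTERS:
            raise ValueError(f"scatter must be one of {SCATTERS}, got {self.scatter!r}")
        if self.scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}, got {self.scaling!r}")
        if self.sg_window == 1:
            if self.sg_deriv != 0:
                raise ValueError("sg_window = 1 (no filtering) requires sg_deriv = 0")
        else:
            if self.sg_window % 2 == 0 or self.sg_window < 3 or self.sg_window > 21:
                raise ValueError("sg_window must be odd and within 3..21 (or 1)")
            if self.sg_polyorder not in SG_POLYORDERS:
                raise ValueError("sg_polyorder must be 2 or 3")
            if self.sg_window <= self.sg_polyorder:
                raise ValueError("sg_window must exceed sg_polyorder")
            if self.sg_deriv not in SG_DERIVS:
                raise ValueError("sg_deriv must be 0, 1 or 2")
            if self.sg_deriv > self.sg_polyorder:
                raise ValueError("sg_deriv must not exceed sg_polyorder")

    @property
    def label(self) -> str:
        """Human-readable id in the conventional report notation.

        The SG polynomial order is included ("SG (7, poly 2)") so that ids
        are unique across the grid.
        """
        parts = []
        if self.scatter == "snv":
            parts.append("SNV")
        elif self.scatter == "msc":
            parts.append("MSC")
        if self.detrend:
            parts.append("linear detrending")
        if self.sg_window == 1:
            parts.append("no Savitzky-Golay filtering")
        else:
            parts.append(
                f"SG ({self.sg_window}, poly {self.sg_polyorder}) "
                f"{_ORDINAL[self.sg_deriv]}"
            )
        if self.scaling == "mean_center":
            parts.append("mean centring")
        elif self.scaling == "autoscale":
            parts.append("mean centring + scaling")
        return " + ".join(parts) if parts else "raw"


IDENTITY_SPEC = PreprocessSpec()


def snv(X: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: each row to mean 0, sample SD (n-1) 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("SNV requires a 2-D matrix with >= 2 columns")
    sd = X.std(axis=1, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(f"SNV undefined for zero-variance row {zero[0]}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc(
    X: np.ndarray, reference: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative Scatter Correction against a reference spectrum.

    Each row x is regressed on the reference (x ~= a + b*ref, least
    squares) and replaced by (x - a) / b. When no reference is given the
    column-wise mean of X is used and returned, so a calibration reference
    can be reused on validation rows.
    """
    X = np.asarray(X, dtype=float)
    if reference is None:
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (X.shape[1],):
        raise ValueError("reference length must equal column count")
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference has zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        bad = int(np.argmin(np.abs(b)))
        raise ValueError(f"degenerate MSC fit (|b| < 1e-12) for row {bad}")
    a = X.mean(axis=1) - b * reference.mean()
    return (X - a[:, None]) / b[:, None], reference


def detrend_linear(X: np.ndarray) -> np.ndarray:
    """Remove the per-row least-squares straight line over column index."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("detrend requires a 2-D matrix with >= 3 columns")
    return signal.detrend(X, axis=1, type="linear")


def savitzky_golay(
    X: np.ndarray,
    window: int,
    polyorder: int,
    deriv: int = 0,
    grid_step: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative filter, row-wise.

    Derivatives are scaled by ``1 / grid_step**deriv`` so the output is in
    absorbance per nm**deriv, making band positions comparable across
    instrument grids. Edges are handled by evaluating the local polynomial
    fit at the ends (same-length output). ``window == 1`` returns the input
    unchanged.
    """
    X = np.asarray(X, dtype=float)
    if window == 1:
        if deriv != 0:
            raise ValueError("window = 1 (no filtering) requires deriv = 0")
        return X.copy()
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")
    return signal.savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=grid_step, axis=1, mode="interp",
    )


@dataclass
class FittedPreprocessor:
    """A PreprocessSpec plus the statistics estimated on calibration rows."""

    spec: PreprocessSpec
    grid_step: float = 1.0
    msc_reference: Optional[np.ndarray] = None
    column_means: Optional[np.ndarray] = None
    column_sds: Optional[np.ndarray] = None

    def _row_ops(self, X: np.ndarray) -> np.ndarray:
        s = self.spec
        if s.scatter == "snv":
            X = snv(X)
        elif s.scatter == "msc":
            X, _ = msc(X, self.msc_reference)
        if s.detrend:
            X = detrend_linear(X)
        if s.sg_window != 1:
            X = savitzky_golay(X, s.sg_window, s.sg_polyorder, s.sg_deriv,
                               self.grid_step)
        return X

    def fit(self, X_cal: np.ndarray) -> "FittedPreprocessor":
        X_cal = np.asarray(X_cal, dtype=float)
        if self.spec.scatter == "msc":
            self.msc_reference = X_cal.mean(axis=0)
        Xt = self._row_ops(X_cal)
        if self.spec.scaling != "none":
            self.column_means = Xt.mean(axis=0)
            if self.spec.scaling == "autoscale":
                sds = Xt.std(axis=0, ddof=1)
                sds[sds == 0] = 1.0  # constant columns pass through centred
                self.column_sds = sds
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xt = self._row_ops(np.asarray(X, dtype=float))
        if self.spec.scaling != "none":
            if self.column_means is None:
                raise RuntimeError("preprocessor not fitted")
            Xt = Xt - self.column_means
            if self.spec.scaling == "autoscale":
                Xt = Xt / self.column_sds
        return Xt


def fit_apply(
    spec: PreprocessSpec,
    X_cal: np.ndarray,
    X_val: Optional[np.ndarray] = None,
    grid_step: float = 1.0,
) -> tuple[np.ndarray, Optional[np.ndarray], FittedPreprocessor]:
    """Fit the operator chain on calibration rows, apply to both sets.

    Identical transformations are applied to calibration and validation
    data: the MSC reference and any column means/SDs come from ``X_cal``
    only.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    if X_val is not None:
        X_val = np.asarray(X_val, dtype=float)
        if X_val.shape[1] != X_cal.shape[1]:
            raise ValueError("X_cal and X_val must have the same column count")
    fitted = FittedPreprocessor(spec=spec, grid_step=grid_step).fit(X_cal)
    Xc = fitted.transform(X_cal)
    Xv = fitted.transform(X_val) if X_val is not None else None
    return Xc, Xv, fitted


def enumerate_grid(
    scatters: Sequence[str] = SCATTERS,
    detrends: Sequence[bool] = (False, True),
    windows: Iterable[int] = (1,) + SG_WINDOWS,
    polyorders: Sequence[int] = SG_POLYORDERS,
    derivs: Sequence[int] = SG_DERIVS,
    scalings: Sequence[str] = SCALINGS,
) -> list[PreprocessSpec]:
    """Deterministic, duplicate-free enumeration of the pre-processing grid.

    The full default grid has 3 scatter x 2 detrend x 58 SG x 3 scaling =
    1044 specs; the 58 SG variants are "no filtering" plus every valid
    (window, polyorder, deriv) combination (window = 3 admits only
    polyorder 2 since the window must exceed the order).
    """
    specs: list[PreprocessSpec] = []
    seen: set[PreprocessSpec] = set()
    for scatter in scatters:
        for detrend in detrends:
            for window in windows:
                if window == 1:
                    sg_combos = [(1, 2, 0)]
                else:
                    sg_combos = [
                        (window, po, dv)
                        for po in polyorders
                        for dv in derivs
                        if window > po and dv <= po
                    ]
                for w, po, dv in sg_combos:
                    for scaling in scalings:
                        spec = PreprocessSpec(
                            scatter=scatter, detrend=detrend, sg_window=w,
                            sg_polyorder=po, sg_deriv=dv, scaling=scaling,
                        )
                        if spec not in seen:
                            seen.add(spec)
                            specs.append(spec)
    return specs
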