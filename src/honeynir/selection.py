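"""Wavelength selection: VIP/SR candidate intervals, siPLS, CARS-PLS.

The cascade mirrors common chemometric practice for reducing a
full-spectrum calibration to a handful of informative bands:

1. Fit a full-spectrum PLS model and compute VIP and selectivity-ratio
   profiles; grid points with VIP >= 1.0 *and* SR above its 0.75 quantile
   become candidate intervals (short gaps merged, short runs dropped).
2. Stepwise interval PLS (siPLS): greedy forward combination of candidate
   intervals minimising RMSECV, stopping when the relative improvement
   falls below 0.5%.
3. Optional refinement by Competitive Adaptive Reweighted Sampling
   (CARS-PLS): Monte-Carlo resampled PLS fits rank variables by
   |regression coefficient|; the retention schedule decays exponentially
   at rate 0.9 per iteration over 30 iterations, never dropping below 30
   variables; the iteration with minimal RMSECV defines the selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pls import fit_pls, rmsecv_curve

__all__ = [
    "IntervalSet",
    "BandSelectionResult",
    "candidate_intervals",
    "sipls_search",
    "cars_pls",
    "cars_retention_schedule",
    "apply_band_mask",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalSet:
    """Sorted, non-overlapping half-open index intervals over a grid."""

    intervals: tuple[tuple[int, int], ...]
    n_points: int

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.intervals:
            if not 0 <= start < end <= self.n_points:
                raise ValueError(f"interval ({start}, {end}) out of range")
            if start <= prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end - 1

    def indices(self, which: int) -> np.ndarray:
        start, end = self.intervals[which]
        return np.arange(start, end)


@dataclass
class BandSelectionResult:
    """Outcome of one selection run."""

    method: str  # "siPLS" or "CARS"
    selected_indices: np.ndarray
    rmsecv_trajectory: list[tuple[int, float]]
    chosen_n_lv: int
    seed: int = 0
    retention_schedule: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.selected_indices.size == 0:
            raise ValueError("selected_indices must be non-empty")


def candidate_intervals(
    vip_values: np.ndarray,
    sr_values: np.ndarray,
    min_len: int = 5,
    max_gap: int = 2,
    sr_quantile: float = 0.75,
    expand_frac: float = 0.25,
) -> IntervalSet:
    """Candidate bands where VIP >= 1.0 and SR exceeds its 0.75 quantile.

    Runs of qualifying points separated by at most ``max_gap`` non-
    qualifying points are merged and runs shorter than ``min_len`` are
    discarded. Each surviving run is then expanded symmetrically by
    ``expand_frac`` of its own length per side (overlaps re-merged):
    threshold crossings systematically under-cover the shoulders of a
    continuous absorption band — for a Gaussian band the VIP >= 1 crossing
    sits well inside the +/-2 sigma support — so candidate intervals are
    grown toward the band's full extent before interval-level search.
    If the combined criterion selects nothing, the VIP >= 1.0 criterion
    alone is used as a fallback (logged); if that is still empty an error
    instructs full-spectrum use.
    """
    vip_values = np.asarray(vip_values, dtype=float)
    sr_values = np.asarray(sr_values, dtype=float)
    if vip_values.shape != sr_values.shape or vip_values.ndim != 1:
        raise ValueError("VIP and SR must be 1-D vectors of equal length")
    p = vip_values.size
    mask = (vip_values >= 1.0) & (sr_values > np.quantile(sr_values, sr_quantile))
    if not mask.any():
        log.info("candidate_intervals: combined VIP/SR mask empty, "
                 "falling back to VIP >= 1.0 alone")
        mask = vip_values >= 1.0
    intervals = _mask_to_intervals(mask, min_len, max_gap)
    if not intervals:
        raise ValueError(
            "no candidate interval satisfies the selection criteria; "
            "use the full spectrum instead"
        )
    intervals = _expand_intervals(intervals, p, expand_frac)
    return IntervalSet(intervals=tuple(intervals), n_points=p)


def _expand_intervals(
    intervals: list[tuple[int, int]], p: int, expand_frac: float
) -> list[tuple[int, int]]:
    if expand_frac <= 0:
        return intervals
    grown = []
    for start, end in intervals:
        pad = int(expand_frac * (end - start))
        grown.append((max(0, start - pad), min(p, end + pad)))
    grown.sort()
    merged = [grown[0]]
    for start, end in grown[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _mask_to_intervals(
    mask: np.ndarray, min_len: int, max_gap: int
) -> list[tuple[int, int]]:
    idx = np.where(mask)[0]
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    for j in idx[1:]:
        if j - prev - 1 <= max_gap:
            prev = j
        else:
            runs.append((int(start), int(prev) + 1))
            start = prev = j
    runs.append((int(start), int(prev) + 1))
    return [(s, e) for s, e in runs if e - s >= min_len]


def sipls_search(
    intervals: IntervalSet,
    X: np.ndarray,
    y: np.ndarray,
    folds,
    max_n_lv: int = 15,
    min_rel_improvement: float = 0.005,
) -> BandSelectionResult:
    """Greedy forward combination of intervals minimising RMSECV.

    Each candidate combination is scored by its best RMSECV over component
    counts 1..max_n_lv. The interval whose addition lowers RMSECV the most
    is accepted while the relative improvement is at least
    ``min_rel_improvement``; ties break towards the lower start index, so
    the search is deterministic and independent of interval presentation
    order. The first (best single) interval is always accepted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not intervals.intervals:
        raise ValueError("need at least one candidate interval")
    order = np.argsort([s for s, _ in intervals.intervals])
    remaining = [int(i) for i in order]
    selected: list[int] = []
    trajectory: list[tuple[int, float]] = []
    current_rmse = np.inf
    chosen_n_lv = 1
    step = 0
    while remaining:
        best = None  # (rmse, start, interval_pos, n_lv)
        for pos in remaining:
            cols = np.concatenate(
                [intervals.indices(i) for i in selected + [pos]]
            )
            cols = np.unique(cols)
            curve = rmsecv_curve(X[:, cols], y, folds, max_n_lv)
            a = int(np.argmin(curve))
            cand = (float(curve[a]), intervals.intervals[pos][0], pos, a + 1)
            if best is None or cand[:2] < best[:2]:
                best = cand
        rmse, _, pos, n_lv = best
        if selected and (current_rmse - rmse) / current_rmse < min_rel_improvement:
            break
        selected.append(pos)
        remaining.remove(pos)
        current_rmse = rmse
        chosen_n_lv = n_lv
        trajectory.append((step, rmse))
        step += 1
    cols = np.unique(np.concatenate([intervals.indices(i) for i in selected]))
    return BandSelectionResult(
        method="siPLS",
        selected_indices=cols,
        rmsecv_trajectory=trajectory,
        chosen_n_lv=chosen_n_lv,
    )


def cars_retention_schedule(
    p: int, n_iterations: int = 30, decay: float = 0.9, min_vars: int = 30
) -> list[int]:
    """Number of variables retained after each CARS iteration.

    ``r_i = max(round(p * decay**i), min_vars)`` for i = 1..n_iterations —
    a single-rate exponential decay clipped at the retention floor.
    """
    return [
        max(int(round(p * decay**i)), min(min_vars, p))
        for i in range(1, n_iterations + 1)
    ]


def cars_pls(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    n_iterations: int = 30,
    decay: float = 0.9,
    min_vars: int = 30,
    runs_per_iteration: int = 1,
    seed: int = 0,
    max_n_lv: int = 10,
    sample_fraction: float = 0.8,
) -> BandSelectionResult:
    """Competitive Adaptive Reweighted Sampling over single wavelengths.

    Per iteration: fit PLS on a Monte-Carlo subset of ``sample_fraction``
    of the samples restricted to the surviving variables, rank variables
    by |coefficient|, enforce retention of the top ``r_i`` (the decaying
    schedule), then resample among survivors with probability proportional
    to |coefficient| (adaptive reweighted sampling), topping up from the
    ranking if duplicates push the unique count below the schedule floor.
    RMSECV of the surviving set is recorded per iteration and the minimum
    defines the selection. Fully reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 variables")
    if p < min_vars:
        log.warning("cars_pls: p=%d < min_vars=%d, degenerating to full spectrum",
                    p, min_vars)
        curve = rmsecv_curve(X, y, folds, max_n_lv)
        a = int(np.argmin(curve))
        return BandSelectionResult(
            method="CARS",
            selected_indices=np.arange(p),
            rmsecv_trajectory=[(0, float(curve[a]))],
            chosen_n_lv=a + 1,
            seed=seed,
            retention_schedule=[p],
        )
    rng = np.random.default_rng(seed)
    schedule = cars_retention_schedule(p, n_iterations, decay, min_vars)
    survivors = np.arange(p)
    best = None  # (rmse, iteration, indices, n_lv)
    trajectory: list[tuple[int, float]] = []
    n_sub = max(2, int(round(sample_fraction * n)))
    for it, r_i in enumerate(schedule, start=1):
        coef_mag = np.zeros(survivors.size)
        for _ in range(runs_per_iteration):
            sub = rng.choice(n, size=n_sub, replace=False)
            a_max = min(max_n_lv, n_sub - 1, survivors.size)
            model = fit_pls(X[np.ix_(sub, survivors)], y[sub], a_max)
            coef_mag += np.abs(model.coefficients)
        r_i = min(r_i, survivors.size)
        rank = np.argsort(coef_mag)[::-1]
        top = survivors[np.sort(rank[:r_i])]
        top_mag = coef_mag[np.sort(rank[:r_i])]
        # adaptive reweighted sampling among the enforced survivors
        w = top_mag / top_mag.sum() if top_mag.sum() > 0 else None
        draws = rng.choice(top.size, size=r_i, replace=True, p=w)
        kept = np.unique(top[draws])
        if kept.size < min(min_vars, r_i):
            # top up with the highest-ranked variables not drawn
            need = min(min_vars, r_i) - kept.size
            extra = [v for v in top[np.argsort(top_mag)[::-1]] if v not in set(kept)]
            kept = np.sort(np.concatenate([kept, np.array(extra[:need], dtype=int)]))
        survivors = kept
        curve = rmsecv_curve(X[:, survivors], y, folds,
                             min(max_n_lv, survivors.size))
        a = int(np.argmin(curve))
        rmse = float(curve[a])
        trajectory.append((it, rmse))
        if best is None or rmse < best[0]:
            best = (rmse, it, survivors.copy(), a + 1)
    return BandSelectionResult(
        method="CARS",
        selected_indices=best[2],
        rmsecv_trajectory=trajectory,
        chosen_n_lv=best[3],
        seed=seed,
        retention_schedule=schedule,
    )


def apply_band_mask(X: np.ndarray, result: BandSelectionResult) -> np.ndarray:
    """Column subset of X at the selected indices, ascending order."""
    X = np.asarray(X)
    idx = np.sort(np.asarray(result.selected_indices, dtype=int))
    if idx.size and (idx[0] < 0 or idx[-1] >= X.shape[1]):
        raise IndexError(
            f"selected index out of range for {X.shape[1]} columns"
        )
    return X[:, idx]
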