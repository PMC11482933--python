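"""Reproducibility-based false-positive modeling and high-confidence filtering.

For a grid of fold-enrichment cutoffs, the false-positive rate FPR(c) is the
fraction of peaks at or above c in one replicate without any (>= 1 nt)
overlapping peak in the other replicate, averaged over both directions.  The
curve is fitted with an exponential decay plus a linear component,
f(c) = A*exp(-k*c) + m*c + b, and the working cutoff c* is the smallest grid
cutoff with modeled FPR at or below ``max_fpr`` (default 5%).  If the fit
fails, the curve never crosses the threshold, or the linearity assumption on
the upper cutoff range does not hold, c* falls back to the last cutoff where
the linearity assumption held.  High-confidence peaks must reach c* and a
minimum summit depth in the enrichment sample (default 5 reads).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .models import Peak

log = logging.getLogger(__name__)

DEFAULT_MAX_FPR = 0.05
DEFAULT_MIN_DEPTH = 5


class InsufficientPeaks(RuntimeError):
    pass


@dataclass(frozen=True)
class FPRPoint:
    cutoff: float
    fpr: float

    def __post_init__(self):
        if not (0.0 <= self.fpr <= 1.0):
            raise ValueError("fpr must lie in [0,1]")


def default_cutoff_grid(fold_enrichments: np.ndarray, n: int = 40,
                        lo: float = 1.0) -> np.ndarray:
    """Log-spaced cutoffs between ``lo`` and the 99.5th percentile of folds."""
    fe = np.asarray(fold_enrichments, dtype=float)
    hi = float(np.percentile(fe, 99.5)) if len(fe) else lo * 10
    hi = max(hi, lo * 1.01)
    return np.geomspace(lo, hi, n)


def _directional_fpr(rep_a: list[Peak], rep_b: list[Peak], grid: np.ndarray) -> np.ndarray:
    by_ref: dict[str, list[Peak]] = {}
    for q in rep_b:
        by_ref.setdefault(q.ref, []).append(q)
    overlapped = []
    for ref in by_ref:
        by_ref[ref].sort(key=lambda q: q.start)
    for p in rep_a:
        hits = by_ref.get(p.ref, [])
        overlapped.append(any(q.start < p.end and p.start < q.end for q in hits))
    folds = np.array([p.fold_enrichment for p in rep_a])
    overlapped = np.array(overlapped, dtype=bool)
    out = np.full(len(grid), np.nan)
    for i, c in enumerate(grid):
        sel = folds >= c
        if sel.sum() > 0:
            out[i] = 1.0 - overlapped[sel].mean()
    return out


def fpr_curve(peaks_rep1: list[Peak], peaks_rep2: list[Peak],
              cutoff_grid: np.ndarray, symmetrize: bool = True,
              min_peaks: int = 10) -> list[FPRPoint]:
    """Reproducibility FPR over fold-enrichment cutoffs for a replicate pair.

    Raises InsufficientPeaks when fewer than ``min_peaks`` peaks survive the
    smallest cutoff in either replicate (caller should take the fallback path).
    """
    grid = np.asarray(cutoff_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("cutoff grid must be strictly increasing")
    c0 = grid[0]
    n1 = sum(p.fold_enrichment >= c0 for p in peaks_rep1)
    n2 = sum(p.fold_enrichment >= c0 for p in peaks_rep2)
    if min(n1, n2) < min_peaks:
        raise InsufficientPeaks(
            f"insufficient_peaks: {n1}/{n2} peaks above cutoff {c0:g}")
    f12 = _directional_fpr(peaks_rep1, peaks_rep2, grid)
    if symmetrize:
        f21 = _directional_fpr(peaks_rep2, peaks_rep1, grid)
        with np.errstate(invalid="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                fpr = np.nanmean(np.vstack([f12, f21]), axis=0)
    else:
        fpr = f12
    return [FPRPoint(float(c), float(v)) for c, v in zip(grid, fpr) if np.isfinite(v)]


def _model(c, A, k, m, b):
    return A * np.exp(-k * c) + m * c + b


@dataclass
class NoiseModel:
    amplitude: float          # A >= 0
    decay: float              # k > 0
    slope: float              # m
    intercept: float          # b
    rmse: float
    converged: bool
    linearity_ok: bool
    cutoffs: np.ndarray = field(default_factory=lambda: np.array([]))
    linear_ok_from: np.ndarray = field(default_factory=lambda: np.array([]))  # bool per cutoff
    selected_cutoff: float | None = None
    selection_reason: str = ""

    def fpr(self, c) -> np.ndarray:
        """Modeled FPR, clipped to [0, 1]."""
        return np.clip(_model(np.asarray(c, dtype=float),
                              self.amplitude, self.decay, self.slope, self.intercept), 0.0, 1.0)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "amplitude": self.amplitude, "decay": self.decay,
                "slope": self.slope, "intercept": self.intercept,
                "rmse": self.rmse, "converged": self.converged,
                "linearity_ok": self.linearity_ok,
                "selected_cutoff": self.selected_cutoff,
                "selection_reason": self.selection_reason,
                "cutoffs": self.cutoffs.tolist(),
            }, fh, indent=1)


def _linear_ok(c: np.ndarray, y: np.ndarray, rmse_tol: float, slope_tol: float) -> bool:
    if len(c) < 2:
        return False
    coef = np.polyfit(c, y, 1)
    resid = y - np.polyval(coef, c)
    return bool(float(np.sqrt(np.mean(resid ** 2))) <= rmse_tol and coef[0] >= slope_tol)


def fit_noise_model(points: list[FPRPoint], linear_rmse_tol: float = 0.01,
                    linear_slope_tol: float = -0.01,
                    min_tail_points: int = 5) -> NoiseModel:
    """Deterministic nonlinear least-squares fit of A*exp(-k*c) + m*c + b.

    Initialization is fixed (A = max fpr, k = 1, m = 0, b = min fpr) with
    bounds A >= 0, k > 0, so the fit is reproducible for given points.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 FPR points to fit the noise model")
    c = np.array([p.cutoff for p in points], dtype=float)
    y = np.array([p.fpr for p in points], dtype=float)
    p0 = [float(y.max()), 1.0, 0.0, float(y.min())]
    bounds = ([0.0, 1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    converged = True
    try:
        popt, _ = curve_fit(_model, c, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        popt = p0
        converged = False
    resid = y - _model(c, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))

    # linearity of the upper half of the cutoff range (exponential term faded)
    upper = c >= np.median(c)
    linearity_ok = _linear_ok(c[upper], y[upper], linear_rmse_tol, linear_slope_tol)

    # expanding-from-the-top windows for the fallback rule
    ok_from = np.zeros(len(c), dtype=bool)
    for i in range(len(c)):
        if len(c) - i >= min_tail_points:
            ok_from[i] = _linear_ok(c[i:], y[i:], linear_rmse_tol, linear_slope_tol)
    return NoiseModel(
        amplitude=float(popt[0]), decay=float(popt[1]), slope=float(popt[2]),
        intercept=float(popt[3]), rmse=rmse, converged=converged,
        linearity_ok=linearity_ok, cutoffs=c, linear_ok_from=ok_from)


def select_cutoff(model: NoiseModel, max_fpr: float = DEFAULT_MAX_FPR) -> NoiseModel:
    """Choose the working fold-enrichment cutoff c*.

    c* is the smallest grid cutoff whose modeled FPR is <= max_fpr.  When the
    model did not converge, the linearity assumption failed, or no cutoff
    meets the target, c* defaults to the last (largest) cutoff where the
    linearity assumption held; with no valid cutoff at all, c* is the grid
    maximum, flagged "conservative_default".
    """
    c = model.cutoffs
    if len(c) == 0:
        raise ValueError("model carries no cutoff grid")
    if model.converged and model.linearity_ok:
        f = model.fpr(c)
        ok = np.nonzero(f <= max_fpr)[0]
        if len(ok):
            return replace(model, selected_cutoff=float(c[ok[0]]), selection_reason="max_fpr")
    lin = np.nonzero(model.linear_ok_from)[0]
    if len(lin):
        return replace(model, selected_cutoff=float(c[lin[-1]]),
                       selection_reason="linearity_fallback")
    return replace(model, selected_cutoff=float(c[-1]),
                   selection_reason="conservative_default")


def filter_high_confidence(peaks: list[Peak], cutoff: float,
                           min_depth: int = DEFAULT_MIN_DEPTH) -> list[Peak]:
    """Flag peaks meeting the fold cutoff and the summit-depth floor.

    Peaks are flagged, not deleted: high_confidence = fold_enrichment >= c*
    AND enrichment summit depth >= min_depth.
    """
    return [replace(p, high_confidence=(p.fold_enrichment >= cutoff and p.depth >= min_depth))
            for p in peaks]
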