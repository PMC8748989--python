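"""Chromatin-accessibility QTL detection within a region of linkage disequilibrium.

Two complementary detectors operate on the normalised intensity matrix
``d_ij`` (windows ``i = 1..I`` by samples ``j = 1..J``) and the lead-variant
minor-allele dosage ``g_j``:

1. a **correlation scan** — per-window Pearson correlation of ``d_i.`` with
   ``g``, two-sided p from the t transform, Benjamini-Hochberg q across the
   region's windows;

2. **caQTLseg** — a penalized segmentation that partitions the window grid
   into alternating *allele-independent* segments (per-window fit
   ``f_i = mean_j d_ij``, residual weight 1) and *allele-dependent* segments
   (per-window linear fit ``f_ij = a_i + g_j * b_i``, residual weight
   ``lambda_1 > 1``), minimising

   ``sum_s ( lambda_2 + (1/J) * sum_j sum_{i in s} lambda^(s) * (d_ij - f_ij)^2 )``

   over all partitionings.  ``lambda_1`` taxes the extra flexibility of the
   allele-dependent model; ``lambda_2`` penalises each segment and controls
   over- versus under-segmentation.  Because both models are fit per window,
   the residual term is additive over windows and the optimum is found by an
   exact two-state dynamic program with a segment-opening penalty.

A permutation statistic ``pi0 = min(n0/n1, 1)`` estimates the fraction of
allele-dependent signal attributable to noise: ``n1`` is the number of base
pairs called allele-dependent with the true genotypes, ``n0`` the average
called under random genotype permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .atac import DEFAULT_STEP, DEFAULT_WINDOW_LENGTH, IntensityMatrix

__all__ = [
    "DEFAULT_LAMBDA1",
    "DEFAULT_LAMBDA2",
    "DEFAULT_LAMBDA1_GRID",
    "DEFAULT_LAMBDA2_GRID",
    "Segment",
    "Segmentation",
    "Pi0Result",
    "CorrelationScanner",
    "CaQTLSegmenter",
    "scan_correlation",
    "fit_segment",
    "segment_caqtl",
    "estimate_pi0",
    "dependent_bp",
    "lambda_sweep",
    "sweep_stability",
]

DEFAULT_LAMBDA1 = 1.075
DEFAULT_LAMBDA2 = 10.0**-1.5
# robustness-sweep grids spanning lambda1 1.025..1.20 and lambda2 1e-1..1e-5
DEFAULT_LAMBDA1_GRID = (1.025, 1.05, 1.075, 1.1, 1.15, 1.2)
DEFAULT_LAMBDA2_GRID = (1e-1, 1e-2, 1e-3, 1e-4, 1e-5)

INDEPENDENT, DEPENDENT = 0, 1
_LABEL_NAMES = {INDEPENDENT: "allele-independent", DEPENDENT: "allele-dependent"}


# ---------------------------------------------------------------------------
# correlation scan


def _as_matrix(d) -> np.ndarray:
    if isinstance(d, IntensityMatrix):
        return d.values
    return np.asarray(d, dtype=float)


def _pearson_scan(D: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window Pearson r of D rows with g, plus two-sided t-test p."""
    I, J = D.shape
    if J < 3:
        raise ValueError("need at least 3 samples for the correlation scan")
    gc = g - g.mean()
    g_ss = float(gc @ gc)
    Dc = D - D.mean(axis=1, keepdims=True)
    d_ss = np.einsum("ij,ij->i", Dc, Dc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Dc @ gc) / np.sqrt(d_ss * g_ss)
    if g_ss == 0:
        r = np.full(I, np.nan)
    r = np.clip(r, -1.0, 1.0, out=r) if not np.all(np.isnan(r)) else r
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((J - 2) / (1.0 - r**2))
    p = np.where(np.isnan(r), np.nan, 2.0 * stats.t.sf(np.abs(t), J - 2))
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[np.isnan(r)] = np.nan
    return r, p


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg over the finite entries; NaN passes through."""
    q = np.full_like(p, np.nan, dtype=float)
    valid = np.isfinite(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


class CorrelationScanner(BaseEstimator):
    """Windowed Pearson-correlation caQTL scan.

    ``fit(X, y)`` takes ``X`` of shape ``(n_samples, n_windows)`` (sklearn
    orientation — the transpose of the intensity matrix) and genotype dosages
    ``y``.  Fitted attributes: ``r_``, ``p_``, ``q_`` per window and
    ``valid_`` (False where the window intensity or the genotype is constant;
    such windows are excluded from the FDR correction).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (n_samples, n_windows)")
        if y.shape != (X.shape[0],):
            raise ValueError("y must hold one genotype dosage per sample (row of X)")
        r, p = _pearson_scan(X.T, y)
        self.r_ = r
        self.p_ = p
        self.q_ = _bh(p)
        self.valid_ = np.isfinite(r)
        self.n_windows_ = X.shape[1]
        return self


def scan_correlation(d, g) -> pd.DataFrame:
    """Scan windows for correlation with genotype dosage.

    ``d`` is an :class:`~allelescan.atac.IntensityMatrix` or an array of shape
    ``(n_windows, n_samples)``.  Returns a frame with per-window ``r``,
    two-sided ``p`` and BH ``q`` (window coordinates included when ``d``
    carries a grid).
    """
    D = _as_matrix(d)
    scanner = CorrelationScanner().fit(D.T, np.asarray(g, dtype=float))
    out = pd.DataFrame({"r": scanner.r_, "p": scanner.p_, "q": scanner.q_})
    if isinstance(d, IntensityMatrix):
        out.insert(0, "window_start", d.grid.starts)
        out.insert(1, "window_end", d.grid.ends)
    return out


# ---------------------------------------------------------------------------
# caQTLseg


def _window_fits(D: np.ndarray, g: np.ndarray):
    """Per-window model fits and residual costs for both segment labels.

    Returns ``(c_ind, c_dep, mean_i, a_dep, b_dep)`` where costs are the
    *unweighted* per-window residual sums ``(1/J) * sum_j (d - f)^2`` (the
    ``lambda_1`` weight is applied by the caller) and the fit parameters are
    the per-window independent mean and the dependent OLS intercept/slope.
    """
    I, J = D.shape
    mean_i = D.mean(axis=1)
    resid_ind = D - mean_i[:, None]
    c_ind = np.einsum("ij,ij->i", resid_ind, resid_ind) / J

    gc = g - g.mean()
    g_ss = float(gc @ gc)
    if g_ss == 0:
        # degenerate: constant genotype — slope forced to 0, fit is the mean
        b_dep = np.zeros(I)
    else:
        b_dep = (D @ gc) / g_ss
    a_dep = mean_i - b_dep * g.mean()
    resid_dep = D - a_dep[:, None] - np.outer(b_dep, g)
    c_dep = np.einsum("ij,ij->i", resid_dep, resid_dep) / J
    return c_ind, c_dep, mean_i, a_dep, b_dep


def fit_segment(d_segment, g, label: str, lambda1: float = DEFAULT_LAMBDA1):
    """Fit one candidate segment under the given model label.

    ``d_segment`` has shape ``(n_windows_in_segment, n_samples)``.  Returns
    ``(fitted, cost)`` with ``fitted`` of the same shape and ``cost`` the
    weighted residual contribution ``(lambda^(s)/J) * sum_ij (d - f)^2``,
    where ``lambda^(s)`` is ``lambda1`` for allele-dependent segments and 1
    for allele-independent ones.
    """
    D = np.asarray(d_segment, dtype=float)
    if D.ndim != 2 or D.shape[0] < 1:
        raise ValueError("segment must contain at least one window")
    g = np.asarray(g, dtype=float)
    c_ind, c_dep, mean_i, a_dep, b_dep = _window_fits(D, g)
    if label in ("independent", "allele-independent"):
        fitted = np.broadcast_to(mean_i[:, None], D.shape).copy()
        return fitted, float(c_ind.sum())
    if label in ("dependent", "allele-dependent"):
        if lambda1 <= 1:
            raise ValueError("lambda1 must be > 1")
        fitted = a_dep[:, None] + np.outer(b_dep, g)
        return fitted, float(lambda1 * c_dep.sum())
    raise ValueError(f"unknown segment label {label!r}")


@dataclass(frozen=True)
class Segment:
    """One maximal run of same-label windows (indices inclusive)."""

    i0: int
    i1: int
    label: str
    cost: float  # lambda2 + weighted residual cost of the segment


@dataclass
class Segmentation:
    """Optimal alternating partition of the window grid."""

    labels: np.ndarray  # (I,) int, 0 = allele-independent, 1 = allele-dependent
    segments: list[Segment]
    total_cost: float
    intercept: np.ndarray  # per-window fitted a_i (mean for independent windows)
    slope: np.ndarray  # per-window fitted b_i (0 for independent windows)
    lambda1: float
    lambda2: float
    n_windows: int
    n_samples: int

    @property
    def dependent_mask(self) -> np.ndarray:
        return self.labels == DEPENDENT

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _dp_labels(c_ind: np.ndarray, c_dep: np.ndarray, lambda2: float) -> np.ndarray:
    """Exact minimum-cost alternating labeling.

    Two-state dynamic program over windows; opening a segment (the first
    window, or any label change) costs ``lambda2`` on top of the per-window
    model cost.  Ties are broken toward fewer segments, then toward the
    allele-independent label.
    """
    I = c_ind.shape[0]
    win_cost = np.stack([c_ind, c_dep])  # (2, I)
    cost = np.empty((I, 2))
    nseg = np.empty((I, 2), dtype=np.int64)
    prev = np.empty((I, 2), dtype=np.int8)
    cost[0] = lambda2 + win_cost[:, 0]
    nseg[0] = 1
    prev[0] = -1
    for i in range(1, I):
        for s in (INDEPENDENT, DEPENDENT):
            o = 1 - s
            stay = (cost[i - 1, s], nseg[i - 1, s])
            switch = (cost[i - 1, o] + lambda2, nseg[i - 1, o] + 1)
            if switch < stay:  # lexicographic: cost first, then segment count
                cost[i, s], nseg[i, s] = switch
                prev[i, s] = o
            else:
                cost[i, s], nseg[i, s] = stay
                prev[i, s] = s
            cost[i, s] += win_cost[s, i]
    # final state: min (cost, nseg), tie toward independent
    final = min(
        (INDEPENDENT, DEPENDENT),
        key=lambda s: (cost[I - 1, s], nseg[I - 1, s], s),
    )
    labels = np.empty(I, dtype=np.int64)
    s = final
    for i in range(I - 1, -1, -1):
        labels[i] = s
        s = prev[i, s] if i > 0 else s
    return labels


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal (i0, i1 inclusive, label) runs."""
    runs = []
    i0 = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i0]:
            runs.append((i0, i - 1, int(labels[i0])))
            i0 = i
    return runs


def _segment_core(D: np.ndarray, g: np.ndarray, lambda1: float, lambda2: float) -> Segmentation:
    if lambda1 <= 1:
        raise ValueError("lambda1 must be > 1")
    if lambda2 <= 0:
        raise ValueError("lambda2 must be > 0")
    I, J = D.shape
    if I < 1:
        raise ValueError("need at least one window")
    c_ind, c_dep_raw, mean_i, a_dep, b_dep = _window_fits(D, g)
    c_dep = lambda1 * c_dep_raw
    labels = _dp_labels(c_ind, c_dep, lambda2)

    segments = []
    total = 0.0
    for i0, i1, lab in _runs(labels):
        win = c_dep[i0 : i1 + 1] if lab == DEPENDENT else c_ind[i0 : i1 + 1]
        seg_cost = lambda2 + float(win.sum())
        segments.append(Segment(i0, i1, _LABEL_NAMES[lab], seg_cost))
        total += seg_cost

    dep = labels == DEPENDENT
    intercept = np.where(dep, a_dep, mean_i)
    slope = np.where(dep, b_dep, 0.0)
    return Segmentation(
        labels=labels,
        segments=segments,
        total_cost=total,
        intercept=intercept,
        slope=slope,
        lambda1=lambda1,
        lambda2=lambda2,
        n_windows=I,
        n_samples=J,
    )


class CaQTLSegmenter(BaseEstimator):
    """Penalized alternating-model segmentation of an LD region (caQTLseg).

    Parameters
    ----------
    lambda1 : float, default 1.075
        Residual weight (> 1) applied inside allele-dependent segments;
        larger values make allele-dependent calls more conservative.
    lambda2 : float, default 10**-1.5
        Per-segment penalty; larger values yield fewer segments.
    window_length, step : int
        Window geometry of the intensity grid, used only to convert window
        calls to covered base pairs (for ``pi0``).

    ``fit(X, y)`` takes ``X`` of shape ``(n_samples, n_windows)`` (transpose
    of the intensity matrix) and dosages ``y``; fitted attributes are
    ``labels_`` (0 = allele-independent, 1 = allele-dependent per window),
    ``segments_``, ``cost_``, ``intercept_``, ``slope_`` and
    ``segmentation_``.  ``predict(X)`` returns the per-window labels.
    """

    def __init__(
        self,
        lambda1: float = DEFAULT_LAMBDA1,
        lambda2: float = DEFAULT_LAMBDA2,
        window_length: int = DEFAULT_WINDOW_LENGTH,
        step: int = DEFAULT_STEP,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.window_length = window_length
        self.step = step

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (n_samples, n_windows)")
        if y.shape != (X.shape[0],):
            raise ValueError("y must hold one genotype dosage per sample (row of X)")
        seg = _segment_core(X.T, y, self.lambda1, self.lambda2)
        self.segmentation_ = seg
        self.labels_ = seg.labels
        self.segments_ = seg.segments
        self.cost_ = seg.total_cost
        self.intercept_ = seg.intercept
        self.slope_ = seg.slope
        self.n_windows_ = seg.n_windows
        return self

    def predict(self, X=None):
        return self.labels_

    def estimate_pi0(self, X, y, n_permutations: int = 500, random_state=None) -> "Pi0Result":
        X = np.asarray(X, dtype=float)
        return estimate_pi0(
            X.T,
            y,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            window_length=self.window_length,
            step=self.step,
            n_permutations=n_permutations,
            seed=random_state,
        )


def segment_caqtl(
    d,
    g,
    lambda1: float = DEFAULT_LAMBDA1,
    lambda2: float = DEFAULT_LAMBDA2,
) -> Segmentation:
    """Segment an intensity matrix (``(n_windows, n_samples)`` orientation)."""
    return _segment_core(_as_matrix(d), np.asarray(g, dtype=float), lambda1, lambda2)


# ---------------------------------------------------------------------------
# pi0 noise estimate


def dependent_bp(
    dependent_mask: np.ndarray,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int = DEFAULT_STEP,
) -> int:
    """Base pairs covered by the union of allele-dependent windows.

    Window ``i`` covers ``[i*step, i*step + window_length)``; overlapping
    windows within one run are merged before counting.
    """
    total = 0
    for i0, i1, lab in _runs(np.asarray(dependent_mask, dtype=np.int64)):
        if lab:
            total += (i1 - i0) * step + window_length
    return total


@dataclass(frozen=True)
class Pi0Result:
    """Permutation noise estimate for a segmentation call.

    ``n1`` — allele-dependent bp with true genotypes; ``n0`` — mean
    allele-dependent bp under random genotype permutations;
    ``pi0 = min(n0/n1, 1)`` (defined as 1 when ``n1 == 0``).
    """

    n0: float
    n1: int
    pi0: float
    n_permutations: int
    seed: int | None
    lambda1: float
    lambda2: float


def estimate_pi0(
    d,
    g,
    lambda1: float = DEFAULT_LAMBDA1,
    lambda2: float = DEFAULT_LAMBDA2,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int = DEFAULT_STEP,
    n_permutations: int = 500,
    seed=None,
) -> Pi0Result:
    """Estimate the noise fraction pi0 = min(n0/n1, 1) by genotype permutation."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    D = _as_matrix(d)
    g = np.asarray(g, dtype=float)
    seg = _segment_core(D, g, lambda1, lambda2)
    n1 = dependent_bp(seg.dependent_mask, window_length, step)

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    null_bp = np.empty(n_permutations)
    for k in range(n_permutations):
        g_perm = g[rng.permutation(len(g))]
        seg_perm = _segment_core(D, g_perm, lambda1, lambda2)
        null_bp[k] = dependent_bp(seg_perm.dependent_mask, window_length, step)
    n0 = float(null_bp.mean())
    pi0 = 1.0 if n1 == 0 else min(n0 / n1, 1.0)
    return Pi0Result(
        n0=n0,
        n1=n1,
        pi0=pi0,
        n_permutations=n_permutations,
        seed=seed if isinstance(seed, (int, np.integer)) or seed is None else None,
        lambda1=lambda1,
        lambda2=lambda2,
    )


# ---------------------------------------------------------------------------
# robustness sweep


def lambda_sweep(
    d,
    g,
    lambda1_grid=DEFAULT_LAMBDA1_GRID,
    lambda2_grid=DEFAULT_LAMBDA2_GRID,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int = DEFAULT_STEP,
    n_permutations: int = 0,
    seed=None,
) -> pd.DataFrame:
    """Segment at every (lambda1, lambda2) grid point.

    Returns one row per grid point with the segment count, the
    allele-dependent window indices and covered bp, and (when
    ``n_permutations > 0``) the pi0 noise estimate.
    """
    D = _as_matrix(d)
    g = np.asarray(g, dtype=float)
    rows = []
    for l1 in lambda1_grid:
        for l2 in lambda2_grid:
            seg = _segment_core(D, g, l1, l2)
            row = {
                "lambda1": l1,
                "lambda2": l2,
                "n_segments": seg.n_segments,
                "n_dependent_windows": int(seg.dependent_mask.sum()),
                "dependent_bp": dependent_bp(seg.dependent_mask, window_length, step),
                "dependent_windows": tuple(np.flatnonzero(seg.dependent_mask)),
                "total_cost": seg.total_cost,
            }
            if n_permutations > 0:
                row["pi0"] = estimate_pi0(
                    D, g, l1, l2, window_length, step, n_permutations, seed
                ).pi0
            rows.append(row)
    return pd.DataFrame(rows)


def _coverage(windows: tuple[int, ...], n_windows: int, window_length: int, step: int) -> np.ndarray:
    cov = np.zeros((n_windows - 1) * step + window_length, dtype=bool)
    for i in windows:
        cov[i * step : i * step + window_length] = True
    return cov


def sweep_stability(
    sweep: pd.DataFrame,
    n_windows: int,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int = DEFAULT_STEP,
) -> float:
    """Minimum pairwise Jaccard overlap of allele-dependent bp across a sweep.

    Two empty call sets count as perfectly concordant; empty versus non-empty
    counts as 0.
    """
    covers = [
        _coverage(w, n_windows, window_length, step) for w in sweep["dependent_windows"]
    ]
    worst = 1.0
    for a in range(len(covers)):
        for b in range(a + 1, len(covers)):
            union = np.logical_or(covers[a], covers[b]).sum()
            if union == 0:
                j = 1.0
            else:
                j = np.logical_and(covers[a], covers[b]).sum() / union
            worst = min(worst, j)
    return worst
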