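"""Thresholding, Cohen's kappa, MESS, Levins niche breadth, and
suitable-area / habitat-change accounting."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSet",
    "KappaScore",
    "thresholds",
    "kappa",
    "binary_map",
    "suitable_area",
    "pct_change",
    "niche_breadth",
    "mess",
    "mess_raster",
]


@dataclass
class ThresholdSet:
    mtp: float
    eq_ss: float
    max_ss: float
    chosen: str = "eq_ss"
    degenerate: bool = False

    @property
    def chosen_value(self) -> float:
        return getattr(self, self.chosen)


@dataclass
class KappaScore:
    kappa: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN


def _sens_spec(tau: float, presence: np.ndarray, background: np.ndarray) -> tuple[float, float]:
    sens = float(np.mean(presence >= tau))
    spec = float(np.mean(background < tau))
    return sens, spec


def thresholds(presence_scores: np.ndarray, background_scores: np.ndarray) -> ThresholdSet:
    """The three candidate binarization thresholds.

    ``mtp`` is the minimum training-presence score.  ``eq_ss`` minimizes
    |sensitivity - specificity| and ``max_ss`` maximizes their sum
    (background treated as pseudo-absence), both scanned over midpoints of
    consecutive distinct observed scores plus the extremes, ties resolved
    to the lower threshold.
    """
    presence = np.asarray(presence_scores, dtype=float)
    background = np.asarray(background_scores, dtype=float)
    if presence.size == 0 or background.size == 0:
        raise ValueError("score sets must be nonempty")
    mtp = float(presence.min())
    all_scores = np.unique(np.concatenate([presence, background]))
    candidates = [all_scores[0]]
    candidates.extend(0.5 * (all_scores[:-1] + all_scores[1:]))
    candidates.append(all_scores[-1] + np.finfo(float).eps)
    degenerate = all_scores.size == 1

    best_eq, best_eq_gap = candidates[0], math.inf
    best_max, best_max_sum = candidates[0], -math.inf
    for tau in candidates:
        sens, spec = _sens_spec(tau, presence, background)
        gap = abs(sens - spec)
        if gap < best_eq_gap - 1e-12:
            best_eq, best_eq_gap = tau, gap
        if sens + spec > best_max_sum + 1e-12:
            best_max, best_max_sum = tau, sens + spec
    return ThresholdSet(mtp=mtp, eq_ss=float(best_eq), max_ss=float(best_max),
                        degenerate=degenerate)


def kappa(tp: int, fp: int, fn: int, tn: int) -> KappaScore:
    """Cohen's kappa from a confusion matrix (TP, FP, FN, TN)."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    k = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaScore(kappa=k, confusion=(tp, fp, fn, tn))


def binary_map(suitability: np.ndarray, tau: float) -> np.ndarray:
    """1 where suitability >= tau, 0 below, NaN propagated."""
    suit = np.asarray(suitability, dtype=float)
    out = np.where(suit >= tau, 1.0, 0.0)
    out[~np.isfinite(suit)] = np.nan
    return out


def suitable_area(bm: np.ndarray, areas: np.ndarray) -> float:
    """km² summed over predicted-present cells."""
    bm = np.asarray(bm, dtype=float)
    return float(np.nansum(np.where(bm == 1.0, areas, 0.0)))


def pct_change(a_cur: float, a_fut: float) -> int:
    """Integer percent change, rounded half away from zero."""
    if a_cur <= 0:
        raise ValueError("current area must be positive")
    x = 100.0 * (a_fut - a_cur) / a_cur
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def niche_breadth(suitability: np.ndarray) -> float:
    """Levins niche breadth of a suitability raster, standardized to [0, 1].

    With p_i = s_i / sum(s) over the n valid cells,
    B = (1 / sum(p_i^2) - 1) / (n - 1): 1 for a uniform (generalist)
    surface, 0 when a single cell holds all suitability.
    """
    s = np.asarray(suitability, dtype=float).ravel()
    s = s[np.isfinite(s)]
    total = s.sum()
    if s.size == 0 or total <= 0:
        raise ValueError("niche breadth undefined: no positive suitability")
    if s.size == 1:
        return 0.0
    p = s / total
    return float((1.0 / np.sum(p * p) - 1.0) / (s.size - 1))


def _similarity(p: float, ref: np.ndarray) -> float:
    vmin, vmax = ref.min(), ref.max()
    if vmax == vmin:
        return 0.0 if p == vmin else -np.inf
    f = 100.0 * np.count_nonzero(ref < p) / ref.size
    if f == 0.0:
        return 100.0 * (p - vmin) / (vmax - vmin)
    if f <= 50.0:
        return 2.0 * f
    if f < 100.0:
        return 2.0 * (100.0 - f)
    return 100.0 * (vmax - p) / (vmax - vmin)


def mess(point_env: pd.Series | dict, reference: pd.DataFrame) -> tuple[float, dict[str, float]]:
    """Multivariate environmental similarity of one point to a reference
    table; returns (MESS, per-variable similarities).  MESS is the minimum
    similarity, negative iff some variable falls outside the reference
    range."""
    sims = {}
    for var in reference.columns:
        ref = reference[var].to_numpy(dtype=float)
        ref = ref[np.isfinite(ref)]
        sims[var] = _similarity(float(point_env[var]), ref)
    return min(sims.values()), sims


def mess_raster(stack, reference: pd.DataFrame, names=None) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Raster-wise MESS of a stack against reference environments."""
    names = list(reference.columns) if names is None else list(names)
    valid = stack.valid_mask(names)
    per_var: dict[str, np.ndarray] = {}
    for var in names:
        ref = reference[var].to_numpy(dtype=float)
        ref = ref[np.isfinite(ref)]
        vmin, vmax = ref.min(), ref.max()
        vals = stack[var][valid]
        sim = np.empty(vals.shape)
        if vmax == vmin:
            sim = np.where(vals == vmin, 0.0, -np.inf)
        else:
            ref_sorted = np.sort(ref)
            f = 100.0 * np.searchsorted(ref_sorted, vals, side="left") / ref.size
            sim = np.where(
                f == 0.0, 100.0 * (vals - vmin) / (vmax - vmin),
                np.where(
                    f <= 50.0, 2.0 * f,
                    np.where(f < 100.0, 2.0 * (100.0 - f),
                             100.0 * (vmax - vals) / (vmax - vmin)),
                ),
            )
        layer = np.full(stack.grid.shape, np.nan)
        layer[valid] = sim
        per_var[var] = layer
    out = np.full(stack.grid.shape, np.nan)
    out[valid] = np.min(np.stack([per_var[v][valid] for v in names]), axis=0)
    return out, per_var
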