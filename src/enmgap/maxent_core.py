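"""Presence-background maximum-entropy model, from scratch.

The model is the L1-penalized Gibbs formulation: with features f(x) and
linear predictor eta(x) = beta . f(x), the fit maximizes

    (1/m) sum_presence eta(x)  -  log sum_background exp(eta(x))
        -  sum_j lambda_j |beta_j|

by proximal-gradient (FISTA) iterations.  The raw output is
q(x) = exp(eta(x)) / sum_background exp(eta), and the logistic output is
s(x) = q(x) e^H / (1 + q(x) e^H) with H the entropy of the normalized
background distribution, so the no-signal model (all beta = 0) scores 0.5
everywhere.

Per-feature penalties follow the Maxent defaults:
lambda_j = rm * c(class, m) * sd_j / sqrt(m), with c for linear/quadratic
features interpolated on ln(m) through (10, 1.0), (30, 0.2), (100, 0.05)
and c = 0.5 for hinges; sd_j is the feature's background standard
deviation after min-max rescaling to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import rankdata

from .geodata_io import ClimateStack

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "ModelConfig",
    "FeatureMapper",
    "MaxentFit",
    "TuningError",
    "DegenerateFitError",
    "SampleSizeError",
    "build_features",
    "fit_penalized",
    "logistic_map",
    "aicc",
    "tune",
    "replicate_fit",
    "auc",
    "jackknife_importance",
    "permutation_importance",
    "sample_background",
    "DEFAULT_FC_GRID",
    "DEFAULT_RM_GRID",
]

DEFAULT_FC_GRID = ("L", "Q", "H", "LQ", "LH", "QH", "LQH")
DEFAULT_RM_GRID = tuple(np.arange(1.0, 5.01, 0.5))


class TuningError(RuntimeError):
    pass


class DegenerateFitError(RuntimeError):
    pass


class SampleSizeError(ValueError):
    pass


class ProjectionError(KeyError):
    pass


@dataclass(frozen=True)
class FeatureSpec:
    classes: tuple[str, ...] = ("L", "Q", "H")
    hinge_knots: int = 20

    def __post_init__(self) -> None:
        cls = tuple(dict.fromkeys(c.upper() for c in self.classes))
        if not cls or not set(cls) <= {"L", "Q", "H"}:
            raise ValueError("feature classes must be a nonempty subset of {L, Q, H}")
        if "H" in cls and self.hinge_knots < 2:
            raise ValueError("hinge features need at least 2 knots")
        object.__setattr__(self, "classes", cls)

    @property
    def label(self) -> str:
        return "".join(c for c in ("L", "Q", "H") if c in self.classes)

    @classmethod
    def from_label(cls, label: str, hinge_knots: int = 20) -> "FeatureSpec":
        return cls(classes=tuple(label.upper()), hinge_knots=hinge_knots)


@dataclass(frozen=True)
class ModelConfig:
    fc: FeatureSpec = FeatureSpec()
    rm: float = 1.0
    n_background: int = 10_000
    n_replicates: int = 20
    train_fraction: float = 0.70
    max_iterations: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rm <= 0:
            raise ValueError("rm must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


class FeatureMapper:
    """Feature expansion fitted on the background sample.

    Linear features are background z-scores, quadratic features squared
    z-scores, hinge features forward/reverse pieces at ``hinge_knots``
    evenly spaced knots between background min and max.  All columns are
    then min-max rescaled to [0, 1] over the background.  Features constant
    on the background are dropped (and logged).
    """

    def __init__(self, background: pd.DataFrame, spec: FeatureSpec):
        self.spec = spec
        self.variables = list(background.columns)
        bg = background.to_numpy(dtype=float)
        self.mean = bg.mean(axis=0)
        self.sd = bg.std(axis=0)
        self.vmin = bg.min(axis=0)
        self.vmax = bg.max(axis=0)
        self.dropped: list[str] = []

        descriptors: list[tuple[int, str, float]] = []  # (var idx, kind, knot)
        for j, var in enumerate(self.variables):
            constant = self.vmax[j] <= self.vmin[j]
            if "L" in spec.classes:
                if constant:
                    self.dropped.append(f"{var}:linear")
                else:
                    descriptors.append((j, "linear", 0.0))
            if "Q" in spec.classes:
                if constant:
                    self.dropped.append(f"{var}:quadratic")
                else:
                    descriptors.append((j, "quadratic", 0.0))
            if "H" in spec.classes:
                if constant:
                    self.dropped.append(f"{var}:hinge")
                    continue
                knots = np.linspace(self.vmin[j], self.vmax[j], spec.hinge_knots)
                for k in knots[:-1]:  # forward hinge undefined at knot == max
                    descriptors.append((j, "hinge_fwd", float(k)))
                for k in knots[1:]:  # reverse hinge undefined at knot == min
                    descriptors.append((j, "hinge_rev", float(k)))
        if self.dropped:
            logger.info("dropped constant-variable features: %s", ", ".join(self.dropped))
        self.descriptors = descriptors

        raw = self._raw_features(bg)
        self.fmin = raw.min(axis=0)
        self.fmax = raw.max(axis=0)
        span = self.fmax - self.fmin
        keep = span > 0
        if not keep.all():
            self.descriptors = [d for d, k in zip(self.descriptors, keep) if k]
            self.fmin, self.fmax = self.fmin[keep], self.fmax[keep]
        self._span = self.fmax - self.fmin
        scaled = self.transform(background)
        self.feature_sd = scaled.std(axis=0)
        self.feature_class = np.array(
            ["H" if d[1].startswith("hinge") else ("Q" if d[1] == "quadratic" else "L")
             for d in self.descriptors]
        )

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def feature_names(self) -> list[str]:
        out = []
        for j, kind, knot in self.descriptors:
            var = self.variables[j]
            out.append(var if kind == "linear" else
                       f"{var}^2" if kind == "quadratic" else f"{var}:{kind}@{knot:g}")
        return out

    def _raw_features(self, env: np.ndarray) -> np.ndarray:
        cols = []
        for j, kind, knot in self.descriptors:
            x = env[:, j]
            if kind == "linear":
                cols.append((x - self.mean[j]) / self.sd[j])
            elif kind == "quadratic":
                cols.append(((x - self.mean[j]) / self.sd[j]) ** 2)
            elif kind == "hinge_fwd":
                cols.append(np.maximum(0.0, (x - knot) / (self.vmax[j] - knot)))
            else:  # hinge_rev
                cols.append(np.maximum(0.0, (knot - x) / (knot - self.vmin[j])))
        if not cols:
            return np.empty((env.shape[0], 0))
        return np.column_stack(cols)

    def transform(self, env: pd.DataFrame, rescale: bool = True) -> np.ndarray:
        arr = env[self.variables].to_numpy(dtype=float)
        raw = self._raw_features(arr)
        if not rescale:
            return raw
        return (raw - self.fmin) / self._span

    def penalties(self, rm: float, m: int) -> np.ndarray:
        c = np.where(
            self.feature_class == "H",
            0.5,
            np.interp(np.log(m), np.log([10.0, 30.0, 100.0]), [1.0, 0.2, 0.05]),
        )
        return rm * c * self.feature_sd / np.sqrt(m)


def build_features(env: pd.DataFrame, background: pd.DataFrame, spec: FeatureSpec,
                   rescale: bool = True) -> tuple[np.ndarray, FeatureMapper]:
    """Design matrix for ``env`` using background-fitted standardization."""
    mapper = FeatureMapper(background, spec)
    return mapper.transform(env, rescale=rescale), mapper


@dataclass
class MaxentFit:
    beta: np.ndarray
    lambdas: np.ndarray
    mapper: FeatureMapper
    rm: float
    log_normalizer: float
    entropy: float
    calib_range: dict[str, tuple[float, float]]
    converged: bool
    n_iter: int
    objective: float

    @property
    def fc_label(self) -> str:
        return self.mapper.spec.label

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.beta) > 1e-8))

    def _clamped(self, env: pd.DataFrame, clamp: bool) -> pd.DataFrame:
        missing = [v for v in self.mapper.variables if v not in env.columns]
        if missing:
            raise ProjectionError(f"missing model variables: {missing}")
        env = env[self.mapper.variables]
        if not clamp:
            return env
        out = env.copy()
        for var in self.mapper.variables:
            lo, hi = self.calib_range[var]
            out[var] = out[var].clip(lo, hi)
        return out

    def eta(self, env: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        X = self.mapper.transform(self._clamped(env, clamp))
        return X @ self.beta

    def raw(self, env: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        return np.exp(self.eta(env, clamp) - self.log_normalizer)

    def logistic(self, env: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        # q e^H / (1 + q e^H), computed in log space for stability
        z = self.eta(env, clamp) - self.log_normalizer + self.entropy
        return expit(z)


def _fista(Xp: np.ndarray, Xb: np.ndarray, lambdas: np.ndarray,
           max_iter: int, tol: float) -> tuple[np.ndarray, bool, int, float]:
    """Minimize -mean(Xp b) + logsumexp(Xb b) + lambdas.|b| by FISTA with
    backtracking line search."""
    pbar = Xp.mean(axis=0)

    def smooth(beta: np.ndarray) -> float:
        return float(-pbar @ beta + logsumexp(Xb @ beta))

    def grad(beta: np.ndarray) -> np.ndarray:
        eta = Xb @ beta
        q = np.exp(eta - logsumexp(eta))
        return -pbar + Xb.T @ q

    def total(beta: np.ndarray) -> float:
        return smooth(beta) + float(lambdas @ np.abs(beta))

    beta = np.zeros(Xp.shape[1])
    y = beta.copy()
    t = 1.0
    L = 1.0
    f_prev = total(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_y = smooth(y)
        grad_y = grad(y)
        while True:
            cand = y - grad_y / L
            cand = np.sign(cand) * np.maximum(np.abs(cand) - lambdas / L, 0.0)
            diff = cand - y
            if smooth(cand) <= g_y + grad_y @ diff + 0.5 * L * diff @ diff + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        beta_new = cand
        f_new = total(beta_new)
        if f_new > f_prev:  # adaptive restart: drop momentum
            y = beta_new.copy()
            t = 1.0
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            y = beta_new + ((t - 1.0) / t_new) * (beta_new - beta)
            t = t_new
        beta = beta_new
        L = max(L / 2.0, 1e-6)  # allow the step to grow again
        if abs(f_prev - f_new) <= tol * (abs(f_prev) + 1.0):
            converged = True
            f_prev = f_new
            break
        f_prev = f_new
    return beta, converged, it, f_prev


def fit_penalized(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    rm: float = 1.0,
    spec: FeatureSpec | None = None,
    max_iterations: int = 5000,
    tol: float = 1e-9,
) -> MaxentFit:
    """Fit the penalized maximum-entropy model.

    ``presence_env`` and ``background_env`` are raw environment tables with
    one column per model variable; standardization and feature expansion
    are fitted on the background.
    """
    if len(presence_env) < 2:
        raise SampleSizeError("need at least 2 presences")
    spec = spec or FeatureSpec()
    mapper = FeatureMapper(background_env, spec)
    if mapper.n_features == 0:
        raise DegenerateFitError("no varying features available")
    Xp = mapper.transform(presence_env)
    Xb = mapper.transform(background_env)
    lambdas = mapper.penalties(rm, len(presence_env))
    beta, converged, n_iter, obj = _fista(Xp, Xb, lambdas, max_iterations, tol)
    if not converged:
        logger.warning("iteration cap (%d) hit before convergence", max_iterations)
    eta_b = Xb @ beta
    logZ = float(logsumexp(eta_b))
    q = np.exp(eta_b - logZ)
    # H = -sum q log q = logZ - E_q[eta]; exact (= log N) when beta = 0
    entropy = float(logZ - q @ eta_b)
    calib = {
        v: (float(background_env[v].min()), float(background_env[v].max()))
        for v in mapper.variables
    }
    return MaxentFit(
        beta=beta, lambdas=lambdas, mapper=mapper, rm=rm,
        log_normalizer=logZ, entropy=entropy, calib_range=calib,
        converged=converged, n_iter=n_iter, objective=-obj,
    )


def logistic_map(fit: MaxentFit, stack: ClimateStack, clamp: bool = True) -> np.ndarray:
    """Project the fit over a stack; returns a [0, 1] raster, NaN off-data."""
    missing = [v for v in fit.mapper.variables if v not in stack]
    if missing:
        raise ProjectionError(f"stack lacks model variables: {missing}")
    valid = stack.valid_mask(fit.mapper.variables)
    env = stack.env_table(valid, fit.mapper.variables)
    out = np.full(stack.grid.shape, np.nan)
    out[valid] = fit.logistic(env, clamp=clamp)
    return out


def aicc(k: int, logL: float, n: int) -> float:
    """Small-sample-corrected AIC; +inf when the correction denominator
    n - k - 1 is not positive."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n - k - 1 <= 0:
        return float("inf")
    return 2.0 * k - 2.0 * logL + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def presence_loglik(fit: MaxentFit, presence_env: pd.DataFrame,
                    study_env: pd.DataFrame) -> float:
    """Sum of log probabilities at presences, with the raw output
    renormalized over all study-area cells."""
    eta_study = fit.eta(study_env, clamp=False)
    eta_p = fit.eta(presence_env, clamp=False)
    return float(np.sum(eta_p - logsumexp(eta_study)))


def tune(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    study_env: pd.DataFrame | None = None,
    fc_grid: Sequence[str] = DEFAULT_FC_GRID,
    rm_grid: Sequence[float] = DEFAULT_RM_GRID,
    hinge_knots: int = 20,
    max_iterations: int = 5000,
) -> pd.DataFrame:
    """AICc model selection over the feature-class x regularization grid.

    Returns one row per candidate with columns ``fc, rm, k, logL, aicc,
    selected``; exactly one row is selected (min AICc, ties to smaller k,
    then smaller rm).
    """
    if not fc_grid or not len(rm_grid):
        raise ValueError("tuning grids must be nonempty")
    study_env = background_env if study_env is None else study_env
    n = len(presence_env)
    rows = []
    for fc_label in fc_grid:
        spec = FeatureSpec.from_label(fc_label, hinge_knots=hinge_knots)
        for rm in rm_grid:
            fit = fit_penalized(presence_env, background_env, rm=rm, spec=spec,
                                max_iterations=max_iterations)
            k = fit.n_nonzero
            logL = presence_loglik(fit, presence_env, study_env)
            rows.append({"fc": spec.label, "rm": float(rm), "k": k,
                         "logL": logL, "aicc": aicc(k, logL, n)})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["aicc"])]
    if finite.empty:
        raise TuningError(
            "every candidate has infinite AICc; more presences are needed"
        )
    best = finite.sort_values(["aicc", "k", "rm"], kind="stable").index[0]
    table["selected"] = False
    table.loc[best, "selected"] = True
    return table


@dataclass
class Replicate:
    fit: MaxentFit
    train_idx: np.ndarray
    test_idx: np.ndarray
    suitability: np.ndarray


def replicate_fit(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    stack: ClimateStack,
    config: ModelConfig,
    clamp: bool = True,
) -> tuple[list[Replicate], np.ndarray]:
    """Bootstrap-replicated fits and the cell-wise mean suitability map.

    Each replicate draws a seeded 70/30 train/test split, bootstrap
    resamples the training presences, fits at the configured FC x RM and
    projects a logistic map over ``stack``.
    """
    n = len(presence_env)
    if n < 5:
        raise SampleSizeError(f"replicate fitting requires >= 5 presences, got {n}")
    rng = np.random.default_rng(config.seed)
    n_train = max(2, int(round(config.train_fraction * n)))
    n_train = min(n_train, n - 1)
    replicates: list[Replicate] = []
    maps = []
    for _ in range(config.n_replicates):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        boot = rng.choice(train_idx, size=n_train, replace=True)
        fit = fit_penalized(
            presence_env.iloc[boot], background_env, rm=config.rm,
            spec=config.fc, max_iterations=config.max_iterations,
        )
        smap = logistic_map(fit, stack, clamp=clamp)
        replicates.append(Replicate(fit, train_idx, test_idx, smap))
        maps.append(smap)
    return replicates, nanmean_maps(maps)


def nanmean_maps(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Cell-wise mean ignoring NaN; NaN where no map has data (warning-free)."""
    arr = np.stack([np.asarray(m, dtype=float) for m in maps])
    finite = np.isfinite(arr)
    count = finite.sum(axis=0)
    total = np.where(finite, arr, 0.0).sum(axis=0)
    return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC; ties count one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def sample_background(
    stack: ClimateStack,
    mask: np.ndarray,
    n: int = 10_000,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Uniform background sample (without replacement) of valid mask cells;
    uses every cell when fewer than ``n`` are available."""
    valid = mask & stack.valid_mask(names)
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise ValueError("no valid cells to sample background from")
    if rows.size <= n:
        if rows.size < n:
            logger.info("only %d valid cells (< %d); using all", rows.size, n)
        sel = np.arange(rows.size)
    else:
        sel = np.random.default_rng(seed).choice(rows.size, size=n, replace=False)
    pick = np.zeros_like(valid)
    pick[rows[sel], cols[sel]] = True
    return stack.env_table(pick, names)


def jackknife_importance(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    spec: FeatureSpec,
    rm: float,
    seed: int = 0,
    train_fraction: float = 0.70,
    max_iterations: int = 5000,
) -> pd.DataFrame:
    """Leave-one-variable-out / only-one-variable test AUCs per variable."""
    variables = list(presence_env.columns)
    rng = np.random.default_rng(seed)
    n = len(presence_env)
    perm = rng.permutation(n)
    n_train = min(max(2, int(round(train_fraction * n))), n - 1)
    train, test = perm[:n_train], perm[n_train:]

    def test_auc(vars_used: list[str]) -> float:
        fit = fit_penalized(
            presence_env.iloc[train][vars_used], background_env[vars_used],
            rm=rm, spec=spec, max_iterations=max_iterations,
        )
        return auc(
            fit.logistic(presence_env.iloc[test][vars_used]),
            fit.logistic(background_env[vars_used]),
        )

    rows = []
    for var in variables:
        others = [v for v in variables if v != var]
        rows.append({
            "variable": var,
            "auc_without": test_auc(others) if others else np.nan,
            "auc_only_with": test_auc([var]),
        })
    return pd.DataFrame(rows)


def permutation_importance(
    fit: MaxentFit,
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    seed: int = 0,
) -> pd.Series:
    """Percent importance per variable: training-AUC drop after shuffling
    the variable across presence+background rows, normalized to sum 100."""
    rng = np.random.default_rng(seed)
    variables = fit.mapper.variables
    combined = pd.concat(
        [presence_env[variables], background_env[variables]], ignore_index=True
    )
    n_p = len(presence_env)
    base = auc(fit.logistic(presence_env), fit.logistic(background_env))
    drops = {}
    for var in variables:
        shuffled = combined.copy()
        shuffled[var] = rng.permutation(shuffled[var].to_numpy())
        scores = fit.logistic(shuffled)
        drops[var] = max(0.0, base - auc(scores[:n_p], scores[n_p:]))
    total = sum(drops.values())
    if total <= 0:
        return pd.Series({v: 100.0 / len(variables) for v in variables})
    return pd.Series({v: 100.0 * d / total for v, d in drops.items()})
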