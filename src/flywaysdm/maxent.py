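"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs distribution ``q_lambda(x) = exp(lambda . f(x)) / Z``
over the background cells, fitted by minimizing the L1-regularized negative
average presence log-likelihood

    J(lambda) = -(1/m) sum_presence lambda . f(x)  +  ln Z(lambda)
                + sum_j beta_j |lambda_j|,

with features f min-max scaled to [0, 1] over the background sample. The
"logistic" suitability output is ``P = q e^H / (1 + q e^H)`` with ``H`` the
entropy of the fitted background distribution, so a typical presence scores
about 0.5 and an all-zero model scores exactly 0.5 everywhere.

The optimizer is cyclic coordinate descent: for each coordinate an exact 1-D
Newton solve of the convex smooth part with the L1 subgradient conditions
(soft-threshold logic). Each coordinate update's positive objective
improvement is credited to the feature's source variable, which is what the
percent-contribution statistic reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .raster import Grid, OccurrenceSet, RasterLayer, RasterStack

__all__ = [
    "FeatureSet",
    "MaxEntModel",
    "EvalReport",
    "build_features",
    "fit",
    "predict_logistic",
    "percent_contribution",
    "jackknife_gain",
    "auc",
    "evaluate_subsample",
    "sample_background",
    "default_beta",
]

_DELTA_CAP = 30.0  # per-update trust region on a [0,1] feature


@dataclass(frozen=True)
class FeatureDef:
    variable: str
    transform: str  # linear | quadratic | hinge
    knot: float = np.nan

    @property
    def label(self) -> str:
        if self.transform == "hinge":
            return f"hinge({self.variable},{self.knot:.3f})"
        return f"{self.transform}({self.variable})"


@dataclass
class FeatureSet:
    """Feature definitions plus per-variable background min-max scaling."""

    variables: list[str]
    definitions: list[FeatureDef]
    scale_min: dict[str, float]
    scale_max: dict[str, float]

    def __len__(self) -> int:
        return len(self.definitions)

    def scaled(self, raw: np.ndarray) -> np.ndarray:
        """Min-max scale raw (n, n_vars) values to [0,1] per variable."""
        out = np.empty_like(raw, dtype=float)
        for j, v in enumerate(self.variables):
            lo, hi = self.scale_min[v], self.scale_max[v]
            out[:, j] = np.clip((raw[:, j] - lo) / (hi - lo), 0.0, 1.0)
        return out

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Raw (n, n_vars) layer values -> (n, n_features) design matrix."""
        s = self.scaled(raw)
        col = {v: j for j, v in enumerate(self.variables)}
        out = np.empty((raw.shape[0], len(self.definitions)))
        for k, d in enumerate(self.definitions):
            x = s[:, col[d.variable]]
            if d.transform == "linear":
                out[:, k] = x
            elif d.transform == "quadratic":
                out[:, k] = x * x
            else:  # hinge
                out[:, k] = np.clip((x - d.knot) / (1.0 - d.knot), 0.0, 1.0)
        return out


def build_features(
    stack: RasterStack,
    presence_cells: tuple[np.ndarray, np.ndarray],
    background_cells: tuple[np.ndarray, np.ndarray],
    classes: Sequence[str] = ("linear", "quadratic", "hinge"),
    variables: Sequence[str] | None = None,
    n_hinge_knots: int = 10,
) -> FeatureSet:
    """Define min-max scaled features; constant-on-background variables drop out."""
    bad = set(classes) - {"linear", "quadratic", "hinge"}
    if bad:
        raise ValueError(f"unknown feature classes {sorted(bad)}")
    variables = list(variables) if variables is not None else list(stack.names)
    br, bc = background_cells
    if len(br) == 0:
        raise ValueError("background sample is empty")
    raw_bg = stack.values_at_cells(br, bc, variables)
    keep, smin, smax = [], {}, {}
    for j, v in enumerate(variables):
        lo, hi = float(np.nanmin(raw_bg[:, j])), float(np.nanmax(raw_bg[:, j]))
        if hi > lo:
            keep.append(v)
            smin[v], smax[v] = lo, hi
    if not keep:
        raise ValueError("all variables are constant over the background")
    fs = FeatureSet(keep, [], smin, smax)
    scaled_bg = fs.scaled(raw_bg[:, [variables.index(v) for v in keep]])
    defs: list[FeatureDef] = []
    for j, v in enumerate(keep):
        if "linear" in classes:
            defs.append(FeatureDef(v, "linear"))
        if "quadratic" in classes:
            defs.append(FeatureDef(v, "quadratic"))
        if "hinge" in classes:
            qs = np.quantile(scaled_bg[:, j], np.linspace(0, 1, n_hinge_knots + 2)[1:-1])
            for t in np.unique(np.round(qs, 6)):
                if 0.0 < t < 1.0:
                    defs.append(FeatureDef(v, "hinge", float(t)))
    fs.definitions = defs
    return fs


def default_beta(
    feature_set: FeatureSet, f_presence: np.ndarray, beta_multiplier: float = 1.0
) -> np.ndarray:
    """Per-feature L1 weights following the published default schedule.

    Base level interpolates on presence count (linear/quadratic features),
    hinge features use a flat 0.5; each feature's weight scales with its
    presence-sample standard deviation over sqrt(m).
    """
    m = f_presence.shape[0]
    lq_table_m = np.array([10.0, 17.0, 30.0, 100.0])
    lq_table_b = np.array([1.0, 0.6, 0.5, 0.05])
    base_lq = float(np.interp(m, lq_table_m, lq_table_b))
    sd = f_presence.std(axis=0)
    sd = np.maximum(sd, 1e-3)
    beta = np.empty(len(feature_set))
    for k, d in enumerate(feature_set.definitions):
        base = 0.5 if d.transform == "hinge" else base_lq
        beta[k] = beta_multiplier * base * sd[k] / np.sqrt(m)
    return beta


@dataclass
class MaxEntModel:
    feature_set: FeatureSet
    lam: np.ndarray
    log_partition: float          # ln Z over the background sample
    entropy: float                # H of the fitted background distribution
    beta: np.ndarray
    n_background: int
    converged: bool
    n_iter: int
    objective: float
    training_credits: dict[str, float] = field(default_factory=dict)
    background_cells: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def gain(self) -> float:
        """Training gain over the uniform model: (1/m) sum ln q + ln N."""
        return self._gain

    _gain: float = 0.0


def _coordinate_delta(Fj: np.ndarray, q: np.ndarray, p_emp: float, lam_j: float, beta_j: float) -> float:
    """Exact 1-D minimizer step for one coordinate of the L1 objective."""

    def hprime(delta: float) -> tuple[float, float]:
        w = q * np.exp(np.clip(delta * Fj, -700, 700))
        s = w.sum()
        m1 = (w @ Fj) / s
        m2 = (w @ (Fj * Fj)) / s
        return m1 - p_emp, max(m2 - m1 * m1, 1e-12)

    d0, _ = hprime(0.0)
    if lam_j == 0.0 and abs(d0) <= beta_j:
        return 0.0

    def solve(target: float) -> float:
        # root of hprime(delta) = target; hprime is increasing in delta
        lo, hi = -_DELTA_CAP, _DELTA_CAP
        d = 0.0
        for _ in range(50):
            g, h = hprime(d)
            g -= target
            if abs(g) < 1e-10:
                break
            if g > 0:
                hi = d
            else:
                lo = d
            step = -g / h
            d_new = d + step
            if not (lo < d_new < hi):
                d_new = 0.5 * (lo + hi)
            if abs(d_new - d) < 1e-12:
                d = d_new
                break
            d = d_new
        return d

    d_pos = solve(-beta_j)
    if lam_j + d_pos > 0:
        return d_pos
    d_neg = solve(beta_j)
    if lam_j + d_neg < 0:
        return d_neg
    return -lam_j


def fit(
    features: FeatureSet,
    f_presence: np.ndarray,
    f_background: np.ndarray,
    beta_multiplier: float = 1.0,
    beta: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MaxEntModel:
    """Fit by cyclic coordinate descent with soft-threshold L1 handling.

    ``f_presence``/``f_background`` are design matrices from
    :meth:`FeatureSet.transform`. ``beta`` overrides the default per-feature
    regularization (use zeros for an unregularized fit).
    """
    m, J = f_presence.shape
    if m < 1:
        raise ValueError("no presence records to fit")
    N = f_background.shape[0]
    if beta is None:
        beta = default_beta(features, f_presence, beta_multiplier)
    beta = np.asarray(beta, float)

    p_emp = f_presence.mean(axis=0)
    lam = np.zeros(J)
    s_bg = np.zeros(N)
    credits: dict[str, float] = {v: 0.0 for v in features.variables}

    def objective(lam_vec, s_vec):
        return float(-(f_presence @ lam_vec).mean() + logsumexp(s_vec) + beta @ np.abs(lam_vec))

    obj = objective(lam, s_bg)  # = ln N at lam=0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        obj_start = obj
        logZ = logsumexp(s_bg)
        q = np.exp(s_bg - logZ)
        for j in range(J):
            Fj = f_background[:, j]
            delta = _coordinate_delta(Fj, q, p_emp[j], lam[j], beta[j])
            if delta == 0.0:
                continue
            # analytic objective change for this 1-D move
            w = q * np.exp(np.clip(delta * Fj, -700, 700))
            sw = w.sum()
            d_obj = (
                -delta * p_emp[j]
                + np.log(sw)
                + beta[j] * (abs(lam[j] + delta) - abs(lam[j]))
            )
            lam[j] += delta
            s_bg += delta * Fj
            q = w / sw
            obj += d_obj
            if d_obj < 0:
                credits[features.definitions[j].variable] += -d_obj
        # refresh against drift
        obj = objective(lam, s_bg)
        if obj_start - obj < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"maxent fit did not converge in {max_iter} cycles", RuntimeWarning)

    logZ = float(logsumexp(s_bg))
    q = np.exp(s_bg - logZ)
    entropy = float(logZ - q @ s_bg)
    model = MaxEntModel(
        feature_set=features,
        lam=lam,
        log_partition=logZ,
        entropy=entropy,
        beta=beta,
        n_background=N,
        converged=converged,
        n_iter=it,
        objective=obj,
        training_credits=credits,
    )
    model._gain = float((f_presence @ lam).mean() - logZ + np.log(N))
    return model


def raw_scores(model: MaxEntModel, raw_values: np.ndarray) -> np.ndarray:
    """ln q at arbitrary points (normalized over the training background)."""
    F = model.feature_set.transform(raw_values)
    return F @ model.lam - model.log_partition


def logistic_scores(model: MaxEntModel, raw_values: np.ndarray) -> np.ndarray:
    lnq = raw_scores(model, raw_values)
    z = lnq + model.entropy
    return 1.0 / (1.0 + np.exp(-z))


def predict_logistic(model: MaxEntModel, stack: RasterStack) -> RasterLayer:
    """Logistic suitability map ``P = q e^H / (1 + q e^H)``; nodata propagates."""
    for v in model.feature_set.variables:
        if v not in stack:
            raise KeyError(f"stack is missing model variable {v!r}")
    mask = stack.finite_mask(model.feature_set.variables)
    rows, cols = np.nonzero(mask)
    raw = stack.values_at_cells(rows, cols, model.feature_set.variables)
    out = np.full(stack.grid.shape, np.nan)
    out[rows, cols] = logistic_scores(model, raw)
    return RasterLayer(stack.grid, "suitability", out)


def percent_contribution(model: MaxEntModel) -> dict[str, float]:
    """Share of cumulative positive training-gain improvement per variable."""
    total = sum(model.training_credits.values())
    if total <= 0:
        warnings.warn("degenerate zero-gain fit: all contributions zero", RuntimeWarning)
        return {v: 0.0 for v in model.training_credits}
    return {v: 100.0 * c / total for v, c in model.training_credits.items()}


def jackknife_gain(
    features: FeatureSet,
    f_presence: np.ndarray,
    f_background: np.ndarray,
    beta_multiplier: float = 1.0,
    **fit_kw,
) -> dict[str, tuple[float, float]]:
    """Per-variable (gain with only that variable, gain without it)."""
    if len(features.variables) < 2:
        raise ValueError("jackknife needs at least two variables")
    out: dict[str, tuple[float, float]] = {}
    for v in features.variables:
        only = [k for k, d in enumerate(features.definitions) if d.variable == v]
        without = [k for k, d in enumerate(features.definitions) if d.variable != v]
        gains = []
        for cols, vars_ in ((only, [v]), (without, [u for u in features.variables if u != v])):
            sub = FeatureSet(
                vars_,
                [features.definitions[k] for k in cols],
                {u: features.scale_min[u] for u in vars_},
                {u: features.scale_max[u] for u in vars_},
            )
            mdl = fit(sub, f_presence[:, cols], f_background[:, cols],
                      beta_multiplier=beta_multiplier, **fit_kw)
            gains.append(mdl.gain)
        out[v] = (gains[0], gains[1])
    return out


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC with the 0.5 tie credit (Mann-Whitney convention)."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    rp = ranks[: p.size].sum()
    return float((rp - p.size * (p.size + 1) / 2) / (p.size * b.size))


def sample_background(
    grid: Grid,
    valid_mask: np.ndarray,
    n_background: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample without replacement of valid cells (all cells if the
    landscape has fewer valid cells than requested)."""
    rows, cols = np.nonzero(valid_mask)
    if rows.size == 0:
        raise ValueError("no valid cells to sample background from")
    if n_background >= rows.size:
        return rows, cols
    idx = rng.choice(rows.size, size=n_background, replace=False)
    return rows[idx], cols[idx]


@dataclass
class EvalReport:
    species: str
    auc_mean: float
    auc_sd: float
    cv: float
    n_replicates: int
    train_fraction: float
    aucs: list[float]
    contributions: dict[str, float]
    jackknife: dict[str, tuple[float, float]]
    mean_map: RasterLayer
    excluded: bool
    n_presence_cells: int

    def passes(self, auc_min: float = 0.90, cv_max: float = 0.15) -> bool:
        return self.auc_mean > auc_min and self.cv < cv_max


def evaluate_subsample(
    stack: RasterStack,
    occ_species: OccurrenceSet,
    variables: Sequence[str] | None = None,
    n_background: int = 10000,
    train_fraction: float = 0.75,
    n_replicates: int = 10,
    seed: int = 0,
    classes: Sequence[str] = ("linear", "quadratic", "hinge"),
    beta_multiplier: float = 1.0,
    auc_min: float = 0.90,
    cv_max: float = 0.15,
    max_iter: int = 500,
    tol: float = 1e-6,
    compute_jackknife: bool = True,
) -> EvalReport:
    """Replicated subsample evaluation: 75/25 presence splits, fresh
    background per replicate, mean logistic map, AUC mean/sd/cv, plus a
    full-data fit for contributions and jackknife gains."""
    species = occ_species.df["species"].iloc[0] if len(occ_species) else "?"
    variables = list(variables) if variables is not None else list(stack.names)
    valid = stack.finite_mask(variables)
    pr, pc = occ_species.unique_cells(stack.grid)
    on_valid = valid[pr, pc]
    pr, pc = pr[on_valid], pc[on_valid]
    if pr.size < 8:
        raise ValueError(
            f"species {species!r}: {pr.size} presence cells, need >= 8 for a 75/25 split"
        )
    rng = np.random.default_rng(seed)
    aucs = []
    map_sum = np.zeros(stack.grid.shape)
    map_n = np.zeros(stack.grid.shape)
    for _ in range(n_replicates):
        perm = rng.permutation(pr.size)
        n_train = max(5, int(round(train_fraction * pr.size)))
        n_train = min(n_train, pr.size - 1)
        tr, te = perm[:n_train], perm[n_train:]
        bg = sample_background(stack.grid, valid, n_background, rng)
        fs = build_features(stack, (pr[tr], pc[tr]), bg, classes, variables)
        f_bg = fs.transform(stack.values_at_cells(bg[0], bg[1], fs.variables))
        f_tr = fs.transform(stack.values_at_cells(pr[tr], pc[tr], fs.variables))
        mdl = fit(fs, f_tr, f_bg, beta_multiplier=beta_multiplier, max_iter=max_iter, tol=tol)
        f_te_scores = logistic_scores(mdl, stack.values_at_cells(pr[te], pc[te], fs.variables))
        bg_scores = logistic_scores(mdl, stack.values_at_cells(bg[0], bg[1], fs.variables))
        aucs.append(auc(f_te_scores, bg_scores))
        rep_map = predict_logistic(mdl, stack).values
        fin = np.isfinite(rep_map)
        map_sum[fin] += rep_map[fin]
        map_n[fin] += 1
    auc_arr = np.array(aucs)
    auc_mean = float(auc_arr.mean())
    auc_sd = float(auc_arr.std(ddof=1)) if n_replicates > 1 else 0.0
    cv = auc_sd / auc_mean if auc_mean > 0 else np.inf

    # full-data fit for contributions / jackknife
    bg = sample_background(stack.grid, valid, n_background, rng)
    fs = build_features(stack, (pr, pc), bg, classes, variables)
    f_bg = fs.transform(stack.values_at_cells(bg[0], bg[1], fs.variables))
    f_pr = fs.transform(stack.values_at_cells(pr, pc, fs.variables))
    full = fit(fs, f_pr, f_bg, beta_multiplier=beta_multiplier, max_iter=max_iter, tol=tol)
    contributions = percent_contribution(full)
    jack = (
        jackknife_gain(fs, f_pr, f_bg, beta_multiplier=beta_multiplier,
                       max_iter=max_iter, tol=tol)
        if compute_jackknife and len(fs.variables) >= 2
        else {}
    )

    mean_vals = np.full(stack.grid.shape, np.nan)
    got = map_n > 0
    mean_vals[got] = map_sum[got] / map_n[got]
    mean_map = RasterLayer(stack.grid, f"suit_{species}", mean_vals)
    return EvalReport(
        species=species,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        cv=float(cv),
        n_replicates=n_replicates,
        train_fraction=train_fraction,
        aucs=aucs,
        contributions=contributions,
        jackknife=jack,
        mean_map=mean_map,
        excluded=not (auc_mean > auc_min and cv < cv_max),
        n_presence_cells=int(pr.size),
    )
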