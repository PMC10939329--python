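"""Presence-background maximum-entropy (MaxEnt) niche model.

The model is the Gibbs distribution q(x) ∝ exp(Σ_f λ_f f(x)) over background
cells, with features f derived from the environmental predictors and scaled
to [0, 1].  Fitting maximises the L1-penalised log-likelihood of the
presences

    L(λ) = mean_presence(η) − log Σ_background e^η − Σ_f β_f |λ_f|,
    η(x) = Σ_f λ_f f(x),

a concave problem solved here by a monotone accelerated proximal-gradient
method (FISTA with restarts and backtracking).  The per-class regularisation
weights β follow the published MaxEnt sample-size schedule.

Fitted models serialise to a plain-text "lambdas" file — one line per
feature (name, λ, min, max) plus the normalisation constants — which is
sufficient to re-project the model onto any predictor stack, with optional
clamping of predictors to their training ranges.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .grids import EnvStack, SuitabilityMap
from .synthetic import BackgroundSet, OccurrenceSet

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold", "categorical")

# MaxEnt's default regularisation schedule: interpolation points of
# (presence sample size, beta) per feature class.
BETA_SCHEDULE = {
    "linear": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "quadratic": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "product": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "hinge": [(0, 0.5), (1, 0.5)],
    "threshold": [(0, 2.0), (100, 1.0)],
    "categorical": [(0, 0.65), (10, 0.5), (17, 0.25)],
}


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature classes to expand and how hard to regularise them."""

    classes: tuple = ("linear", "quadratic", "hinge")
    n_hinge_knots: int = 30
    n_threshold_knots: int = 10
    beta_multiplier: float = 1.0
    class_beta: Mapping[str, float] | None = None  # overrides the schedule
    max_iter: int = 500
    tol: float = 1e-9
    dedupe_presences: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if "hinge" in self.classes and self.n_hinge_knots < 2:
            raise ValueError("n_hinge_knots must be >= 2")
        if "threshold" in self.classes and self.n_threshold_knots < 2:
            raise ValueError("n_threshold_knots must be >= 2")
        if self.beta_multiplier < 0:
            raise ValueError("beta_multiplier must be >= 0")


def _schedule_beta(cls: str, m: int) -> float:
    pts = BETA_SCHEDULE[cls]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(m, xs, ys))


@dataclass
class Feature:
    """One scaled feature: its transform kind, variables, range and λ.

    ``fmin``/``fmax`` are the training min/max of the *raw* transform value
    (v, v², v1·v2, or the hinge knot and variable max), so each lambdas-file
    line is self-sufficient for projection.
    """

    kind: str
    variables: tuple
    fmin: float
    fmax: float
    lam: float = 0.0
    knot: float | None = None
    code: float | None = None

    @property
    def name(self) -> str:
        v = self.variables
        if self.kind == "linear":
            return v[0]
        if self.kind == "quadratic":
            return f"{v[0]}^2"
        if self.kind == "product":
            return f"{v[0]}*{v[1]}"
        if self.kind == "hinge":
            return f"'{v[0]}"
        if self.kind == "threshold":
            return f"({_fmt(self.knot)}<{v[0]})"
        if self.kind == "categorical":
            return f"({v[0]}={_fmt(self.code)})"
        raise AssertionError(self.kind)

    def evaluate(self, vars_: Mapping[str, np.ndarray]) -> np.ndarray:
        """Scaled feature value; [0, 1] whenever inputs are in training range."""
        span = self.fmax - self.fmin
        if self.kind == "linear":
            raw = vars_[self.variables[0]]
        elif self.kind == "quadratic":
            raw = vars_[self.variables[0]] ** 2
        elif self.kind == "product":
            raw = vars_[self.variables[0]] * vars_[self.variables[1]]
        elif self.kind == "hinge":
            raw = vars_[self.variables[0]]
            if span <= 0:
                return np.zeros_like(raw)
            return np.clip((raw - self.fmin) / span, 0.0, 1.0)
        elif self.kind == "threshold":
            return (vars_[self.variables[0]] >= self.knot).astype(float)
        elif self.kind == "categorical":
            return (vars_[self.variables[0]] == self.code).astype(float)
        else:
            raise AssertionError(self.kind)
        if span <= 0:
            return np.zeros_like(raw)
        return (raw - self.fmin) / span


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def build_features(
    var_values: Mapping[str, np.ndarray],
    config: FeatureConfig,
    categorical: Sequence[str] = (),
) -> list[Feature]:
    """Construct the feature list from training-sample values per variable.

    Ranges and knots come from the supplied values (presences + background).
    Hinge and threshold knots sit at equal quantiles.  Constant variables
    yield no features.  A linear feature is always emitted for every
    continuous variable (with λ fixed at 0 if the class is disabled) so the
    lambdas file records every training range.
    """
    continuous = [v for v in var_values if v not in set(categorical)]
    feats: list[Feature] = []
    ranges = {v: (float(np.min(var_values[v])), float(np.max(var_values[v]))) for v in continuous}
    for v in continuous:
        lo, hi = ranges[v]
        if hi <= lo:
            continue
        feats.append(Feature("linear", (v,), lo, hi))
    if "quadratic" in config.classes:
        for v in continuous:
            lo, hi = ranges[v]
            if hi <= lo:
                continue
            sq = var_values[v] ** 2
            feats.append(Feature("quadratic", (v,), float(sq.min()), float(sq.max())))
    if "product" in config.classes:
        for i, v1 in enumerate(continuous):
            for v2 in continuous[i + 1 :]:
                if ranges[v1][1] <= ranges[v1][0] or ranges[v2][1] <= ranges[v2][0]:
                    continue
                pr = var_values[v1] * var_values[v2]
                lo, hi = float(pr.min()), float(pr.max())
                if hi > lo:
                    feats.append(Feature("product", (v1, v2), lo, hi))
    if "hinge" in config.classes:
        for v in continuous:
            lo, hi = ranges[v]
            if hi <= lo:
                continue
            qs = np.quantile(var_values[v], np.linspace(0, 1, config.n_hinge_knots + 1)[:-1])
            for knot in np.unique(qs):
                if hi > knot:
                    feats.append(Feature("hinge", (v,), float(knot), hi, knot=float(knot)))
    if "threshold" in config.classes:
        for v in continuous:
            lo, hi = ranges[v]
            if hi <= lo:
                continue
            qs = np.quantile(var_values[v], np.linspace(0, 1, config.n_threshold_knots + 2)[1:-1])
            for knot in np.unique(qs):
                feats.append(Feature("threshold", (v,), 0.0, 1.0, knot=float(knot)))
    if "categorical" in config.classes:
        for v in categorical:
            if v not in var_values:
                continue
            for code in np.unique(var_values[v]):
                feats.append(Feature("categorical", (v,), 0.0, 1.0, code=float(code)))
    return feats


def expand_features(
    var_values: Mapping[str, np.ndarray],
    features: Sequence[Feature],
    training_ranges: Mapping[str, tuple] | None = None,
    clamp: bool = False,
) -> np.ndarray:
    """Feature matrix, shape (n_samples, n_features).

    With ``clamp`` each continuous variable is first restricted to its
    training range; without it, values outside the range produce feature
    values outside [0, 1] (flagged downstream via the clamp fraction).
    """
    vars_ = dict(var_values)
    if clamp:
        if training_ranges is None:
            raise ValueError("clamping requires training_ranges")
        for v, (lo, hi) in training_ranges.items():
            if v in vars_:
                vars_[v] = np.clip(vars_[v], lo, hi)
    cols = [f.evaluate(vars_) for f in features]
    if not cols:
        n = len(next(iter(vars_.values()))) if vars_ else 0
        return np.zeros((n, 0))
    return np.stack(cols, axis=-1)


@dataclass
class LambdaModel:
    """A fitted model: features with coefficients plus normalisation constants.

    ``raw(x) = exp(η(x) − linearPredictorNormalizer) / densityNormalizer``
    sums to 1 over the training background.  ``entropy`` is the entropy of
    that distribution; the cloglog and logistic outputs are
    ``1 − exp(−e^H · raw)`` and ``e^H raw / (1 + e^H raw)``.
    """

    features: list
    linear_predictor_normalizer: float
    density_normalizer: float
    entropy: float
    n_background: int
    training_ranges: dict
    species_id: str = "species"
    converged: bool = True
    gain: float = 0.0
    contribution_trace: dict = field(default_factory=dict)  # feature name -> gain share

    def __post_init__(self) -> None:
        if self.density_normalizer <= 0:
            raise ValueError("densityNormalizer must be positive")
        for v, (lo, hi) in self.training_ranges.items():
            if lo > hi:
                raise ValueError(f"training range of {v!r} has min > max")

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            for v in f.variables:
                if v not in seen:
                    seen.append(v)
        return seen

    def eta(self, var_values: Mapping[str, np.ndarray], clamp: bool = True) -> np.ndarray:
        X = expand_features(var_values, self.features, self.training_ranges, clamp=clamp)
        lam = np.array([f.lam for f in self.features])
        return X @ lam

    def score_values(
        self, var_values: Mapping[str, np.ndarray], clamp: bool = True, output: str = "cloglog"
    ) -> np.ndarray:
        eta = self.eta(var_values, clamp=clamp)
        # separable fits can push eta high enough to overflow; inf raw maps to 1
        with np.errstate(over="ignore"):
            raw = np.exp(eta - self.linear_predictor_normalizer) / self.density_normalizer
            if output == "raw":
                return raw
            eH = math.exp(self.entropy)
            if output == "cloglog":
                return 1.0 - np.exp(-eH * raw)
            if output == "logistic":
                return np.where(np.isinf(raw), 1.0, eH * raw / (1.0 + eH * raw))
        raise ValueError(f"unknown output {output!r}")

    def score_cells(
        self, stack: EnvStack, cells: np.ndarray, clamp: bool = True, output: str = "cloglog"
    ) -> np.ndarray:
        vals = _cell_values(stack, cells, self.variables)
        return self.score_values(vals, clamp=clamp, output=output)


def _cell_values(stack: EnvStack, cells: np.ndarray, variables: Sequence[str]) -> dict:
    missing = [v for v in variables if v not in stack.layer_names]
    if missing:
        raise KeyError(f"stack is missing predictor(s): {missing}")
    mat = stack.values_at_cells(cells, variables)
    return {v: mat[:, i] for i, v in enumerate(variables)}


# ---------------------------------------------------------------------------
# fitting


def penalized_objective(
    lam: np.ndarray, Xp: np.ndarray, Xb: np.ndarray, betas: np.ndarray
) -> float:
    """Negative penalised log-likelihood (the quantity minimised)."""
    eta_b = Xb @ lam
    eta_p = Xp @ lam
    return float(logsumexp(eta_b) - eta_p.mean() + betas @ np.abs(lam))


def _soft(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def fit_gibbs(
    Xp: np.ndarray,
    Xb: np.ndarray,
    betas: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> tuple[np.ndarray, bool, dict]:
    """Minimise the L1-penalised negative log-likelihood.

    Monotone FISTA: accelerated proximal-gradient steps with backtracking
    line search, restarting the momentum whenever the objective would rise.
    Returns (λ, converged, per-feature gain attribution).

    The gain (log-likelihood improvement over the featureless model) earned
    in each accepted step is attributed to features in proportion to
    |Δλ_f · ∂L/∂λ_f|, which reduces to MaxEnt's per-iteration attribution
    when one coordinate moves at a time.
    """
    n_feat = Xb.shape[1]
    lam = np.zeros(n_feat)
    if n_feat == 0:
        return lam, True, {}
    mean_p = Xp.mean(axis=0)

    def smooth(l):
        return float(logsumexp(Xb @ l) - (Xp @ l).mean())

    def grad(l):
        eta_b = Xb @ l
        q = np.exp(eta_b - logsumexp(eta_b))
        return Xb.T @ q - mean_p

    y = lam.copy()
    t = 1.0
    L = 1.0
    J_lam = smooth(lam) + betas @ np.abs(lam)
    gain_attr = np.zeros(n_feat)
    converged = False
    for _ in range(max_iter):
        g = grad(y)
        s_y = smooth(y)
        while True:
            cand = _soft(y - g / L, betas / L)
            d = cand - y
            s_cand = smooth(cand)
            if s_cand <= s_y + g @ d + 0.5 * L * (d @ d) + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        J_cand = s_cand + betas @ np.abs(cand)
        if J_cand > J_lam + 1e-15:
            # momentum overshoot: restart from the best iterate
            y = lam.copy()
            t = 1.0
            continue
        dlam = cand - lam
        dgain = J_lam - J_cand
        if dgain > 0:
            w = np.abs(dlam * grad(lam))
            tot = w.sum()
            gain_attr += dgain * (w / tot if tot > 0 else 1.0 / n_feat)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        y = cand + ((t - 1.0) / t_new) * dlam
        t = t_new
        if abs(J_lam - J_cand) < tol * (1.0 + abs(J_cand)):
            lam, J_lam = cand, J_cand
            converged = True
            break
        lam, J_lam = cand, J_cand
        L = max(L * 0.9, 1e-6)
    return lam, converged, {"gain_attr": gain_attr}


def compute_betas(features: Sequence[Feature], Xp: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Per-feature L1 weights: schedule(class, m) x sd(f over presences)/√m."""
    m = max(Xp.shape[0], 1)
    betas = np.empty(len(features))
    var_p = Xp.var(axis=0) if Xp.shape[0] else np.zeros(len(features))
    for i, f in enumerate(features):
        base = (
            config.class_beta[f.kind]
            if config.class_beta and f.kind in config.class_beta
            else _schedule_beta(f.kind, m)
        )
        sd = math.sqrt(max(float(var_p[i]), 2.5e-3))
        betas[i] = config.beta_multiplier * base * sd / math.sqrt(m)
    return betas


def fit_maxent(
    presences: OccurrenceSet | np.ndarray,
    background: BackgroundSet | np.ndarray,
    stack: EnvStack,
    config: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    species_id: str | None = None,
) -> LambdaModel:
    """Fit the model from presence and background cells on a stack.

    Presences are reduced to one record per grid cell (standard MaxEnt
    behaviour, avoiding pseudo-replication) and must fall on valid cells.
    Deterministic: the optimiser is seed-free; ``seed`` is accepted for
    interface symmetry with stochastic stages.
    """
    if isinstance(presences, OccurrenceSet):
        pcells = presences.cell_index
        species_id = species_id or presences.species_id
    else:
        pcells = np.asarray(presences, dtype=int)
    species_id = species_id or "species"
    pcells = pcells[~stack.nodata_mask.ravel()[pcells]]
    if config.dedupe_presences:
        pcells = np.unique(pcells)
    if pcells.size == 0:
        raise ValueError("no usable presence records on valid cells")
    bcells = background.sample_cells if isinstance(background, BackgroundSet) else np.asarray(background, dtype=int)
    if bcells.size == 0:
        raise ValueError("background is empty")

    variables = list(stack.layer_names)
    categorical = [v for v in variables if v in stack.categorical]
    pv = _cell_values(stack, pcells, variables)
    bv = _cell_values(stack, bcells, variables)
    train_v = {v: np.concatenate([pv[v], bv[v]]) for v in variables}
    features = build_features(train_v, config, categorical=categorical)
    # fit only the enabled classes; the always-emitted linear range rows stay at λ=0
    fit_mask = np.array(
        [f.kind in config.classes for f in features], dtype=bool
    )
    Xp_all = expand_features(pv, features)
    Xb_all = expand_features(bv, features)
    Xp, Xb = Xp_all[:, fit_mask], Xb_all[:, fit_mask]
    active = [f for f, k in zip(features, fit_mask) if k]
    betas = compute_betas(active, Xp, config)
    lam_active, converged, info = fit_gibbs(Xp, Xb, betas, config.max_iter, config.tol)

    lam = np.zeros(len(features))
    lam[fit_mask] = lam_active
    for f, l in zip(features, lam):
        f.lam = float(l)

    eta_b = Xb_all @ lam
    lpn = float(eta_b.max())
    weights = np.exp(eta_b - lpn)
    dn = float(weights.sum())
    r = weights / dn
    entropy = float(-(r * np.log(np.maximum(r, 1e-300))).sum())
    gain = math.log(len(bcells)) - (logsumexp(eta_b) - float((Xp_all @ lam).mean()))

    contrib: dict[str, float] = {}
    if "gain_attr" in info:
        for f, gshare in zip(active, info["gain_attr"]):
            contrib[f.name] = contrib.get(f.name, 0.0) + float(gshare)

    ranges = {
        v: (float(train_v[v].min()), float(train_v[v].max()))
        for v in variables
        if v not in categorical
    }
    return LambdaModel(
        features=features,
        linear_predictor_normalizer=lpn,
        density_normalizer=dn,
        entropy=entropy,
        n_background=len(bcells),
        training_ranges=ranges,
        species_id=species_id,
        converged=converged,
        gain=float(gain),
        contribution_trace=contrib,
    )


def predict(
    model: LambdaModel,
    stack: EnvStack,
    clamp: bool = True,
    output: str = "cloglog",
) -> SuitabilityMap:
    """Project a fitted model onto a stack; unit-scale suitability map.

    With ``clamp`` each predictor is restricted to its training range and the
    fraction of valid cells where any predictor was clamped is recorded on
    the returned map.  ``output`` ∈ {raw, logistic, cloglog}; raw is the
    Gibbs density (sums to 1 over the training background, not bounded by 1),
    returned on the "density" scale.
    """
    variables = model.variables or list(model.training_ranges)
    grid_vals = {}
    missing = [v for v in variables if v not in stack.layer_names]
    if missing:
        raise KeyError(f"stack is missing predictor(s): {missing}")
    for v in variables:
        grid_vals[v] = stack.layer(v)
    clamp_fraction = 0.0
    if clamp:
        hit = np.zeros((stack.grid.rows, stack.grid.cols), dtype=bool)
        for v, (lo, hi) in model.training_ranges.items():
            if v in grid_vals:
                hit |= (grid_vals[v] < lo) | (grid_vals[v] > hi)
        valid = ~stack.nodata_mask
        clamp_fraction = float(hit[valid].mean()) if valid.any() else 0.0
    scores = model.score_values(grid_vals, clamp=clamp, output=output)
    scores = np.where(stack.nodata_mask, 0.0, scores)
    return SuitabilityMap(
        values=scores,
        grid=stack.grid,
        nodata_mask=stack.nodata_mask.copy(),
        scale="density" if output == "raw" else "unit",
        key=(model.species_id, stack.key),
        clamp_fraction=clamp_fraction,
    )


# ---------------------------------------------------------------------------
# variable contribution and importance


def percent_contribution(model: LambdaModel) -> dict:
    """Percent contribution per variable, from the fit's gain attribution.

    Product features split their share equally between their two variables;
    the result is normalised to sum to 100.
    """
    by_var: dict[str, float] = {}
    for f in model.features:
        share = model.contribution_trace.get(f.name, 0.0)
        if share == 0.0:
            continue
        for v in f.variables:
            by_var[v] = by_var.get(v, 0.0) + share / len(f.variables)
    for v in model.variables:
        by_var.setdefault(v, 0.0)
    total = sum(by_var.values())
    if total <= 0:
        n = len(by_var)
        return {v: 100.0 / n for v in by_var}
    return {v: 100.0 * s / total for v, s in by_var.items()}


def permutation_importance(
    model: LambdaModel,
    presences: OccurrenceSet | np.ndarray,
    background: BackgroundSet | np.ndarray,
    stack: EnvStack,
    seed: int = 0,
) -> dict:
    """Percent importance per variable: training-AUC drop after permutation.

    Each variable's values are shuffled across the pooled presence +
    background records, the model is re-applied, and the decrease in
    training AUC is recorded; drops (floored at 0) are normalised to 100.
    """
    from .evaluation import auc_presence_background

    pcells = presences.cell_index if isinstance(presences, OccurrenceSet) else np.asarray(presences, dtype=int)
    bcells = background.sample_cells if isinstance(background, BackgroundSet) else np.asarray(background, dtype=int)
    variables = model.variables
    pv = _cell_values(stack, pcells, variables)
    bv = _cell_values(stack, bcells, variables)
    n_p = len(pcells)
    base_p = model.score_values(pv, clamp=True, output="raw")
    base_b = model.score_values(bv, clamp=True, output="raw")
    auc0 = auc_presence_background(base_p, base_b)
    rng = np.random.default_rng(seed)
    drops = {}
    for v in variables:
        pooled = np.concatenate([pv[v], bv[v]])
        perm = rng.permutation(pooled)
        pv2 = dict(pv)
        bv2 = dict(bv)
        pv2[v] = perm[:n_p]
        bv2[v] = perm[n_p:]
        auc_v = auc_presence_background(
            model.score_values(pv2, clamp=True, output="raw"),
            model.score_values(bv2, clamp=True, output="raw"),
        )
        drops[v] = max(auc0 - auc_v, 0.0)
    total = sum(drops.values())
    if total <= 0:
        return {v: 100.0 / len(variables) for v in variables}
    return {v: 100.0 * d / total for v, d in drops.items()}


# ---------------------------------------------------------------------------
# lambdas text format

_SPECIAL = ("linearPredictorNormalizer", "densityNormalizer", "numBackgroundPoints", "entropy")


def write_lambdas(model: LambdaModel, destination: str | Path) -> Path:
    """Serialise a fitted model to the plain-text lambdas dialect.

    One ``name, lambda, min, max`` line per feature (including zero-λ linear
    lines that record every training range), followed by the normaliser,
    background-count and entropy lines.
    """
    path = Path(destination)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for f in model.features:
        lines.append(f"{f.name}, {_fmt(f.lam)}, {_fmt(f.fmin)}, {_fmt(f.fmax)}")
    lines.append(f"linearPredictorNormalizer, {_fmt(model.linear_predictor_normalizer)}")
    lines.append(f"densityNormalizer, {_fmt(model.density_normalizer)}")
    lines.append(f"numBackgroundPoints, {model.n_background}")
    lines.append(f"entropy, {_fmt(model.entropy)}")
    path.write_text("\n".join(lines) + "\n")
    return path

_RE_THRESHOLD = re.compile(r"^\((?P<knot>[^<]+)<(?P<var>[^)]+)\)$")
_RE_CATEGORICAL = re.compile(r"^\((?P<var>[^=]+)=(?P<code>[^)]+)\)$")


def _parse_feature(name: str, lam: float, fmin: float, fmax: float) -> Feature:
    if name.startswith("'"):
        return Feature("hinge", (name[1:],), fmin, fmax, lam=lam, knot=fmin)
    m = _RE_THRESHOLD.match(name)
    if m:
        return Feature("threshold", (m["var"],), fmin, fmax, lam=lam, knot=float(m["knot"]))
    m = _RE_CATEGORICAL.match(name)
    if m:
        return Feature("categorical", (m["var"],), fmin, fmax, lam=lam, code=float(m["code"]))
    if name.endswith("^2"):
        return Feature("quadratic", (name[:-2],), fmin, fmax, lam=lam)
    if "*" in name:
        v1, v2 = name.split("*", 1)
        return Feature("product", (v1, v2), fmin, fmax, lam=lam)
    return Feature("linear", (name,), fmin, fmax, lam=lam)


def read_lambdas(source: str | Path, species_id: str | None = None) -> LambdaModel:
    """Parse a lambdas file back into a model; inverse of :func:`write_lambdas`."""
    path = Path(source)
    features: list[Feature] = []
    special: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if parts[0] in _SPECIAL:
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: malformed {parts[0]} line")
            special[parts[0]] = float(parts[1])
            continue
        if len(parts) != 4:
            raise ValueError(f"line {lineno}: expected 'name, lambda, min, max'")
        try:
            lam, fmin, fmax = (float(p) for p in parts[1:])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric field") from None
        features.append(_parse_feature(parts[0], lam, fmin, fmax))
    missing = [k for k in _SPECIAL if k not in special]
    if missing:
        raise ValueError(f"lambdas file missing required line(s): {missing}")
    ranges = {
        f.variables[0]: (f.fmin, f.fmax) for f in features if f.kind == "linear"
    }
    return LambdaModel(
        features=features,
        linear_predictor_normalizer=special["linearPredictorNormalizer"],
        density_normalizer=special["densityNormalizer"],
        entropy=special["entropy"],
        n_background=int(special["numBackgroundPoints"]),
        training_ranges=ranges,
        species_id=species_id or path.stem,
    )
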