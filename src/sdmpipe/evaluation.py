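"""Model validation: cross-validation, AUC, continuous Boyce Index,
dual-threshold quality flags, and the variable-selection procedure.

AUC is the presence-vs-background rank statistic: the probability that a
randomly chosen presence scores above a randomly chosen background point
(ties count one half).  The Boyce Index slides a window along the
suitability gradient and correlates (Spearman) the predicted-to-expected
presence ratio P/E with the window position; +1 means presences concentrate
monotonically in high-suitability cells, 0 means the model is no better than
random.  Models are judged against the conventional AUC 0.7 and Boyce 0.5
thresholds, giving a quadrant flag per species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EnvStack
from .maxent import FeatureConfig, LambdaModel, fit_maxent
from .synthetic import BackgroundSet, OccurrenceSet

AUC_THRESHOLD = 0.7
BOYCE_THRESHOLD = 0.5
FLAGS = ("pass_both", "auc_only", "boyce_only", "fail_both")


def auc_presence_background(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC of presence over background scores; ties score 0.5.

    Constant scores give 0.5 (the model ranks nothing).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def boyce_index(
    presence_scores,
    landscape_scores,
    n_windows: int = 101,
    window_fraction: float = 0.1,
) -> float:
    """Continuous Boyce Index.

    Scores are first mapped through the landscape empirical CDF, so the
    index depends only on ranks and is invariant under any strictly monotone
    transform of the suitability scale.  ``n_windows`` moving windows of
    width ``window_fraction`` (of the cumulative-probability range) slide
    across [0, 1]; per window, P = fraction of presences inside and E =
    fraction of landscape cells inside; windows with E = 0 are dropped and
    the result is the Spearman correlation (mid-ranks for ties) of P/E
    against the window midpoint.  Returns NaN when undefined (e.g. all
    presence scores identical).
    """
    p = np.asarray(presence_scores, dtype=float)
    land = np.asarray(landscape_scores, dtype=float)
    if p.size == 0 or land.size == 0:
        raise ValueError("presence and landscape scores must be non-empty")
    if np.unique(p).size < 2:
        return float("nan")
    order = np.sort(land)
    # empirical CDF (average of <= and <, handling ties symmetrically)
    cdf_p = (np.searchsorted(order, p, "right") + np.searchsorted(order, p, "left")) / (
        2.0 * land.size
    )
    cdf_l = (np.arange(land.size) + 0.5) / land.size
    w = window_fraction
    mids = np.linspace(w / 2.0, 1.0 - w / 2.0, n_windows)
    lo = mids - w / 2.0
    hi = mids + w / 2.0
    P = np.array([(np.sum((cdf_p >= a) & (cdf_p <= b))) / p.size for a, b in zip(lo, hi)])
    E = np.array([(np.sum((cdf_l >= a) & (cdf_l <= b))) / land.size for a, b in zip(lo, hi)])
    keep = E > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 windows with non-zero expected frequency")
    ratio = P[keep] / E[keep]
    if np.unique(ratio).size < 2:
        return float("nan")
    rho = stats.spearmanr(ratio, mids[keep]).statistic
    return float(rho)


def quality_flags(
    mean_auc: float,
    boyce: float,
    auc_threshold: float = AUC_THRESHOLD,
    boyce_threshold: float = BOYCE_THRESHOLD,
) -> str:
    """Quadrant classification against the AUC and Boyce thresholds."""
    auc_ok = mean_auc > auc_threshold
    boyce_ok = not np.isnan(boyce) and boyce > boyce_threshold
    if auc_ok and boyce_ok:
        return "pass_both"
    if auc_ok:
        return "auc_only"
    if boyce_ok:
        return "boyce_only"
    return "fail_both"


@dataclass
class ValidationReport:
    """Cross-validation result for one species."""

    species_id: str
    fold_auc: list
    boyce: float
    n_presences: int
    auc_threshold: float = AUC_THRESHOLD
    boyce_threshold: float = BOYCE_THRESHOLD

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def flag(self) -> str:
        return quality_flags(self.mean_auc, self.boyce, self.auc_threshold, self.boyce_threshold)

    def maxent_results_frame(self) -> pd.DataFrame:
        """maxentResults.csv-style table: one row per fold plus the mean."""
        rows = [
            {"species": self.species_id, "replicate": i, "test_auc": a, "n_presences": self.n_presences}
            for i, a in enumerate(self.fold_auc)
        ]
        rows.append(
            {
                "species": self.species_id,
                "replicate": "mean",
                "test_auc": self.mean_auc,
                "n_presences": self.n_presences,
            }
        )
        return pd.DataFrame(rows)

    def boyce_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": self.species_id,
                    "boyce_index": self.boyce,
                    "flag": self.flag,
                }
            ]
        )

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.maxent_results_frame().to_csv(directory / "maxentResults.csv", index=False)
        self.boyce_frame().to_csv(directory / "boyce_index_score.csv", index=False)


def crossvalidate(
    presences: OccurrenceSet,
    background: BackgroundSet | np.ndarray,
    stack: EnvStack,
    config: FeatureConfig = FeatureConfig(),
    k: int = 10,
    seed: int = 0,
    boyce_windows: int = 101,
) -> tuple[ValidationReport, LambdaModel]:
    """k-fold cross-validation plus a final full-data refit.

    Presences are shuffled into k folds of near-equal size (differing by at
    most one); each fold is held out in turn, the model is fitted on the
    rest, and held-out presences are scored against the background to give a
    fold AUC.  The Boyce Index is computed from the final full-data model's
    presence scores against the whole-landscape score distribution.  If
    there are fewer presences than folds, k is reduced with a warning.
    """
    cells = presences.cell_index
    n = len(cells)
    if n < k:
        warnings.warn(f"only {n} presences; reducing folds from {k} to {n}")
        k = max(n, 2) if n >= 2 else 1
        k = min(k, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [order[i::k] for i in range(k)]
    fold_auc = []
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i]) if k > 1 else folds[i]
        model_i = fit_maxent(cells[train_idx], background, stack, config, species_id=presences.species_id)
        p_scores = model_i.score_cells(stack, cells[test_idx], output="raw")
        bcells = background.sample_cells if isinstance(background, BackgroundSet) else np.asarray(background)
        b_scores = model_i.score_cells(stack, bcells, output="raw")
        fold_auc.append(auc_presence_background(p_scores, b_scores))
    final = fit_maxent(presences, background, stack, config, species_id=presences.species_id)
    land_scores = final.score_cells(stack, stack.valid_cells, output="raw")
    pres_scores = final.score_cells(stack, cells, output="raw")
    bi = boyce_index(pres_scores, land_scores, n_windows=boyce_windows)
    report = ValidationReport(
        species_id=presences.species_id,
        fold_auc=fold_auc,
        boyce=bi,
        n_presences=n,
    )
    return report, final


# ---------------------------------------------------------------------------
# variable selection


@dataclass(frozen=True)
class SelectionRules:
    """Keep a variable iff it is statistically informative and simple.

    A variable is retained when (mean contribution >= c_min OR mean
    importance >= i_min) AND (its complexity class is "simple" OR it is
    whitelisted on ecological grounds).
    """

    c_min: float = 0.5
    i_min: float = 0.5
    whitelist: tuple = ("BIO15",)


def select_variables(
    contributions: pd.DataFrame,
    importances: pd.DataFrame,
    complexity: Mapping[str, str],
    rules: SelectionRules = SelectionRules(),
) -> pd.DataFrame:
    """Apply the contribution/importance/complexity selection procedure.

    ``contributions`` and ``importances`` are species x variable tables whose
    rows each sum to 100.  Returns a per-variable table with mean metrics,
    complexity class and the ``selected`` flag; raises if the rules would
    eliminate every variable.
    """
    if not contributions.columns.equals(importances.columns):
        raise ValueError("contribution and importance tables must share variables")
    for name, df in (("contribution", contributions), ("importance", importances)):
        sums = df.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=0.5):
            bad = sums[~np.isclose(sums, 100.0, atol=0.5)]
            raise ValueError(f"{name} rows must each sum to 100; offending rows: {list(bad.index)}")
    mean_c = contributions.mean(axis=0)
    mean_i = importances.mean(axis=0)
    rows = []
    for v in contributions.columns:
        cls = complexity.get(v, "simple")
        informative = (mean_c[v] >= rules.c_min) or (mean_i[v] >= rules.i_min)
        simple_ok = (cls == "simple") or (v in rules.whitelist)
        rows.append(
            {
                "variable": v,
                "mean_contribution": float(mean_c[v]),
                "mean_importance": float(mean_i[v]),
                "complexity": cls,
                "selected": bool(informative and simple_ok),
            }
        )
    table = pd.DataFrame(rows).set_index("variable")
    if not table["selected"].any():
        raise ValueError("selection rules eliminated every variable")
    return table
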