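"""Repeated random-split evaluation, calibration and variable importance.

The evaluation protocol: draw many independent random 90/10
training/test splits (splits may repeat), refit the model — including its
cross-validated tuning parameter — on every training set, predict the test
set, and average two figures of merit over the splits:

* Pearson correlation between observed and predicted peak forces
  (undefined when a fit degenerates to a constant predictor; such splits
  are excluded from the correlation average and counted), and
* nRMSE — root-mean-square error divided by the mean of the target over
  the *full* data set.

Because the correlation is occasionally undefined, nRMSE identifies the
best model/configuration.  Calibration is summarized by the least-squares
line of observed on predicted over a random subsample of pooled test
points.  Variable importance uses elastic-net inclusion frequencies and
standardized-coefficient effect-size ranks, and gain for the boosted trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import derive_seed
from .features import SENSOR_CONFIGURATIONS
from .models import (ElasticNetSpec, FittedModel, GbtSpec, fit_elastic_net,
                     fit_gbt, gain_importance, predict)

TARGETS = ("patella", "achilles")


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def nrmse(predicted, observed, full_data_mean: float) -> float:
    """RMSE normalized by the full-data mean of the dependent variable."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if full_data_mean <= 0:
        raise ValueError("full_data_mean must be strictly positive")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)) / full_data_mean)


def correlation(predicted, observed) -> Optional[float]:
    """Pearson correlation, or ``None`` when either vector is constant."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size < 2:
        raise ValueError("need at least two points for a correlation")
    if np.ptp(predicted) == 0.0 or np.ptp(observed) == 0.0:
        return None
    return float(np.corrcoef(predicted, observed)[0, 1])


# ---------------------------------------------------------------------------
# split-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    split_id: int
    correlation: Optional[float]    # None iff constant_predictor
    nrmse: float
    constant_predictor: bool
    lambda_: Optional[float] = None
    n_trees: Optional[int] = None
    enet_coef_std: Optional[np.ndarray] = None
    gbt_gain: Optional[dict] = None


@dataclass
class EvalSummary:
    mean_correlation: Optional[float]
    mean_nrmse: float
    n_splits: int
    n_undefined: int


def _fit_for_spec(X, y, spec, seed):
    if isinstance(spec, ElasticNetSpec):
        return fit_elastic_net(X, y, spec, seed)
    if isinstance(spec, GbtSpec):
        return fit_gbt(X, y, spec, seed)
    if hasattr(spec, "fit"):  # duck-typed baseline/oracle predictors
        return spec.fit(X, y, seed)
    raise TypeError(f"unknown model spec {type(spec).__name__}")


def repeated_split_eval(X: pd.DataFrame, y, spec, n_splits: int = 2500,
                        train_frac: float = 0.9, seed: int = 0,
                        collect_importance: bool = False) -> list:
    """Evaluate one model spec over repeated random 90/10 splits.

    Each split is drawn independently from the seeded stream (identical
    partitions may therefore recur); the model and its CV-chosen tuning
    parameter are refit on every training set.  ``collect_importance``
    additionally stores per-split standardized coefficients (elastic net)
    or gains (boosted trees) for the importance reports.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    if n_splits > 0 and n - n_train < 1:
        raise ValueError("test set would be empty")
    full_mean = float(y.mean())

    results = []
    for i in range(n_splits):
        rng = np.random.default_rng(derive_seed(seed, "split", i))
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        Xtr = X.iloc[train_idx] if isinstance(X, pd.DataFrame) else X[train_idx]
        Xte = X.iloc[test_idx] if isinstance(X, pd.DataFrame) else X[test_idx]
        model = _fit_for_spec(Xtr, y[train_idx], spec, derive_seed(seed, "fit", i))
        if isinstance(model, FittedModel):
            pred = np.asarray(predict(model, Xte), dtype=float)
        else:
            pred = np.asarray(model.predict(Xte), dtype=float)
        obs = y[test_idx]

        constant = bool(np.ptp(pred) == 0.0)
        corr = None if constant or np.ptp(obs) == 0.0 else correlation(pred, obs)
        res = SplitResult(
            split_id=i,
            correlation=corr,
            nrmse=nrmse(pred, obs, full_mean),
            constant_predictor=constant,
            lambda_=getattr(model, "lambda_", None),
            n_trees=getattr(model, "n_trees", None),
        )
        if collect_importance and isinstance(model, FittedModel):
            if model.family == "elastic_net":
                res.enet_coef_std = model.coef_std.copy()
            else:
                res.gbt_gain = gain_importance(model)
        results.append(res)
    return results


def summarize(results: list) -> EvalSummary:
    """Average split results; undefined correlations are excluded, counted."""
    n = len(results)
    defined = [r.correlation for r in results if r.correlation is not None]
    mean_corr = float(np.mean(defined)) if defined else None
    mean_nrmse = float(np.mean([r.nrmse for r in results])) if n else float("nan")
    return EvalSummary(mean_correlation=mean_corr, mean_nrmse=mean_nrmse,
                       n_splits=n, n_undefined=n - len(defined))


# ---------------------------------------------------------------------------
# grid evaluation and model selection
# ---------------------------------------------------------------------------

def default_model_grid() -> list:
    """The replication tuning grid: 3 elastic-net + 4 boosted-tree cells."""
    grid = [ElasticNetSpec(alpha=a) for a in (0.0, 0.5, 1.0)]
    grid += [GbtSpec(depth=d, learning_rate=lr)
             for d in (3, 6) for lr in (0.1, 0.3)]
    return grid


@dataclass(frozen=True)
class GridCell:
    target: str
    config_id: int
    family: str
    model_label: str

    @property
    def n_sites(self) -> int:
        return len(SENSOR_CONFIGURATIONS[self.config_id].sites)


def evaluate_grid(design_matrices: dict, model_grid: Optional[list] = None,
                  targets=TARGETS, n_splits: int = 2500,
                  train_frac: float = 0.9, seed: int = 0,
                  collect_importance: bool = False):
    """Run the full protocol: every model cell on every configuration/target.

    Parameters
    ----------
    design_matrices:
        ``config_id`` -> :class:`DesignMatrix` (all sharing trial order).
    model_grid:
        Model specs; defaults to the replication grid.

    Returns
    -------
    (table, details): a tidy DataFrame with one row per cell (mean
    correlation, mean nRMSE, undefined count) and a dict mapping
    :class:`GridCell` to the raw split results.
    """
    if model_grid is None:
        model_grid = default_model_grid()
    rows, details = [], {}
    for target in targets:
        for config_id, dm in sorted(design_matrices.items()):
            y = dm.targets[target].to_numpy()
            for spec in model_grid:
                family = "elastic_net" if isinstance(spec, ElasticNetSpec) else "gbt"
                cell_seed = derive_seed(seed, target, config_id, spec.label)
                results = repeated_split_eval(
                    dm.X, y, spec, n_splits=n_splits, train_frac=train_frac,
                    seed=cell_seed, collect_importance=collect_importance)
                summ = summarize(results)
                cell = GridCell(target=target, config_id=config_id,
                                family=family, model_label=spec.label)
                details[cell] = results
                rows.append({
                    "target": target,
                    "config_id": config_id,
                    "config": SENSOR_CONFIGURATIONS[config_id].label,
                    "family": family,
                    "model": spec.label,
                    "mean_correlation": summ.mean_correlation,
                    "mean_nrmse": summ.mean_nrmse,
                    "n_undefined": summ.n_undefined,
                    "n_splits": summ.n_splits,
                })
    return pd.DataFrame(rows), details


def select_best(table: pd.DataFrame) -> dict:
    """Best (model, configuration) per target by minimum mean nRMSE.

    Ties break toward fewer sensors, then the elastic net before boosting
    (fewer tuned parameters), then the table order.
    """
    if table.empty:
        raise ValueError("empty evaluation grid")
    best = {}
    fam_rank = {"elastic_net": 0, "gbt": 1}
    for target, sub in table.groupby("target"):
        sub = sub.copy()
        sub["_sites"] = sub["config_id"].map(
            lambda c: len(SENSOR_CONFIGURATIONS[c].sites))
        sub["_fam"] = sub["family"].map(fam_rank)
        sub = sub.sort_values(["mean_nrmse", "_sites", "_fam"],
                              kind="stable")
        best[target] = sub.iloc[0].drop(["_sites", "_fam"]).to_dict()
    return best


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    intercept: Optional[float]
    slope: Optional[float]
    indices: np.ndarray
    degenerate: bool = False


def calibration_stats(predicted, observed, subsample: int = 250,
                      seed: int = 0) -> CalibrationResult:
    """Least-squares line of observed on predicted over a random subsample.

    The identity line (intercept 0, slope 1) is the no-bias reference; the
    subsample keeps calibration scatter plots readable.  Degenerate
    predictor variance flags the result instead of raising.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size < subsample:
        raise ValueError("pooled data smaller than the requested subsample")
    rng = np.random.default_rng(seed)
    idx = rng.choice(predicted.size, size=subsample, replace=False)
    px, ox = predicted[idx], observed[idx]
    if np.ptp(px) == 0.0:
        return CalibrationResult(None, None, idx, degenerate=True)
    slope, intercept = np.polyfit(px, ox, 1)
    return CalibrationResult(float(intercept), float(slope), idx)


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    columns: list
    inclusion_frequency: Optional[np.ndarray] = None  # elastic net
    effect_size_rank: Optional[np.ndarray] = None     # elastic net
    mean_gain: Optional[np.ndarray] = None            # gbt
    gain_rank: Optional[np.ndarray] = None            # gbt
    below_10pct: list = field(default_factory=list)
    at_least_90pct: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        data = {"predictor": self.columns}
        for name in ("inclusion_frequency", "effect_size_rank",
                     "mean_gain", "gain_rank"):
            val = getattr(self, name)
            if val is not None:
                data[name] = val
        return pd.DataFrame(data)


def enet_importance(results: list, columns: list) -> ImportanceReport:
    """Inclusion frequencies and effect-size ranks from elastic-net splits.

    Effect sizes are |standardized coefficient| so ranks are scale-free;
    within each split, zeroed predictors share the worst (tied-average)
    rank.  Also lists predictors included in <10% and >=90% of splits.
    """
    coefs = [r.enet_coef_std for r in results if r.enet_coef_std is not None]
    if not coefs:
        raise ValueError("no elastic-net coefficient records in results")
    C = np.vstack(coefs)
    if C.shape[1] != len(columns):
        raise ValueError("coefficient records do not match the column schema")
    inclusion = (C != 0.0).mean(axis=0)
    ranks = np.vstack([rankdata(-np.abs(row), method="average") for row in C])
    mean_rank = ranks.mean(axis=0)
    return ImportanceReport(
        columns=list(columns),
        inclusion_frequency=inclusion,
        effect_size_rank=mean_rank,
        below_10pct=[c for c, f in zip(columns, inclusion) if f < 0.10],
        at_least_90pct=[c for c, f in zip(columns, inclusion) if f >= 0.90],
    )


def gbt_importance(results: list, columns: list) -> ImportanceReport:
    """Average gains and gain ranks from boosted-tree splits.

    Features never split on receive gain 0 (and thus the worst tied rank
    within their split).
    """
    gains = [r.gbt_gain for r in results if r.gbt_gain is not None]
    if not gains:
        raise ValueError("no boosted-tree gain records in results")
    G = np.array([[g.get(c, 0.0) for c in columns] for g in gains])
    if np.any(G < 0) or not np.all(np.isfinite(G)):
        raise ValueError("gains must be finite and non-negative")
    ranks = np.vstack([rankdata(-row, method="average") for row in G])
    return ImportanceReport(
        columns=list(columns),
        mean_gain=G.mean(axis=0),
        gain_rank=ranks.mean(axis=0),
    )
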