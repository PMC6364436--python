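"""Gradient-boosted decision-tree scorer, grid search, and importances.

The classifier is xgboost's regularized GBDT with a binary-logistic
objective.  The default hyperparameters are the AUPVR-optimal tuple
(eta 0.1, gamma 10, 30 rounds, depth 7, subsample 1, scale_pos_weight 1)
and the base score -- the model's prior before any trees -- is set to
the rSNP/cSNP count ratio of the training composition, which for a
heavily imbalanced reference set pulls the initial logit toward the
negative class.  Training is single-threaded by default so that scores
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .cv_eval import FoldAssignment, aupvr, avgrank
from .io import CompositionReport, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """xgboost hyperparameters; objective fixed to binary:logistic."""

    eta: float = 0.1
    gamma: float = 10.0
    nrounds: int = 30
    max_depth: int = 7
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    scale_pos_weight: float = 1.0
    base_score: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.eta <= 1):
            raise ValidationError("eta must be in (0, 1]")
        if self.nrounds < 1:
            raise ValidationError("nrounds must be >= 1")
        if not (0 < self.subsample <= 1 and 0 < self.colsample_bytree <= 1):
            raise ValidationError("subsample/colsample_bytree must be in (0, 1]")
        if not (0 < self.base_score < 1):
            raise ValidationError("base_score must be in (0, 1)")

    def xgb_params(self, seed: int, nthread: int = 1) -> dict:
        return {
            "booster": "gbtree",
            "objective": "binary:logistic",
            "eta": self.eta,
            "gamma": self.gamma,
            "max_depth": self.max_depth,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "scale_pos_weight": self.scale_pos_weight,
            "base_score": self.base_score,
            "seed": seed,
            "nthread": nthread,
        }


def default_config(
    composition: CompositionReport, mode: str = "count_ratio", **overrides
) -> ModelConfig:
    """AUPVR-optimal hyperparameters with a data-derived base score.

    ``mode='count_ratio'`` sets base_score = n_rsnp / n_csnp (the inverse
    class imbalance); ``mode='prevalence'`` uses n_rsnp / n_total.  A
    ratio >= 1 (balanced or rSNP-majority data) is clamped to 0.5 with a
    warning, since the base score is a probability.
    """
    if mode == "count_ratio":
        base = composition.inv_imbalance
    elif mode == "prevalence":
        base = composition.n_rsnp / composition.n_total
    else:
        raise ValueError(f"unknown base_score mode {mode!r}")
    if base >= 1.0:
        warnings.warn(
            f"base score {base:.4g} is not a valid probability; clamping to 0.5",
            stacklevel=2,
        )
        base = 0.5
    return ModelConfig(base_score=base, **overrides)


@dataclass
class Scorer:
    """A trained booster plus the training column order and loss history."""

    booster: xgb.Booster
    columns: tuple[str, ...]
    config: ModelConfig
    train_logloss: tuple[float, ...]


def _as_matrix(X: pd.DataFrame, columns: Optional[tuple[str, ...]] = None) -> np.ndarray:
    if not all(np.issubdtype(dt, np.number) for dt in X.dtypes):
        raise ValidationError("model input matrix must be fully numeric")
    if columns is not None:
        if set(X.columns) != set(columns):
            raise ValidationError("prediction matrix columns do not match training columns")
        X = X[list(columns)]
    return X.to_numpy(dtype=np.float64)


def train(
    X: pd.DataFrame,
    labels: Sequence[bool],
    config: ModelConfig,
    seed: int = 0,
    nthread: int = 1,
) -> Scorer:
    """Train the GBDT on a fully numeric matrix; deterministic when nthread=1."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("training requires both classes")
    mat = _as_matrix(X)
    dtrain = xgb.DMatrix(mat, label=y.astype(np.float64), feature_names=list(X.columns))
    evals_result: dict = {}
    booster = xgb.train(
        config.xgb_params(seed=seed, nthread=nthread),
        dtrain,
        num_boost_round=config.nrounds,
        evals=[(dtrain, "train")],
        evals_result=evals_result,
        verbose_eval=False,
    )
    history = tuple(float(v) for v in evals_result["train"]["logloss"])
    return Scorer(
        booster=booster,
        columns=tuple(X.columns),
        config=config,
        train_logloss=history,
    )


def predict(scorer: Scorer, X: pd.DataFrame) -> pd.Series:
    """Scores in (0, 1), row-aligned with X; columns realigned by name."""
    mat = _as_matrix(X, columns=scorer.columns)
    dmat = xgb.DMatrix(mat, feature_names=list(scorer.columns))
    scores = scorer.booster.predict(dmat)
    return pd.Series(np.asarray(scores, dtype=float), index=X.index, name="score")


def grid_from_mapping(grid: Mapping[str, Sequence]) -> list[ModelConfig]:
    """Expand a {param: [values]} mapping into the full Cartesian grid."""
    keys = list(grid)
    configs = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        configs.append(ModelConfig(**dict(zip(keys, combo))))
    return configs


def grid_search(
    configs: Sequence[ModelConfig],
    X: pd.DataFrame,
    labels: pd.Series,
    loci: pd.Series,
    folds: FoldAssignment,
    objective: str = "aupvr",
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustively evaluate each config by mean validation objective over folds.

    Maximizes AUPVR or minimizes AVGRANK.  Ties break by position in the
    given config sequence (deterministic).
    """
    if not configs:
        raise ValidationError("empty hyperparameter grid")
    if objective not in ("aupvr", "avgrank"):
        raise ValueError(f"objective must be 'aupvr' or 'avgrank', got {objective!r}")
    rows = []
    for ci, config in enumerate(configs):
        fold_vals = []
        for fold in range(folds.k):
            val_ids = folds.fold_snps(fold)
            train_ids = [s for s in X.index if folds.fold_of[s] != fold]
            scorer = train(X.loc[train_ids], labels.loc[train_ids], config, seed=seed)
            scores = predict(scorer, X.loc[val_ids])
            if objective == "aupvr":
                fold_vals.append(aupvr(scores, labels.loc[val_ids]))
            else:
                fold_vals.append(
                    avgrank(scores, labels.loc[val_ids], loci.loc[val_ids])
                )
        rows.append({"config_index": ci, objective: float(np.mean(fold_vals)), **asdict(config)})
    results = pd.DataFrame(rows)
    if objective == "aupvr":
        best_idx = int(results[objective].idxmax())
    else:
        best_idx = int(results[objective].idxmin())
    return configs[best_idx], results


def feature_importance(
    X: pd.DataFrame,
    labels: Sequence[bool],
    seed: int = 0,
    n_estimators: int = 200,
    n_permutations: int = 5,
) -> pd.DataFrame:
    """Random-forest Gini and permutation importances, each normalized to sum 1.

    A diagnostic, not part of the scoring pipeline: it ranks feature
    contributions (e.g. whether the geometric LLR columns outrank noise).
    """
    y = np.asarray(labels, dtype=bool)
    mat = _as_matrix(X)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(mat, y)
    gini = forest.feature_importances_.astype(float)
    perm = permutation_importance(
        forest, mat, y, n_repeats=n_permutations, random_state=seed, n_jobs=1
    ).importances_mean
    perm = np.clip(perm, 0.0, None)
    def _norm(v: np.ndarray) -> np.ndarray:
        total = v.sum()
        return v / total if total > 0 else np.full_like(v, 1.0 / v.size)
    return pd.DataFrame(
        {"gini": _norm(gini), "permutation": _norm(perm)}, index=X.columns
    )
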