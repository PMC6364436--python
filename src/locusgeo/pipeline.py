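"""End-to-end orchestration: the with/without-geometry comparison protocol.

For every replication and fold the pipeline (1) one-hot encodes the
table, (2) fits min-max scaling on the training rows only, (3) computes
the ten intralocus radius columns, (4) fits class-conditional radius
distributions on training SNPs only -- the leakage discipline: no
validation label or radius influences any fitted parameter -- (5)
converts radii to ten LLR feature columns for all SNPs, and (6) trains
two GBDT models on identical folds: the base feature matrix alone and
the base matrix plus the LLR block.  Validation AUPVR / AUROC / AVGRANK
are aggregated per replication with bootstrap CIs over replication
means.  Because loci never straddle folds, radii (a purely intralocus
quantity) carry no cross-fold information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cv_eval import EvalResult, aupvr, auroc, avgrank, replicate_folds
from .encoding import EncodedMatrix, apply_minmax, binary_encode, fit_minmax
from .geometry import all_radii
from .io import (
    RSNP,
    FeatureTable,
    SnpRecord,
    ValidationError,
    validate_dataset,
)
from .model import ModelConfig, default_config, predict, train
from .radius_stats import (
    default_families,
    fit_class_conditionals,
    llr_features,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Cross-validation and modelling knobs for one comparison run."""

    k: int = 5
    n_reps: int = 10
    base_seed: int = 0
    model: Optional[ModelConfig] = None  # None -> data-derived default
    families: Optional[Mapping[str, str]] = None  # None -> package defaults
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


@dataclass
class ComparisonResult:
    """Paired evaluation of base vs base+LLR models on identical folds."""

    base: EvalResult
    with_llr: EvalResult
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "with_llr": self.with_llr.to_dict(),
            "manifest": self.manifest,
        }


def compute_fold_features(
    encoded: EncodedMatrix,
    labels: pd.Series,
    loci: pd.Series,
    train_ids: Sequence[str],
    families: Optional[Mapping[str, str]] = None,
):
    """Leakage-disciplined per-fold geometric features.

    Returns (llr_block, fits, scaling): scaling is fitted on training
    rows only; radius distributions are fitted on training SNPs only;
    the LLR block covers all SNPs (training and validation alike).
    """
    scaling = fit_minmax(encoded, subset=train_ids, fit_subset="train")
    scaled = apply_minmax(encoded, scaling)
    radii = all_radii(encoded, scaled, loci)
    fits = fit_class_conditionals(
        radii, labels, families=families, fit_subset=pd.Index(train_ids)
    )
    block = llr_features(radii, fits)
    return block, fits, scaling


def _evaluate_fold(
    X: pd.DataFrame,
    labels: pd.Series,
    loci: pd.Series,
    train_ids: list[str],
    val_ids: list[str],
    config: ModelConfig,
    seed: int,
) -> dict[str, float]:
    scorer = train(X.loc[train_ids], labels.loc[train_ids] == RSNP, config, seed=seed)
    scores = predict(scorer, X.loc[val_ids])
    y_val = (labels.loc[val_ids] == RSNP).to_numpy()
    return {
        "aupvr": aupvr(scores, y_val),
        "auroc": auroc(scores, y_val),
        "avgrank": avgrank(scores, y_val, loci.loc[val_ids]),
    }


def run_comparison(
    table: FeatureTable,
    records: Sequence[SnpRecord],
    config: RunConfig,
) -> ComparisonResult:
    """The full protocol: both models on identical folds, replicated CV."""
    records = list(records)
    composition = validate_dataset(records)
    model_config = config.model or default_config(composition)
    families = dict(config.families) if config.families else default_families()

    labels = pd.Series({r.snp_id: r.label for r in records}).loc[table.snp_ids]
    loci = pd.Series({r.snp_id: r.locus_id for r in records}).loc[table.snp_ids]
    encoded = binary_encode(table)
    logger.info("encoded dimension: %d", encoded.n_dims)

    assignments = replicate_folds(records, config.k, config.n_reps, config.base_seed)
    rows_base, rows_llr = [], []
    for assignment in assignments:
        straddling = assignment.straddling_loci(records)
        if straddling:  # defensive: violated only by a bug in fold assignment
            raise ValidationError(f"loci straddle folds: {straddling[:5]}")
        for fold in range(assignment.k):
            val_ids = [s for s in table.snp_ids if assignment.fold_of[s] == fold]
            train_ids = [s for s in table.snp_ids if assignment.fold_of[s] != fold]
            block, _, _ = compute_fold_features(
                encoded, labels, loci, train_ids, families=families
            )
            X_base = encoded.data
            X_llr = pd.concat([encoded.data, block], axis=1)
            seed = config.base_seed * 10000 + assignment.replication_id * 100 + fold
            meta = {"replication": assignment.replication_id, "fold": fold}
            rows_base.append(
                meta | _evaluate_fold(X_base, labels, loci, train_ids, val_ids, model_config, seed)
            )
            rows_llr.append(
                meta | _evaluate_fold(X_llr, labels, loci, train_ids, val_ids, model_config, seed)
            )

    manifest = {
        "version": __version__,
        "k": config.k,
        "n_reps": config.n_reps,
        "base_seed": config.base_seed,
        "encoded_dimension": encoded.n_dims,
        "n_llr_features": 10,
        "model": {**model_config.__dict__},
        "composition": {
            "n_rsnp": composition.n_rsnp,
            "n_csnp": composition.n_csnp,
            "n_loci": composition.n_loci,
        },
    }
    return ComparisonResult(
        base=EvalResult(pd.DataFrame(rows_base), ci_seed=config.base_seed, n_boot=config.n_boot),
        with_llr=EvalResult(pd.DataFrame(rows_llr), ci_seed=config.base_seed, n_boot=config.n_boot),
        manifest=manifest,
    )


def grasp_filter(
    predictions: pd.DataFrame,
    associations: pd.DataFrame,
    p_max: float = 5e-8,
    score_min: float = 0.7,
) -> pd.DataFrame:
    """Join predictions with trait associations and keep strong candidates.

    Inner join on ``snp_id``; keep rows with association p-value strictly
    below ``p_max`` (genome-wide significance) and prediction score at
    least ``score_min``; sorted by descending score.
    """
    for df, cols in ((predictions, ("snp_id", "score")), (associations, ("snp_id", "pvalue"))):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"table missing required columns {missing}")
    joined = predictions.merge(associations[["snp_id", "pvalue"]], on="snp_id", how="inner")
    kept = joined[(joined["pvalue"] < p_max) & (joined["score"] >= score_min)]
    return kept.sort_values("score", ascending=False).reset_index(drop=True)
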