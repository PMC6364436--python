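"""Locus-coherent cross-validation and the three evaluation metrics.

Because the SNPs of one LD locus are near-duplicates in feature space,
folds are assigned at the locus level: an rSNP and all its linked cSNPs
always land in the same fold.  Loci are dealt to folds in serpentine
order after sorting by descending cSNP count (ties shuffled under the
seed), which balances both the per-fold SNP counts and class ratios.

Metrics: AUROC (Mann-Whitney normalization), AUPVR (average precision,
imbalance-sensitive), and AVGRANK -- the mean over loci of the
within-locus rank of the locus's regulatory SNP(s) when SNPs are sorted
by descending classifier score.  AVGRANK models the cost structure of
post-GWAS follow-up, where each locus is examined top-score-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import SnpRecord, ValidationError


@dataclass
class FoldAssignment:
    """Mapping of SNPs to folds for one replication; locus-coherent by construction."""

    replication_id: int
    k: int
    fold_of: dict[str, int]  # snp_id -> fold in 0..k-1
    seed: int

    def fold_snps(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]

    def straddling_loci(self, records: Sequence[SnpRecord]) -> list[str]:
        """Loci whose SNPs span more than one fold (must be empty)."""
        folds_per_locus: dict[str, set[int]] = {}
        for r in records:
            folds_per_locus.setdefault(r.locus_id, set()).add(self.fold_of[r.snp_id])
        return [loc for loc, fs in folds_per_locus.items() if len(fs) > 1]


def assign_folds(records: Sequence[SnpRecord], k: int, seed: int, replication_id: int = 0) -> FoldAssignment:
    """Deal loci to ``k`` folds, stratifying on per-locus cSNP count.

    Loci are sorted by descending cSNP count with ties shuffled under
    ``seed``, then dealt in serpentine order (0..k-1, k-1..0, ...); every
    SNP inherits its locus's fold.
    """
    if k < 2:
        raise ValidationError(f"need k >= 2 folds, got {k}")
    csnp_count: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    for r in records:
        members.setdefault(r.locus_id, []).append(r.snp_id)
        csnp_count[r.locus_id] = csnp_count.get(r.locus_id, 0) + (0 if r.is_rsnp else 1)
    loci = list(members)
    if len(loci) < k:
        raise ValidationError(f"only {len(loci)} loci for {k} folds")
    rng = np.random.default_rng(seed)
    rng.shuffle(loci)  # randomizes order within equal-count ties
    loci.sort(key=lambda loc: -csnp_count[loc])  # stable: tie order from shuffle
    pattern = list(range(k)) + list(range(k - 1, -1, -1))
    fold_of: dict[str, int] = {}
    for i, loc in enumerate(loci):
        fold = pattern[i % (2 * k)]
        for snp in members[loc]:
            fold_of[snp] = fold
    return FoldAssignment(replication_id=replication_id, k=k, fold_of=fold_of, seed=seed)


def replicate_folds(
    records: Sequence[SnpRecord], k: int, n_reps: int, base_seed: int
) -> list[FoldAssignment]:
    """Independent fold assignments with seeds base_seed + 0..n_reps-1."""
    return [
        assign_folds(records, k, seed=base_seed + rep, replication_id=rep)
        for rep in range(n_reps)
    ]


def _check_two_class(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValidationError("metric needs both classes present")


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve (ties earn half credit)."""
    labels = np.asarray(labels, dtype=bool)
    _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupvr(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision-recall curve (average precision)."""
    labels = np.asarray(labels, dtype=bool)
    if not labels.any():
        raise ValidationError("AUPVR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def avgrank(
    scores: Sequence[float], labels: Sequence[bool], loci: Sequence[str]
) -> float:
    """Mean over loci of the within-locus rank of the regulatory SNP(s).

    Within each locus, SNPs are ranked by descending score (tied scores
    receive their average rank); the locus value is the mean rank of its
    rSNP(s); singleton loci contribute rank 1.  Lower is better; a
    perfect scorer achieves 1.0.
    """
    df = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "label": np.asarray(labels, dtype=bool),
            "locus": list(loci),
        }
    )
    locus_values = []
    for _, grp in df.groupby("locus", sort=False):
        if not grp["label"].any():
            raise ValidationError("a locus without any rSNP has no AVGRANK contribution")
        ranks = stats.rankdata(-grp["score"].to_numpy(), method="average")
        locus_values.append(float(ranks[grp["label"].to_numpy()].mean()))
    return float(np.mean(locus_values))


def bootstrap_ci(
    values: Sequence[float], n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile 95% CI of the sample mean from ``n_boot`` resamples."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("bootstrap CI needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    low, high = np.percentile(means, [2.5, 97.5])
    return float(low), float(high)


@dataclass
class EvalResult:
    """Per-(replication, fold) metrics with bootstrap CIs on replication means."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    # rows columns: replication, fold, aupvr, auroc, avgrank
    ci_seed: int = 0
    n_boot: int = 1000

    METRICS = ("aupvr", "auroc", "avgrank")

    def replication_means(self) -> pd.DataFrame:
        return self.rows.groupby("replication")[list(self.METRICS)].mean()

    def summary(self) -> dict:
        reps = self.replication_means()
        out = {}
        for i, m in enumerate(self.METRICS):
            vals = reps[m].to_numpy()
            if vals.size >= 2:
                low, high = bootstrap_ci(vals, n_boot=self.n_boot, seed=self.ci_seed + i)
            else:
                low = high = float(vals[0])
            out[m] = {"mean": float(vals.mean()), "ci_low": low, "ci_high": high}
        return out

    def to_dict(self) -> dict:
        return {
            "per_fold": self.rows.to_dict(orient="records"),
            "summary": self.summary(),
        }
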