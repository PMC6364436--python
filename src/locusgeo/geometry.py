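"""Pairwise data-space distances and the intralocus radius.

For a SNP s with locus neighbourhood L(s), the intralocus radius under a
distance d is the average distance from s to every other SNP of its
locus:

    lambda(s | d) = 1 / (|L(s)| - 1) * sum_{s' in L(s), s' != s} d(s, s')

Five metrics are supported -- Canberra, Euclidean, Manhattan, cosine
(1 - cosine similarity) and Pearson (1 - sample correlation between the
two feature vectors) -- each on the unscaled and the min-max scaled
matrix, giving ten (metric, scaling) combinations.  Singleton loci
(|L(s)| = 1, a lone regulatory SNP) have no radius and are marked NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .encoding import EncodedMatrix

logger = logging.getLogger(__name__)

METRICS = ("canberra", "euclidean", "manhattan", "cosine", "pearson")

_SCIPY_NAME = {
    "canberra": "canberra",
    "euclidean": "euclidean",
    "manhattan": "cityblock",
    "cosine": "cosine",
    "pearson": "correlation",
}


@dataclass(frozen=True)
class DistanceSpec:
    """One of the ten admissible (metric, scaled) combinations."""

    metric: str
    scaled: bool

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def key(self) -> str:
        return f"{self.metric}_{'scaled' if self.scaled else 'unscaled'}"


ALL_SPECS: tuple[DistanceSpec, ...] = tuple(
    DistanceSpec(metric, scaled) for metric in METRICS for scaled in (False, True)
)


def pairwise_distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    """Distance between two feature vectors under one of the five metrics.

    Degenerate cases (zero-norm vector under cosine, zero-variance vector
    under Pearson) are assigned distance 1, i.e. similarity/correlation is
    treated as 0; a warning is emitted since genuinely constant encoded
    rows are pathological.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size == 0:
        raise ValueError("vectors must be 1-D, non-empty, and of equal length")
    if metric == "manhattan":
        return float(np.abs(u - v).sum())
    if metric == "euclidean":
        return float(np.sqrt(((u - v) ** 2).sum()))
    if metric == "canberra":
        num = np.abs(u - v)
        den = np.abs(u) + np.abs(v)
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return float(terms.sum())
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            warnings.warn("cosine distance of a zero-norm vector set to 1", stacklevel=2)
            return 1.0
        return float(1.0 - (u @ v) / (nu * nv))
    if metric == "pearson":
        uc, vc = u - u.mean(), v - v.mean()
        nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
        if nu == 0.0 or nv == 0.0:
            warnings.warn("pearson distance of a zero-variance vector set to 1", stacklevel=2)
            return 1.0
        return float(1.0 - (uc @ vc) / (nu * nv))
    raise ValueError(f"unknown metric {metric!r}")


def _locus_distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    """Full pairwise distance matrix for one locus's rows."""
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            condensed = pdist(X, metric=_SCIPY_NAME[metric])
    if np.isnan(condensed).any():
        # scipy yields NaN for degenerate cosine/correlation pairs; the
        # package convention treats similarity 0 -> distance 1
        logger.warning("degenerate %s distances within a locus set to 1", metric)
        condensed = np.where(np.isnan(condensed), 1.0, condensed)
    return squareform(condensed)


def _iter_loci(loci: Mapping[str, str] | pd.Series) -> Iterator[tuple[str, list[str]]]:
    series = pd.Series(dict(loci)) if not isinstance(loci, pd.Series) else loci
    for locus_id, members in series.groupby(series).groups.items():
        yield str(locus_id), list(members)


def intralocus_radius(
    matrix: EncodedMatrix, loci: Mapping[str, str] | pd.Series, metric: str
) -> pd.Series:
    """Per-SNP intralocus radius under one metric; NaN for singleton loci.

    ``loci`` maps snp_id -> locus_id.  For a scaled combination, pass
    the already-scaled matrix.
    """
    missing = [s for s in pd.Series(dict(loci)).index if s not in matrix.data.index]
    if missing:
        raise KeyError(f"SNPs missing from the encoded matrix: {missing[:5]}")
    radii = pd.Series(np.nan, index=matrix.data.index, dtype=float, name=metric)
    for _, members in _iter_loci(loci):
        if len(members) < 2:
            continue  # singleton locus: no radius
        X = matrix.data.loc[members].to_numpy()
        D = _locus_distance_matrix(X, metric)
        radii.loc[members] = D.sum(axis=1) / (len(members) - 1)
    return radii


def all_radii(
    matrix_unscaled: EncodedMatrix,
    matrix_scaled: EncodedMatrix,
    loci: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Radius table: one column per (metric, scaling) combination.

    Columns are named by ``DistanceSpec.key`` (e.g. ``pearson_scaled``);
    singleton-locus SNPs are NaN in every column.
    """
    if not matrix_unscaled.data.index.equals(matrix_scaled.data.index):
        raise ValueError("unscaled and scaled matrices are not row-aligned")
    columns = {}
    for spec in ALL_SPECS:
        matrix = matrix_scaled if spec.scaled else matrix_unscaled
        columns[spec.key] = intralocus_radius(matrix, loci, spec.metric)
    return pd.DataFrame(columns)
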