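"""Binary (one-hot) encoding of categorical features and min-max scaling.

Distances between SNP feature vectors are only meaningful on a fully
numeric matrix, so categorical annotations are expanded to one indicator
column per declared level (including levels unobserved in the data, so
that the encoded dimension is a function of the schema alone).  Min-max
scaling tames high-variance continuous annotations before the Canberra /
Euclidean / Manhattan distances; it is fitted on an explicit row subset
(the training fold, inside cross-validation) and applied without
clipping, so out-of-fit rows may fall outside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import FeatureTable, SchemaError, ValidationError


class EncodingError(ValueError):
    pass


@dataclass
class EncodedMatrix:
    """Numeric SNP-by-column matrix with per-column provenance.

    ``provenance`` maps each encoded column name to ``(source_feature,
    level)``; ``level`` is None for pass-through numeric columns.
    """

    data: pd.DataFrame  # float64, index = snp_id
    provenance: dict[str, tuple[str, Optional[str]]]

    @property
    def n_dims(self) -> int:
        return self.data.shape[1]

    def subset(self, snp_ids: Sequence[str]) -> "EncodedMatrix":
        return EncodedMatrix(self.data.loc[list(snp_ids)], dict(self.provenance))


def binary_encode(table: FeatureTable) -> EncodedMatrix:
    """Expand a typed feature table into a fully numeric matrix.

    Continuous and integer columns pass through unchanged (as float64);
    each categorical column becomes ``|levels|`` 0/1 indicator columns
    named ``<feature>=<level>``, in declared level order.  Column order
    follows the source-feature order of the schema.
    """
    blocks: list[pd.DataFrame] = []
    provenance: dict[str, tuple[str, Optional[str]]] = {}
    for name, spec in table.schema.items():
        col = table.data[name]
        if spec.kind in ("continuous", "integer"):
            blocks.append(col.astype(np.float64).to_frame(name))
            provenance[name] = (name, None)
        else:
            values = col.astype(str)
            bad = set(values) - set(spec.levels)
            if bad:
                raise EncodingError(
                    f"column {name!r}: values outside declared levels: {sorted(bad)}"
                )
            indicators = {}
            for level in spec.levels:
                cname = f"{name}={level}"
                indicators[cname] = (values == level).astype(np.float64)
                provenance[cname] = (name, level)
            blocks.append(pd.DataFrame(indicators, index=table.data.index))
    data = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=table.data.index)
    return EncodedMatrix(data=data, provenance=provenance)


@dataclass
class ScalingParams:
    """Per-column (min, max) fitted on a stated subset of rows."""

    minima: pd.Series
    maxima: pd.Series
    fit_subset: str = "all"

    def __post_init__(self) -> None:
        if not self.minima.index.equals(self.maxima.index):
            raise ValidationError("min/max column indices disagree")
        if (self.minima > self.maxima).any():
            raise ValidationError("per-column min exceeds max")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "fit_subset": self.fit_subset,
            "columns": {
                c: {"min": float(self.minima[c]), "max": float(self.maxima[c])}
                for c in self.minima.index
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScalingParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cols = doc["columns"]
        return cls(
            minima=pd.Series({c: v["min"] for c, v in cols.items()}, dtype=float),
            maxima=pd.Series({c: v["max"] for c, v in cols.items()}, dtype=float),
            fit_subset=doc.get("fit_subset", "unknown"),
        )


def fit_minmax(
    matrix: EncodedMatrix, subset: Optional[Sequence[str]] = None, fit_subset: str = "all"
) -> ScalingParams:
    """Column minima/maxima over ``subset`` rows (all rows when None)."""
    rows = matrix.data if subset is None else matrix.data.loc[list(subset)]
    if rows.shape[0] == 0:
        raise ValidationError("cannot fit min-max scaling on an empty subset")
    return ScalingParams(minima=rows.min(axis=0), maxima=rows.max(axis=0), fit_subset=fit_subset)


def apply_minmax(matrix: EncodedMatrix, params: ScalingParams) -> EncodedMatrix:
    """Map x to (x - min) / (max - min) columnwise, without clipping.

    Constant columns (max == min) map to 0 everywhere.  Rows outside the
    fit subset may produce values outside [0, 1]; they are transformed by
    the same affine formula.
    """
    if list(matrix.data.columns) != list(params.minima.index):
        raise SchemaError("scaling parameters do not match matrix columns")
    span = (params.maxima - params.minima).to_numpy()
    shifted = matrix.data.to_numpy() - params.minima.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(span > 0, shifted / np.where(span > 0, span, 1.0), 0.0)
    return EncodedMatrix(
        data=pd.DataFrame(scaled, index=matrix.data.index, columns=matrix.data.columns),
        provenance=dict(matrix.provenance),
    )
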