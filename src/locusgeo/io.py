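"""Data model and delimited-text I/O for locus-grouped SNP feature tables.

A dataset is a TSV file with key columns ``snp_id``, ``locus_id``,
``label`` (literal ``rSNP`` or ``cSNP``) followed by annotation feature
columns, plus a YAML sidecar schema declaring each feature column as
``continuous``, ``integer`` or ``categorical`` (with its closed level
set).  SNPs sharing a ``locus_id`` are in linkage disequilibrium with a
shared regulatory SNP and form the grouping unit for cross-validation
and for the intralocus radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

RSNP = "rSNP"
CSNP = "cSNP"
KEY_COLUMNS = ("snp_id", "locus_id", "label")


class SchemaError(ValueError):
    """A column declaration is missing, malformed, or inconsistent."""


class ValidationError(ValueError):
    """Table contents violate a dataset invariant."""


class DegenerateDatasetError(ValueError):
    """A dataset lacks one of the two classes; composition ratios are undefined."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP: identifier, LD-locus membership, class label, optional coordinate.

    ``coord`` is a ``(chromosome, position)`` pair with 1-based inclusive
    positions; no computation in this package uses it, it is carried for
    provenance only.
    """

    snp_id: str
    locus_id: str
    label: str
    coord: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.label not in (RSNP, CSNP):
            raise ValidationError(
                f"label for {self.snp_id!r} must be {RSNP!r} or {CSNP!r}, got {self.label!r}"
            )

    @property
    def is_rsnp(self) -> bool:
        return self.label == RSNP


@dataclass(frozen=True)
class ColumnSpec:
    """Declared type of one feature column."""

    kind: str  # continuous | integer | categorical
    levels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer", "categorical"):
            raise SchemaError(f"unknown column kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise SchemaError("categorical column requires a non-empty level set")
        if self.kind != "categorical" and self.levels is not None:
            raise SchemaError(f"{self.kind} column must not declare levels")


@dataclass
class FeatureTable:
    """Typed, ordered SNP-by-feature table.

    ``data`` is indexed by ``snp_id`` in file order; ``schema`` maps each
    feature column name to its :class:`ColumnSpec`, in column order.
    """

    data: pd.DataFrame
    schema: dict[str, ColumnSpec]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate snp_id values: {dupes}")
        missing = [c for c in self.schema if c not in self.data.columns]
        if missing:
            raise SchemaError(f"schema declares absent columns: {missing}")
        extra = [c for c in self.data.columns if c not in self.schema]
        if extra:
            raise SchemaError(f"columns missing from schema: {extra}")
        for name, spec in self.schema.items():
            col = self.data[name]
            if spec.kind == "categorical":
                bad = set(col.astype(str)) - set(spec.levels)
                if bad:
                    raise ValidationError(
                        f"column {name!r} has values outside declared levels: {sorted(bad)}"
                    )
            else:
                if col.isna().any():
                    raise ValidationError(f"column {name!r} has missing values")

    @property
    def snp_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def n_features(self) -> int:
        return len(self.schema)

    def subset(self, snp_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(snp_ids)], dict(self.schema))


@dataclass(frozen=True)
class CompositionReport:
    """Class and locus composition of a dataset."""

    n_rsnp: int
    n_csnp: int
    n_total: int
    imbalance: float  # cSNP / rSNP
    inv_imbalance: float  # rSNP / cSNP
    n_loci: int
    locus_size_min: int
    locus_size_median: float
    locus_size_max: int


def validate_dataset(records: Iterable[SnpRecord]) -> CompositionReport:
    """Count classes and loci and compute the class-imbalance ratios.

    Raises :class:`DegenerateDatasetError` when either class is absent,
    since the cSNP/rSNP ratio (and the classifier's base score derived
    from its inverse) would be undefined.
    """
    records = list(records)
    n_rsnp = sum(r.is_rsnp for r in records)
    n_csnp = len(records) - n_rsnp
    if n_rsnp == 0 or n_csnp == 0:
        raise DegenerateDatasetError(
            f"dataset needs both classes (got {n_rsnp} rSNP, {n_csnp} cSNP)"
        )
    sizes = pd.Series([r.locus_id for r in records]).value_counts()
    return CompositionReport(
        n_rsnp=n_rsnp,
        n_csnp=n_csnp,
        n_total=len(records),
        imbalance=n_csnp / n_rsnp,
        inv_imbalance=n_rsnp / n_csnp,
        n_loci=len(sizes),
        locus_size_min=int(sizes.min()),
        locus_size_median=float(sizes.median()),
        locus_size_max=int(sizes.max()),
    )


def _schema_from_mapping(mapping: dict) -> dict[str, ColumnSpec]:
    schema: dict[str, ColumnSpec] = {}
    for name, decl in mapping.items():
        if isinstance(decl, str):
            schema[name] = ColumnSpec(kind=decl)
        else:
            levels = decl.get("levels")
            schema[name] = ColumnSpec(
                kind=decl["type"], levels=tuple(map(str, levels)) if levels else None
            )
    return schema


def read_schema(path: str | Path) -> dict[str, ColumnSpec]:
    """Read a YAML sidecar schema (``columns:`` mapping of name -> type decl)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "columns" not in doc:
        raise SchemaError(f"{path}: schema file must contain a 'columns' mapping")
    return _schema_from_mapping(doc["columns"])


def write_schema(schema: dict[str, ColumnSpec], path: str | Path) -> None:
    doc = {
        "columns": {
            name: (
                {"type": spec.kind, "levels": list(spec.levels)}
                if spec.kind == "categorical"
                else {"type": spec.kind}
            )
            for name, spec in schema.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_feature_table(
    path: str | Path, schema: dict[str, ColumnSpec]
) -> tuple[FeatureTable, list[SnpRecord]]:
    """Read a TSV feature table, validating it against ``schema``.

    Row order is the file order and is preserved throughout the pipeline.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "locus_id": str, "label": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required key columns {missing}")
    records = [
        SnpRecord(snp_id=row.snp_id, locus_id=row.locus_id, label=row.label)
        for row in df[list(KEY_COLUMNS)].itertuples(index=False)
    ]
    feats = df.drop(columns=list(KEY_COLUMNS)).set_axis(df["snp_id"], axis=0)
    feats.index.name = "snp_id"
    for name, spec in schema.items():
        if spec.kind == "categorical":
            feats[name] = feats[name].astype(str)
        else:
            feats[name] = pd.to_numeric(feats[name])
    table = FeatureTable(feats, dict(schema))
    return table, records


def write_feature_table(
    table: FeatureTable, records: Sequence[SnpRecord], path: str | Path
) -> None:
    """Write table + records back to TSV (inverse of :func:`read_feature_table`)."""
    by_id = {r.snp_id: r for r in records}
    out = table.data.copy()
    out.insert(0, "locus_id", [by_id[s].locus_id for s in table.snp_ids])
    out.insert(1, "label", [by_id[s].label for s in table.snp_ids])
    out.to_csv(path, sep="\t", index=True, index_label="snp_id")


def write_predictions(scores: pd.DataFrame, path: str | Path) -> None:
    """Write per-SNP scores as TSV with columns snp_id, locus_id, label, score."""
    required = ["snp_id", "locus_id", "label", "score"]
    missing = [c for c in required if c not in scores.columns]
    if missing:
        raise ValidationError(f"prediction table missing columns {missing}")
    scores[required].to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "locus_id": str, "label": str})


def write_metrics(result, path: str | Path) -> None:
    """Serialize an evaluation result (any object with ``to_dict``) as JSON."""
    doc = result.to_dict() if hasattr(result, "to_dict") else result
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
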