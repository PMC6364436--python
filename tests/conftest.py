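import numpy as np
import pandas as pd
import pytest

from locusgeo import synth
from locusgeo.io import CSNP, RSNP, ColumnSpec, FeatureTable, SnpRecord


@pytest.fixture(scope="session")
def small_dataset():
    """Geometry-biased synthetic dataset shared by read-only tests."""
    config = synth.SyntheticConfig(
        n_loci=50, csnp_mean=8.0, rsnp_displacement=3.0, cloud_sd=1.0, seed=11
    )
    return synth.generate(config)


@pytest.fixture(scope="session")
def null_dataset():
    """No displacement, no signal: radii carry no class information."""
    config = synth.SyntheticConfig(
        n_loci=50, csnp_mean=8.0, rsnp_displacement=0.0, cloud_sd=1.0, seed=12
    )
    return synth.generate(config)


@pytest.fixture
def tiny_table():
    """Hand-built 2-locus table with one categorical feature."""
    records = [
        SnpRecord("rs1", "locA", RSNP),
        SnpRecord("rs2", "locA", CSNP),
        SnpRecord("rs3", "locA", CSNP),
        SnpRecord("rs4", "locB", RSNP),
        SnpRecord("rs5", "locB", CSNP),
    ]
    data = pd.DataFrame(
        {
            "f1": [0.0, 1.0, 2.0, 10.0, 12.0],
            "f2": [5.0, 5.5, 4.5, -1.0, -2.0],
            "cat": ["A", "B", "A", "C", "A"],
        },
        index=pd.Index([r.snp_id for r in records], name="snp_id"),
    )
    schema = {
        "f1": ColumnSpec("continuous"),
        "f2": ColumnSpec("continuous"),
        "cat": ColumnSpec("categorical", levels=("A", "B", "C")),
    }
    return FeatureTable(data, schema), records


def locus_series(records):
    return pd.Series({r.snp_id: r.locus_id for r in records})


def label_series(records):
    return pd.Series({r.snp_id: r.label for r in records})
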