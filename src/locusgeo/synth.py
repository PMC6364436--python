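"""Synthetic locus-structured SNP data with known geometric structure.

The generator emulates the structure a locus-grouped reference SNP set
presents to this pipeline: each LD locus is a "cloud" in feature space
-- a centroid plus Gaussian within-locus dispersion -- holding exactly
one regulatory SNP (rSNP) and a negative-binomially distributed number
of control SNPs (cSNPs), mean ~14.5, matching the ~14.5:1 class
imbalance of curated reference sets.  The rSNP may be displaced radially
from the centroid (``rsnp_displacement``), which is precisely the
class-conditional radius bias the geometric LLR features are designed to
detect; a fraction of loci are singletons (a lone rSNP), exercising the
likelihood-ratio = 1 rule.  Optional "signal" columns carry a direct
mean shift for rSNPs, and categorical columns are drawn with
within-locus concordance.  It emulates geometry only: none of the
population-genetic structure of real annotation data (LD decay, allele
frequencies, feature semantics) is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CSNP, RSNP, ColumnSpec, FeatureTable, SnpRecord, ValidationError


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; the defaults emulate the target study conditions.

    ``csnp_mean``/``csnp_dispersion`` parameterize a shifted negative
    binomial (minimum 1) for per-locus cSNP counts; ``cloud_sd`` is the
    within-locus Gaussian dispersion per continuous feature;
    ``rsnp_displacement`` is the radial offset of the rSNP from its locus
    centroid in the continuous subspace (0 = geometric null);
    ``signal_features`` continuous columns additionally shift their mean
    by ``signal_effect`` for rSNPs, giving directly class-discriminative
    signal independent of geometry.
    """

    n_loci: int = 200
    csnp_mean: float = 14.5
    csnp_dispersion: float = 8.0
    singleton_fraction: float = 0.05
    n_continuous: int = 20
    cat_levels: tuple[int, ...] = (2, 3, 4, 6)
    centroid_sd: float = 3.0
    cloud_sd: float = 1.0
    rsnp_displacement: float = 0.0
    cat_concordance: float = 0.8
    signal_features: int = 0
    signal_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValidationError("need at least one locus")
        if self.cloud_sd <= 0:
            raise ValidationError("cloud_sd must be positive")
        if not (0 <= self.singleton_fraction < 1):
            raise ValidationError("singleton_fraction must be in [0, 1)")
        if self.n_continuous < 1:
            raise ValidationError("need at least one continuous feature")


@dataclass
class GroundTruth:
    """Generator bookkeeping for downstream tests and audits."""

    n_rsnp: int
    n_csnp: int
    n_loci: int
    singleton_loci: list[str]
    csnp_counts: dict[str, int]
    rsnp_displacement: float
    cloud_sd: float
    config: dict = field(default_factory=dict)


def _csnp_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-locus cSNP counts: 0 for singleton loci, else 1 + NB(r, p)."""
    n = config.n_loci
    singleton = rng.random(n) < config.singleton_fraction
    r = config.csnp_dispersion
    m = max(config.csnp_mean - 1.0, 0.1)  # mean of the NB part after the +1 shift
    p = r / (r + m)
    counts = 1 + rng.negative_binomial(r, p, size=n)
    counts[singleton] = 0
    if (counts > 0).sum() == 0 and n > 0:
        counts[0] = max(1, int(round(config.csnp_mean)))  # guarantee both classes
    return counts


def generate(config: SyntheticConfig) -> tuple[FeatureTable, list[SnpRecord], GroundTruth]:
    """Draw a locus-structured dataset; bit-reproducible under config.seed."""
    rng = np.random.default_rng(config.seed)
    counts = _csnp_counts(config, rng)
    n_cont = config.n_continuous + config.signal_features
    cont_names = [f"cont_{i:02d}" for i in range(config.n_continuous)] + [
        f"sig_{i:02d}" for i in range(config.signal_features)
    ]
    cat_names = [f"cat_{i:02d}" for i in range(len(config.cat_levels))]

    rows = []
    records: list[SnpRecord] = []
    singleton_loci: list[str] = []
    csnp_counts: dict[str, int] = {}
    snp_serial = 0
    for li in range(config.n_loci):
        locus_id = f"locus_{li:04d}"
        n_csnp_here = int(counts[li])
        csnp_counts[locus_id] = n_csnp_here
        if n_csnp_here == 0:
            singleton_loci.append(locus_id)
        centroid = rng.normal(0.0, config.centroid_sd, size=n_cont)
        cat_dominant = [rng.integers(k) for k in config.cat_levels]
        labels = [RSNP] + [CSNP] * n_csnp_here
        for label in labels:
            snp_id = f"rs{snp_serial:06d}"
            snp_serial += 1
            vec = centroid + rng.normal(0.0, config.cloud_sd, size=n_cont)
            if label == RSNP and config.rsnp_displacement > 0:
                direction = rng.normal(size=n_cont)
                direction /= np.linalg.norm(direction)
                vec = vec + config.rsnp_displacement * direction
            if label == RSNP and config.signal_features > 0:
                vec[config.n_continuous :] += config.signal_effect
            cats = []
            for dom, k in zip(cat_dominant, config.cat_levels):
                if rng.random() < config.cat_concordance:
                    cats.append(f"L{dom}")
                else:
                    cats.append(f"L{rng.integers(k)}")
            rows.append([snp_id, *vec, *cats])
            records.append(SnpRecord(snp_id=snp_id, locus_id=locus_id, label=label))

    columns = ["snp_id", *cont_names, *cat_names]
    df = pd.DataFrame(rows, columns=columns).set_index("snp_id")
    for name in cont_names:
        df[name] = df[name].astype(float)
    schema: dict[str, ColumnSpec] = {n: ColumnSpec(kind="continuous") for n in cont_names}
    for name, k in zip(cat_names, config.cat_levels):
        schema[name] = ColumnSpec(
            kind="categorical", levels=tuple(f"L{j}" for j in range(k))
        )
    table = FeatureTable(df, schema)
    n_rsnp = sum(r.is_rsnp for r in records)
    truth = GroundTruth(
        n_rsnp=n_rsnp,
        n_csnp=len(records) - n_rsnp,
        n_loci=config.n_loci,
        singleton_loci=singleton_loci,
        csnp_counts=csnp_counts,
        rsnp_displacement=config.rsnp_displacement,
        cloud_sd=config.cloud_sd,
        config=asdict(config),
    )
    return table, records, truth


GWS_THRESHOLD = 5e-8  # genome-wide significance


def make_association_table(
    records: Sequence[SnpRecord],
    n_significant: int = 0,
    seed: int = 0,
    significant_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-SNP trait-association p-values, a chosen subset genome-wide significant.

    Non-significant SNPs draw p uniformly on [1e-6, 1]; the designated
    significant SNPs draw p uniformly on [1e-12, 5e-8).  Used as a
    fixture for the significance-and-score join filter.
    """
    rng = np.random.default_rng(seed)
    ids = [r.snp_id for r in records]
    if significant_ids is None:
        if n_significant > len(ids):
            raise ValidationError("more significant SNPs requested than SNPs present")
        significant_ids = list(rng.choice(ids, size=n_significant, replace=False))
    sig = set(significant_ids)
    pvals = [
        float(rng.uniform(1e-12, GWS_THRESHOLD * 0.999))
        if s in sig
        else float(rng.uniform(1e-6, 1.0))
        for s in ids
    ]
    return pd.DataFrame({"snp_id": ids, "pvalue": pvals})
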