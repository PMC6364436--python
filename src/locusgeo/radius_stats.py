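"""Class-conditional statistics of intralocus radii and the LLR features.

The discriminative signal exploited here is that regulatory SNPs sit at
a different typical distance from their locus neighbours than control
SNPs do.  Radii are split by class, summarised (moments, kernel
densities, binned empirical log-likelihood ratios), modelled
parametrically (normal for cosine/Pearson radii, log-normal for the
rest, chosen by AIC), and each SNP's radius is converted to a
log-likelihood ratio ln p_r(lambda) - ln p_c(lambda) under the fitted
class-conditional densities.  Ten such LLR columns (5 metrics x
scaled/unscaled) are appended to the base feature table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ALL_SPECS
from .io import RSNP, FeatureTable, ColumnSpec, ValidationError

logger = logging.getLogger(__name__)

LLR_PREFIX = "LLR_"
LLR_CLAMP = 50.0  # nats; far-tail radii under training-fold fits stay finite
DEFAULT_BINS = 11


@dataclass
class RadiusClassSets:
    """Radii of one (metric, scaling) combination partitioned by class."""

    rsnp: np.ndarray
    csnp: np.ndarray


def split_by_class(radii: pd.Series, labels: pd.Series) -> RadiusClassSets:
    """Partition finite radii by the SNP class label (NaN = singleton, dropped)."""
    labels = labels.loc[radii.index]
    finite = radii.notna()
    is_r = labels == RSNP
    return RadiusClassSets(
        rsnp=radii[finite & is_r].to_numpy(float),
        csnp=radii[finite & ~is_r].to_numpy(float),
    )


def radius_moments(samples: np.ndarray) -> tuple[float, float]:
    """Sample skewness g1 = m3/m2^(3/2) and raw kurtosis m4/m2^2.

    Kurtosis is reported raw (normal -> 3, not excess), matching the
    moments convention of the R fitting ecosystem.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 3:
        raise ValidationError("moments need at least 3 samples")
    if np.ptp(samples) == 0:
        raise ValidationError("moments undefined for zero-variance samples")
    skew = float(stats.skew(samples, bias=True))
    kurt = float(stats.kurtosis(samples, fisher=False, bias=True))
    return skew, kurt


def radius_density(samples: np.ndarray) -> stats.gaussian_kde:
    """Gaussian kernel density estimate with Scott's plug-in bandwidth."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValidationError("density estimation needs at least 2 samples")
    if np.ptp(samples) == 0:
        raise ValidationError("density undefined for constant samples")
    return stats.gaussian_kde(samples)


@dataclass
class EmpiricalLlr:
    """Binned empirical log-likelihood ratio diagnostic.

    ``llr`` holds, per bin, ln[(N_r/sum N_r) / (N_c/sum N_c)] in the
    default normalized mode, or ln(N_r/N_c) in raw mode (the plain count
    ratio, which embeds the class imbalance as a constant offset).  Bins
    where either class count is zero receive a +0.5 pseudocount on both
    classes and are flagged.
    """

    edges: np.ndarray
    counts_rsnp: np.ndarray
    counts_csnp: np.ndarray
    llr: np.ndarray
    mode: str
    pseudocount_bins: np.ndarray  # bool flags


def empirical_llr(
    sets: RadiusClassSets, n_bins: int = DEFAULT_BINS, mode: str = "normalized"
) -> EmpiricalLlr:
    """Equal-width binned LLRs over the pooled radius range."""
    if mode not in ("normalized", "raw"):
        raise ValueError(f"mode must be 'normalized' or 'raw', got {mode!r}")
    if sets.rsnp.size == 0 or sets.csnp.size == 0:
        raise ValidationError("empirical LLR needs radii from both classes")
    pooled = np.concatenate([sets.rsnp, sets.csnp])
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    n_r, _ = np.histogram(sets.rsnp, bins=edges)
    n_c, _ = np.histogram(sets.csnp, bins=edges)
    flagged = (n_r == 0) | (n_c == 0)
    r = n_r + np.where(flagged, 0.5, 0.0)
    c = n_c + np.where(flagged, 0.5, 0.0)
    if mode == "normalized":
        llr = np.log((r / r.sum()) / (c / c.sum()))
    else:
        llr = np.log(r / c)
    return EmpiricalLlr(
        edges=edges,
        counts_rsnp=n_r,
        counts_csnp=n_c,
        llr=llr,
        mode=mode,
        pseudocount_bins=flagged,
    )


@dataclass
class RadiusDistFit:
    """Maximum-likelihood parametric model of one class's radii.

    ``mu``/``sigma`` are the location/scale on the natural scale for the
    normal family and on the log scale for the log-normal family.  MLE
    uses the divisor-n variance, consistent with the AIC likelihood.
    """

    spec_key: str
    label: str
    family: str  # normal | lognormal
    mu: float
    sigma: float
    aic: float
    n: int

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "normal":
            return stats.norm.logpdf(x, loc=self.mu, scale=self.sigma)
        return stats.lognorm.logpdf(x, s=self.sigma, scale=math.exp(self.mu))

    def to_dict(self) -> dict:
        return {
            "spec": self.spec_key,
            "label": self.label,
            "family": self.family,
            "mu": self.mu,
            "sigma": self.sigma,
            "aic": self.aic,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RadiusDistFit":
        return cls(
            spec_key=doc["spec"],
            label=doc["label"],
            family=doc["family"],
            mu=float(doc["mu"]),
            sigma=float(doc["sigma"]),
            aic=float(doc["aic"]),
            n=int(doc["n"]),
        )


def fit_radius_distribution(
    samples: np.ndarray, family: str, spec_key: str = "", label: str = ""
) -> RadiusDistFit:
    """Fit a normal or log-normal model by maximum likelihood.

    Log-normal fits require strictly positive samples; non-positive
    values are replaced by epsilon = (smallest positive sample) * 1e-3,
    with a log message.  AIC = 2k - 2 ln L with k = 2.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ValidationError(f"need >= 10 samples to fit, got {samples.size}")
    if np.ptp(samples) == 0:
        raise ValidationError("cannot fit a scale family to identical samples")
    if family == "normal":
        mu = float(samples.mean())
        sigma = float(samples.std(ddof=0))
        loglik = float(stats.norm.logpdf(samples, loc=mu, scale=sigma).sum())
    elif family == "lognormal":
        if (samples <= 0).any():
            positive = samples[samples > 0]
            if positive.size == 0:
                raise ValidationError("lognormal fit needs at least one positive sample")
            eps = positive.min() * 1e-3
            n_repl = int((samples <= 0).sum())
            logger.info("lognormal fit: replaced %d non-positive radii by %.3g", n_repl, eps)
            samples = np.where(samples <= 0, eps, samples)
        logs = np.log(samples)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=0))
        if sigma == 0:
            raise ValidationError("cannot fit a scale family to identical samples")
        loglik = float(stats.lognorm.logpdf(samples, s=sigma, scale=math.exp(mu)).sum())
    else:
        raise ValueError(f"unknown family {family!r}")
    aic = 2 * 2 - 2 * loglik
    return RadiusDistFit(
        spec_key=spec_key, label=label, family=family, mu=mu, sigma=sigma, aic=aic,
        n=int(samples.size),
    )


def select_family_by_aic(samples: np.ndarray) -> str:
    """Diagnostic AIC-based family choice between normal and log-normal."""
    fits = {f: fit_radius_distribution(samples, f) for f in ("normal", "lognormal")}
    return min(fits, key=lambda f: fits[f].aic)


def default_families() -> dict[str, str]:
    """Family per (metric, scaling) combination.

    Cosine and Pearson radii (bounded, roughly symmetric) use the normal
    family; the unbounded, right-skewed Canberra/Euclidean/Manhattan
    radii use the log-normal family.
    """
    return {
        spec.key: ("normal" if spec.metric in ("cosine", "pearson") else "lognormal")
        for spec in ALL_SPECS
    }


def fit_class_conditionals(
    radii: pd.DataFrame,
    labels: pd.Series,
    families: Optional[Mapping[str, str]] = None,
    fit_subset: Optional[pd.Index] = None,
) -> dict[str, tuple[RadiusDistFit, RadiusDistFit]]:
    """Fit (rSNP, cSNP) radius models for every radius column.

    ``fit_subset`` restricts estimation to the given SNPs (the training
    fold inside cross-validation, to avoid leaking validation radii into
    the density parameters).
    """
    families = dict(families) if families is not None else default_families()
    subset = radii if fit_subset is None else radii.loc[fit_subset]
    fits: dict[str, tuple[RadiusDistFit, RadiusDistFit]] = {}
    for key in radii.columns:
        sets = split_by_class(subset[key], labels)
        family = families[key]
        fits[key] = (
            fit_radius_distribution(sets.rsnp, family, spec_key=key, label="rSNP"),
            fit_radius_distribution(sets.csnp, family, spec_key=key, label="cSNP"),
        )
    return fits


def llr_features(
    radii: pd.DataFrame, fits: Mapping[str, tuple[RadiusDistFit, RadiusDistFit]]
) -> pd.DataFrame:
    """Per-SNP log-likelihood-ratio features, one column per radius column.

    LLR(s) = ln p_r(lambda) - ln p_c(lambda); singleton-locus SNPs (NaN
    radius) get LLR = 0, i.e. a likelihood ratio of 1, carrying no
    geometric evidence either way.  Values are clamped to +/-50 nats.
    """
    out = {}
    for key in radii.columns:
        if key not in fits:
            raise ValidationError(f"no distribution fit available for {key!r}")
        fit_r, fit_c = fits[key]
        lam = radii[key].to_numpy(float)
        finite = np.isfinite(lam)
        llr = np.zeros_like(lam)
        if finite.any():
            x = lam[finite]
            vals = fit_r.logpdf(x) - fit_c.logpdf(x)
            n_clamped = int((np.abs(vals) > LLR_CLAMP).sum())
            if n_clamped:
                logger.info("%s: clamped %d LLR values to +/-%g", key, n_clamped, LLR_CLAMP)
            llr[finite] = np.clip(vals, -LLR_CLAMP, LLR_CLAMP)
        out[LLR_PREFIX + key] = llr
    return pd.DataFrame(out, index=radii.index)


def append_llr(table: FeatureTable, block: pd.DataFrame) -> FeatureTable:
    """Append the LLR columns to a feature table as continuous features."""
    if not table.data.index.equals(block.index):
        raise ValidationError("LLR block is not row-aligned with the feature table")
    schema = dict(table.schema)
    for col in block.columns:
        schema[col] = ColumnSpec(kind="continuous")
    return FeatureTable(pd.concat([table.data, block], axis=1), schema)
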