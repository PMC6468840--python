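"""Peak-table cleaning and normalization.

The default pipeline mirrors standard untargeted-metabolomics practice for
feature tables from stool or biofluid samples:

1. drop features missing in more than half the samples (the raw missingness
   mask is evaluated before any imputation, so wholly-missing features never
   reach the imputer);
2. replace remaining missing cells with half of the feature's minimum
   observed value (missing-at-low-abundance assumption);
3. drop the lowest-variability features by interquartile range (near-constant
   signals carry no contrast);
4. divide each sample by its median feature intensity (dilution/water-content
   correction);
5. generalized log transform g(x) = log2((x + sqrt(x^2 + lambda^2)) / 2),
   variance-stabilizing and defined at zero;
6. auto-scale each feature to mean 0, unit (n-1) standard deviation.

Univariate tests are meant to run on the *untransformed* (but normalized)
table, so :func:`run_pipeline` returns both tables plus a step-by-step log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .peaktable import PeakTable, PeakTableError

__all__ = [
    "PreprocessConfig",
    "PreprocessResult",
    "impute_half_min",
    "filter_missing",
    "filter_iqr",
    "normalize_sample_median",
    "glog",
    "autoscale",
    "auto_glog_lambda",
    "run_pipeline",
]

DEFAULT_STEPS = ("filter_missing", "impute", "filter_iqr", "normalize_median", "glog", "autoscale")


@dataclass
class PreprocessConfig:
    max_missing_fraction: float = 0.5     # strict >: exactly 50% missing is kept
    iqr_filter_fraction: float = 0.25
    glog_lambda: float | str = "auto"
    steps: tuple[str, ...] = DEFAULT_STEPS

    def __post_init__(self) -> None:
        for name, v in (("max_missing_fraction", self.max_missing_fraction),
                        ("iqr_filter_fraction", self.iqr_filter_fraction)):
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        unknown = set(self.steps) - set(DEFAULT_STEPS)
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")


@dataclass
class PreprocessResult:
    transformed: PeakTable          # after the full step list
    untransformed: PeakTable        # after filters/imputation/normalization, before glog+autoscale
    log: list[dict] = field(default_factory=list)


def impute_half_min(pt: PeakTable) -> PeakTable:
    """Replace each missing cell with half the feature's minimum observed value."""
    out = pt.copy()
    X = out.intensities
    for i in range(X.shape[0]):
        row = X[i]
        missing = np.isnan(row)
        if not missing.any():
            continue
        observed = row[~missing]
        if observed.size == 0:
            raise PeakTableError(
                f"feature {i} (m/z {pt.mz[i]:.4f}) is entirely missing; filter before imputing"
            )
        row[missing] = observed.min() / 2.0
    return out


def filter_missing(pt: PeakTable, max_fraction: float = 0.5) -> PeakTable:
    """Drop features whose missing fraction is strictly greater than ``max_fraction``."""
    frac = np.isnan(pt.intensities).mean(axis=1)
    return pt.select_features(np.flatnonzero(frac <= max_fraction))


def filter_iqr(pt: PeakTable, fraction: float = 0.25) -> PeakTable:
    """Drop the ``floor(fraction * n)`` features with the lowest intensity IQR.

    Ranking is ascending by IQR with stable ties (original order wins), so
    near-constant features go first.
    """
    if fraction == 0:
        return pt.copy()
    n = pt.n_features
    iqr = np.nanpercentile(pt.intensities, 75, axis=1) - np.nanpercentile(pt.intensities, 25, axis=1)
    n_drop = math.floor(fraction * n)
    order = np.argsort(iqr, kind="stable")
    drop = set(order[:n_drop].tolist())
    return pt.select_features(np.array([i for i in range(n) if i not in drop], dtype=int))


def normalize_sample_median(pt: PeakTable) -> PeakTable:
    """Divide each sample column by its median over observed features."""
    out = pt.copy()
    X = out.intensities
    for j, sid in enumerate(pt.sample_ids):
        med = np.nanmedian(X[:, j])
        if not np.isfinite(med) or med <= 0:
            raise PeakTableError(f"sample {sid!r}: non-positive median intensity {med}")
        X[:, j] = X[:, j] / med
    return out


def glog(pt: PeakTable, lam: float) -> PeakTable:
    """Generalized log transform, elementwise log2((x + sqrt(x^2 + lam^2)) / 2)."""
    if lam <= 0:
        raise ValueError(f"glog lambda must be positive, got {lam}")
    out = pt.copy()
    X = out.intensities
    out.intensities = np.log2((X + np.sqrt(X**2 + lam**2)) / 2.0)
    return out


def auto_glog_lambda(pt: PeakTable) -> float:
    """Default glog lambda: one tenth of the smallest positive intensity."""
    X = pt.intensities
    positive = X[np.isfinite(X) & (X > 0)]
    if positive.size == 0:
        raise PeakTableError("no positive intensities; cannot choose glog lambda")
    return float(positive.min() / 10.0)


def autoscale(pt: PeakTable) -> PeakTable:
    """Center each feature and scale to unit (n-1) standard deviation."""
    out = pt.copy()
    X = out.intensities
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise PeakTableError(
            f"zero-variance features at rows {zero[:10].tolist()}; filter before autoscaling"
        )
    out.intensities = (X - mean) / sd
    return out


def run_pipeline(pt: PeakTable, config: PreprocessConfig | None = None) -> PreprocessResult:
    """Run the configured cleaning steps, recording feature counts per step."""
    cfg = config or PreprocessConfig()
    log: list[dict] = []
    current = pt.copy()
    untransformed = current

    def record(step: str, before: int, after: int, **params) -> None:
        log.append({"step": step, "features_before": before, "features_after": after, **params})

    for step in cfg.steps:
        before = current.n_features
        if step == "filter_missing":
            current = filter_missing(current, cfg.max_missing_fraction)
            record(step, before, current.n_features, max_fraction=cfg.max_missing_fraction)
        elif step == "impute":
            current = impute_half_min(current)
            record(step, before, current.n_features)
        elif step == "filter_iqr":
            current = filter_iqr(current, cfg.iqr_filter_fraction)
            record(step, before, current.n_features, fraction=cfg.iqr_filter_fraction)
        elif step == "normalize_median":
            current = normalize_sample_median(current)
            record(step, before, current.n_features)
            untransformed = current
        elif step == "glog":
            lam = auto_glog_lambda(current) if cfg.glog_lambda == "auto" else float(cfg.glog_lambda)
            untransformed = current
            current = glog(current, lam)
            record(step, before, current.n_features, glog_lambda=lam)
        elif step == "autoscale":
            current = autoscale(current)
            record(step, before, current.n_features)
    return PreprocessResult(transformed=current, untransformed=untransformed, log=log)
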