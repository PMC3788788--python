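"""Per-patient normalized differential expression.

Raw tumour and healthy intensities are log2-transformed, then each patient's
deviation from the healthy-cohort mean is standardized feature by feature:

    Y[g, p] = (log2 E[g, p] - mu_H[g]) / (sd_H[g] + w * sd_C[g] + s0)

where ``mu_H`` and ``sd_H`` are the mean and standard deviation of log2
expression across healthy controls, ``sd_C`` is the standard deviation across
the tumour cohort (weighted by ``w``, penalizing features that vary wildly
between patients), and ``s0`` is a small additive stabilizer against
near-zero denominators.  The same transform applies unchanged to miRNA
expression when miRNA measurements are used for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "NormalizedDEMatrix",
    "NormalizationStats",
    "log_transform",
    "normalize_differential",
]


@dataclass(frozen=True)
class NormalizedDEMatrix:
    """Features x patients grid of unitless standardized log-differences."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValidationError("normalized DE values must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature moments used by the standardization, kept for audit."""

    feature_ids: tuple[str, ...]
    healthy_mean: np.ndarray
    healthy_sd: np.ndarray
    cancer_sd: np.ndarray
    n_healthy: int
    n_cancer: int

    def __post_init__(self) -> None:
        k = len(self.feature_ids)
        for name in ("healthy_mean", "healthy_sd", "cancer_sd"):
            arr = getattr(self, name)
            if arr.shape != (k,):
                raise ValidationError(f"{name} must have shape ({k},)")
        if np.any(self.healthy_sd < 0) or np.any(self.cancer_sd < 0):
            raise ValidationError("standard deviations must be nonnegative")
        if self.n_healthy < 2 or self.n_cancer < 2:
            raise ValidationError("need >= 2 healthy and >= 2 tumour samples")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "healthy_mean": self.healthy_mean,
                "healthy_sd": self.healthy_sd,
                "cancer_sd": self.cancer_sd,
            },
            index=list(self.feature_ids),
        )


def log_transform(expr: ExpressionMatrix) -> pd.DataFrame:
    """Elementwise base-2 logarithm of a positive expression matrix."""
    return pd.DataFrame(
        np.log2(expr.values), index=expr.feature_ids, columns=expr.sample_ids
    )


def normalize_differential(
    tumour: ExpressionMatrix,
    healthy: ExpressionMatrix,
    s0: float = 0.1,
    cancer_var_weight: float = 1.0,
) -> tuple[NormalizedDEMatrix, NormalizationStats]:
    """Standardize each patient's log2 deviation from the healthy mean.

    Both matrices must carry identical feature-id lists (same order).
    Standard deviations use the n-1 denominator, so two samples per cohort
    is the minimum.  Returns the per-patient matrix together with the
    per-feature statistics that produced it.
    """
    if tumour.feature_ids != healthy.feature_ids:
        raise ValidationError(
            "tumour and healthy matrices must share an identical feature id list"
        )
    if s0 < 0 or cancer_var_weight < 0:
        raise ValidationError("s0 and cancer_var_weight must be nonnegative")
    n = len(healthy.sample_ids)
    m = len(tumour.sample_ids)
    if n < 2 or m < 2:
        raise ValidationError("need >= 2 healthy and >= 2 tumour samples")

    log_t = np.log2(tumour.values)
    log_h = np.log2(healthy.values)
    mu_h = log_h.mean(axis=1)
    sd_h = log_h.std(axis=1, ddof=1)
    sd_c = log_t.std(axis=1, ddof=1)

    denom = sd_h + cancer_var_weight * sd_c + s0
    if np.any(denom == 0):
        bad = [f for f, d in zip(tumour.feature_ids, denom) if d == 0]
        raise ValidationError(
            "zero denominator (all SDs zero and s0=0) for features "
            f"{bad[:10]}; set s0 > 0"
        )

    y = (log_t - mu_h[:, None]) / denom[:, None]
    stats = NormalizationStats(
        feature_ids=tuple(tumour.feature_ids),
        healthy_mean=mu_h,
        healthy_sd=sd_h,
        cancer_sd=sd_c,
        n_healthy=n,
        n_cancer=m,
    )
    return (
        NormalizedDEMatrix(
            pd.DataFrame(y, index=tumour.feature_ids, columns=tumour.sample_ids)
        ),
        stats,
    )
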