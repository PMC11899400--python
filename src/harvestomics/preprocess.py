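"""Intensity-table correction and normalisation chain.

Stages, in their default order: pooled-QC LOESS drift correction ->
QC-RSD stability filter -> internal-standard relative quantification
(optional) -> half-minimum imputation + log2 -> autoscaling. Each stage
takes and returns a :class:`FeatureTable` so the order stays configurable.

Drift correction follows the QC-RLSC convention: per feature, a locally
weighted (tricube, degree-1) regression of the pooled-QC intensities on
injection order estimates the instrument drift curve; every injection is
rescaled by (median fitted QC level / fitted drift at its own injection
order). Beyond the outermost QC injections the fit is clamped to the
nearest fitted value rather than extrapolated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import InsufficientQCError, InvalidArgumentError, InvalidInputError
from .feature_table import FeatureTable

logger = logging.getLogger(__name__)

MIN_QC_FOR_LOESS = 4
DEFAULT_MAX_RSD = 30.0  # percent; features less stable than this on QC are dropped


@dataclass
class QCStats:
    """Per-feature QC relative standard deviation before/after correction."""

    rsd_before: pd.Series
    rsd_after: pd.Series

    @property
    def improved_fraction(self) -> float:
        """Share of features whose QC RSD decreased under correction."""
        ok = self.rsd_before.notna() & self.rsd_after.notna()
        if not ok.any():
            return float("nan")
        return float((self.rsd_after[ok] < self.rsd_before[ok]).mean())


def qc_rsd(table: FeatureTable) -> pd.Series:
    """QC-sample RSD (sd/mean x 100, percent) per feature.

    Uses the sample (ddof=1) standard deviation; undefined (NaN) where the
    QC mean is not positive.
    """
    qc = table.qc_values()
    if qc.empty:
        raise InvalidInputError("table has no QC rows")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    rsd = sd / mean * 100.0
    rsd[mean <= 0] = np.nan
    return rsd


def qc_loess_correct(table: FeatureTable, span: float = 0.75) -> tuple[FeatureTable, QCStats]:
    """Remove injection-order drift using the pooled-QC injections.

    Parameters
    ----------
    table:
        Raw intensity table with >= 4 QC rows.
    span:
        LOESS smoothing fraction in (0, 1].

    Returns the corrected table and before/after QC RSD statistics. The
    median QC level of each feature is preserved. Features whose fitted
    drift is non-positive anywhere fall back to a constant (global median)
    scaling and are logged.
    """
    if not 0 < span <= 1:
        raise InvalidArgumentError(f"span must be in (0, 1], got {span}")
    if table.n_qc < MIN_QC_FOR_LOESS:
        raise InsufficientQCError(
            f"drift correction needs >= {MIN_QC_FOR_LOESS} QC injections, found {table.n_qc}"
        )

    orders = table.samples["injection_order"].to_numpy(dtype=float)
    qc_mask = table.qc_mask
    qc_orders = orders[qc_mask]
    sort = np.argsort(qc_orders)
    qc_x = qc_orders[sort]

    rsd_before = qc_rsd(table)
    corrected = table.values.to_numpy(dtype=float).copy()
    fallbacks: list[str] = []

    for j, feat in enumerate(table.feature_ids):
        qc_y = corrected[qc_mask, j][sort]
        fitted_qc = lowess(qc_y, qc_x, frac=span, it=3, return_sorted=False)
        # clamped interpolation of the drift curve to every injection
        drift = np.interp(orders, qc_x, fitted_qc)
        reference = float(np.median(fitted_qc))
        if (drift <= 0).any() or reference <= 0:
            qc_median = float(np.median(qc_y))
            factor = reference / qc_median if qc_median > 0 else 1.0
            corrected[:, j] *= factor
            fallbacks.append(feat)
        else:
            corrected[:, j] *= reference / drift

    if fallbacks:
        logger.warning(
            "non-positive fitted drift for %d feature(s); used global median scaling: %s",
            len(fallbacks), ", ".join(fallbacks[:10]),
        )

    out = table.with_values(pd.DataFrame(corrected, index=table.values.index, columns=table.feature_ids))
    stats = QCStats(rsd_before=rsd_before, rsd_after=qc_rsd(out))
    return out, stats


def rsd_filter(table: FeatureTable, max_rsd: float = DEFAULT_MAX_RSD) -> FeatureTable:
    """Drop features whose QC RSD exceeds ``max_rsd`` percent (default 30)."""
    rsd = qc_rsd(table)
    drop = rsd.index[(rsd > max_rsd) | rsd.isna()]
    if len(drop):
        logger.info("RSD filter removed %d/%d features at %.1f%%", len(drop), table.n_features, max_rsd)
    return table.drop_features(drop)


def internal_standard_normalize(
    table: FeatureTable, is_feature: str, is_concentration: float = 1.0
) -> FeatureTable:
    """Relative quantification against a spiked internal standard.

    Each intensity becomes (intensity / internal-standard intensity) x
    ``is_concentration``; the internal-standard column is removed.
    """
    if is_feature not in table.values.columns:
        raise InvalidArgumentError(f"internal standard {is_feature!r} not in table")
    is_values = table.values[is_feature]
    bad = is_values[is_values <= 0]
    if len(bad):
        raise InvalidInputError(
            f"internal standard non-positive in sample(s): {', '.join(map(str, bad.index[:5]))}"
        )
    values = table.values.drop(columns=[is_feature]).div(is_values, axis=0) * is_concentration
    return table.with_values(values)


def impute_and_log2(table: FeatureTable) -> FeatureTable:
    """Replace zeros/missing by half the feature's minimum positive value, then log2.

    Features with no positive value at all cannot be imputed and are dropped
    with a warning.
    """
    if table.values.empty:
        raise InvalidInputError("table is empty")
    values = table.values.copy()
    dead = []
    for feat in values.columns:
        col = values[feat]
        positive = col[col > 0]
        if positive.empty:
            dead.append(feat)
            continue
        fill = positive.min() / 2.0
        values[feat] = col.where(col > 0, fill).fillna(fill)
    if dead:
        warnings.warn(f"dropped {len(dead)} feature(s) with no positive values", stacklevel=2)
        values = values.drop(columns=dead)
    return table.with_values(np.log2(values), transformed=True)


def autoscale(table: FeatureTable) -> FeatureTable:
    """Mean-centre and scale every feature to unit sample standard deviation.

    Zero-variance features cannot be scaled and are dropped with a warning.
    """
    if len(table.values) < 2:
        raise InvalidInputError("autoscaling needs >= 2 samples")
    values = table.values
    sd = values.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        warnings.warn(f"dropped {len(constant)} zero-variance feature(s)", stacklevel=2)
        values = values.drop(columns=constant)
        sd = sd.drop(constant)
    scaled = (values - values.mean(axis=0)) / sd
    return table.with_values(scaled, transformed=True)


def preprocess_pipeline(
    table: FeatureTable,
    span: float = 0.75,
    max_rsd: float = DEFAULT_MAX_RSD,
    is_feature: str | None = None,
    is_concentration: float = 1.0,
    drift_correct: bool = True,
) -> tuple[FeatureTable, QCStats | None]:
    """Default chain: correct -> filter -> (IS-normalise) -> impute/log2 -> autoscale.

    Returns the model-ready (autoscaled, QC rows removed) table and the QC
    statistics from drift correction (None when correction is skipped).
    """
    stats = None
    if drift_correct:
        table, stats = qc_loess_correct(table, span=span)
    table = rsd_filter(table, max_rsd=max_rsd)
    if is_feature is not None:
        table = internal_standard_normalize(table, is_feature, is_concentration)
    table = table.without_qc()
    table = impute_and_log2(table)
    table = autoscale(table)
    return table, stats
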