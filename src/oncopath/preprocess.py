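"""RPKM preprocessing: outlier capping and log2 transformation.

Raw RPKM matrices contain extreme per-cell-line maxima (a handful of
transcripts dominate the library).  The capping rule calibrates every value
above a panel-wide ceiling down to that ceiling, where the ceiling is the
most frequent value among the per-cell-line maxima.  Capping is followed by
``log2(x + 1)``.  Protein matrices arrive already log2-scaled and bypass
both steps; the ``scale`` tag on :class:`~oncopath.containers.ExpressionMatrix`
enforces this.

Both steps are also exposed as sklearn-compatible transformers
(:class:`RPKMCapper`, :class:`Log2Transformer`) operating on
``(n_samples, n_features)`` arrays, so they compose with sklearn pipelines.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import LOG2, RPKM, ExpressionMatrix

__all__ = [
    "CappingReport",
    "cap_outliers",
    "log2_transform",
    "RPKMCapper",
    "Log2Transformer",
]


@dataclass
class CappingReport:
    """What the capping step did: per-sample maxima, the calibration value
    (modal maximum) and how many values were replaced."""

    per_sample_max: pd.Series
    calibration_value: float
    n_values_capped: int


def _round_sig(x: float, digits: int = 4) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def modal_maximum(per_sample_max: np.ndarray, digits: int = 4) -> float:
    """Most frequent value among per-sample maxima.

    Continuous maxima are rounded to ``digits`` significant digits before
    counting; ties among equally frequent values are broken toward the
    smallest (the most conservative cap).  The returned value is an original
    (un-rounded) maximum: the smallest one falling in the winning bin.
    """
    rounded = np.array([_round_sig(float(v), digits) for v in per_sample_max])
    counts = Counter(rounded)
    best_count = max(counts.values())
    winner = min(v for v, c in counts.items() if c == best_count)
    return float(per_sample_max[rounded == winner].min())


def cap_outliers(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, CappingReport]:
    """Cap all RPKM values above the modal per-sample maximum.

    Every value strictly greater than the calibration value (the mode of the
    per-cell-line maxima) is replaced by the calibration value; everything
    else is untouched.  The operation is idempotent and never increases a
    value.
    """
    if matrix.scale != RPKM:
        raise ValueError("cap_outliers expects an RPKM-scale matrix")
    if matrix.n_samples == 0 or matrix.n_features == 0:
        raise ValueError("cannot cap an empty matrix")
    values = matrix.values.to_numpy(dtype=float)
    per_sample_max = np.nanmax(values, axis=0)
    calibration = modal_maximum(per_sample_max)
    mask = values > calibration
    n_capped = int(np.count_nonzero(mask))
    capped = np.where(mask, calibration, values)
    report = CappingReport(
        per_sample_max=pd.Series(per_sample_max, index=matrix.sample_ids, name="max_rpkm"),
        calibration_value=calibration,
        n_values_capped=n_capped,
    )
    out = ExpressionMatrix(
        values=pd.DataFrame(capped, index=matrix.feature_ids, columns=matrix.sample_ids),
        scale=RPKM,
        gene_symbols=matrix.gene_symbols,
        biotypes=matrix.biotypes,
    )
    return out, report


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply ``x -> log2(x + pseudocount)`` to an RPKM matrix."""
    if matrix.scale != RPKM:
        raise ValueError("log2_transform expects an RPKM-scale matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = matrix.values.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError("negative values cannot be log2-transformed")
    out = np.log2(values + pseudocount)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids),
        scale=LOG2,
        gene_symbols=matrix.gene_symbols,
        biotypes=matrix.biotypes,
    )


class RPKMCapper(BaseEstimator, TransformerMixin):
    """Sklearn transformer applying the modal-maximum capping rule.

    Operates on ``(n_samples, n_features)`` arrays.  ``fit`` learns the
    calibration value (the mode of per-sample maxima, rounded to
    ``sig_digits`` significant digits for counting, smallest tied value);
    ``transform`` clips values above it.

    Attributes
    ----------
    calibration_value_ : float
        The learned cap.
    n_values_capped_ : int
        Values clipped when ``transform`` was last called.
    """

    def __init__(self, sig_digits: int = 4):
        self.sig_digits = sig_digits

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        self.n_features_in_ = X.shape[1]
        self.calibration_value_ = modal_maximum(X.max(axis=1), self.sig_digits)
        return self

    def transform(self, X):
        check_is_fitted(self, "calibration_value_")
        X = check_array(X, ensure_all_finite=True)
        mask = X > self.calibration_value_
        self.n_values_capped_ = int(np.count_nonzero(mask))
        return np.where(mask, self.calibration_value_, X)


class Log2Transformer(BaseEstimator, TransformerMixin):
    """Stateless ``log2(x + pseudocount)`` transformer for RPKM arrays."""

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite=True)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, ensure_all_finite=True)
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if X.min() < 0:
            raise ValueError("negative values cannot be log2-transformed")
        return np.log2(X + self.pseudocount)
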