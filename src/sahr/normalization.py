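"""Median-of-ratios count normalization (DESeq-style size factors)."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("sahr")


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Scale samples by median-of-ratios size factors.

    The pseudo-reference sample is the per-gene geometric mean over the
    fitting data, restricted to genes expressed in every fitting sample;
    a sample's size factor is the median over those genes of its count
    divided by the reference.  ``transform`` divides counts by the size
    factor, so two samples differing only in sequencing depth become
    comparable.

    Follows the sklearn sample-orientation convention: ``X`` is
    samples x genes.

    Parameters
    ----------
    allow_pseudo_reference:
        When no gene is expressed in all samples the fit fails by default.
        Setting this flag computes the geometric mean over the nonzero
        counts of each gene instead (explicitly opting in to the fallback).

    Attributes
    ----------
    log_reference_ : per-gene log geometric-mean reference (NaN where
        undefined); ``reference_gene_mask_`` marks the genes used;
        ``size_factors_`` holds the factors of the fitting data.
    """

    def __init__(self, allow_pseudo_reference: bool = False):
        self.allow_pseudo_reference = allow_pseudo_reference

    def fit(self, X, y=None):
        X = self._validate(X)
        counts = np.asarray(X, dtype=float)
        with np.errstate(divide="ignore"):
            logc = np.log(counts)
        all_nonzero = (counts > 0).all(axis=0)
        if all_nonzero.any():
            log_ref = np.where(all_nonzero, np.mean(logc, axis=0), np.nan)
            mask = all_nonzero
        elif self.allow_pseudo_reference:
            nz = counts > 0
            with np.errstate(invalid="ignore"):
                log_ref = np.nansum(np.where(nz, logc, np.nan), axis=0) / nz.sum(axis=0)
            mask = nz.any(axis=0)
            log_ref = np.where(mask, log_ref, np.nan)
        else:
            raise ValidationError(
                "no gene has nonzero counts in every sample; pass "
                "allow_pseudo_reference=True to opt in to the nonzero-mean fallback"
            )
        self.log_reference_ = log_ref
        self.reference_gene_mask_ = mask
        self.n_features_in_ = counts.shape[1]
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
        self.size_factors_ = self._factors(counts)
        logger.info(
            "normalize: %d/%d reference genes, size factors in [%.3g, %.3g]",
            int(mask.sum()), counts.shape[1],
            self.size_factors_.min(), self.size_factors_.max(),
        )
        return self

    def _validate(self, X):
        arr = np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValidationError("normalization needs a 2-d matrix with >= 2 samples")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        return X

    def _factors(self, counts: np.ndarray) -> np.ndarray:
        mask = self.reference_gene_mask_
        ratios = counts[:, mask] / np.exp(self.log_reference_[mask])
        # a fitted-on-other-data sample may have zeros on reference genes
        ratios = np.where(ratios > 0, ratios, np.nan)
        factors = np.nanmedian(ratios, axis=1)
        if np.isnan(factors).any() or (factors <= 0).any():
            raise ValidationError("a sample shares no expressed gene with the reference")
        return factors

    def transform(self, X):
        if not hasattr(self, "log_reference_"):
            raise ValidationError("normalizer is not fitted")
        self._validate(X)
        counts = np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float)
        if counts.shape[1] != self.n_features_in_:
            raise ValidationError("gene dimension differs from the fitted data")
        factors = self._factors(counts)
        normalized = counts / factors[:, None]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(normalized, index=X.index, columns=X.columns)
        return normalized

    def get_size_factors(self, X) -> np.ndarray:
        """Size factors for the given samples under the fitted reference."""
        self._validate(X)
        counts = np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float)
        return self._factors(counts)


def median_of_ratios_normalize(
    matrix: ExpressionMatrix, allow_pseudo_reference: bool = False
) -> ExpressionMatrix:
    """Attach size factors and normalized values to an expression matrix.

    The reference is built from, and the factors computed on, the full
    matrix (genes x samples container; transposed internally to the
    samples x genes estimator convention).
    """
    norm = MedianOfRatiosNormalizer(allow_pseudo_reference=allow_pseudo_reference)
    normalized_t = norm.fit_transform(matrix.counts.T)
    return ExpressionMatrix(
        counts=matrix.counts,
        normalized=normalized_t.T,
        size_factors=pd.Series(norm.size_factors_, index=matrix.sample_ids),
    )
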