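"""Total-spectral-count normalization and the log2 MA representation.

Normalization scales each sample so its total spectral count equals the
grand mean of the sample totals; this is idempotent and leaves the group
log-ratio M invariant under any common rescaling of the raw counts.

The MA table is built at the group level from log2(value + pseudo_count):
M = mean_high - mean_low, A_raw = (mean_high + mean_low) / 2, and the
"justified" abundance A = A_raw + a_offset shifts essentially all
observed proteins onto a positive abundance axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import GROUP_HIGH, GROUP_LOW, CountMatrix, ValidationError


class TotalCountNormalizer(TransformerMixin, BaseEstimator):
    """Scale every sample (row) to a common total count.

    Follows the scikit-learn convention X of shape (n_samples,
    n_features).  ``fit`` records the grand mean of the row totals as
    the common target; ``transform`` rescales each row of its input by
    target / row_total.  With ``target_total`` given, ``fit`` is a
    no-op validation.

    Attributes
    ----------
    target_total_ : float
        Total every transformed row sums to.
    """

    def __init__(self, target_total: float | None = None):
        self.target_total = target_total

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        totals = X.sum(axis=1)
        if (totals <= 0).any():
            raise ValidationError(
                f"zero-total sample(s) at row index "
                f"{np.flatnonzero(totals <= 0).tolist()}"
            )
        self.target_total_ = (
            float(totals.mean()) if self.target_total is None
            else float(self.target_total)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        totals = X.sum(axis=1)
        if (totals <= 0).any():
            raise ValidationError(
                f"zero-total sample(s) at row index "
                f"{np.flatnonzero(totals <= 0).tolist()}"
            )
        return X * (self.target_total_ / totals)[:, None]


def normalize_total_counts(matrix: CountMatrix) -> CountMatrix:
    """Normalize a CountMatrix on total spectral counts per sample.

    Each sample's counts are multiplied by (grand mean of sample
    totals) / (that sample's total), so all post-normalization sample
    totals equal the grand mean.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValidationError(f"zero-total sample(s): {zero}")
    scaled = TotalCountNormalizer().fit_transform(matrix.counts.to_numpy().T).T
    counts = pd.DataFrame(scaled, index=matrix.counts.index,
                          columns=matrix.counts.columns)
    return CountMatrix(counts, matrix.groups)


def compute_ma(matrix: CountMatrix, pseudo_count: float = 0.05,
               a_offset: float = 4.0) -> pd.DataFrame:
    """Build the per-protein MA table from a normalized CountMatrix.

    Returns a DataFrame indexed by protein with columns mean_high,
    mean_low (group means of log2(value + pseudo_count)), M, A_raw, A.
    """
    if pseudo_count < 0:
        raise ValidationError("pseudo_count must be non-negative")
    vals = matrix.counts.to_numpy()
    if pseudo_count == 0 and (vals == 0).any():
        raise ValidationError(
            "pseudo_count = 0 with zero counts present would give -inf"
        )
    log2 = pd.DataFrame(np.log2(vals + pseudo_count),
                        index=matrix.counts.index, columns=matrix.counts.columns)
    mean_high = log2[matrix.samples_in(GROUP_HIGH)].mean(axis=1)
    mean_low = log2[matrix.samples_in(GROUP_LOW)].mean(axis=1)
    m = mean_high - mean_low
    a_raw = (mean_high + mean_low) / 2.0
    ma = pd.DataFrame(
        {
            "mean_high": mean_high,
            "mean_low": mean_low,
            "M": m,
            "A_raw": a_raw,
            "A": a_raw + a_offset,
        }
    ).rename_axis("protein")
    return ma
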