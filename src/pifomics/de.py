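"""Signed fold changes and empirical-Bayes moderated t-statistics.

The moderated t shrinks each protein's pooled log2-scale variance s2
toward a global prior (d0, s0_2) fitted across all proteins by moment
matching on log variances: with d_g residual degrees of freedom per
protein, e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2) has variance
trigamma(d_g/2) + trigamma(d0/2) under the scaled-chi-square hierarchy,
so trigamma(d0/2) = var(e) - trigamma(d_g/2) identifies d0 (infinite
when the right-hand side is non-positive, i.e. the observed variances
are no more spread than pure chi-square noise).  The moderated variance
is the degrees-of-freedom-weighted convex combination
(d0*s0_2 + d_g*s2) / (d0 + d_g) and the statistic is referred to a
Student t with d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import GROUP_HIGH, GROUP_LOW, CountMatrix
from .simulate import ConfigurationError


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0), by Newton iteration on
    the nearly-linear reciprocal scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, d_g: int) -> tuple[float, float]:
    """Moment-fit the variance-prior hyperparameters (d0, s0_2).

    Zero variances (log undefined) are excluded from the moment fit
    with a warning.  Returns d0 = inf when the log-variances are no more
    dispersed than chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    if d_g < 1:
        raise ConfigurationError("residual degrees of freedom must be >= 1")
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise ValueError("all variances are zero: degenerate data")
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} zero/non-finite variance(s) excluded "
            "from the prior fit"
        )
    s2 = s2[ok]
    if s2.size < 10:
        raise ValueError(f"need >= 10 finite variances, got {s2.size}")

    half_dg = d_g / 2.0
    e = np.log(s2) - special.digamma(half_dg) + np.log(half_dg)
    rhs = np.var(e, ddof=1) - _trigamma(half_dg)
    if rhs <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_2 = float(
            np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return float(d0), s0_2


def moderated_t(
    m: np.ndarray,
    s2: np.ndarray,
    d0: float,
    s0_2: float,
    n_high: int,
    n_low: int,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderated t-statistics, total degrees of freedom, two-sided p.

    s2_tilde is the convex combination of the prior and the per-protein
    pooled variance; the limits d0 = 0 (no shrinkage, ordinary t) and
    d0 = inf (full shrinkage, normal reference) are handled exactly.
    """
    if n_high < 2 or n_low < 2:
        raise ConfigurationError("each group needs >= 2 samples")
    m = np.asarray(m, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d_g = n_high + n_low - 2
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s2_tilde * (1.0 / n_high + 1.0 / n_low))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(m == 0.0, 0.0, m / se)
    degenerate = (se == 0.0) & (m != 0.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} protein(s) with zero moderated "
            "variance and nonzero difference: p set to 0"
        )
        t = np.where(degenerate, np.sign(m) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(m == 0.0, 1.0, p)
    return t, df_total, p


class ModeratedTTest(BaseEstimator):
    """Two-group empirical-Bayes moderated t-test, scikit-learn style.

    ``fit`` takes X of shape (n_samples, n_features) of log2-scale
    abundances and two-level group labels y; the contrast is
    ``contrast[0]`` minus ``contrast[1]``.

    Parameters
    ----------
    contrast : tuple of str, default ("high", "low")
        Group labels defining the sign of the difference.
    shrink : bool, default True
        If False, skip moderation (d0 = 0): ordinary pooled-variance t.

    Attributes
    ----------
    d0_, s0_2_ : fitted variance-prior hyperparameters.
    m_ : per-feature group difference (contrast[0] - contrast[1]).
    s2_, s2_tilde_ : pooled and moderated variances.
    t_, p_, df_total_ : moderated statistic, two-sided p, reference df.
    t_ordinary_ : unmoderated pooled-variance t (diagnostic).
    """

    def __init__(self, contrast: tuple[str, str] = (GROUP_HIGH, GROUP_LOW),
                 shrink: bool = True):
        self.contrast = contrast
        self.shrink = shrink

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        a, b = self.contrast
        ia, ib = y == a, y == b
        n_a, n_b = int(ia.sum()), int(ib.sum())
        if n_a < 2 or n_b < 2:
            raise ConfigurationError(
                f"each group needs >= 2 samples, got {n_a} {a!r} / {n_b} {b!r}"
            )
        xa, xb = X[ia], X[ib]
        self.m_ = xa.mean(axis=0) - xb.mean(axis=0)
        d_g = n_a + n_b - 2
        ss = xa.var(axis=0, ddof=1) * (n_a - 1) + xb.var(axis=0, ddof=1) * (n_b - 1)
        self.s2_ = ss / d_g
        self.d_g_ = d_g
        self.n_high_, self.n_low_ = n_a, n_b

        if self.shrink:
            self.d0_, self.s0_2_ = fit_variance_prior(self.s2_, d_g)
        else:
            self.d0_, self.s0_2_ = 0.0, 0.0
        self.t_, self.df_total_, self.p_ = moderated_t(
            self.m_, self.s2_, self.d0_, self.s0_2_, n_a, n_b
        )
        if np.isinf(self.df_total_):
            self.s2_tilde_ = np.full_like(self.s2_, self.s0_2_)
        else:
            self.s2_tilde_ = (self.d0_ * self.s0_2_ + d_g * self.s2_) / (
                self.d0_ + d_g
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(self.s2_ * (1.0 / n_a + 1.0 / n_b))
            self.t_ordinary_ = np.where(self.m_ == 0.0, 0.0, self.m_ / se)
        return self

    def score(self, X=None, y=None):  # pragma: no cover - sklearn API nicety
        check_is_fitted(self)
        return float(np.mean(self.p_ < 0.05))


def signed_fold_change(matrix: CountMatrix, pseudo_count: float = 0.05) -> pd.Series:
    """Signed fold change of normalized count means, high over low.

    r = (mean_high + pseudo) / (mean_low + pseudo); the fold is r when
    r >= 1 and -1/r otherwise, so |fold| >= 1 with +1.0 at equality.
    """
    mean_high = matrix.counts[matrix.samples_in(GROUP_HIGH)].mean(axis=1)
    mean_low = matrix.counts[matrix.samples_in(GROUP_LOW)].mean(axis=1)
    r = (mean_high + pseudo_count) / (mean_low + pseudo_count)
    fold = np.where(r >= 1.0, r, -1.0 / r)
    return pd.Series(fold, index=matrix.counts.index, name="fold")


def de_table(matrix: CountMatrix, pseudo_count: float = 0.05) -> pd.DataFrame:
    """Full per-protein DE table from a normalized CountMatrix.

    Columns: fold, M, s2, s2_tilde, t_ordinary, t_mod, df, p.  The
    fitted prior hyperparameters are stored in ``df.attrs['d0']`` and
    ``df.attrs['s0_2']``.
    """
    log2 = np.log2(matrix.counts.to_numpy() + pseudo_count)
    est = ModeratedTTest().fit(log2.T, matrix.groups.to_numpy())
    out = pd.DataFrame(
        {
            "fold": signed_fold_change(matrix, pseudo_count),
            "M": est.m_,
            "s2": est.s2_,
            "s2_tilde": est.s2_tilde_,
            "t_ordinary": est.t_ordinary_,
            "t_mod": est.t_,
            "df": est.df_total_,
            "p": est.p_,
        },
        index=matrix.counts.index,
    ).rename_axis("protein")
    out.attrs["d0"] = est.d0_
    out.attrs["s0_2"] = est.s0_2_
    return out


def de_filter(
    table: pd.DataFrame,
    min_fold: float = 1.3,
    max_fold: float = 15.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int, int]:
    """Keep proteins with min_fold <= |fold| <= max_fold and p < alpha.

    Both fold bounds are inclusive.  Returns the filtered table and the
    (n_up, n_down) counts by fold sign.
    """
    if min_fold > max_fold:
        raise ConfigurationError("min_fold must not exceed max_fold")
    absf = table["fold"].abs()
    keep = (absf >= min_fold) & (absf <= max_fold) & (table["p"] < alpha)
    passed = table.loc[keep]
    n_up = int((passed["fold"] > 0).sum())
    n_down = int((passed["fold"] < 0).sum())
    return passed, n_up, n_down
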