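"""Compartment-proteome overlay and binomial sign-skew test.

Overlays an annotation list (e.g. a mitoproteome symbol list) on the MA
table and asks whether the matched proteins' expression differences M
deviate from a 50:50 up/down equilibrium, by an exact binomial test.
A collective skew of a compartment's proteins toward one group is a
proxy for higher compartment (e.g. mitochondrial) content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SkewReport:
    """Result of the compartment sign-skew analysis."""

    n_listed: int
    n_matched: int
    k_pos: int
    k_neg: int
    n_ties: int
    p_binom: float
    tail_overlap_up: int = 0
    tail_overlap_down: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def overlay_annotation(ma: pd.DataFrame, symbols: set[str]) -> pd.DataFrame:
    """Rows of the MA table whose protein id matches the symbol list.

    Matching is case-insensitive exact-string after trimming; an empty
    intersection is a warning, not an error.
    """
    if not symbols:
        raise ValueError("empty symbol list")
    wanted = {s.strip().upper() for s in symbols}
    mask = ma.index.astype(str).str.strip().str.upper().isin(wanted)
    matched = ma.loc[mask]
    if matched.empty:
        logger.warning("no annotation symbols matched the dataset")
    return matched


def binomial_skew_p(k_pos: int, n: int, method: str = "doubling") -> float:
    """Exact two-sided binomial p against proportion 0.5.

    ``doubling`` doubles the smaller tail (capped at 1); ``minlike``
    sums all outcomes no more likely than the observed one.
    """
    if n < 1:
        raise ValueError("need at least one informative sign")
    if method == "doubling":
        lower = stats.binom.cdf(k_pos, n, 0.5)
        upper = stats.binom.sf(k_pos - 1, n, 0.5)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "minlike":
        return float(stats.binomtest(k_pos, n, 0.5).pvalue)
    raise ValueError(f"unknown method {method!r}")


def binomial_skew_test(
    m_values: pd.Series | np.ndarray,
    n_listed: int | None = None,
    method: str = "doubling",
) -> SkewReport:
    """Skew of the signs of M for a matched protein subset.

    Ties (M exactly 0) are excluded from the binomial sample size and
    reported separately; all-ties input is an error.
    """
    m = np.asarray(m_values, dtype=float)
    k_pos = int((m > 0).sum())
    k_neg = int((m < 0).sum())
    n_ties = int((m == 0).sum())
    n = k_pos + k_neg
    if n == 0:
        raise ValueError("no informative signs (all M values are ties)")
    p = binomial_skew_p(k_pos, n, method=method)
    return SkewReport(
        n_listed=len(m) if n_listed is None else n_listed,
        n_matched=len(m),
        k_pos=k_pos,
        k_neg=k_neg,
        n_ties=n_ties,
        p_binom=p,
    )


def skew_report(
    ma: pd.DataFrame,
    symbols: set[str],
    pif: pd.DataFrame | None = None,
    method: str = "doubling",
) -> SkewReport:
    """Full compartment report: overlay, sign test, PIF-tail overlap."""
    matched = overlay_annotation(ma, symbols)
    if matched.empty:
        return SkewReport(len(symbols), 0, 0, 0, 0, 1.0)
    rep = binomial_skew_test(matched["M"], n_listed=len(symbols), method=method)
    if pif is not None and "tail" in pif:
        tails = pif.loc[pif.index.intersection(matched.index), "tail"]
        rep.tail_overlap_up = int((tails == "up").sum())
        rep.tail_overlap_down = int((tails == "down").sum())
    return rep
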