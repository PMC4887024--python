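"""Phenotypic Impact Factor (PIF) scoring and extreme-set selection.

PIF multiplies each protein's justified average abundance A by its
group difference M, so that abundant, strongly changing proteins score
highest and lowly abundant (noisy, near the detection limit) proteins
are de-emphasized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ConfigurationError


def compute_pif(ma: pd.DataFrame, use_justified: bool = True) -> pd.DataFrame:
    """PIF table from an MA table: pif = A * M.

    With ``use_justified`` (default) the offset abundance A is used as
    the weight; ``use_justified=False`` weights by A_raw instead.
    """
    a = ma["A"] if use_justified else ma["A_raw"]
    out = pd.DataFrame({"A": ma["A"], "M": ma["M"], "pif": a * ma["M"]})
    return out.rename_axis("protein")


def tail_size(n: int, tail_fraction: float) -> int:
    """Per-tail count: tail_fraction * n rounded half away from zero."""
    return int(np.floor(tail_fraction * n + 0.5))


def _ordered(table: pd.DataFrame, ascending: bool) -> pd.Index:
    # Boundary ties broken by larger |M|, then lexicographic protein id.
    t = table.assign(_absm=table["M"].abs(), _id=table.index)
    t = t.sort_values(
        ["pif", "_absm", "_id"],
        ascending=[ascending, False, True],
        kind="mergesort",
    )
    return t.index


def select_extreme(
    pif: pd.DataFrame, tail_fraction: float = 0.05
) -> tuple[pd.Index, pd.Index]:
    """The k most up- and k most down-regulated proteins by PIF.

    k = round(tail_fraction * N), rounding half away from zero; the two
    tails are disjoint by construction and must not overlap.
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ConfigurationError("tail_fraction must lie in (0, 0.5)")
    n = len(pif)
    k = tail_size(n, tail_fraction)
    if 2 * k > n:
        raise ConfigurationError(
            f"tails of size {k} overlap on {n} proteins"
        )
    up = _ordered(pif, ascending=False)[:k]
    down = _ordered(pif, ascending=True)[:k]
    return up, down


def top_k_by_pif(pif: pd.DataFrame, k: int = 40) -> tuple[pd.Index, pd.Index]:
    """The k/2 largest and k/2 smallest PIF proteins, rank-ordered.

    Returned up-set is in decreasing PIF order, down-set in increasing
    (most extreme first).  k must be even and at most N.
    """
    if k % 2 != 0 or k <= 0:
        raise ConfigurationError("k must be a positive even integer")
    if k > len(pif):
        raise ConfigurationError(f"k={k} exceeds {len(pif)} proteins")
    half = k // 2
    up = _ordered(pif, ascending=False)[:half]
    down = _ordered(pif, ascending=True)[:half]
    return up, down


def pif_table(
    ma: pd.DataFrame,
    tail_fraction: float = 0.05,
    top_k: int = 40,
    use_justified: bool = True,
) -> pd.DataFrame:
    """Annotated PIF table with tail membership and top-k ranks.

    Columns: A, M, pif, tail in {up, down, none}, topk_rank (1-based
    within each tail, 0 when not in the top k).
    """
    table = compute_pif(ma, use_justified=use_justified)
    up, down = select_extreme(table, tail_fraction)
    half = min(top_k // 2, len(up))
    tk_up, tk_down = top_k_by_pif(table, 2 * half) if half else (table.index[:0],) * 2
    table["tail"] = "none"
    table.loc[up, "tail"] = "up"
    table.loc[down, "tail"] = "down"
    table["topk_rank"] = 0
    table.loc[tk_up, "topk_rank"] = np.arange(1, len(tk_up) + 1)
    table.loc[tk_down, "topk_rank"] = np.arange(1, len(tk_down) + 1)
    return table
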