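"""Two-list hypergeometric enrichment and upstream-regulator scoring.

Enrichment compares a target protein list against a background using
upper-tail hypergeometric p-values with Benjamini-Hochberg adjustment.

Upstream-regulator analysis asks, for each regulator in a signed
regulator->target network, whether the observed expression directions
of its targets are collectively consistent with the regulator being
activated or inhibited: each informative target contributes
(expected direction * observed sign), and the activation z-score is
(n_consistent_activation - n_consistent_inhibition) / sqrt(N).  A
Fisher exact p quantifies whether the regulator's targets overlap the
differentially expressed set more than chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    target: set[str],
    background: set[str],
    terms: dict[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the target.

    With N background proteins, K of them in the term and n in the
    target list, p = P[X >= k] for the observed overlap k.  Terms with
    no background member are skipped; q is BH over the tested terms.
    """
    extra = set(target) - set(background)
    if extra:
        raise ValueError(f"target proteins outside background: {sorted(extra)}")
    if len(background) < 2:
        raise ValueError("background must contain at least 2 proteins")
    bg = set(background)
    tg = set(target)
    rows = []
    for term, members in terms.items():
        members_bg = members & bg
        big_k = len(members_bg)
        if big_k == 0:
            continue
        k = len(members_bg & tg)
        p = float(stats.hypergeom.sf(k - 1, len(bg), big_k, len(tg)))
        rows.append((term, big_k, k, len(bg), len(tg), min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "K", "k", "N", "n", "p_hyper"]
    ).set_index("term")
    out["q"] = bh_adjust(out["p_hyper"]) if len(out) else []
    return out.sort_values(["p_hyper", "term"], kind="mergesort")


def activation_z(
    network: pd.DataFrame,
    observed: pd.Series,
) -> pd.DataFrame:
    """Per-regulator activation z-scores from observed DE directions.

    ``network`` has columns (regulator, target, direction) with
    direction +1 for regulator-activates-target and -1 for represses;
    ``observed`` maps protein -> observed sign (+1 up / -1 down in the
    contrast), normally restricted to DE-passing proteins.  Targets
    absent from ``observed`` are non-informative.  A regulator with no
    informative target gets z = NaN (reported missing, not 0).
    """
    obs = observed.copy()
    obs.index = obs.index.astype(str).str.strip().str.upper()
    rows = []
    for reg, edges in network.groupby("regulator", sort=True):
        targets = edges["target"].astype(str).str.strip().str.upper()
        known = targets.isin(obs.index)
        informative = edges.loc[known]
        n = int(known.sum())
        if n == 0:
            rows.append((reg, 0, 0, 0, np.nan))
            continue
        s = informative["direction"].to_numpy() * obs.loc[
            targets[known]
        ].to_numpy()
        n_act = int((s > 0).sum())
        n_inh = int((s < 0).sum())
        z = (n_act - n_inh) / math.sqrt(n)
        rows.append((reg, n, n_act, n_inh, z))
    return pd.DataFrame(
        rows,
        columns=[
            "regulator", "N_informative",
            "n_consistent_activation", "n_consistent_inhibition", "z",
        ],
    ).set_index("regulator")


def overlap_p(
    targets: set[str], de_set: set[str], background: set[str]
) -> float:
    """One-sided Fisher exact p for target/DE overlap enrichment."""
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    t = set(targets) & bg
    d = set(de_set) & bg
    a = len(t & d)
    b = len(t - d)
    c = len(d - t)
    dd = len(bg) - a - b - c
    return float(stats.fisher_exact([[a, b], [c, dd]], alternative="greater")[1])


@dataclass
class RegulatorState:
    state: str  # activated | inhibited | strong | moderate | weak | none
    sign: int  # +1 / -1 / 0
    label: str  # Activated, Inhibited, +++/---, ++/--, +/-, none


def classify_regulator(
    z: float,
    p_overlap: float,
    z_threshold: float = 2.0,
    qualified_bands: tuple[float, float, float] = (1.7, 1.5, 1.0),
    alpha: float = 0.05,
) -> RegulatorState:
    """Categorical activation call from z and the overlap p-value.

    Any call requires p_overlap < alpha.  |z| strictly above
    ``z_threshold`` gives activated/inhibited by sign; otherwise the
    qualified bands (default strong >= 1.7, moderate >= 1.5,
    weak > 1.0) apply, carrying the sign; |z| = z_threshold exactly
    falls in the strong qualified band.
    """
    hi, mid, lo = qualified_bands
    if not (hi > mid > lo > 0):
        raise ValueError("qualified bands must be strictly decreasing and > 0")
    if z is None or not np.isfinite(z) or not (p_overlap < alpha):
        return RegulatorState("none", 0, "none")
    az = abs(z)
    sign = 1 if z > 0 else (-1 if z < 0 else 0)
    mark = "+" if sign > 0 else "-"
    if az > z_threshold:
        return RegulatorState(
            "activated" if sign > 0 else "inhibited", sign,
            "Activated" if sign > 0 else "Inhibited",
        )
    if az >= hi:
        return RegulatorState("strong", sign, mark * 3)
    if az >= mid:
        return RegulatorState("moderate", sign, mark * 2)
    if az > lo:
        return RegulatorState("weak", sign, mark)
    return RegulatorState("none", 0, "none")


def regulator_predictions(
    network: pd.DataFrame,
    observed: pd.Series,
    de_set: set[str],
    background: set[str],
    z_threshold: float = 2.0,
    qualified_bands: tuple[float, float, float] = (1.7, 1.5, 1.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-regulator table: z, overlap p, and categorical state."""
    table = activation_z(network, observed)
    de_upper = {s.strip().upper() for s in de_set}
    bg_upper = {s.strip().upper() for s in background}
    p_vals, states, labels = [], [], []
    for reg in table.index:
        targets = set(
            network.loc[network["regulator"] == reg, "target"]
            .astype(str).str.strip().str.upper()
        )
        p = overlap_p(targets, de_upper, bg_upper)
        st = classify_regulator(
            table.loc[reg, "z"], p, z_threshold, qualified_bands, alpha
        )
        p_vals.append(p)
        states.append(st.state)
        labels.append(st.label)
    table["p_overlap"] = p_vals
    table["state"] = states
    table["label"] = labels
    return table
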