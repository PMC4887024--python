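"""Synthetic spectral-count data with known ground truth.

Emulates the structure of a two-group label-free shotgun-proteomics
experiment: a heavy-tailed (lognormal) distribution of baseline protein
abundances, non-negative overdispersed counts with many zeros at low
abundance (negative binomial, variance = mu + phi * mu**2), a planted
fraction of differentially expressed proteins, a compartment subset
(e.g. the mitoproteome) whose planted effects are directionally biased,
and a regulator network whose target directions are sign-consistent with
a latent regulator state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GROUP_HIGH, GROUP_LOW, CountMatrix


class ConfigurationError(ValueError):
    """Raised for an invalid simulation or pipeline configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic spectral-count generator.

    Defaults mirror the shape of an 1817-protein, 4-vs-4 broiler breast
    muscle experiment with a 228-protein mitochondrial annotation subset.

    Attributes
    ----------
    n_proteins, n_per_group
        Matrix dimensions: proteins by (2 * n_per_group) samples.
    baseline_log_mean, baseline_log_sd
        Natural-log location/spread of the lognormal baseline mean
        spectral count per protein.  The defaults put the median protein
        near 7 counts with a long right tail into the thousands
        (GAPDH-like dominant proteins).
    dispersion
        Negative-binomial overdispersion phi; count variance is
        mu + phi * mu**2.  phi = 0 is the Poisson limit.
    de_fraction
        Fraction of proteins with a planted nonzero log2 effect.
    effect_log2_sd
        Spread of planted log2 effects (drawn half-normal, signed).
    effect_log2_magnitude
        If not None, every planted effect has exactly this absolute
        log2 magnitude (signs still random); used for power studies.
    n_compartment
        Number of proteins flagged as compartment (mitoproteome) members.
    compartment_up_prob
        Probability that a planted effect on a compartment protein is
        positive (up in group "high"); 0.5 means no compartment skew.
    n_regulators, targets_per_regulator
        Shape of the regulator network drawn from planted DE proteins.
    seed
        Master seed; all stage-level streams derive from it.
    """

    n_proteins: int = 1817
    n_per_group: int = 4
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.2
    de_fraction: float = 0.1
    effect_log2_sd: float = 1.0
    effect_log2_magnitude: float | None = None
    n_compartment: int = 228
    compartment_up_prob: float = 0.75
    n_regulators: int = 3
    targets_per_regulator: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_per_group", "n_compartment",
                     "n_regulators", "targets_per_regulator"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ConfigurationError(f"{name} must be an integer, got {v!r}")
        if self.n_proteins <= 0 or self.n_per_group <= 0:
            raise ConfigurationError("matrix dimensions must be positive")
        if self.n_compartment < 0 or self.n_compartment > self.n_proteins:
            raise ConfigurationError(
                "n_compartment must lie in [0, n_proteins]"
            )
        for name in ("de_fraction", "compartment_up_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a proportion in [0, 1]")
        if self.baseline_log_sd <= 0 or self.effect_log2_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")


@dataclass
class GroundTruth:
    """Planted truth behind a synthetic dataset.

    ``effects`` holds the planted log2 effect per protein (exactly 0 for
    non-DE proteins); ``compartment`` flags annotation-subset membership.
    ``network``/``regulator_states`` are populated by
    :func:`generate_regulator_network`.
    """

    effects: pd.Series
    compartment: pd.Series
    network: pd.DataFrame | None = None
    regulator_states: pd.Series | None = None

    @property
    def de_proteins(self) -> pd.Index:
        return self.effects.index[self.effects != 0.0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"effect_log2": self.effects, "compartment": self.compartment.astype(int)}
        ).rename_axis("protein")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float, size: tuple[int, ...]) -> np.ndarray:
    """Negative-binomial counts with variance mu + phi * mu**2."""
    if dispersion == 0.0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a spectral-count matrix and its ground truth.

    Group "low" is the reference: its per-protein mean is the lognormal
    baseline.  Group "high" means are baseline * 2**effect.  The same
    seed yields bit-identical output.
    """
    cfg = config
    rng_base, rng_assign, rng_sign, rng_mag, rng_counts = _streams(cfg.seed, 5)

    proteins = pd.Index(
        [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)], name="protein"
    )
    samples = [f"high_{i + 1}" for i in range(cfg.n_per_group)] + [
        f"low_{i + 1}" for i in range(cfg.n_per_group)
    ]
    groups = pd.Series(
        [GROUP_HIGH] * cfg.n_per_group + [GROUP_LOW] * cfg.n_per_group,
        index=pd.Index(samples, name="sample"),
    )

    baseline = np.exp(
        rng_base.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_proteins)
    )

    n_de = int(round(cfg.de_fraction * cfg.n_proteins))
    de_idx = rng_assign.choice(cfg.n_proteins, size=n_de, replace=False)
    comp_idx = rng_assign.choice(cfg.n_proteins, size=cfg.n_compartment, replace=False)
    compartment = np.zeros(cfg.n_proteins, dtype=bool)
    compartment[comp_idx] = True

    # Effect signs: compartment members are biased up in "high" with
    # probability compartment_up_prob; everything else is symmetric.
    p_up = np.where(compartment[de_idx], cfg.compartment_up_prob, 0.5)
    signs = np.where(rng_sign.random(n_de) < p_up, 1.0, -1.0)
    if cfg.effect_log2_magnitude is not None:
        mags = np.full(n_de, float(cfg.effect_log2_magnitude))
    else:
        mags = np.abs(rng_mag.normal(0.0, cfg.effect_log2_sd, n_de))
    effects = np.zeros(cfg.n_proteins)
    effects[de_idx] = signs * mags

    mean_low = baseline
    mean_high = baseline * np.power(2.0, effects)
    high = _nb_counts(
        rng_counts, mean_high[:, None], cfg.dispersion,
        (cfg.n_proteins, cfg.n_per_group),
    )
    low = _nb_counts(
        rng_counts, mean_low[:, None], cfg.dispersion,
        (cfg.n_proteins, cfg.n_per_group),
    )
    counts = pd.DataFrame(
        np.hstack([high, low]), index=proteins, columns=groups.index
    )

    truth = GroundTruth(
        effects=pd.Series(effects, index=proteins, name="effect_log2"),
        compartment=pd.Series(compartment, index=proteins, name="compartment"),
    )
    return CountMatrix(counts, groups), truth


def generate_regulator_network(
    truth: GroundTruth,
    consistency: float = 1.0,
    n_regulators: int = 3,
    targets_per_regulator: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a signed regulator->target network over planted DE proteins.

    Each regulator gets a latent state (+1 activated / -1 inhibited in
    group "high").  For a fraction ``consistency`` of its edges the
    literature direction is set so that (direction * planted sign)
    agrees with that state; the remaining edges disagree.  The edge
    table (columns regulator, target, direction) is also attached to
    ``truth.network`` with states in ``truth.regulator_states``.
    """
    if not 0.0 <= consistency <= 1.0:
        raise ConfigurationError("consistency must be a proportion in [0, 1]")
    de = truth.de_proteins
    if targets_per_regulator > len(de):
        raise ConfigurationError(
            f"requested {targets_per_regulator} targets per regulator but only "
            f"{len(de)} planted DE proteins are available"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    planted_sign = np.sign(truth.effects)

    rows = []
    states = {}
    for r in range(1, n_regulators + 1):
        name = f"REG{r:02d}"
        state = 1 if rng.random() < 0.5 else -1
        states[name] = state
        targets = rng.choice(np.asarray(de), size=targets_per_regulator, replace=False)
        n_consistent = int(round(consistency * targets_per_regulator))
        for j, t in enumerate(targets):
            want = state if j < n_consistent else -state
            # direction * observed sign == want  =>  direction = want * sign
            direction = int(want * planted_sign[t])
            rows.append((name, t, direction))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "direction"])
    truth.network = edges
    truth.regulator_states = pd.Series(states, name="state")
    return edges


def write_simulation(
    outdir: str | Path,
    matrix: CountMatrix,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the generated dataset as plain-text pipeline inputs.

    Emits the count matrix, group map, compartment symbol list, a small
    GMT file of ground-truth sets, the regulator network (if generated)
    and the ground-truth table.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["counts"] = outdir / "counts.tsv"
    matrix.counts.rename_axis("protein").to_csv(paths["counts"], sep="\t")
    paths["groups"] = outdir / "groups.tsv"
    matrix.groups.rename("group").rename_axis("sample").to_csv(
        paths["groups"], sep="\t"
    )
    paths["compartment"] = outdir / "compartment.txt"
    paths["compartment"].write_text(
        "".join(f"{p}\n" for p in truth.compartment.index[truth.compartment])
    )

    up = truth.effects.index[truth.effects > 0]
    down = truth.effects.index[truth.effects < 0]
    comp = truth.compartment.index[truth.compartment]
    paths["gmt"] = outdir / "truth_sets.gmt"
    with open(paths["gmt"], "w") as fh:
        for term, members in (
            ("PLANTED_UP", up), ("PLANTED_DOWN", down), ("COMPARTMENT", comp),
        ):
            fh.write("\t".join([term, f"synthetic {term.lower()} set", *members]) + "\n")

    if truth.network is not None:
        paths["network"] = outdir / "network.tsv"
        truth.network.to_csv(paths["network"], sep="\t", index=False)

    paths["truth"] = outdir / "ground_truth.tsv"
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    return paths
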