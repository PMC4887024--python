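"""End-to-end pipeline: normalize -> MA -> DE -> PIF -> skew ->
cluster -> enrichment -> regulators, with TSV outputs and a JSON run
summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import GROUP_HIGH, GROUP_LOW, CountMatrix
from .simulate import ConfigurationError
from .preprocess import normalize_total_counts, compute_ma
from .de import de_table, de_filter
from .pif import pif_table
from .mito import skew_report
from .cluster import row_standardize, hierarchical_cluster, export_heatmap
from .enrich import hypergeom_enrichment, regulator_predictions
from .io import atomic_write_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis.

    Defaults reproduce the published analysis choices: 0.05 pseudo
    count, abundance offset 4, 5% PIF tails, top 40 proteins for the
    heatmap, the 1.3-15 fold / p < 0.05 DE filter, and the z > 2.0 /
    qualified-band regulator classification.
    """

    pseudo_count: float = 0.05
    a_offset: float = 4.0
    tail_fraction: float = 0.05
    top_k: int = 40
    min_fold: float = 1.3
    max_fold: float = 15.0
    alpha: float = 0.05
    z_threshold: float = 2.0
    qualified_bands: tuple[float, float, float] = (1.7, 1.5, 1.0)
    use_justified_a: bool = True
    skew_method: str = "doubling"
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    heatmap_image: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudo_count < 0:
            raise ConfigurationError("pseudo_count must be non-negative")
        if not 0.0 < self.tail_fraction < 0.5:
            raise ConfigurationError("tail_fraction must lie in (0, 0.5)")
        if self.top_k <= 0 or self.top_k % 2:
            raise ConfigurationError("top_k must be a positive even integer")
        if not 1.0 < self.min_fold <= self.max_fold:
            raise ConfigurationError("need 1 < min_fold <= max_fold")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        hi, mid, lo = self.qualified_bands
        if not hi > mid > lo > 0:
            raise ConfigurationError(
                "qualified_bands must be strictly decreasing and > 0"
            )


def phenotype_contrast(values: pd.Series, groups: pd.Series) -> dict[str, float]:
    """Group means and their difference (high minus low) for a
    per-sample phenotype such as feed efficiency."""
    v = values.reindex(groups.index).astype(float)
    mean_high = float(v[groups == GROUP_HIGH].mean())
    mean_low = float(v[groups == GROUP_LOW].mean())
    return {
        "mean_high": mean_high,
        "mean_low": mean_low,
        "difference": mean_high - mean_low,
    }


def _stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:
        raise PipelineError(f"[{name}] {exc}") from exc


def run_pipeline(
    matrix: CountMatrix,
    config: PipelineConfig,
    outdir: str | Path,
    mito_symbols: set[str] | None = None,
    gmt_terms: dict[str, set[str]] | None = None,
    network: pd.DataFrame | None = None,
    phenotype: pd.Series | None = None,
) -> dict:
    """Run every stage for which inputs are available and write results.

    Stages with absent optional inputs (compartment list, term sets,
    regulator network) are skipped and recorded as such in the JSON
    summary.  Any stage error aborts with a stage-tagged message;
    outputs interrupted mid-write keep a '.partial' suffix.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "versions": {
            "pifomics": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "skipped": [],
    }

    def do_normalize() -> CountMatrix:
        nm = normalize_total_counts(matrix)
        atomic_write_table(
            nm.counts.rename_axis("protein"), outdir / "normalized_counts.tsv"
        )
        summary["stages"]["normalize"] = {"n_proteins": int(nm.counts.shape[0])}
        return nm

    normalized = _stage("normalize", do_normalize)

    def do_ma() -> pd.DataFrame:
        t = compute_ma(normalized, config.pseudo_count, config.a_offset)
        atomic_write_table(t, outdir / "ma_table.tsv")
        summary["stages"]["ma"] = {"n_proteins": int(len(t))}
        return t

    ma = _stage("ma", do_ma)

    def do_de() -> pd.DataFrame:
        t = de_table(normalized, config.pseudo_count)
        passed, n_up, n_down = de_filter(
            t, config.min_fold, config.max_fold, config.alpha
        )
        t["pass_de"] = t.index.isin(passed.index).astype(int)
        atomic_write_table(t, outdir / "de_table.tsv")
        summary["stages"]["de"] = {
            "n_proteins": int(len(t)),
            "n_pass": int(len(passed)),
            "n_up": n_up,
            "n_down": n_down,
            "d0": float(t.attrs["d0"]),
            "s0_2": float(t.attrs["s0_2"]),
        }
        return t

    de = _stage("de", do_de)

    def do_pif() -> pd.DataFrame:
        t = pif_table(
            ma, config.tail_fraction, config.top_k, config.use_justified_a
        )
        atomic_write_table(t, outdir / "pif_table.tsv")
        summary["stages"]["pif"] = {
            "n_proteins": int(len(t)),
            "n_up_tail": int((t["tail"] == "up").sum()),
            "n_down_tail": int((t["tail"] == "down").sum()),
        }
        return t

    pif = _stage("pif", do_pif)

    if mito_symbols is not None:
        def do_mito() -> None:
            rep = skew_report(ma, mito_symbols, pif, method=config.skew_method)
            atomic_write_table(
                pd.DataFrame([rep.to_dict()]), outdir / "mito_skew.tsv",
                index=False,
            )
            summary["stages"]["mito_skew"] = rep.to_dict()

        _stage("mito_skew", do_mito)
    else:
        summary["skipped"].append("mito_skew")
        logger.info("mito_skew stage skipped (no compartment list)")

    def do_cluster() -> None:
        top = pif.index[pif["topk_rank"] > 0]
        log2 = np.log2(normalized.counts.loc[top] + config.pseudo_count)
        std = row_standardize(log2)
        res = hierarchical_cluster(
            std, metric=config.cluster_metric, method=config.cluster_method
        )
        export_heatmap(
            res, std, outdir / "heatmap_ordered.tsv",
            outdir / "heatmap.png" if config.heatmap_image else None,
        )
        part = res.col_partition.rename_axis("sample").to_frame()
        part["group"] = matrix.groups.reindex(part.index)
        atomic_write_table(part, outdir / "cluster_partition.tsv")
        summary["stages"]["cluster"] = {
            "n_proteins": int(std.shape[0]),
            "purity": res.purity(matrix.groups),
        }

    _stage("cluster", do_cluster)

    bg = set(ma.index.astype(str).str.upper())
    if gmt_terms is not None:
        def do_enrich() -> None:
            frames = []
            for tail in ("up", "down"):
                target = set(
                    pif.index[pif["tail"] == tail].astype(str).str.upper()
                )
                res = hypergeom_enrichment(target, bg, gmt_terms)
                res.insert(0, "list", tail)
                frames.append(res)
            out = pd.concat(frames)
            atomic_write_table(out, outdir / "enrichment.tsv")
            summary["stages"]["enrichment"] = {"n_terms": int(len(out))}

        _stage("enrichment", do_enrich)
    else:
        summary["skipped"].append("enrichment")
        logger.info("enrichment stage skipped (no GMT term sets)")

    if network is not None:
        def do_regulators() -> None:
            passed = de.loc[de["pass_de"] == 1]
            observed = pd.Series(
                np.sign(passed["fold"]).astype(int),
                index=passed.index.astype(str).str.upper(),
            )
            res = regulator_predictions(
                network, observed, set(observed.index), bg,
                config.z_threshold, config.qualified_bands, config.alpha,
            )
            atomic_write_table(res, outdir / "regulators.tsv")
            summary["stages"]["regulators"] = {"n_regulators": int(len(res))}

        _stage("regulators", do_regulators)
    else:
        summary["skipped"].append("regulators")
        logger.info("regulators stage skipped (no network)")

    if phenotype is not None:
        summary["phenotype"] = phenotype_contrast(phenotype, matrix.groups)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
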