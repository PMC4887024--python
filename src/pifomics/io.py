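"""Readers and writers for the pipeline's plain-text formats.

Formats: TSV count matrices and result tables, one-symbol-per-line
annotation lists, GMT term sets, and a signed regulator-network TSV.
Symbols are whitespace-trimmed and upper-cased on input so that matching
is case-insensitive exact-string throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def _normalize_symbol(s: str) -> str:
    return s.strip().upper()


def read_count_matrix(path: str | Path, group_path: str | Path) -> CountMatrix:
    """Load a protein-by-sample count TSV and its sample->group map.

    The count file has a header row of sample ids and protein ids in the
    first column; the group file has columns (sample, group).  Proteins
    with zero counts in every sample are dropped (logged).
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate protein ids {dups}")
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric counts ({exc})") from exc

    gm = pd.read_csv(group_path, sep="\t")
    if gm.shape[1] < 2:
        raise ParseError(f"{group_path}: expected columns (sample, group)")
    gm = gm.iloc[:, :2]
    gm.columns = ["sample", "group"]
    if gm["sample"].duplicated().any():
        dups = gm.loc[gm["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"{group_path}: duplicate samples {dups}")
    unknown = set(gm["sample"].astype(str)) - set(counts.columns)
    if unknown:
        raise ValidationError(
            f"{group_path}: samples not present in the count matrix: "
            f"{sorted(unknown)}"
        )
    groups = gm.set_index("sample")["group"].astype(str)

    nonzero = counts.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropped %d all-zero protein(s)", n_dropped)
        counts = counts.loc[nonzero]

    return CountMatrix(counts, groups)


def write_count_matrix(matrix: CountMatrix, path: str | Path,
                       group_path: str | Path | None = None) -> None:
    matrix.counts.rename_axis("protein").to_csv(path, sep="\t")
    if group_path is not None:
        matrix.groups.rename("group").rename_axis("sample").to_csv(
            group_path, sep="\t"
        )


def read_symbol_list(path: str | Path) -> set[str]:
    """Read one symbol per line; trimmed, upper-cased, deduplicated."""
    symbols: list[str] = []
    for line in Path(path).read_text().splitlines():
        s = _normalize_symbol(line)
        if s:
            symbols.append(s)
    n_dup = len(symbols) - len(set(symbols))
    if n_dup:
        logger.warning("%s: %d duplicate symbol(s) collapsed", path, n_dup)
    return set(symbols)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: term, description, then tab-separated members.

    A term with zero members is retained with an empty set (warned).
    """
    terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs at least term and description"
            )
        term = fields[0].strip()
        members = {_normalize_symbol(f) for f in fields[2:] if f.strip()}
        if not members:
            logger.warning("%s:%d: term %r has no members", path, lineno, term)
        if term in terms:
            logger.warning("%s:%d: duplicate term %r merged", path, lineno, term)
            members |= terms[term]
        terms[term] = members
    return terms


def read_regulator_network(path: str | Path) -> pd.DataFrame:
    """Read a (regulator, target, direction) TSV; direction must be +/-1.

    The direction is the literature-expected regulation: +1 the regulator
    activates the target, -1 it represses it.
    """
    rows = []
    lines = Path(path).read_text().splitlines()
    start = 0
    if lines and lines[0].lower().startswith("regulator"):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        reg, target, direction = fields
        try:
            d = int(direction)
        except ValueError:
            d = None
        if d not in (1, -1):
            raise ParseError(
                f"{path}:{lineno}: direction must be +1 or -1, got {direction!r}"
            )
        rows.append((_normalize_symbol(reg), _normalize_symbol(target), d))
    df = pd.DataFrame(rows, columns=["regulator", "target", "direction"])
    n_dup = int(df.duplicated(["regulator", "target"]).sum())
    if n_dup:
        logger.warning("%s: %d duplicate edge(s) dropped", path, n_dup)
        df = df.drop_duplicates(["regulator", "target"], keep="first")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table with fixed column order and '.' decimals."""
    df.to_csv(path, sep="\t", index=index)


def atomic_write_table(df: pd.DataFrame, path: str | Path,
                       index: bool = True) -> None:
    """Write via a '.partial' file renamed on success, so an aborted run
    leaves its incomplete outputs marked."""
    path = Path(path)
    tmp = path.with_name(path.name + ".partial")
    df.to_csv(tmp, sep="\t", index=index)
    tmp.replace(path)
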