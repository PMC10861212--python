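"""Readers and writers for the on-disk artifacts the pipeline exchanges.

Every stage communicates through plain text: GMT gene sets (Broad dialect),
TSV edge lists for weighted gene networks, TSV differential-expression tables,
and TSV expression matrices.  All gene symbols pass through a single
normalization function (uppercase), which doubles as a pragmatic mouse→human
orthology mapping; an explicit orthology table can override it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "contrast", "timepoint", "log2fc", "p", "fdr", "mean_expr"]


class ParseError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: stripped, uppercase.

    Uppercasing doubles as the documented approximation for mouse→human
    symbol translation (true orthology tables can be supplied where needed).
    """
    return symbol.strip().upper()


def load_orthology(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping source symbols to target symbols."""
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {i}: expected 2 tab-separated columns")
        mapping[normalize_symbol(parts[0])] = normalize_symbol(parts[1])
    return mapping


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free collection of gene symbols."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet requires a nonempty name")
        normed = []
        seen = set()
        for g in self.genes:
            s = normalize_symbol(g)
            if s in seen:
                logger.warning("GeneSet %s: duplicate symbol %s dropped", self.name, s)
                continue
            seen.add(s)
            normed.append(s)
        object.__setattr__(self, "genes", tuple(normed))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in set(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: list[GeneSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {i}: GMT lines need >= 3 tab-separated fields")
        sets.append(GeneSet(name=parts[0], description=parts[1], genes=tuple(parts[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.description or "na", *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read a weighted undirected edge list TSV with columns geneA, geneB, weight.

    Repeated pairs keep the maximum weight; self-loops are dropped with a
    warning (the node survives only if another edge references it).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    required = {"geneA", "geneB", "weight"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a = normalize_symbol(str(row.geneA))
        b = normalize_symbol(str(row.geneB))
        w = float(row.weight)
        if not (0.0 < w <= 1.0):
            raise ParseError(f"{path}: edge {a}-{b} weight {w} outside (0, 1]")
        if a == b:
            logger.warning("%s: self-loop on %s dropped", path, a)
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    return g


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    rows = [f"{a}\t{b}\t{d['weight']:.6g}" for a, b, d in g.edges(data=True)]
    Path(path).write_text("geneA\tgeneB\tweight\n" + "\n".join(rows) + "\n")


def validate_de_table(df: pd.DataFrame, source: str = "DE table") -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing columns {missing}")
    df = df.copy()
    df["gene"] = df["gene"].map(normalize_symbol)
    for col in ("log2fc", "p", "fdr", "mean_expr"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ParseError(f"{source}: non-numeric {col} at row {int(bad.idxmax()) + 2}")
        df[col] = vals
    for col in ("p", "fdr"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            row = int(((df[col] < 0) | (df[col] > 1)).idxmax())
            raise ParseError(f"{source}: {col} outside [0, 1] at row {row + 2}")
    if df.duplicated(subset=["gene", "contrast", "timepoint"]).any():
        raise ParseError(f"{source}: duplicate (gene, contrast, timepoint) records")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene, per-contrast, per-timepoint DE table TSV."""
    df = pd.read_csv(path, sep="\t")
    return validate_de_table(df, source=str(path))


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=DE_COLUMNS)


def read_expr_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_symbol(str(g)) for g in df.index]
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene row {dup}")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative expression values")
    return df


def write_expr_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a sample→group TSV (columns: sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns sample, group")
    return dict(zip(df["sample"], df["group"]))


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Generic labelled numeric matrix TSV (signatures, perturbation libraries)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray, tuple, set, frozenset)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
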