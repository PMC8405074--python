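"""Readers and writers for the tabular formats the pipeline consumes.

All expression values are assumed to be post-normalised, log2-scale
measurements (the usual output of microarray preprocessing); raw platform
files are out of scope.  Gene symbols are normalised to a canonical key
(upper case, stripped) so that matrices, networks and gene-set libraries
from different sources join cleanly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netmark")

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "GeneSetLibrary",
    "normalize_symbol",
    "read_expression",
    "write_expression",
    "read_edgelist",
    "write_edgelist",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
    "read_qpcr",
    "write_qpcr",
    "write_table",
]

SURVIVAL_COLUMNS = ["subject", "time", "event", "expression"]
QPCR_COLUMNS = ["sample", "group", "ct_target", "ct_housekeeping"]


class ParseError(ValueError):
    """A file failed validation; the message names the offending location."""


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol key: strip surrounding whitespace, upper-case.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """Log2-scale gene-by-sample expression with a group label per sample.

    ``values`` is a genes x samples float DataFrame (index: unique symbols,
    columns: unique sample identifiers); ``groups`` maps every sample to a
    label (e.g. ``case``/``control``).
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate gene symbol after normalization: {dup}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ParseError(f"samples without a group label: {missing}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ParseError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


@dataclass
class GeneSetLibrary:
    """Named gene sets (GMT): term -> (description, member symbols)."""

    sets: dict[str, "GeneSet"] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.genes
        return out


@dataclass
class GeneSet:
    description: str
    genes: set[str]


def _read_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    return [ln for ln in lines if ln.strip() != ""]


def read_expression(path, group_assignment: dict[str, str]) -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample IDs, first column =
    gene symbols) and attach per-sample group labels.

    Symbols are normalised; duplicate symbol rows are collapsed to the row
    with the highest mean expression (the common probe->gene convention).
    """
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicate sample identifiers in header")
    unknown = [s for s in samples if s not in group_assignment]
    if unknown:
        raise ParseError(f"{path}: no group assignment for samples {unknown}")
    rows: list[tuple[str, list[float]]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(samples) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
            )
        symbol = normalize_symbol(fields[0])
        vals = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell in column {col} ({cell!r})"
                ) from None
            if not math.isfinite(v):
                raise ParseError(f"{path}:{lineno}: non-finite value in column {col}")
            vals.append(v)
        rows.append((symbol, vals))
    df = pd.DataFrame(
        [v for _, v in rows],
        index=[s for s, _ in rows],
        columns=samples,
        dtype=float,
    )
    if df.index.duplicated().any():
        # keep, per duplicated symbol, the row with highest mean expression
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.loc[sorted(df.index, key=lambda g: [s for s, _ in rows].index(g))]
    groups = {s: group_assignment[s] for s in samples}
    return ExpressionMatrix(values=df, groups=groups)


def write_expression(matrix: ExpressionMatrix, path, groups_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    if groups_path is not None:
        with open(groups_path, "w", encoding="utf-8") as fh:
            fh.write("sample\tgroup\n")
            for s in matrix.samples:
                fh.write(f"{s}\t{matrix.groups[s]}\n")


def read_groups(path) -> dict[str, str]:
    """Read a two-column sample/group TSV (header required)."""
    lines = _read_lines(path)
    if not lines or lines[0].split("\t")[:2] != ["sample", "group"]:
        raise ParseError(f"{path}: expected header 'sample\\tgroup'")
    out: dict[str, str] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields")
        out[fields[0]] = fields[1]
    return out


def read_edgelist(path) -> nx.Graph:
    """Read a two-column (optional third weight column, ignored) edge list
    into a simple undirected graph.

    Duplicate and reversed pairs are merged; self-loops are dropped with a
    logged warning.
    """
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty edge list")
    g = nx.Graph()
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
        a, b = normalize_symbol(fields[0]), normalize_symbol(fields[1])
        if a == b:
            logger.warning("%s:%d: dropping self-loop %s-%s", path, lineno, a, b)
            continue
        g.add_edge(a, b)
    return g


def write_edgelist(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path) -> GeneSetLibrary:
    """Read a GMT gene-set library (term <TAB> description <TAB> genes...)."""
    lib = GeneSetLibrary()
    for lineno, ln in enumerate(_read_lines(path), start=1):
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        term = fields[0].strip()
        if term in lib.sets:
            raise ParseError(f"{path}:{lineno}: duplicate term name {term!r}")
        genes = {normalize_symbol(g) for g in fields[2:] if g.strip()}
        if not genes:
            raise ParseError(f"{path}:{lineno}: gene set {term!r} is empty")
        lib.sets[term] = GeneSet(description=fields[1], genes=genes)
    if not lib.sets:
        raise ParseError(f"{path}: empty GMT file")
    return lib


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, gs in library:
            fh.write("\t".join([term, gs.description, *sorted(gs.genes)]) + "\n")


def _read_columned(path, required: list[str]) -> pd.DataFrame:
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    for col in required:
        if col not in header:
            raise ParseError(f"{path}: missing required column {col!r}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{path}:{lineno}: ragged row")
        rows.append(fields)
    return pd.DataFrame(rows, columns=header)[required]


def read_survival(path) -> pd.DataFrame:
    """Read a survival table: subject, time (>0), event (0/1), expression."""
    df = _read_columned(path, SURVIVAL_COLUMNS)
    try:
        df["time"] = df["time"].astype(float)
        df["expression"] = df["expression"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric time/expression value ({exc})") from None
    if not set(df["event"]) <= {"0", "1"}:
        bad = sorted(set(df["event"]) - {"0", "1"})
        raise ParseError(f"{path}: event values must be 0/1, got {bad}")
    df["event"] = df["event"].astype(int)
    if (df["time"] <= 0).any():
        raise ParseError(f"{path}: follow-up times must be > 0")
    return df.reset_index(drop=True)


def write_survival(df: pd.DataFrame, path) -> None:
    df[SURVIVAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_qpcr(path) -> pd.DataFrame:
    """Read a Ct table: sample, group, ct_target, ct_housekeeping."""
    df = _read_columned(path, QPCR_COLUMNS)
    try:
        df["ct_target"] = df["ct_target"].astype(float)
        df["ct_housekeeping"] = df["ct_housekeeping"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric Ct value ({exc})") from None
    cts = df[["ct_target", "ct_housekeeping"]].to_numpy()
    if not (np.isfinite(cts).all() and (cts > 0).all()):
        raise ParseError(f"{path}: Ct values must be finite and positive")
    if df["group"].nunique() < 2:
        raise ParseError(f"{path}: need at least 2 groups for comparative analysis")
    return df.reset_index(drop=True)


def write_qpcr(df: pd.DataFrame, path) -> None:
    df[QPCR_COLUMNS].to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV without the index."""
    df.to_csv(path, sep="\t", index=False)
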