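"""Readers and writers for the pipeline's text formats.

All formats are plain tab-delimited UTF-8 text with LF line endings and fixed
column orders, so outputs are bit-exact across runs:

* expression matrix — first column gene identifiers, header encodes
  ``t<hours>_rep<index>`` per sample column;
* GRP / GMT gene-set collections;
* SIF and weighted edge-list TSV for networks;
* genes × perturbations integer rank matrix for signature references.

Loading never rescales or imputes values; malformed input raises
:class:`FormatError` with the offending record named.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionSeries",
    "GeneSetCollection",
    "SignatureReference",
    "read_expression_table",
    "write_expression_table",
    "read_gene_sets",
    "write_gene_set",
    "read_network",
    "write_network",
    "read_signature_reference",
    "write_signature_reference",
]

DEFAULT_HEADER_PATTERN = r"t(?P<time>\d+(?:\.\d+)?)_rep(?P<rep>\d+)"


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


@dataclass(frozen=True)
class ExpressionSeries:
    """A log2-scale expression matrix with (time, replicate) sample annotations.

    Parameters
    ----------
    values
        genes × samples matrix; rows indexed by unique gene identifier,
        columns by sample label.
    times
        Time in hours for each sample column.
    replicates
        Replicate index (1-based) for each sample column.
    """

    values: pd.DataFrame
    times: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "replicates", np.asarray(self.replicates, dtype=int))
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise FormatError(f"duplicate gene identifiers: {dupes}")
        if len(self.times) != self.values.shape[1] or len(self.replicates) != self.values.shape[1]:
            raise FormatError("sample annotations do not match the number of columns")
        if np.any(self.times < 0):
            raise FormatError("negative time annotation")
        if np.any(self.replicates < 1):
            raise FormatError("replicate indices must be positive")
        pairs = list(zip(self.times.tolist(), self.replicates.tolist()))
        if len(set(pairs)) != len(pairs):
            raise FormatError("duplicate (time, replicate) sample annotation")
        if len(np.unique(self.times)) < 2:
            raise FormatError("an expression series needs at least 2 distinct time points")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)][:5].tolist()
            raise FormatError(f"missing values are an error, not imputed (first genes: {bad})")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def unique_times(self) -> np.ndarray:
        """Distinct time points in ascending order."""
        return np.unique(self.times)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, genes: Sequence[str]) -> "ExpressionSeries":
        """Restrict to the given genes, preserving their stated order."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from the series: {missing[:5]}")
        return ExpressionSeries(self.values.loc[list(genes)], self.times, self.replicates)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, non-empty sets of gene identifiers with optional descriptions."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class SignatureReference:
    """A genes × perturbations rank matrix.

    Each column is a permutation of ``1..N`` over a shared gene universe;
    rank 1 marks the gene most strongly up-regulated by that perturbation and
    rank N the most strongly down-regulated.
    """

    ranks: pd.DataFrame

    def __post_init__(self) -> None:
        n = self.ranks.shape[0]
        expected = np.arange(1, n + 1)
        for col in self.ranks.columns:
            vals = np.sort(self.ranks[col].to_numpy())
            if not np.array_equal(vals, expected):
                raise FormatError(
                    f"column {col!r} is not a permutation of 1..{n} (repeated or missing ranks)"
                )

    @property
    def universe(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def perturbations(self) -> list[str]:
        return list(self.ranks.columns)

    def ranking(self, perturbation: str) -> pd.Series:
        return self.ranks[perturbation]


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(
    path: str | Path, header_pattern: str = DEFAULT_HEADER_PATTERN
) -> ExpressionSeries:
    """Load a tab-delimited expression matrix.

    The first column holds gene identifiers; every other column header must
    match ``header_pattern`` with named groups ``time`` and ``rep``.
    """
    path = Path(path)
    pat = re.compile(header_pattern)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header has no sample columns")
        labels = header[1:]
        times, reps = [], []
        for label in labels:
            m = pat.fullmatch(label)
            if m is None:
                raise FormatError(f"{path}: unparseable sample header column {label!r}")
            times.append(float(m.group("time")))
            reps.append(int(m.group("rep")))
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            genes.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    seen: set[str] = set()
    dupes = sorted({g for g in genes if g in seen or seen.add(g)})  # type: ignore[func-returns-value]
    if dupes:
        raise FormatError(f"{path}: duplicate gene rows: {dupes}")
    values = pd.DataFrame(rows, index=genes, columns=labels, dtype=float)
    return ExpressionSeries(values, np.array(times), np.array(reps))


def write_expression_table(series: ExpressionSeries, path: str | Path) -> None:
    """Write a series as tab-delimited text with ``t<h>_rep<j>`` headers."""
    path = Path(path)
    labels = [_sample_label(t, r) for t, r in zip(series.times, series.replicates)]
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(labels) + "\n")
        for gene, row in series.values.iterrows():
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _sample_label(time_h: float, rep: int) -> str:
    t = int(time_h) if float(time_h).is_integer() else time_h
    return f"t{t}_rep{rep}"


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(
    path: str | Path, dialect: str | None = None, upper: bool = False
) -> GeneSetCollection:
    """Read a GRP (one identifier per line, one set) or GMT file.

    ``dialect`` defaults to the file extension. ``upper=True`` upper-cases
    identifiers on load (case-normalisation policy).
    """
    path = Path(path)
    dialect = (dialect or path.suffix.lstrip(".")).lower()
    if dialect not in {"grp", "gmt"}:
        raise FormatError(f"unknown gene-set dialect {dialect!r}")
    norm = (lambda g: g.upper()) if upper else (lambda g: g)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        if dialect == "grp":
            members = frozenset(norm(line.strip()) for line in fh if line.strip())
            if not members:
                raise FormatError(f"{path}: empty gene set")
            sets[path.stem] = members
        else:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: GMT line needs name, description, members")
                name, desc = parts[0], parts[1]
                if name in sets:
                    raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
                members = frozenset(norm(g) for g in parts[2:] if g)
                if not members:
                    raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
                sets[name] = members
                descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    """Write one gene set as a GRP file (sorted, one identifier per line)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# networks


def write_network(graph: nx.Graph, path: str | Path, dialect: str = "tsv") -> None:
    """Write a gene association network as SIF or weighted edge-list TSV.

    SIF uses the relation token ``pcor``; the TSV columns are
    ``geneA  geneB  pcor  p  p_adjusted``. Edges are emitted in lexicographic
    order of the (sorted) endpoint pair so output is deterministic.
    """
    if any(u == v for u, v in graph.edges):
        raise FormatError("self-loops are not allowed in a gene association network")
    path = Path(path)
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in graph.edges)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if dialect == "sif":
            for u, v in edges:
                fh.write(f"{u}\tpcor\t{v}\n")
        elif dialect == "tsv":
            fh.write("geneA\tgeneB\tpcor\tp\tp_adjusted\n")
            for u, v in edges:
                data = graph.edges[u, v]
                fh.write(
                    f"{u}\t{v}\t{data.get('pcor', float('nan'))!r}"
                    f"\t{data.get('p', float('nan'))!r}"
                    f"\t{data.get('p_adjusted', float('nan'))!r}\n"
                )
        else:
            raise FormatError(f"unknown network dialect {dialect!r}")


def read_network(path: str | Path) -> nx.Graph:
    """Read a weighted edge-list TSV written by :func:`write_network`."""
    path = Path(path)
    graph = nx.Graph()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["geneA", "geneB"]:
            raise FormatError(f"{path}: not a weighted edge-list TSV")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{path}:{lineno}: ragged row")
            u, v, pcor, p, p_adj = parts
            graph.add_edge(u, v, pcor=float(pcor), p=float(p), p_adjusted=float(p_adj))
    return graph


# ---------------------------------------------------------------------------
# signature references


def read_signature_reference(path: str | Path) -> SignatureReference:
    """Read a genes × perturbations integer rank matrix."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene identifiers")
    try:
        ranks = df.astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer rank ({exc})") from exc
    if not (ranks == df).all().all():
        raise FormatError(f"{path}: ranks must be integers")
    ranks.index = ranks.index.astype(str)
    ranks.columns = ranks.columns.astype(str)
    return SignatureReference(ranks)


def write_signature_reference(reference: SignatureReference, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(reference.perturbations) + "\n")
        for gene, row in reference.ranks.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
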