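"""Directed simple graph container and edge-list / GML / GraphML I/O.

Graphs are :class:`networkx.DiGraph` instances with opaque string node
labels.  All functions in this package assume (and preserve) simplicity:
no self-loops and no duplicate directed links.  A bidirectional pair
(i->j and j->i) is two distinct links and is allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Union

import networkx as nx

logger = logging.getLogger("ditruss")

__all__ = [
    "CleanupReport",
    "EdgeListError",
    "read_edge_list",
    "write_edge_list",
    "read_network",
    "write_network",
    "max_degree",
    "reciprocity",
    "check_simple",
]


class EdgeListError(ValueError):
    """Malformed edge-list input, or a simplicity violation under strict policy."""


@dataclass
class CleanupReport:
    """What :func:`read_edge_list` dropped or ignored while parsing."""

    lines: int = 0
    links: int = 0
    self_loops: int = 0
    duplicates: int = 0
    extra_field_lines: int = 0

    def dirty(self) -> bool:
        return bool(self.self_loops or self.duplicates)


def _detect_delimiter(line: str) -> Union[str, None]:
    # Auto-detect among tab / comma / generic whitespace.
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # str.split(None): any whitespace run


def read_edge_list(
    source: Union[str, Path, IO[str], Iterable[str]],
    strict: bool = False,
) -> tuple[nx.DiGraph, CleanupReport]:
    """Parse a two-column edge list into a simple directed graph.

    Parameters
    ----------
    source
        Path, open text stream, or iterable of lines.  Lines starting
        with ``#`` and blank lines are skipped.  The delimiter is
        auto-detected (tab, comma, or whitespace) from the first data
        line.  Fields beyond the second (e.g. weights) are ignored.
    strict
        If True, self-loops and duplicate directed links raise
        :class:`EdgeListError` instead of being dropped, and empty
        input is an error.

    Returns
    -------
    (graph, report)
        The cleaned graph and a :class:`CleanupReport` of what was
        dropped.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_edge_list(fh, strict=strict)

    g = nx.DiGraph()
    report = CleanupReport()
    delim: Union[str, None] = None
    delim_set = False

    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        report.lines += 1
        if not delim_set:
            delim = _detect_delimiter(line)
            delim_set = True
        fields = line.split(delim)
        fields = [f for f in fields if f != ""]
        if len(fields) < 2:
            raise EdgeListError(
                f"line {lineno}: expected at least 2 fields, got {len(fields)}: {line!r}"
            )
        if len(fields) > 2:
            report.extra_field_lines += 1
        u, v = fields[0], fields[1]
        if u == v:
            report.self_loops += 1
            if strict:
                raise EdgeListError(f"line {lineno}: self-loop {u!r} -> {v!r}")
            logger.warning("dropping self-loop %s -> %s (line %d)", u, v, lineno)
            continue
        if g.has_edge(u, v):
            report.duplicates += 1
            if strict:
                raise EdgeListError(f"line {lineno}: duplicate link {u!r} -> {v!r}")
            logger.warning("dropping duplicate link %s -> %s (line %d)", u, v, lineno)
            continue
        g.add_edge(u, v)
        report.links += 1

    if report.extra_field_lines:
        logger.info(
            "ignored extra fields (e.g. weights) on %d lines", report.extra_field_lines
        )
    if strict and report.lines == 0:
        raise EdgeListError("empty input under strict policy")
    return g, report


def write_edge_list(graph: nx.DiGraph, stream: Union[IO[str], None] = None) -> str:
    """Serialize as ``source<TAB>target`` lines in lexicographic order.

    Round-trips exactly through :func:`read_edge_list`.  Returns the
    text; also writes it to *stream* if given.
    """
    lines = [f"{u}\t{v}\n" for u, v in sorted(graph.edges())]
    text = "".join(lines)
    if stream is not None:
        stream.write(text)
    return text


_FORMATS = ("edgelist", "gml", "graphml")


def _infer_format(path: Union[str, Path]) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".gml":
        return "gml"
    if suffix == ".graphml":
        return "graphml"
    return "edgelist"


def read_network(
    path: Union[str, Path], fmt: Union[str, None] = None, strict: bool = False
) -> tuple[nx.DiGraph, CleanupReport]:
    """Read a directed network from edge-list, GML or GraphML.

    Format is inferred from the file suffix unless *fmt* is given.
    GML/GraphML input is coerced to a simple DiGraph (self-loops
    removed; an undirected file is interpreted as reciprocal links).
    """
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        return read_edge_list(path, strict=strict)
    if fmt == "gml":
        raw = nx.read_gml(str(path), label="label")
    else:
        raw = nx.read_graphml(str(path))
    g = nx.DiGraph()
    report = CleanupReport()
    g.add_nodes_from(str(n) for n in raw.nodes())
    for u, v in raw.to_directed().edges():
        u, v = str(u), str(v)
        if u == v:
            report.self_loops += 1
            if strict:
                raise EdgeListError(f"self-loop {u!r} in {path}")
            continue
        if not g.has_edge(u, v):
            g.add_edge(u, v)
            report.links += 1
    return g, report


def write_network(graph: nx.DiGraph, path: Union[str, Path], fmt: Union[str, None] = None) -> None:
    """Write a directed network as edge-list, GML or GraphML (by suffix)."""
    fmt = fmt or _infer_format(path)
    if fmt == "edgelist":
        with open(path, "wt", encoding="utf-8") as fh:
            write_edge_list(graph, fh)
    elif fmt == "gml":
        nx.write_gml(graph, str(path))
    elif fmt == "graphml":
        nx.write_graphml(graph, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def check_simple(graph: nx.DiGraph) -> None:
    """Raise if *graph* violates the simplicity contract (self-loops)."""
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise EdgeListError(f"graph has {len(loops)} self-loop(s), e.g. {loops[0]}")


def max_degree(graph: nx.DiGraph) -> int:
    """Maximum total degree (in + out) over nodes; 0 for an empty graph.

    Reported informationally only: truss levels are not bounded by it
    in any form this package asserts.
    """
    if graph.number_of_nodes() == 0:
        return 0
    return max(d for _, d in graph.degree())


def reciprocity(graph: nx.DiGraph) -> float:
    """Fraction of links that sit in a bidirectional pair.

    Defined as twice the number of bidirectionally adjacent node pairs
    divided by the total number of directed links; lies in [0, 1] and
    equals 1 iff every link is reciprocated.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("reciprocity is undefined for a graph with no links")
    mutual = sum(1 for u, v in graph.edges() if u < v and graph.has_edge(v, u))
    return 2.0 * mutual / m
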