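"""Reading, validating and exporting causal loop diagrams.

A causal loop diagram (CLD) is a directed, unweighted network whose nodes
are *variables* (dynamic causes or effects of a problem, identified by a
positive integer id and a human-readable name) and whose edges are
*causal links* (directed cause–effect arrows, optionally signed with a
polarity).  The on-disk representation is two delimited text files: a
variable key mapping ids to names, and an edge list of (source, target)
id pairs with an optional polarity column.

Polarity is parsed and stored but deliberately ignored by every metric in
this package: the analysis treats the CLD as an unsigned directed graph.
"""

from __future__ import annotations

import csv
import io
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

logger = logging.getLogger("cldnet")

Polarity = Literal["positive", "negative", "unknown"]

_POLARITY_ALIASES: dict[str, Polarity] = {
    "positive": "positive", "pos": "positive", "+": "positive", "1": "positive",
    "s": "positive",  # "same direction" notation
    "negative": "negative", "neg": "negative", "-": "negative", "-1": "negative",
    "o": "negative",  # "opposite direction" notation
    "": "unknown", "unknown": "unknown", "?": "unknown", "0": "unknown",
}


class CLDError(Exception):
    """Base class for all CLD construction and parsing errors."""


class MissingInputError(CLDError):
    """An input file does not exist."""


class VariableKeyError(CLDError):
    """Malformed variable key file (bad id, duplicate id, empty name...)."""


class EdgeListError(CLDError):
    """Malformed edge list file (non-integer endpoint, bad row shape...)."""


class SelfLoopError(EdgeListError):
    """A row declares a variable as its own direct cause.

    At the grain of a CLD a variable "causing itself" carries no meaning
    and would corrupt the N(N-1) density denominator, so it is rejected
    rather than silently dropped.
    """


class EmptyGraphError(CLDError):
    """A graph was requested over an empty variable set."""


class UnknownFormatError(CLDError):
    """Unrecognised export format name."""


@dataclass(frozen=True)
class Dialect:
    """Delimited-text configuration for key and edge-list files.

    ``id_col``/``name_col`` locate the variable key columns and
    ``source_col``/``target_col`` the edge-list columns.  With
    ``header=True`` they may be column names; otherwise they are
    0-based positional indices.
    """

    delimiter: str = ","
    header: bool = True
    id_col: str | int = 0
    name_col: str | int = 1
    source_col: str | int = 0
    target_col: str | int = 1


@dataclass(frozen=True, order=True)
class Variable:
    """A CLD variable: integer id plus human-readable label."""

    id: int
    name: str


@dataclass(frozen=True, order=True)
class CausalLink:
    """A directed causal arrow between two variables, optionally signed."""

    source: int
    target: int
    polarity: Polarity = "unknown"


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


def parse_polarity(raw: str) -> Polarity:
    """Map a raw polarity token to {positive, negative, unknown}."""
    return _POLARITY_ALIASES.get(raw.strip().lower(), "unknown")


def _resolve_col(col: str | int, fieldnames: Sequence[str] | None,
                 row_len: int, what: str, err: type[CLDError]) -> int:
    if isinstance(col, int):
        if col >= row_len:
            raise err(f"{what} column index {col} out of range for row of width {row_len}")
        return col
    if fieldnames is None:
        raise err(f"{what} column given by name {col!r} but the file has no header")
    try:
        return list(fieldnames).index(col)
    except ValueError:
        raise err(f"{what} column {col!r} not found in header {list(fieldnames)}") from None


def _open_rows(path: str | Path, dialect: Dialect,
               err: type[CLDError]) -> tuple[list[list[str]], list[str] | None]:
    p = Path(path)
    if not p.exists():
        raise MissingInputError(f"input file not found: {p}")
    with p.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=dialect.delimiter) if any(c.strip() for c in r)]
    if not rows:
        raise err(f"file {p} is empty")
    header = None
    if dialect.header:
        header = [c.strip() for c in rows[0]]
        rows = rows[1:]
    return rows, header


def read_variable_key(path: str | Path, dialect: Dialect = Dialect()) -> list[Variable]:
    """Read the variable key (id → name) from a delimited text file.

    File order is preserved.  Duplicate ids, duplicate names (after
    whitespace normalisation), non-integer ids and empty names each raise
    :class:`VariableKeyError`.
    """
    rows, header = _open_rows(path, dialect, VariableKeyError)
    variables: list[Variable] = []
    seen_ids: set[int] = set()
    seen_names: dict[str, int] = {}
    for lineno, row in enumerate(rows, start=2 if dialect.header else 1):
        i = _resolve_col(dialect.id_col, header, len(row), "id", VariableKeyError)
        j = _resolve_col(dialect.name_col, header, len(row), "name", VariableKeyError)
        raw_id = row[i].strip()
        try:
            vid = int(raw_id)
        except ValueError:
            raise VariableKeyError(f"non-integer variable id {raw_id!r} at line {lineno}") from None
        if vid <= 0:
            raise VariableKeyError(f"variable id must be positive, got {vid} at line {lineno}")
        name = row[j].strip()
        if not name:
            raise VariableKeyError(f"empty variable name for id {vid} at line {lineno}")
        if vid in seen_ids:
            raise VariableKeyError(f"duplicate variable id {vid} at line {lineno}")
        norm = _normalize_name(name)
        if norm in seen_names:
            raise VariableKeyError(
                f"duplicate variable name {name!r} at line {lineno} "
                f"(clashes with id {seen_names[norm]} after whitespace normalisation)")
        seen_ids.add(vid)
        seen_names[norm] = vid
        variables.append(Variable(vid, name))
    return variables


def read_edge_list(path: str | Path, dialect: Dialect = Dialect(),
                   polarity_column: str | int | None = None) -> list[CausalLink]:
    """Read the directed edge list from a delimited text file.

    Duplicate (source, target) rows are collapsed to one link with a
    logged warning (the network is unweighted).  Self-loop rows raise
    :class:`SelfLoopError` naming the offending row.  When
    ``polarity_column`` is given the sign is parsed from it; otherwise
    every link's polarity is ``unknown``.
    """
    rows, header = _open_rows(path, dialect, EdgeListError)
    links: list[CausalLink] = []
    seen: set[tuple[int, int]] = set()
    for lineno, row in enumerate(rows, start=2 if dialect.header else 1):
        i = _resolve_col(dialect.source_col, header, len(row), "source", EdgeListError)
        j = _resolve_col(dialect.target_col, header, len(row), "target", EdgeListError)
        try:
            s = int(row[i].strip())
            t = int(row[j].strip())
        except ValueError:
            raise EdgeListError(
                f"non-integer endpoint in row {row!r} at line {lineno}") from None
        if s == t:
            raise SelfLoopError(f"self-loop row {row!r} at line {lineno}: variable {s} cannot cause itself")
        pol: Polarity = "unknown"
        if polarity_column is not None:
            k = _resolve_col(polarity_column, header, len(row), "polarity", EdgeListError)
            pol = parse_polarity(row[k])
        if (s, t) in seen:
            logger.warning("duplicate edge (%d, %d) at line %d collapsed", s, t, lineno)
            continue
        seen.add((s, t))
        links.append(CausalLink(s, t, pol))
    return links


class CLDGraph:
    """Directed unweighted graph over integer-id variables with name labels.

    Isolates (degree-0 variables) are first-class citizens: they count
    toward N and appear in every per-variable table.  Successor and
    predecessor lists are kept sorted so all traversals are deterministic.
    """

    def __init__(self, variables: Iterable[Variable], links: Iterable[CausalLink]):
        self._names: dict[int, str] = {}
        for v in variables:
            if v.id in self._names:
                raise VariableKeyError(f"duplicate variable id {v.id}")
            self._names[v.id] = v.name
        if not self._names:
            raise EmptyGraphError("a CLD graph needs at least one variable")
        self._succ: dict[int, list[int]] = {v: [] for v in self._names}
        self._pred: dict[int, list[int]] = {v: [] for v in self._names}
        self._polarity: dict[tuple[int, int], Polarity] = {}
        for link in links:
            if link.source == link.target:
                raise SelfLoopError(f"self-loop on variable {link.source}")
            for end in (link.source, link.target):
                if end not in self._names:
                    raise EdgeListError(f"link endpoint {end} is not a known variable")
            key = (link.source, link.target)
            if key in self._polarity:
                logger.warning("duplicate link %s collapsed", key)
                continue
            self._polarity[key] = link.polarity
            self._succ[link.source].append(link.target)
            self._pred[link.target].append(link.source)
        for adj in (self._succ, self._pred):
            for k in adj:
                adj[k].sort()

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self._names)

    @property
    def n_edges(self) -> int:
        return len(self._polarity)

    def nodes(self) -> list[int]:
        """Variable ids in ascending order."""
        return sorted(self._names)

    def name(self, node: int) -> str:
        return self._names[node]

    def names(self) -> Mapping[int, str]:
        return dict(self._names)

    def has_node(self, node: int) -> bool:
        return node in self._names

    def has_edge(self, source: int, target: int) -> bool:
        return (source, target) in self._polarity

    def successors(self, node: int) -> list[int]:
        return self._succ[node]

    def predecessors(self, node: int) -> list[int]:
        return self._pred[node]

    def edges(self) -> Iterator[CausalLink]:
        for (s, t) in sorted(self._polarity):
            yield CausalLink(s, t, self._polarity[(s, t)])

    def polarity(self, source: int, target: int) -> Polarity:
        return self._polarity[(source, target)]

    def isolates(self) -> list[int]:
        return [v for v in self.nodes() if not self._succ[v] and not self._pred[v]]

    def variables(self) -> list[Variable]:
        return [Variable(v, self._names[v]) for v in self.nodes()]

    def reversed(self) -> "CLDGraph":
        """Graph with every arc flipped (used by tests and path tracing)."""
        return CLDGraph(self.variables(),
                        [CausalLink(l.target, l.source, l.polarity) for l in self.edges()])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CLDGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CLDGraph):
            return NotImplemented
        return self._names == other._names and self._polarity == other._polarity

    def __hash__(self):  # graphs are mutable in principle; identity hash
        return id(self)


def build_graph(variables: Sequence[Variable], links: Sequence[CausalLink]) -> CLDGraph:
    """Assemble a :class:`CLDGraph` from a parsed key and edge list.

    The node universe is the union of the key and the edge endpoints;
    the key is authoritative for names.  Endpoints missing from the key
    are added as ``unlabelled-<id>`` with a warning, so an incomplete key
    never silently drops causal structure.
    """
    if not variables:
        raise EmptyGraphError("variable list is empty")
    known = {v.id for v in variables}
    extra: list[Variable] = []
    for link in links:
        for end in (link.source, link.target):
            if end not in known:
                logger.warning("edge endpoint %d absent from variable key; "
                               "added as unlabelled-%d", end, end)
                extra.append(Variable(end, f"unlabelled-{end}"))
                known.add(end)
    return CLDGraph(list(variables) + extra, links)


def read_cld(key_path: str | Path, edges_path: str | Path,
             dialect: Dialect = Dialect(),
             polarity_column: str | int | None = None) -> CLDGraph:
    """Convenience: key + edge list → validated graph."""
    return build_graph(read_variable_key(key_path, dialect),
                       read_edge_list(edges_path, dialect, polarity_column))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_graph(g: CLDGraph, format: str) -> str:
    """Serialize a graph as ``edge-csv``, ``graphml`` or ``dot`` text.

    ``edge-csv`` is round-trip safe: re-reading it with
    :func:`read_edge_list` reproduces the link set exactly.  GraphML
    nodes carry the variable name and edges the polarity, so external
    viewers can label the drawing.
    """
    if format == "edge-csv":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["source", "target", "polarity"])
        for link in g.edges():
            w.writerow([link.source, link.target, link.polarity])
        return buf.getvalue()
    if format == "graphml":
        return _to_graphml(g)
    if format == "dot":
        lines = ["digraph CLD {"]
        for v in g.nodes():
            lines.append(f'  n{v} [label="{_dot_escape(g.name(v))}"];')
        for link in g.edges():
            attr = "" if link.polarity == "unknown" else f' [label="{link.polarity[0]}"]'
            lines.append(f"  n{link.source} -> n{link.target}{attr};")
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise UnknownFormatError(f"unknown export format {format!r}; "
                             "expected one of edge-csv, graphml, dot")


def export_variable_key(g: CLDGraph) -> str:
    """Serialize the id → name key as CSV (inverse of read_variable_key)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["id", "name"])
    for v in g.nodes():
        w.writerow([v, g.name(v)])
    return buf.getvalue()


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _to_graphml(g: CLDGraph) -> str:
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    key_name = ET.SubElement(root, f"{{{ns}}}key", id="d_name", attrib={
        "for": "node", "attr.name": "name", "attr.type": "string"})
    key_pol = ET.SubElement(root, f"{{{ns}}}key", id="d_pol", attrib={
        "for": "edge", "attr.name": "polarity", "attr.type": "string"})
    del key_name, key_pol
    graph = ET.SubElement(root, f"{{{ns}}}graph", id="CLD", edgedefault="directed")
    for v in g.nodes():
        node = ET.SubElement(graph, f"{{{ns}}}node", id=str(v))
        data = ET.SubElement(node, f"{{{ns}}}data", key="d_name")
        data.text = g.name(v)
    for link in g.edges():
        edge = ET.SubElement(graph, f"{{{ns}}}edge",
                             source=str(link.source), target=str(link.target))
        data = ET.SubElement(edge, f"{{{ns}}}data", key="d_pol")
        data.text = link.polarity
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"
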