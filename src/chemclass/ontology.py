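"""Ontology ingestion: chemical entries arranged by is-a links.

Two on-disk dialects are supported:

* **tsv** — one entry per row with columns ``id, name, definition, smiles,
  parents, star_rating, mappings``; ``parents`` and ``mappings`` are
  pipe-separated lists.
* **obograph-json** — the OBO-Graphs JSON exchange format: ``nodes`` carry
  ``id``, ``lbl``, ``meta.definition.val`` and ``meta.xrefs``; ``edges`` with
  ``pred == "is_a"`` carry the child→parent links.  SMILES strings and star
  ratings travel in ``meta.basicPropertyValues`` under predicates ending in
  ``smiles`` / ``star_rating``.

The loaded graph is validated: every parent reference must resolve and the
is-a relation must be acyclic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "OntologyEntry",
    "OntologyGraph",
    "OntologyParseError",
    "DanglingReferenceError",
    "CycleError",
    "load_ontology",
]

TSV_COLUMNS = ("id", "name", "definition", "smiles", "parents", "star_rating", "mappings")


class OntologyParseError(ValueError):
    """Raised when an ontology document cannot be parsed or validated."""


class DanglingReferenceError(OntologyParseError):
    """An is-a edge points at an id that does not exist in the document."""


class CycleError(OntologyParseError):
    """The is-a relation contains a cycle; one witness cycle is reported."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("is-a cycle detected: " + " -> ".join(cycle + cycle[:1]))


@dataclass(frozen=True)
class OntologyEntry:
    """One chemical entry: either a concrete structure or a grouping class."""

    id: str
    name: str
    definition: str | None = None
    smiles: str | None = None
    parents: tuple[str, ...] = ()
    star_rating: int | None = None
    mappings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyParseError("entry with empty id")
        if self.smiles is not None and self.smiles == "":
            raise OntologyParseError(f"{self.id}: smiles present but empty")


@dataclass
class OntologyGraph:
    """Validated ontology: entries keyed by id plus the is-a child→parent adjacency."""

    entries: dict[str, OntologyEntry] = field(default_factory=dict)

    @property
    def edges(self) -> dict[str, tuple[str, ...]]:
        return {e.id: e.parents for e in self.entries.values() if e.parents}

    def children_of(self) -> dict[str, list[str]]:
        """Reverse adjacency: parent id -> list of direct child ids."""
        rev: dict[str, list[str]] = {eid: [] for eid in self.entries}
        for entry in self.entries.values():
            for parent in entry.parents:
                rev[parent].append(entry.id)
        return rev

    def to_networkx(self) -> "nx.DiGraph":
        """Child→parent directed graph over all entries (isolates included)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.entries)
        for entry in self.entries.values():
            for parent in entry.parents:
                g.add_edge(entry.id, parent)
        return g

    def validate(self) -> None:
        for entry in self.entries.values():
            for parent in entry.parents:
                if parent not in self.entries:
                    raise DanglingReferenceError(
                        f"entry {entry.id!r} references missing parent {parent!r}"
                    )
        g = self.to_networkx()
        try:
            cycle_edges = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([u for u, _ in cycle_edges])


def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(part for part in (p.strip() for p in cell.split("|")) if part)


def _entries_from_tsv(path: Path) -> Iterable[OntologyEntry]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise OntologyParseError(f"{path}: missing header row with an 'id' column")
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get("id") or "").strip()
            if not rid:
                raise OntologyParseError(f"{path}:{lineno}: record with empty id")
            star = (row.get("star_rating") or "").strip()
            try:
                yield OntologyEntry(
                    id=rid,
                    name=(row.get("name") or rid).strip(),
                    definition=(row.get("definition") or "").strip() or None,
                    smiles=(row.get("smiles") or "").strip() or None,
                    parents=_split_list(row.get("parents") or ""),
                    star_rating=int(star) if star else None,
                    mappings=_split_list(row.get("mappings") or ""),
                )
            except ValueError as exc:
                raise OntologyParseError(f"{path}:{lineno}: {exc}") from exc


def _entries_from_obograph(path: Path) -> Iterable[OntologyEntry]:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OntologyParseError(f"{path}: invalid JSON ({exc})") from exc
    graphs = doc.get("graphs")
    if not graphs:
        raise OntologyParseError(f"{path}: no 'graphs' array")
    graph = graphs[0]
    parents: dict[str, list[str]] = {}
    for edge in graph.get("edges", []):
        if edge.get("pred") == "is_a":
            parents.setdefault(edge["sub"], []).append(edge["obj"])
    for node in graph.get("nodes", []):
        nid = node.get("id")
        if not nid:
            raise OntologyParseError(f"{path}: node without id: {node!r}")
        meta = node.get("meta") or {}
        definition = (meta.get("definition") or {}).get("val")
        smiles = None
        star = None
        for bpv in meta.get("basicPropertyValues", []):
            pred = str(bpv.get("pred", "")).lower()
            if pred.endswith("smiles"):
                smiles = bpv.get("val")
            elif pred.endswith("star_rating"):
                star = int(bpv.get("val"))
        mappings = tuple(x.get("val", "") for x in meta.get("xrefs", []) if x.get("val"))
        yield OntologyEntry(
            id=nid,
            name=node.get("lbl", nid),
            definition=definition or None,
            smiles=smiles or None,
            parents=tuple(parents.get(nid, ())),
            star_rating=star,
            mappings=mappings,
        )


def load_ontology(source: str | Path, dialect: str = "tsv") -> OntologyGraph:
    """Load and validate an ontology document.

    Parameters
    ----------
    source:
        Path to the document.
    dialect:
        ``"tsv"`` or ``"obograph-json"``.

    Raises
    ------
    OntologyParseError
        On malformed documents, duplicate ids, dangling parent references
        (:class:`DanglingReferenceError`) or is-a cycles (:class:`CycleError`).
    """
    path = Path(source)
    if dialect == "tsv":
        entries = _entries_from_tsv(path)
    elif dialect == "obograph-json":
        entries = _entries_from_obograph(path)
    else:
        raise ValueError(f"unknown ontology dialect {dialect!r}")
    graph = OntologyGraph()
    for entry in entries:
        if entry.id in graph.entries:
            raise OntologyParseError(f"{path}: duplicate id {entry.id!r}")
        graph.entries[entry.id] = entry
    graph.validate()
    return graph
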