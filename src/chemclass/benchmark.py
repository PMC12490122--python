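"""Benchmark construction from an ontology of chemical entries.

Entries are partitioned into *structures* (leaf entries with a ground,
wildcard-free SMILES), *classes* (direct or indirect is-a superclasses of at
least one structure — any SMILES attached to a class is deliberately
ignored), and *discarded* entries (everything else, which sweeps up roles,
obsolete terms and wildcard structures automatically).

Class membership follows the true path rule: a structure is a positive
example of every ancestor class, and negatives are implicit (every benchmark
structure that is not a positive).  Classes are then filtered on member
count and on having a textual definition, and the structures receive a
single global seeded train/test split.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .ontology import OntologyGraph, load_ontology

__all__ = [
    "Structure",
    "BenchmarkClass",
    "Benchmark",
    "partition_entries",
    "compute_positives",
    "apply_class_filters",
    "split_structures",
    "make_slim",
    "build_benchmark",
    "save_benchmark",
    "load_benchmark",
]

WILDCARD = "*"


@dataclass(frozen=True)
class Structure:
    """A concrete molecule: leaf ontology entry with a ground SMILES."""

    id: str
    name: str
    smiles: str

    def __post_init__(self) -> None:
        if WILDCARD in self.smiles:
            raise ValueError(f"{self.id}: structure SMILES contains a wildcard")


@dataclass
class BenchmarkClass:
    """A grouping class with its true-path-closed positive structure ids."""

    id: str
    name: str
    definition: str | None
    positive_ids: frozenset[str]
    mappings: tuple[str, ...] = ()

    def negative_ids(self, universe: Iterable[str]) -> frozenset[str]:
        """Implicit negatives: every benchmark structure not a positive."""
        return frozenset(universe) - self.positive_ids


@dataclass
class Benchmark:
    classes: list[BenchmarkClass]
    structures: dict[str, Structure]
    split: dict[str, str]  # structure id -> "train" | "test"
    seed: int
    train_fraction: float = 0.8
    meta: dict = field(default_factory=dict)

    def split_ids(self, partition: str) -> list[str]:
        return sorted(sid for sid, part in self.split.items() if part == partition)

    def class_by_id(self, class_id: str) -> BenchmarkClass:
        for cls in self.classes:
            if cls.id == class_id:
                return cls
        raise KeyError(class_id)

    def members(self, class_id: str, partition: str | None = None) -> list[Structure]:
        cls = self.class_by_id(class_id)
        ids = cls.positive_ids
        if partition is not None:
            ids = {i for i in ids if self.split[i] == partition}
        return [self.structures[i] for i in sorted(ids)]

    def non_members(self, class_id: str, partition: str | None = None) -> list[Structure]:
        cls = self.class_by_id(class_id)
        ids = cls.negative_ids(self.structures)
        if partition is not None:
            ids = {i for i in ids if self.split[i] == partition}
        return [self.structures[i] for i in sorted(ids)]


def partition_entries(
    graph: OntologyGraph,
) -> tuple[list[Structure], set[str], set[str]]:
    """Partition ontology entries into (structures, class ids, discarded ids).

    An entry becomes a structure iff it has a SMILES, the SMILES is
    wildcard-free, and the entry has no is-a children.  Otherwise it becomes
    a class iff it is a direct or indirect superclass of at least one
    structure.  Everything else is discarded.  The three sets are disjoint
    and cover every entry.
    """
    children = graph.children_of()
    structures: list[Structure] = []
    structure_ids: set[str] = set()
    for entry in graph.entries.values():
        if entry.smiles and WILDCARD not in entry.smiles and not children[entry.id]:
            structures.append(Structure(entry.id, entry.name, entry.smiles))
            structure_ids.add(entry.id)

    # A class is any entry with >=1 structure among its transitive descendants.
    class_ids: set[str] = set()
    for entry in graph.entries.values():
        if entry.id in structure_ids:
            continue
        if _descendant_structures(children, entry.id, structure_ids):
            class_ids.add(entry.id)

    discarded = set(graph.entries) - structure_ids - class_ids
    return structures, class_ids, discarded


def _descendant_structures(
    children: Mapping[str, list[str]], root: str, structure_ids: set[str]
) -> set[str]:
    """BFS over the reverse is-a adjacency collecting structure descendants."""
    seen: set[str] = set()
    hits: set[str] = set()
    queue = list(children[root])
    while queue:
        node = queue.pop()
        if node in seen:
            continue
        seen.add(node)
        if node in structure_ids:
            hits.add(node)
        queue.extend(children[node])
    return hits


def compute_positives(
    graph: OntologyGraph, structures: Sequence[Structure], class_id: str
) -> frozenset[str]:
    """True-path-closed positives: structures below ``class_id`` in the is-a DAG."""
    if class_id not in graph.entries:
        raise KeyError(f"unknown class id {class_id!r}")
    structure_ids = {s.id for s in structures}
    return frozenset(_descendant_structures(graph.children_of(), class_id, structure_ids))


def apply_class_filters(
    classes: Sequence[BenchmarkClass],
    min_members: int = 25,
    max_members: int = 5000,
    require_definition: bool = True,
) -> list[BenchmarkClass]:
    """Keep classes with ``min_members <= |positives| <= max_members`` and,
    when required, a nonempty textual definition.

    The defaults mirror a benchmark built for program learning: at least 25
    members so the held-out evaluation has support, at most 5000 to drop
    very high-level groupings.
    """
    if min_members > max_members:
        raise ValueError(f"min_members ({min_members}) > max_members ({max_members})")
    kept = []
    for cls in classes:
        if not (min_members <= len(cls.positive_ids) <= max_members):
            continue
        if require_definition and not (cls.definition or "").strip():
            continue
        kept.append(cls)
    return kept


def split_structures(
    structure_ids: Iterable[str], train_fraction: float = 0.8, seed: int = 0
) -> dict[str, str]:
    """Seeded global train/test split over all structures (not per class).

    Deterministic for a fixed seed; |train| = round(fraction * n).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = sorted(structure_ids)
    rng = random.Random(seed)
    rng.shuffle(ids)
    n_train = round(train_fraction * len(ids))
    return {sid: ("train" if i < n_train else "test") for i, sid in enumerate(ids)}


def make_slim(
    benchmark: Benchmark,
    keep: Iterable[str] | None = None,
    mapping_prefixes: Iterable[str] | None = None,
) -> Benchmark:
    """Subset the benchmark to a named list of classes or to classes carrying
    a cross-reference with one of the given prefixes.  Structures and split
    are unchanged.
    """
    if keep is None and mapping_prefixes is None:
        raise ValueError("make_slim needs a keep list or mapping prefixes")
    if keep is not None:
        keep_set = set(keep)
        selected = [c for c in benchmark.classes if c.id in keep_set]
    else:
        prefixes = tuple(mapping_prefixes or ())
        selected = [
            c
            for c in benchmark.classes
            if any(m.split(":")[0] in prefixes for m in c.mappings)
        ]
    meta = dict(benchmark.meta)
    meta["slim"] = {"keep": sorted(keep) if keep else None,
                    "mapping_prefixes": sorted(mapping_prefixes) if mapping_prefixes else None}
    return replace(benchmark, classes=selected, meta=meta)


def build_benchmark(
    graph: OntologyGraph,
    min_members: int = 25,
    max_members: int = 5000,
    require_definition: bool = True,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> Benchmark:
    """Full pipeline: partition, positives, filters, split."""
    structures, class_ids, _ = partition_entries(graph)
    classes = []
    for cid in sorted(class_ids):
        entry = graph.entries[cid]
        positives = compute_positives(graph, structures, cid)
        classes.append(
            BenchmarkClass(
                id=cid,
                name=entry.name,
                definition=entry.definition,
                positive_ids=positives,
                mappings=entry.mappings,
            )
        )
    classes = apply_class_filters(classes, min_members, max_members, require_definition)
    split = split_structures([s.id for s in structures], train_fraction, seed)
    return Benchmark(
        classes=classes,
        structures={s.id: s for s in structures},
        split=split,
        seed=seed,
        train_fraction=train_fraction,
        meta={
            "min_members": min_members,
            "max_members": max_members,
            "require_definition": require_definition,
        },
    )


# ---------------------------------------------------------------------------
# On-disk layout: classes.jsonl, structures.tsv, split.tsv, meta.json


def save_benchmark(benchmark: Benchmark, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "classes.jsonl", "w", encoding="utf-8") as fh:
        for cls in benchmark.classes:
            fh.write(
                json.dumps(
                    {
                        "id": cls.id,
                        "name": cls.name,
                        "definition": cls.definition,
                        "positive_ids": sorted(cls.positive_ids),
                        "mappings": list(cls.mappings),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    with open(out / "structures.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tname\tsmiles\n")
        for sid in sorted(benchmark.structures):
            s = benchmark.structures[sid]
            fh.write(f"{s.id}\t{s.name}\t{s.smiles}\n")
    with open(out / "split.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tpartition\n")
        for sid in sorted(benchmark.split):
            fh.write(f"{sid}\t{benchmark.split[sid]}\n")
    meta = dict(benchmark.meta)
    meta.update({"seed": benchmark.seed, "train_fraction": benchmark.train_fraction})
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def load_benchmark(in_dir: str | Path) -> Benchmark:
    src = Path(in_dir)
    classes = []
    with open(src / "classes.jsonl", encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            classes.append(
                BenchmarkClass(
                    id=rec["id"],
                    name=rec["name"],
                    definition=rec.get("definition"),
                    positive_ids=frozenset(rec["positive_ids"]),
                    mappings=tuple(rec.get("mappings", ())),
                )
            )
    structures = {}
    with open(src / "structures.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            sid, name, smiles = line.rstrip("\n").split("\t")
            structures[sid] = Structure(sid, name, smiles)
    split = {}
    with open(src / "split.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            sid, part = line.rstrip("\n").split("\t")
            split[sid] = part
    meta = json.loads((src / "meta.json").read_text())
    return Benchmark(
        classes=classes,
        structures=structures,
        split=split,
        seed=meta.pop("seed", 0),
        train_fraction=meta.pop("train_fraction", 0.8),
        meta=meta,
    )
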