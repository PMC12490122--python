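import random

import networkx as nx
import pytest

from chemclass.benchmark import (
    BenchmarkClass,
    apply_class_filters,
    build_benchmark,
    compute_positives,
    load_benchmark,
    make_slim,
    partition_entries,
    save_benchmark,
    split_structures,
)
from chemclass.ontology import OntologyEntry, OntologyGraph


def graph_of(*entries: OntologyEntry) -> OntologyGraph:
    g = OntologyGraph(entries={e.id: e for e in entries})
    g.validate()
    return g


class TestPartition:
    def test_hand_traced_partition_rules(self):
        g = graph_of(
            OntologyEntry("C", "parent"),
            OntologyEntry("D", "no descendants"),
            OntologyEntry("A", "leaf", smiles="CCO", parents=("C",)),
            OntologyEntry("B", "wildcard leaf", smiles="C*"),
        )
        structures, classes, discarded = partition_entries(g)
        assert {s.id for s in structures} == {"A"}
        assert classes == {"C"}
        assert discarded == {"B", "D"}

    def test_entry_with_smiles_but_structure_child_becomes_class(self):
        g = graph_of(
            OntologyEntry("P", "generic", smiles="CC"),
            OntologyEntry("S", "leaf", smiles="CCC", parents=("P",)),
        )
        structures, classes, _ = partition_entries(g)
        assert {s.id for s in structures} == {"S"}
        assert classes == {"P"}

    def test_empty_graph(self):
        structures, classes, discarded = partition_entries(OntologyGraph())
        assert (structures, classes, discarded) == ([], set(), set())

    def test_partition_is_total_disjoint_cover(self, toy):
        structures, classes, discarded = partition_entries(toy.graph)
        ids = {s.id for s in structures}
        assert ids | classes | discarded == set(toy.graph.entries)
        assert not (ids & classes) and not (ids & discarded) and not (classes & discarded)


class TestPositives:
    def test_chain_true_path(self):
        g = graph_of(
            OntologyEntry("C1", "top"),
            OntologyEntry("C2", "mid", parents=("C1",)),
            OntologyEntry("S", "leaf", smiles="CC", parents=("C2",)),
        )
        structures, _, _ = partition_entries(g)
        assert compute_positives(g, structures, "C1") == {"S"}

    def test_diamond_counted_once(self):
        g = graph_of(
            OntologyEntry("C1", "top"),
            OntologyEntry("C2", "left", parents=("C1",)),
            OntologyEntry("C3", "right", parents=("C1",)),
            OntologyEntry("S", "leaf", smiles="CC", parents=("C2", "C3")),
        )
        structures, _, _ = partition_entries(g)
        assert compute_positives(g, structures, "C1") == frozenset({"S"})

    def test_unknown_class_id_raises(self, toy):
        structures, _, _ = partition_entries(toy.graph)
        with pytest.raises(KeyError):
            compute_positives(toy.graph, structures, "NOPE")

    def test_closure_matches_networkx_oracle_on_random_dags(self):
        rng = random.Random(7)
        for _ in range(100):
            n = rng.randint(4, 100)
            entries = []
            for i in range(n):
                # child -> parent edges only toward higher indices: acyclic
                parents = tuple(
                    f"N{j}" for j in range(i + 1, n) if rng.random() < 2.0 / n
                )
                has_smiles = rng.random() < 0.4
                entries.append(
                    OntologyEntry(
                        f"N{i}", f"node {i}",
                        smiles="CC" if has_smiles else None,
                        parents=parents,
                    )
                )
            g = graph_of(*entries)
            structures, classes, _ = partition_entries(g)
            structure_ids = {s.id for s in structures}
            oracle_graph = g.to_networkx()
            for cid in classes:
                oracle = {
                    s for s in structure_ids
                    if cid in nx.descendants(oracle_graph, s)
                }
                assert compute_positives(g, structures, cid) == oracle

    def test_true_path_rule_parent_superset_of_child(self, toy):
        structures, classes, _ = partition_entries(toy.graph)
        for cls_id in classes:
            for parent in toy.graph.entries[cls_id].parents:
                if parent in classes:
                    assert compute_positives(toy.graph, structures, parent) >= \
                        compute_positives(toy.graph, structures, cls_id)


def _cls(n_members: int, definition: str | None = "def") -> BenchmarkClass:
    return BenchmarkClass(
        id=f"c{n_members}", name="c", definition=definition,
        positive_ids=frozenset(f"s{i}" for i in range(n_members)),
    )


class TestFilters:
    @pytest.mark.parametrize(
        "n,kept", [(24, False), (25, True), (5000, True), (5001, False)]
    )
    def test_member_count_bounds(self, n, kept):
        assert bool(apply_class_filters([_cls(n)])) is kept

    def test_definition_requirement_togglable(self):
        cls = _cls(30, definition=None)
        assert apply_class_filters([cls]) == []
        assert apply_class_filters([cls], require_definition=False) == [cls]

    def test_min_greater_than_max_rejected(self):
        with pytest.raises(ValueError):
            apply_class_filters([_cls(30)], min_members=10, max_members=5)

    def test_filters_monotone_in_bounds(self):
        classes = [_cls(n) for n in (1, 10, 25, 100, 400)]
        tight = {c.id for c in apply_class_filters(classes, 25, 200)}
        loose = {c.id for c in apply_class_filters(classes, 5, 5000)}
        assert tight <= loose


class TestSplit:
    def test_exact_proportion(self):
        split = split_structures([f"s{i}" for i in range(10)], 0.8, seed=3)
        parts = list(split.values())
        assert parts.count("train") == 8 and parts.count("test") == 2

    def test_seed_determinism_and_seed_sensitivity(self):
        ids = [f"s{i}" for i in range(100)]
        a = split_structures(ids, 0.8, seed=11)
        b = split_structures(ids, 0.8, seed=11)
        c = split_structures(ids, 0.8, seed=12)
        assert a == b
        assert a != c
        for split in (a, c):
            assert list(split.values()).count("train") == 80

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_structures(["a"], 1.0, seed=0)


class TestSlim:
    def test_keep_all_is_identity(self, toy):
        slim = make_slim(toy.benchmark, keep=[c.id for c in toy.benchmark.classes])
        assert [c.id for c in slim.classes] == [c.id for c in toy.benchmark.classes]
        assert slim.structures == toy.benchmark.structures

    def test_keep_single_class(self, toy):
        slim = make_slim(toy.benchmark, keep=["ALK"])
        assert [c.id for c in slim.classes] == ["ALK"]

    def test_mapping_prefix_selection(self, toy):
        # the toy fixture tags exactly ALK and ALC with KEGG mappings
        slim = make_slim(toy.benchmark, mapping_prefixes=["KEGG"])
        assert {c.id for c in slim.classes} == {"ALK", "ALC"}

    def test_empty_selection_is_valid_empty_benchmark(self, toy):
        slim = make_slim(toy.benchmark, keep=["NOT_A_CLASS"])
        assert slim.classes == []


def test_benchmark_directory_roundtrip(toy, tmp_path):
    save_benchmark(toy.benchmark, tmp_path / "bm")
    loaded = load_benchmark(tmp_path / "bm")
    assert {c.id: c.positive_ids for c in loaded.classes} == \
        {c.id: c.positive_ids for c in toy.benchmark.classes}
    assert loaded.split == toy.benchmark.split
    assert loaded.structures == toy.benchmark.structures
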