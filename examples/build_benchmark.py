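"""Build a classification benchmark from an ontology document.

Generates the packaged toy ontology (five homologous series plus decoy
entries), partitions entries into structures / grouping classes / discarded,
applies the member-count and definition filters, and splits structures 80/20.
"""

import tempfile

from chemclass import build_benchmark, load_ontology
from chemclass.benchmark import partition_entries
from chemclass.synthetic import generate_toy_benchmark

with tempfile.TemporaryDirectory() as tmp:
    path, expected = generate_toy_benchmark(tmp, n_members=30, seed=1)
    graph = load_ontology(path, dialect="tsv")

structures, class_ids, discarded = partition_entries(graph)
print(f"entries: {len(graph.entries)}")
print(f"  structures (leaf, ground SMILES): {len(structures)}")
print(f"  candidate classes (superclass of >=1 structure): {len(class_ids)}")
print(f"  discarded (wildcards, roles, ...): {len(discarded)}")

benchmark = build_benchmark(graph, min_members=25, max_members=5000, seed=1)
print(f"classes kept by the 25/5000/definition filters: "
      f"{sorted(c.id for c in benchmark.classes)}")
n_train = len(benchmark.split_ids("train"))
print(f"split: {n_train} train / {len(benchmark.structures) - n_train} test")
# Every class keeps its true-path-closed positives; negatives are implicit
# (all other benchmark structures), so each class sees the same universe.
alk = benchmark.class_by_id("ALK")
print(f"class {alk.id!r}: {len(alk.positive_ids)} positives, "
      f"{len(alk.negative_ids(benchmark.structures))} implicit negatives")
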