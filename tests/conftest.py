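from types import SimpleNamespace

import pytest

from chemclass import build_benchmark, load_ontology
from chemclass.synthetic import generate_toy_benchmark


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Toy ontology document, its independently computed expectation, the
    loaded graph and the built benchmark (seed 1)."""
    d = tmp_path_factory.mktemp("toy")
    path, expectation = generate_toy_benchmark(d, n_members=30, seed=1)
    graph = load_ontology(path, "tsv")
    benchmark = build_benchmark(graph, seed=1)
    return SimpleNamespace(
        path=path, expectation=expectation, graph=graph, benchmark=benchmark
    )
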