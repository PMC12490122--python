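"""Classify de-novo SMILES strings with a learned suite.

Learns exact programs for the toy classes, ensembles them, and runs every
class program on new molecules.  Each call returns a membership boolean, a
plain-text explanation produced by the program itself, and a confidence:
training precision for positive calls, training NPV for negative calls.
The single-SMARTS baseline is shown for comparison.
"""

import tempfile

from chemclass import LearnConfig, MockBackend, build_benchmark, load_ontology
from chemclass.loop import learn_suite
from chemclass.runtime import build_ensemble, classify_structure, smarts_baseline
from chemclass.synthetic import build_mock_corpus, generate_toy_benchmark

with tempfile.TemporaryDirectory() as tmp:
    path, _ = generate_toy_benchmark(tmp, n_members=30, seed=1)
    benchmark = build_benchmark(load_ontology(path), seed=1)

suite = learn_suite(
    benchmark, LearnConfig(seed=1), MockBackend(build_mock_corpus("all_correct"))
)
ensemble = build_ensemble([suite])

for smiles in ("CCCCO", "CCCCCl", "CCc1ccccc1"):
    print(f"\n{smiles}:")
    for call in classify_structure(ensemble, smiles):
        if call.m:
            print(f"  {call.class_name:15s} member "
                  f"(confidence {call.confidence:.2f}): {call.e}")

# Naive baseline: a single substructure pattern per class
print("\nSMARTS baseline 'CCC[N,O]' on CCCO:", smarts_baseline("CCC[N,O]", "CCCO"))
print("SMARTS baseline 'CCC[N,O]' on CC:  ", smarts_baseline("CCC[N,O]", "CC"))
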