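"""Learn one classifier program per class with the iterative loop.

Uses the deterministic mock backend scripted with the "improving" corpus:
each class's responses get better over three attempts, crossing the 0.8
training-F1 threshold on the third.  The printed per-attempt scores show the
loop issuing feedback prompts (misclassified examples + explanations) until
the threshold is met, then stopping.
"""

import tempfile

from chemclass import LearnConfig, MockBackend, build_benchmark, load_ontology
from chemclass.loop import learn_suite, learnability
from chemclass.synthetic import build_mock_corpus, generate_toy_benchmark

with tempfile.TemporaryDirectory() as tmp:
    path, _ = generate_toy_benchmark(tmp, n_members=30, seed=1)
    benchmark = build_benchmark(load_ontology(path), seed=1)

config = LearnConfig(model_id="mock", f1_threshold=0.8, max_attempts=4, seed=1)
backend = MockBackend(build_mock_corpus("improving"))
suite = learn_suite(benchmark, config, backend, label="improving-demo")

for cid, result in sorted(suite.results.items()):
    scores = ", ".join(f"{a.f1:.3f}" for a in result.attempts)
    print(f"{result.class_name:15s} attempts: [{scores}] "
          f"converged={result.converged} learnability={learnability(result):.3f}")

# The second attempt's prompt carried feedback from the first program's
# mistakes; here is the start of one such feedback prompt:
first = suite.results[sorted(suite.results)[0]]
print("\n--- feedback prompt (attempt 2, first lines) ---")
print("\n".join(first.attempts[1].feedback_text.splitlines()[:4]))
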