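import json

import pytest

from chemclass.executor import ClassifierProgram, evaluate_program
from chemclass.generation import LearnConfig, MockBackend
from chemclass.loop import (
    GitTrail,
    JsonlTrail,
    learn_class,
    learn_suite,
    learnability,
    load_suite,
    save_suite,
)
from chemclass.synthetic import build_mock_corpus


def backend_for(kind):
    return MockBackend(build_mock_corpus(kind))


@pytest.fixture
def config():
    return LearnConfig(seed=1)


class TestLearnClass:
    def test_improving_corpus_converges_at_scripted_attempt(self, toy, config):
        backend = backend_for("improving")
        result = learn_class(toy.benchmark.classes[0], toy.benchmark, config, backend)
        assert len(result.attempts) == 3
        assert result.converged
        assert result.best.attempt_index == 3
        assert result.attempts[0].f1 < result.attempts[1].f1 < result.attempts[2].f1
        # no prompt was issued past convergence
        assert backend.calls == [(toy.benchmark.classes[0].id, a) for a in (1, 2, 3)]

    def test_all_broken_exhausts_attempts_with_zero_f1(self, toy, config):
        result = learn_class(
            toy.benchmark.classes[0], toy.benchmark, config, backend_for("all_broken")
        )
        assert len(result.attempts) == config.max_attempts == 4
        assert not result.converged
        assert learnability(result) == 0.0
        assert all(a.evaluation.fatal_error for a in result.attempts)

    def test_single_attempt_when_first_program_meets_threshold(self, toy, config):
        backend = backend_for("all_correct")
        result = learn_class(toy.benchmark.classes[0], toy.benchmark, config, backend)
        assert len(result.attempts) == 1 and result.converged
        assert all(attempt == 1 for _, attempt in backend.calls)

    def test_regressing_corpus_retains_peak_not_last(self, toy, config):
        result = learn_class(
            toy.benchmark.classes[0], toy.benchmark, config, backend_for("regressing")
        )
        assert len(result.attempts) == 4 and not result.converged
        assert result.best.attempt_index == 2
        assert learnability(result) == result.attempts[1].f1
        assert result.attempts[1].f1 > result.attempts[3].f1

    def test_crashy_programs_contained_and_iterated(self, toy, config):
        clx = toy.benchmark.class_by_id("CLX")
        result = learn_class(clx, toy.benchmark, config, backend_for("crashy"))
        # every chloroalkane positive raises -> all fn -> F1 0, all 4 attempts used
        assert len(result.attempts) == 4 and learnability(result) == 0.0
        assert result.attempts[0].evaluation.fatal_error is None
        assert result.attempts[0].evaluation.per_example_errors

    def test_generation_failure_consumes_attempt(self, toy, config):
        result = learn_class(toy.benchmark.classes[0], toy.benchmark, config, MockBackend({}))
        assert len(result.attempts) == 4
        assert all(a.f1 == 0.0 for a in result.attempts)
        assert not result.converged


class TestFeedbackFlow:
    def test_feedback_prompt_contains_captured_error_verbatim(self, toy, config):
        result = learn_class(
            toy.benchmark.classes[0], toy.benchmark, config, backend_for("all_broken")
        )
        first_error = result.attempts[0].evaluation.fatal_error
        second_prompt = result.attempts[1].feedback_text
        assert first_error and first_error.strip() in second_prompt

    def test_feedback_exposes_misclassified_training_example(self, toy, config):
        # the improving corpus under-covers long chains at attempt 1; those
        # false negatives must be surfaced with the program's explanation
        result = learn_class(
            toy.benchmark.classes[0], toy.benchmark, config, backend_for("improving")
        )
        mis = result.attempts[0].evaluation.misclassified
        assert mis
        fb = result.attempts[1].feedback_text
        sid, label, explanation = mis[0]
        assert toy.benchmark.structures[sid].smiles in fb
        assert label == "positive"


class TestLearnSuite:
    def test_all_correct_suite_converges_everywhere(self, toy, config):
        suite = learn_suite(toy.benchmark, config, backend_for("all_correct"))
        assert len(suite.results) == 5
        assert all(r.converged and learnability(r) == 1.0 for r in suite.results.values())

    def test_class_subset(self, toy, config):
        suite = learn_suite(
            toy.benchmark, config, backend_for("all_correct"), class_ids=["ALK", "ALC"]
        )
        assert set(suite.results) == {"ALK", "ALC"}

    def test_rerun_is_byte_identical(self, toy, config, tmp_path):
        for d in ("a", "b"):
            learn_suite(
                toy.benchmark, config, backend_for("improving"),
                out_dir=tmp_path / d, trail=JsonlTrail(tmp_path / d / "trail"),
            )
        for name in ["suite.json"] + [
            p.name for p in (tmp_path / "a" / "programs").iterdir()
        ]:
            a = (tmp_path / "a" / ("programs/" + name if name != "suite.json" else name))
            b = (tmp_path / "b" / ("programs/" + name if name != "suite.json" else name))
            assert a.read_bytes() == b.read_bytes()

    def test_suite_roundtrip_preserves_scores(self, toy, config, tmp_path):
        suite = learn_suite(toy.benchmark, config, backend_for("improving"))
        save_suite(suite, tmp_path / "suite")
        loaded = load_suite(tmp_path / "suite")
        assert {cid: learnability(r) for cid, r in loaded.results.items()} == \
            {cid: learnability(r) for cid, r in suite.results.items()}
        assert all(loaded.results[c].converged == suite.results[c].converged
                   for c in suite.results)


class TestTrail:
    def test_one_commit_per_attempt_with_feedback_in_message(self, toy, config, tmp_path):
        trail = GitTrail(tmp_path / "trail")
        result = learn_class(
            toy.benchmark.classes[0], toy.benchmark, config,
            backend_for("improving"), trail=trail,
        )
        slug = result.function_name[3:]
        commits = trail.commits(slug)
        assert len(commits) == len(result.attempts) == 3
        # attempt-2 commit message carries the feedback block verbatim
        assert result.attempts[1].feedback_text.strip() in commits[1][1]

    def test_replaying_trail_reproduces_scores(self, toy, config, tmp_path):
        trail = GitTrail(tmp_path / "trail")
        cls = toy.benchmark.classes[0]
        result = learn_class(toy.benchmark.classes[0], toy.benchmark, config,
                             backend_for("regressing"), trail=trail)
        positives = toy.benchmark.members(cls.id, "train")
        negatives = toy.benchmark.non_members(cls.id, "train")
        for source, attempt in zip(
            trail.program_versions(result.function_name[3:]), result.attempts
        ):
            if attempt.evaluation.fatal_error:
                continue
            replay = evaluate_program(
                ClassifierProgram(cls.id, result.function_name, source),
                positives, negatives,
            )
            assert replay.f1 == pytest.approx(attempt.f1)

    def test_jsonl_fallback_records_attempts(self, toy, config, tmp_path):
        trail = JsonlTrail(tmp_path / "trail")
        result = learn_class(toy.benchmark.classes[0], toy.benchmark, config,
                             backend_for("improving"), trail=trail)
        assert len(trail.program_versions(result.function_name[3:])) == 3


def test_skipped_class_with_no_training_positives(toy, config):
    from chemclass.benchmark import Benchmark, BenchmarkClass

    cls = toy.benchmark.classes[0]
    # force every positive of this class into the test partition
    split = dict(toy.benchmark.split)
    for sid in cls.positive_ids:
        split[sid] = "test"
    bench = Benchmark(
        classes=toy.benchmark.classes, structures=toy.benchmark.structures,
        split=split, seed=toy.benchmark.seed,
    )
    result = learn_class(cls, bench, config, backend_for("all_correct"))
    assert result.skipped_reason and result.attempts == []
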