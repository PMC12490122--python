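import pytest
from hypothesis import given, settings, strategies as st

from chemclass.generation import (
    EXEMPLAR_PROGRAM,
    GenerationError,
    LearnConfig,
    MockBackend,
    PromptBundle,
    build_feedback_prompt,
    build_initial_prompt,
    parse_response,
)

POSITIVES = [(f"alcohol-{i}", "C" * i + "O") for i in range(1, 6)]
NEGATIVES = [(f"alkane-{i}", "C" * i) for i in range(1, 6)]


def initial(config=None, **kwargs):
    defaults = dict(
        class_name="alcohol",
        function_name="is_alcohol",
        definition="A compound with a hydroxy group.",
        positives=POSITIVES,
        negatives=NEGATIVES,
        config=config or LearnConfig(seed=5),
    )
    defaults.update(kwargs)
    return build_initial_prompt(**defaults)


class TestInitialPrompt:
    def test_contains_examples_and_exemplar_verbatim(self):
        prompt = initial()
        for _, smi in POSITIVES:
            assert smi in prompt.text
        assert EXEMPLAR_PROGRAM.rstrip("\n") in prompt.text
        assert "is_alcohol" in prompt.text
        assert prompt.kind == "initial" and prompt.attempt_index == 1

    def test_definition_block_toggles(self):
        with_def = initial().text
        without = initial(config=LearnConfig(seed=5, include_definition=False)).text
        assert "A compound with a hydroxy group." in with_def
        assert "A compound with a hydroxy group." not in without

    def test_use_the_force_instructions_toggle(self):
        forced = initial(config=LearnConfig(seed=5, use_the_force=True)).text
        plain = initial().text
        assert "avoid assuming that the provided positive" in forced
        assert "avoid assuming" not in plain

    def test_byte_identical_for_same_inputs_and_seed(self):
        assert initial().text == initial().text

    def test_sampling_is_seed_deterministic_when_capped(self):
        many = [(f"p{i}", "C" * (i % 20 + 1) + "O") for i in range(200)]
        cfg = LearnConfig(seed=9, positive_sample_size=10, negative_sample_size=5)
        a = initial(config=cfg, positives=many).text
        b = initial(config=cfg, positives=many).text
        assert a == b
        other = initial(config=LearnConfig(seed=10, positive_sample_size=10,
                                           negative_sample_size=5),
                        positives=many).text
        assert a != other

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            initial(positives=[])


class TestFeedbackPrompt:
    def test_misclassified_examples_with_explanations_included(self):
        prompt = build_feedback_prompt(
            previous_source="def is_alcohol(s):\n    return False, 'no'\n",
            attempt_index=2,
            f1=0.4,
            misclassified=[
                ("alcohol-1", "CO", "positive", "rejected: too short"),
                ("alkane-2", "CC", "negative", "accepted: looks alkyl"),
            ],
            fatal_error=None,
            config=LearnConfig(seed=1),
        )
        assert "CO" in prompt.text and "rejected: too short" in prompt.text
        assert "CC" in prompt.text and "accepted: looks alkyl" in prompt.text
        assert "def is_alcohol" in prompt.text
        assert prompt.kind == "feedback"

    def test_fatal_error_text_shown_instead_of_misclassifications(self):
        prompt = build_feedback_prompt(
            previous_source="def is_x(:\n",
            attempt_index=2,
            f1=0.0,
            misclassified=[],
            fatal_error="SyntaxError: invalid syntax (line 1)",
            config=LearnConfig(seed=1),
        )
        assert "SyntaxError: invalid syntax (line 1)" in prompt.text
        assert "Misclassified examples" not in prompt.text

    def test_zero_listed_misclassifications_still_requests_improvement(self):
        prompt = build_feedback_prompt(
            previous_source="def is_x(s):\n    return True, 'yes'\n",
            attempt_index=3,
            f1=0.6,
            misclassified=[],
            fatal_error=None,
            config=LearnConfig(seed=1),
        )
        assert "0.6" in prompt.text
        assert "improve" in prompt.text.lower()

    def test_threshold_already_met_is_a_logic_error(self):
        with pytest.raises(ValueError):
            build_feedback_prompt(
                previous_source="x",
                attempt_index=2,
                f1=0.9,
                misclassified=[],
                fatal_error=None,
                config=LearnConfig(seed=1),
            )

    def test_feedback_cap_bounds_listed_examples(self):
        mis = [(f"n{i}", f"SMI{i}", "negative", f"expl{i}") for i in range(100)]
        cfg = LearnConfig(seed=1, feedback_example_cap=5)
        prompt = build_feedback_prompt(
            previous_source="def is_x(s):\n    return True, 'yes'\n",
            attempt_index=2, f1=0.3, misclassified=mis, fatal_error=None, config=cfg,
        )
        shown = sum(1 for i in range(100) if f" SMI{i} [" in prompt.text)
        assert shown == 5


class TestParseResponse:
    def test_single_fenced_block(self):
        r = parse_response("thinking...\n```\ndef f(): pass\n```")
        assert r.reasoning == "thinking..."
        assert r.program_source == "def f(): pass\n"

    def test_two_blocks_concatenated_in_order(self):
        raw = "a\n```python\nHELPER = 1\n```\nb\n```python\ndef f():\n    return HELPER\n```\n"
        r = parse_response(raw)
        assert r.program_source == "HELPER = 1\ndef f():\n    return HELPER\n"
        assert "a" in r.reasoning and "b" in r.reasoning

    def test_fence_free_prose_gives_empty_source(self):
        r = parse_response("no code here, only words")
        assert r.program_source == ""
        assert r.reasoning == "no code here, only words"

    def test_fence_free_code_recovered_heuristically(self):
        raw = "I will write it below.\ndef f():\n    return 1\n"
        r = parse_response(raw)
        assert r.program_source.startswith("def f():")

    @settings(max_examples=60, derandomize=True)
    @given(
        body=st.text(
            alphabet=st.characters(blacklist_characters="`", blacklist_categories=("Cs",)),
            min_size=1,
        ).map(lambda s: s.rstrip("\n") + "\n").filter(lambda s: s.strip()),
        prose=st.text(
            alphabet=st.characters(blacklist_characters="`", blacklist_categories=("Cs",)),
            max_size=40,
        ),
    )
    def test_fence_roundtrip_recovers_source(self, body, prose):
        raw = f"{prose}\n```python\n{body}```\n"
        assert parse_response(raw).program_source == body


class TestMockBackend:
    def test_scripted_response_returned(self):
        backend = MockBackend({("alcohol", 1): "response_A"})
        prompt = PromptBundle(text="x", kind="initial", attempt_index=1, inputs_digest="d")
        assert backend.generate(prompt, "alcohol", "mock") == "response_A"

    def test_missing_script_entry_is_generation_error(self):
        backend = MockBackend({})
        prompt = PromptBundle(text="x", kind="initial", attempt_index=1, inputs_digest="d")
        with pytest.raises(GenerationError):
            backend.generate(prompt, "alcohol", "mock")

    def test_jsonl_roundtrip(self, tmp_path):
        path = tmp_path / "script.jsonl"
        path.write_text('{"class_id": "X", "attempt": 2, "response": "hi"}\n')
        backend = MockBackend.from_jsonl(path)
        assert backend.script == {("X", 2): "hi"}
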