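"""Prompt construction, text-generation backends and response parsing.

Program synthesis is driven by a text-generation backend behind a minimal
synchronous contract: prompt text in, raw completion out.  The packaged
:class:`MockBackend` replays a scripted corpus keyed by ``(class_id,
attempt_index)`` and makes the whole learning pipeline deterministic; live
API adapters can be registered under a model id by implementing
:class:`Backend`.

Responses interleave free-text reasoning with fenced code blocks; parsing
separates the two, concatenating all fenced blocks into the candidate
program source.
"""

from __future__ import annotations

import hashlib
import json
import random
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

__all__ = [
    "LearnConfig",
    "PromptBundle",
    "GenerationResponse",
    "GenerationError",
    "Backend",
    "MockBackend",
    "BackendRegistry",
    "EXEMPLAR_PROGRAM",
    "build_initial_prompt",
    "build_feedback_prompt",
    "parse_response",
]


@dataclass(frozen=True)
class LearnConfig:
    """Hyperparameters of the iterative learning loop.

    ``f1_threshold`` is the training F1 at which refinement stops (default
    0.8) and ``max_attempts`` bounds the number of generate/evaluate rounds
    (default 4); a stricter variant is 0.9 with 6 attempts.
    ``use_the_force`` adds instructions allowing the generator to distrust
    provided training labels.
    """

    model_id: str = "mock"
    f1_threshold: float = 0.8
    max_attempts: int = 4
    include_definition: bool = True
    use_the_force: bool = False
    positive_sample_size: int = 50
    negative_sample_size: int = 50
    feedback_example_cap: int = 25
    negative_eval_cap: int | None = None
    strict_errors: bool = False
    call_timeout_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f1_threshold <= 1:
            raise ValueError("f1_threshold must be in (0, 1]")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.positive_sample_size < 1 or self.negative_sample_size < 1:
            raise ValueError("sample sizes must be >= 1")


@dataclass(frozen=True)
class PromptBundle:
    text: str
    kind: str  # "initial" | "feedback"
    attempt_index: int
    inputs_digest: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("empty prompt")
        if self.attempt_index < 1:
            raise ValueError("attempt_index must be >= 1")
        if self.kind == "feedback" and self.attempt_index == 1:
            raise ValueError("feedback prompts only occur after the first attempt")


@dataclass(frozen=True)
class GenerationResponse:
    raw: str
    reasoning: str
    program_source: str


class GenerationError(RuntimeError):
    """Backend exhaustion, refusal or missing script entry."""


class Backend(Protocol):
    def generate(self, prompt: PromptBundle, class_id: str, model_id: str) -> str: ...


# The exemplar handed to the generator: a manually written classifier with
# the same contract the synthesized programs must satisfy (SMILES in,
# (bool, explanation) out).
EXEMPLAR_PROGRAM = '''\
"""Classify a SMILES string as an alkane (acyclic, fully saturated hydrocarbon)."""
from rdkit import Chem


def is_alkane(smiles: str):
    """Return (True, reason) if the molecule is an alkane, else (False, reason)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False, "SMILES could not be parsed"
    if any(atom.GetAtomicNum() not in (1, 6) for atom in mol.GetAtoms()):
        return False, "contains atoms other than carbon and hydrogen"
    if mol.GetRingInfo().NumRings() > 0:
        return False, "contains a ring"
    if any(bond.GetBondTypeAsDouble() != 1.0 for bond in mol.GetBonds()):
        return False, "contains an unsaturated bond"
    return True, "acyclic saturated hydrocarbon"
'''


def _class_rng(seed: int, class_id: str, purpose: str) -> random.Random:
    # string hashing via crc32 keeps the stream stable across interpreter runs
    mix = zlib.crc32(f"{purpose}:{class_id}".encode()) & 0x7FFFFFFF
    return random.Random((seed * 2654435761 + mix) % (2**31))


def _sample(pairs: Sequence[tuple[str, str]], k: int, rng: random.Random) -> list[tuple[str, str]]:
    pairs = sorted(pairs)
    if len(pairs) <= k:
        return pairs
    return sorted(rng.sample(pairs, k))


def _digest(*chunks: str) -> str:
    h = hashlib.sha256()
    for chunk in chunks:
        h.update(chunk.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


_FORCE_TEXT = (
    "Use your own chemical judgment: avoid assuming that the provided positive "
    "and negative examples were all correct; if an example appears mislabeled, "
    "prioritize a chemically sound rule over fitting that example."
)


def build_initial_prompt(
    class_name: str,
    function_name: str,
    definition: str | None,
    positives: Sequence[tuple[str, str]],
    negatives: Sequence[tuple[str, str]],
    config: LearnConfig,
    class_id: str | None = None,
    exemplar: str = EXEMPLAR_PROGRAM,
) -> PromptBundle:
    """First-attempt prompt: task instructions, class name (and definition if
    configured), sampled positive and negative (name, SMILES) examples, and
    the exemplar program.  Deterministic for fixed inputs, config and seed.
    """
    if not positives:
        raise ValueError("initial prompt requires at least one positive example")
    rng = _class_rng(config.seed, class_id or class_name, "prompt")
    pos = _sample(positives, config.positive_sample_size, rng)
    neg = _sample(negatives, config.negative_sample_size, rng)

    lines: list[str] = []
    lines.append(
        "Write a Python function that classifies chemical structures given as "
        "SMILES strings."
    )
    lines.append(
        f"The function must be named `{function_name}`, take a single SMILES "
        "string argument, and return a tuple (bool, str): a boolean membership "
        "decision and a concise plain-text explanation for that decision."
    )
    lines.append(
        "Think step by step about the structural features that define the class "
        "before writing code, and include clear documentation in the program. "
        "Put the final program in a fenced code block."
    )
    lines.append(f"Chemical class: {class_name}")
    if config.include_definition and definition:
        lines.append(f"Definition: {definition}")
    if config.use_the_force:
        lines.append(_FORCE_TEXT)
    lines.append("Positive examples (name, SMILES):")
    lines.extend(f"  - {name}: {smi}" for name, smi in pos)
    lines.append("Negative examples (name, SMILES):")
    lines.extend(f"  - {name}: {smi}" for name, smi in neg)
    lines.append("Example of a program with the required contract:")
    lines.append("```python")
    lines.append(exemplar.rstrip("\n"))
    lines.append("```")
    text = "\n".join(lines) + "\n"
    digest = _digest(
        class_name,
        "\n".join(f"{n}\t{s}" for n, s in pos),
        "\n".join(f"{n}\t{s}" for n, s in neg),
    )
    return PromptBundle(text=text, kind="initial", attempt_index=1, inputs_digest=digest)


def build_feedback_prompt(
    previous_source: str,
    attempt_index: int,
    f1: float,
    misclassified: Sequence[tuple[str, str, str, str]],
    fatal_error: str | None,
    config: LearnConfig,
    class_id: str = "",
) -> PromptBundle:
    """Refinement prompt carrying (a) the previous program, (b) a capped,
    seeded selection of misclassified examples with the explanations the
    program gave, and (c) any captured compile/runtime error text.

    ``misclassified`` rows are (name, smiles, true_label, explanation) with
    true_label in {"positive", "negative"}.
    """
    if f1 >= config.f1_threshold:
        raise ValueError("feedback requested although the previous attempt met the threshold")
    lines = ["The previous program did not reach the required F1 score."]
    lines.append(f"Training F1 of the previous attempt: {f1:.4f} "
                 f"(required: {config.f1_threshold}).")
    lines.append("Previous program:")
    lines.append("```python")
    lines.append(previous_source.rstrip("\n"))
    lines.append("```")
    if fatal_error:
        lines.append("The program failed to run. Captured error:")
        lines.append(fatal_error.rstrip("\n"))
    else:
        rng = _class_rng(config.seed, class_id, f"feedback{attempt_index}")
        fns = [m for m in misclassified if m[2] == "positive"]
        fps = [m for m in misclassified if m[2] == "negative"]
        cap = config.feedback_example_cap
        shown = _sample([(f"{n}\t{s}\t{e}", l) for n, s, l, e in fns], cap, rng) + \
            _sample([(f"{n}\t{s}\t{e}", l) for n, s, l, e in fps], cap, rng)
        if shown:
            lines.append("Misclassified examples (name, SMILES, true label, "
                         "explanation the program gave):")
            for packed, label in shown:
                name, smi, expl = packed.split("\t", 2)
                lines.append(f"  - {name}: {smi} [true: {label}] -> {expl}")
        else:
            lines.append("No individual misclassifications are listed, but the "
                         "F1 score above is below the threshold; improve "
                         "precision and recall on the class as a whole.")
    lines.append(
        "Adapt the program to fix these problems while keeping the same "
        "function name and return contract. Reason step by step, then put the "
        "revised program in a fenced code block."
    )
    text = "\n".join(lines) + "\n"
    return PromptBundle(
        text=text,
        kind="feedback",
        attempt_index=attempt_index,
        inputs_digest=_digest(previous_source, text),
    )


# ---------------------------------------------------------------------------
# Backends


class MockBackend:
    """Deterministic scripted backend: responses keyed by (class_id, attempt).

    The script may be given as a mapping or loaded from a JSONL file with
    records ``{"class_id": ..., "attempt": ..., "response": ...}``.
    """

    def __init__(self, script: dict[tuple[str, int], str]):
        self.script = dict(script)
        self.calls: list[tuple[str, int]] = []

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "MockBackend":
        script = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                script[(rec["class_id"], int(rec["attempt"]))] = rec["response"]
        return cls(script)

    def generate(self, prompt: PromptBundle, class_id: str, model_id: str) -> str:
        key = (class_id, prompt.attempt_index)
        self.calls.append(key)
        try:
            return self.script[key]
        except KeyError:
            raise GenerationError(
                f"mock backend has no scripted response for class {class_id!r} "
                f"attempt {prompt.attempt_index}"
            ) from None


class BackendRegistry:
    """Model-id → backend factory registry."""

    def __init__(self) -> None:
        self._factories: dict[str, object] = {}

    def register(self, model_id: str, backend: Backend) -> None:
        self._factories[model_id] = backend

    def get(self, model_id: str) -> Backend:
        try:
            return self._factories[model_id]  # type: ignore[return-value]
        except KeyError:
            raise GenerationError(f"no backend registered for model {model_id!r}") from None


# ---------------------------------------------------------------------------
# Response parsing

_FENCE_RE = re.compile(r"```[ \t]*[A-Za-z0-9_+-]*[ \t]*\n(.*?)```", re.DOTALL)


def parse_response(raw: str) -> GenerationResponse:
    """Split a completion into reasoning and program source.

    The program source is the concatenation of all fenced code blocks, in
    order; everything outside the fences is reasoning.  A fence-free
    response yields an empty program source (the learning loop scores such
    an attempt as F1 = 0).
    """
    if not raw:
        raise ValueError("empty response")
    blocks = _FENCE_RE.findall(raw)
    if blocks:
        source = "\n".join(b.rstrip("\n") for b in blocks) + "\n"
        reasoning = _FENCE_RE.sub("", raw).strip()
        return GenerationResponse(raw=raw, reasoning=reasoning, program_source=source)
    # heuristic fallback: longest suffix starting at a line that parses as code
    lines = raw.splitlines()
    for i, line in enumerate(lines):
        if re.match(r"^\s*(def |class |import |from )", line):
            candidate = "\n".join(lines[i:])
            try:
                compile(candidate, "<response>", "exec")
            except SyntaxError:
                continue
            reasoning = "\n".join(lines[:i]).strip()
            return GenerationResponse(
                raw=raw, reasoning=reasoning, program_source=candidate + "\n"
            )
    return GenerationResponse(raw=raw, reasoning=raw.strip(), program_source="")
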