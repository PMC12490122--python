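"""Compile and run candidate classifier programs against labeled SMILES.

Each evaluation runs in an isolated child process (see ``_worker.py``): a
fatal load-time failure — syntax error, blocked import, missing function —
zeroes the whole attempt, while exceptions raised on individual molecules
are contained per example.  By default a per-example failure counts as a
misclassification in the unfavorable direction (a positive becomes a false
negative, a negative a false positive); strict mode instead zeroes the
attempt on any error.
"""

from __future__ import annotations

import json
import re
import subprocess
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .benchmark import Structure
from .metrics import ContingencyTable, MetricSet, derive_metrics

__all__ = [
    "ClassifierProgram",
    "ClassificationResult",
    "ProgramEvaluation",
    "ProgramHandle",
    "SlugError",
    "slugify",
    "compile_program",
    "classify_one",
    "evaluate_program",
]

_WORKER = Path(__file__).with_name("_worker.py")


class SlugError(ValueError):
    """The class name reduces to an empty function-name token."""


def slugify(class_name: str) -> str:
    """Map a class name to its classifier function name ``is_<slug>``:
    lowercase, non-alphanumeric runs collapsed to single underscores."""
    if not class_name:
        raise SlugError("empty class name")
    slug = re.sub(r"[^a-z0-9]+", "_", class_name.lower()).strip("_")
    if not slug:
        raise SlugError(f"class name {class_name!r} has no alphanumeric content")
    return f"is_{slug}"


@dataclass(frozen=True)
class ClassifierProgram:
    class_id: str
    function_name: str
    source: str
    attempt_index: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.source:
            raise ValueError("program source is empty")
        if not re.fullmatch(r"is_[a-z0-9_]+", self.function_name):
            raise ValueError(f"bad function name {self.function_name!r}")


@dataclass(frozen=True)
class ClassificationResult:
    m: bool
    e: str


@dataclass
class ProgramEvaluation:
    table: ContingencyTable
    misclassified: list[tuple[str, str, str]]  # (structure id, true label, explanation)
    fatal_error: str | None = None
    per_example_errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def metrics(self) -> MetricSet:
        return derive_metrics(self.table)

    @property
    def f1(self) -> float:
        return 0.0 if self.fatal_error else self.metrics.f1


def _run_worker(
    source: str,
    function_name: str,
    smiles: Sequence[str],
    timeout_s: float,
    check_only: bool = False,
) -> dict:
    request = json.dumps(
        {
            "source": source,
            "function_name": function_name,
            "smiles": list(smiles),
            "timeout_s": timeout_s,
            "check_only": check_only,
        }
    )
    budget = 60.0 + timeout_s * max(1, len(smiles))
    try:
        proc = subprocess.run(
            [sys.executable, str(_WORKER)],
            input=request,
            capture_output=True,
            text=True,
            timeout=budget,
        )
    except subprocess.TimeoutExpired:
        return {"fatal": f"evaluation exceeded the {budget:.0f} s process budget"}
    if proc.returncode != 0 or not proc.stdout.strip():
        tail = (proc.stderr or "").strip()[-2000:]
        return {"fatal": f"worker process failed (exit {proc.returncode}): {tail}"}
    return json.loads(proc.stdout.splitlines()[-1])


@dataclass
class ProgramHandle:
    """A compiled program: classification requests are dispatched to a fresh
    sandbox process per batch (the programs are standalone by design, each
    parsing its own SMILES, so there is no shared state to keep warm)."""

    program: ClassifierProgram
    timeout_s: float = 10.0

    def classify_many(
        self, smiles: Sequence[str]
    ) -> list[ClassificationResult | str]:
        """One entry per input: a :class:`ClassificationResult`, or the error
        message string for contained per-example failures."""
        reply = _run_worker(
            self.program.source, self.program.function_name, smiles, self.timeout_s
        )
        if "fatal" in reply:
            return [f"fatal: {reply['fatal']}"] * len(smiles)
        out: list[ClassificationResult | str] = []
        for status, m, e in reply["results"]:
            out.append(ClassificationResult(bool(m), e) if status == "ok" else e)
        return out


def compile_program(
    program: ClassifierProgram, timeout_s: float = 10.0
) -> tuple[ProgramHandle | None, str | None]:
    """Load the source in the sandbox and verify the classifier function
    exists.  Returns ``(handle, None)`` on success or ``(None, error_text)``
    on a fatal load failure."""
    reply = _run_worker(program.source, program.function_name, [], timeout_s, check_only=True)
    if "fatal" in reply:
        return None, reply["fatal"]
    return ProgramHandle(program, timeout_s), None


def classify_one(
    handle: ProgramHandle, smiles: str
) -> ClassificationResult | str:
    if not smiles:
        raise ValueError("empty SMILES")
    return handle.classify_many([smiles])[0]


def evaluate_program(
    program: ClassifierProgram,
    positives: Sequence[Structure],
    negatives: Sequence[Structure],
    timeout_s: float = 10.0,
    strict_errors: bool = False,
) -> ProgramEvaluation:
    """Run the program over labeled positives and negatives and aggregate a
    contingency table.

    Fatal load errors zero the table (F1 = 0).  Per-example errors are
    contained: lenient mode books them as misclassifications in the
    unfavorable direction, strict mode escalates the first one to fatal.
    """
    pos_ids = {s.id for s in positives}
    if pos_ids & {s.id for s in negatives}:
        raise ValueError("positive and negative sets overlap")
    reply = _run_worker(
        program.source,
        program.function_name,
        [s.smiles for s in positives] + [s.smiles for s in negatives],
        timeout_s,
    )
    if "fatal" in reply:
        return ProgramEvaluation(
            table=ContingencyTable(), misclassified=[], fatal_error=reply["fatal"]
        )
    results = reply["results"]
    per_example_errors: list[tuple[str, str]] = []
    misclassified: list[tuple[str, str, str]] = []
    tp = fp = tn = fn = 0
    labeled = [(s, "positive") for s in positives] + [(s, "negative") for s in negatives]
    for (structure, label), (status, m, e) in zip(labeled, results):
        if status != "ok":
            if strict_errors:
                return ProgramEvaluation(
                    table=ContingencyTable(),
                    misclassified=[],
                    fatal_error=f"per-example error on {structure.id}: {e}",
                )
            per_example_errors.append((structure.id, e))
            # unfavorable direction: failed positive -> fn, failed negative -> fp
            if label == "positive":
                fn += 1
            else:
                fp += 1
            misclassified.append((structure.id, label, f"program error: {e}"))
            continue
        if label == "positive":
            if m:
                tp += 1
            else:
                fn += 1
                misclassified.append((structure.id, label, e))
        else:
            if m:
                fp += 1
                misclassified.append((structure.id, label, e))
            else:
                tn += 1
    return ProgramEvaluation(
        table=ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn),
        misclassified=misclassified,
        per_example_errors=per_example_errors,
    )
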