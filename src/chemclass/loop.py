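"""The iterative program-learning loop.

For each benchmark class: build a prompt (initial, or feedback derived from
the previous attempt's misclassifications and captured errors), ask the
text-generation backend for a program, parse it, evaluate it in the sandbox
on the training-split positives and negatives, and repeat until the training
F1 reaches the configured threshold or the attempt budget is exhausted.
Every attempt is recorded in an audit trail — a git repository with one
commit per attempt (the model's reasoning and, from the second attempt on,
the feedback text ride along in the commit message) or a plain JSONL log
when git is unavailable.

The retained program for a class is the best attempt by training F1 (ties
broken toward the earlier attempt); that score is the class's *learnability*
and is the key used downstream for filtering and ensembling.
"""

from __future__ import annotations

import json
import os
import random
import shutil
import subprocess
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from .benchmark import Benchmark, BenchmarkClass, Structure
from .executor import (
    ClassifierProgram,
    ProgramEvaluation,
    evaluate_program,
    slugify,
)
from .generation import (
    Backend,
    GenerationError,
    LearnConfig,
    PromptBundle,
    build_feedback_prompt,
    build_initial_prompt,
    parse_response,
)
from .metrics import ContingencyTable

__all__ = [
    "AttemptRecord",
    "LearnedClassResult",
    "ProgramSuite",
    "GitTrail",
    "JsonlTrail",
    "open_trail",
    "record_attempt",
    "learn_class",
    "learn_suite",
    "learnability",
    "save_suite",
    "load_suite",
]


@dataclass
class AttemptRecord:
    attempt_index: int
    prompt_digest: str
    prompt_kind: str
    reasoning: str
    program_source: str
    evaluation: ProgramEvaluation
    f1: float
    feedback_text: str | None = None  # full feedback prompt for attempts > 1


@dataclass
class LearnedClassResult:
    class_id: str
    class_name: str
    function_name: str
    attempts: list[AttemptRecord] = field(default_factory=list)
    skipped_reason: str | None = None

    @property
    def best(self) -> AttemptRecord | None:
        if not self.attempts:
            return None
        return max(self.attempts, key=lambda a: (a.f1, -a.attempt_index))

    @property
    def converged(self) -> bool:
        return self._threshold is not None and self.best is not None and \
            self.best.f1 >= self._threshold

    _threshold: float | None = None

    @property
    def best_program(self) -> ClassifierProgram | None:
        best = self.best
        if best is None or not best.program_source:
            return None
        return ClassifierProgram(
            class_id=self.class_id,
            function_name=self.function_name,
            source=best.program_source,
            attempt_index=best.attempt_index,
        )


def learnability(result: LearnedClassResult) -> float:
    """Best training F1 over all attempts (0 for an all-failed class)."""
    if not result.attempts:
        return 0.0
    return result.best.f1


@dataclass
class ProgramSuite:
    label: str
    config: LearnConfig
    results: dict[str, LearnedClassResult] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Audit trail stores


class GitTrail:
    """One git commit per learning attempt, per class program file."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        if not (self.root / ".git").exists():
            self._git("init", "-q")
            self._git("config", "user.name", "trail")
            self._git("config", "user.email", "trail@localhost")

    def _git(self, *args: str, env: dict | None = None) -> str:
        merged = dict(os.environ)
        if env:
            merged.update(env)
        proc = subprocess.run(
            ["git", *args], cwd=self.root, capture_output=True, text=True, env=merged
        )
        if proc.returncode != 0:
            raise RuntimeError(f"git {' '.join(args)} failed: {proc.stderr.strip()}")
        return proc.stdout

    def record(self, class_id: str, slug: str, attempt: AttemptRecord) -> None:
        path = self.root / "programs" / f"{slug}.py"
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(attempt.program_source or "# no program was produced\n")
        message = [
            f"{class_id} attempt {attempt.attempt_index} f1={attempt.f1:.4f}",
            "",
            "Reasoning:",
            attempt.reasoning or "(none)",
        ]
        if attempt.feedback_text:
            message += ["", "Feedback:", attempt.feedback_text]
        # deterministic commit timestamps keep reruns byte-identical
        stamp = f"2000-01-01T00:00:{attempt.attempt_index % 60:02d} +0000"
        env = {"GIT_AUTHOR_DATE": stamp, "GIT_COMMITTER_DATE": stamp}
        self._git("add", str(path.relative_to(self.root)))
        # verbatim cleanup: reasoning/feedback may contain '#' lines or
        # trailing whitespace that git's default cleanup would strip
        self._git("commit", "-q", "--allow-empty", "--cleanup=verbatim",
                  "-m", "\n".join(message), env=env)

    def commits(self, slug: str) -> list[tuple[str, str]]:
        """(hash, full message) per commit touching the class program, oldest first."""
        out = self._git(
            "log", "--reverse", "--format=%H%x00%B%x01", "--", f"programs/{slug}.py"
        )
        records = []
        for chunk in out.split("\x01"):
            chunk = chunk.strip("\n")
            if not chunk:
                continue
            sha, message = chunk.split("\x00", 1)
            records.append((sha.strip(), message))
        return records

    def program_versions(self, slug: str) -> list[str]:
        """Program source at each commit, oldest first (for trail replay)."""
        return [
            self._git("show", f"{sha}:programs/{slug}.py")
            for sha, _ in self.commits(slug)
        ]


class JsonlTrail:
    """Append-only fallback store with the same record/replay surface."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.path = self.root / "trail.jsonl"

    def record(self, class_id: str, slug: str, attempt: AttemptRecord) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(
                json.dumps(
                    {
                        "class_id": class_id,
                        "slug": slug,
                        "attempt": attempt.attempt_index,
                        "f1": attempt.f1,
                        "reasoning": attempt.reasoning,
                        "feedback": attempt.feedback_text,
                        "source": attempt.program_source,
                    },
                    sort_keys=True,
                )
                + "\n"
            )

    def commits(self, slug: str) -> list[tuple[str, str]]:
        records = []
        if self.path.exists():
            with open(self.path, encoding="utf-8") as fh:
                for i, line in enumerate(fh):
                    rec = json.loads(line)
                    if rec["slug"] == slug:
                        records.append((str(i), rec["reasoning"] or ""))
        return records

    def program_versions(self, slug: str) -> list[str]:
        versions = []
        if self.path.exists():
            with open(self.path, encoding="utf-8") as fh:
                for line in fh:
                    rec = json.loads(line)
                    if rec["slug"] == slug:
                        versions.append(rec["source"])
        return versions


def open_trail(root: str | Path):
    """Git-backed trail when git is on PATH, JSONL otherwise."""
    if shutil.which("git"):
        return GitTrail(root)
    return JsonlTrail(root)


def record_attempt(store, class_id: str, slug: str, attempt: AttemptRecord) -> None:
    store.record(class_id, slug, attempt)


# ---------------------------------------------------------------------------
# Learning


def _named_pairs(structures: Sequence[Structure]) -> list[tuple[str, str]]:
    return [(s.name, s.smiles) for s in structures]


def _capped_negatives(
    negatives: list[Structure], cap: int | None, seed: int, class_id: str
) -> list[Structure]:
    if cap is None or len(negatives) <= cap:
        return negatives
    rng = random.Random((seed * 7919 + zlib.crc32(class_id.encode())) % (2**31))
    return sorted(rng.sample(negatives, cap), key=lambda s: s.id)


def learn_class(
    cls: BenchmarkClass,
    benchmark: Benchmark,
    config: LearnConfig,
    backend: Backend,
    trail=None,
) -> LearnedClassResult:
    """Run the full prompt→generate→parse→execute→score→feedback cycle for
    one class against the training split.

    A failed generation, unparseable response or fatally broken program
    scores F1 = 0 and still consumes an attempt; the loop stops early the
    moment an attempt reaches ``config.f1_threshold``.
    """
    slug = slugify(cls.name)
    result = LearnedClassResult(class_id=cls.id, class_name=cls.name, function_name=slug)
    result._threshold = config.f1_threshold
    positives = benchmark.members(cls.id, "train")
    if not positives:
        result.skipped_reason = "no training positives after the split"
        return result
    negatives = _capped_negatives(
        benchmark.non_members(cls.id, "train"), config.negative_eval_cap,
        config.seed, cls.id,
    )
    by_id = {s.id: s for s in positives + negatives}

    previous: AttemptRecord | None = None
    for attempt_index in range(1, config.max_attempts + 1):
        if attempt_index == 1:
            prompt = build_initial_prompt(
                class_name=cls.name,
                function_name=slug,
                definition=cls.definition,
                positives=_named_pairs(positives),
                negatives=_named_pairs(negatives),
                config=config,
                class_id=cls.id,
            )
        else:
            mis = [
                (by_id[sid].name, by_id[sid].smiles, label, expl)
                for sid, label, expl in previous.evaluation.misclassified
                if sid in by_id
            ]
            prompt = build_feedback_prompt(
                previous_source=previous.program_source or "# no program was produced",
                attempt_index=attempt_index,
                f1=previous.f1,
                misclassified=mis,
                fatal_error=previous.evaluation.fatal_error,
                config=config,
                class_id=cls.id,
            )

        reasoning = ""
        source = ""
        try:
            raw = backend.generate(prompt, cls.id, config.model_id)
            parsed = parse_response(raw)
            reasoning, source = parsed.reasoning, parsed.program_source
        except GenerationError as exc:
            evaluation = ProgramEvaluation(
                table=ContingencyTable(), misclassified=[],
                fatal_error=f"generation failed: {exc}",
            )
        else:
            if not source:
                evaluation = ProgramEvaluation(
                    table=ContingencyTable(), misclassified=[],
                    fatal_error="response contained no program source",
                )
            else:
                program = ClassifierProgram(
                    class_id=cls.id,
                    function_name=slug,
                    source=source,
                    attempt_index=attempt_index,
                    provenance={"model_id": config.model_id,
                                "prompt_digest": prompt.inputs_digest},
                )
                evaluation = evaluate_program(
                    program, positives, negatives,
                    timeout_s=config.call_timeout_s,
                    strict_errors=config.strict_errors,
                )

        record = AttemptRecord(
            attempt_index=attempt_index,
            prompt_digest=prompt.inputs_digest,
            prompt_kind=prompt.kind,
            reasoning=reasoning,
            program_source=source,
            evaluation=evaluation,
            f1=evaluation.f1,
            feedback_text=prompt.text if prompt.kind == "feedback" else None,
        )
        result.attempts.append(record)
        if trail is not None:
            record_attempt(trail, cls.id, slug[3:], record)  # file name sans is_ prefix
        previous = record
        if record.f1 >= config.f1_threshold:
            break
    return result


def learn_suite(
    benchmark: Benchmark,
    config: LearnConfig,
    backend: Backend,
    label: str = "experiment",
    class_ids: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
    trail=None,
) -> ProgramSuite:
    """Learn a program per class, independently; optionally persist the suite
    as it grows (interrupted runs resume by skipping classes whose metadata
    is already on disk)."""
    suite = ProgramSuite(label=label, config=config)
    selected = [
        c for c in benchmark.classes if class_ids is None or c.id in set(class_ids)
    ]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None and trail is None:
        trail = open_trail(out / "trail")
    for cls in selected:
        if out is not None:
            meta_path = out / "programs" / f"{slugify(cls.name)[3:]}.meta.json"
            if meta_path.exists():
                suite.results[cls.id] = _result_from_meta(meta_path, out)
                continue
        result = learn_class(cls, benchmark, config, backend, trail=trail)
        suite.results[cls.id] = result
        if out is not None:
            _persist_class(out, result, config)
    if out is not None:
        _write_suite_json(out, suite)
    return suite


# ---------------------------------------------------------------------------
# Suite persistence: programs/<slug>.py + <slug>.meta.json + suite.json


def _persist_class(out: Path, result: LearnedClassResult, config: LearnConfig) -> None:
    programs = out / "programs"
    programs.mkdir(parents=True, exist_ok=True)
    slug = result.function_name[3:]
    best = result.best
    if best is not None and best.program_source:
        (programs / f"{slug}.py").write_text(best.program_source)
    table = best.evaluation.table if best is not None else ContingencyTable()
    metrics = best.evaluation.metrics.as_dict() if best is not None else {}
    meta = {
        "class_id": result.class_id,
        "class_name": result.class_name,
        "function_name": result.function_name,
        "attempts": len(result.attempts),
        "best_attempt": best.attempt_index if best else None,
        "converged": result.converged,
        "skipped_reason": result.skipped_reason,
        "train_table": {"tp": table.tp, "fp": table.fp, "tn": table.tn, "fn": table.fn},
        "train_metrics": metrics,
        "attempt_f1": [a.f1 for a in result.attempts],
        "provenance": {"model_id": config.model_id, "seed": config.seed},
    }
    (programs / f"{slug}.meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _result_from_meta(meta_path: Path, out: Path) -> LearnedClassResult:
    meta = json.loads(meta_path.read_text())
    result = LearnedClassResult(
        class_id=meta["class_id"],
        class_name=meta["class_name"],
        function_name=meta["function_name"],
        skipped_reason=meta.get("skipped_reason"),
    )
    source_path = meta_path.with_name(meta_path.name.replace(".meta.json", ".py"))
    source = source_path.read_text() if source_path.exists() else ""
    t = meta["train_table"]
    table = ContingencyTable(tp=t["tp"], fp=t["fp"], tn=t["tn"], fn=t["fn"])
    for i, f1 in enumerate(meta.get("attempt_f1", []), start=1):
        is_best = i == meta.get("best_attempt")
        result.attempts.append(
            AttemptRecord(
                attempt_index=i,
                prompt_digest="",
                prompt_kind="initial" if i == 1 else "feedback",
                reasoning="",
                program_source=source if is_best else "",
                evaluation=ProgramEvaluation(
                    table=table if is_best else ContingencyTable(), misclassified=[]
                ),
                f1=f1,
            )
        )
    return result


def _config_dict(config: LearnConfig) -> dict:
    return asdict(config)


def _write_suite_json(out: Path, suite: ProgramSuite) -> None:
    summary = {
        cid: {
            "f1": learnability(res),
            "converged": res.converged,
            "attempts": len(res.attempts),
            "skipped_reason": res.skipped_reason,
        }
        for cid, res in suite.results.items()
    }
    (out / "suite.json").write_text(
        json.dumps(
            {"label": suite.label, "config": _config_dict(suite.config),
             "classes": summary},
            indent=2,
            sort_keys=True,
        )
    )


def save_suite(suite: ProgramSuite, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for result in suite.results.values():
        _persist_class(out, result, suite.config)
    _write_suite_json(out, suite)
    return out


def load_suite(in_dir: str | Path) -> ProgramSuite:
    src = Path(in_dir)
    doc = json.loads((src / "suite.json").read_text())
    config = LearnConfig(**doc["config"])
    suite = ProgramSuite(label=doc["label"], config=config)
    for meta_path in sorted((src / "programs").glob("*.meta.json")):
        result = _result_from_meta(meta_path, src)
        result._threshold = config.f1_threshold
        suite.results[result.class_id] = result
    return suite
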