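"""Running learned classifier suites on de-novo structures.

An *ensemble* suite picks, per class, the program with the best training F1
across several experiment suites.  Classifying a SMILES string runs every
class's program and attaches a confidence derived from that program's
training contingency table: the training precision for a positive call and
the training negative predictive value (NPV) for a negative call.  The
confidence is conditional on the training split resembling the population
the de-novo molecule is drawn from; callers get that caveat in the output
metadata rather than any numerical adjustment.

A naive single-SMARTS baseline is included: a class whose ontology entry
carries a wildcard/R-group SMILES can treat it as a SMARTS pattern and call
membership by substructure match alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .executor import ClassifierProgram, ProgramHandle, evaluate_program
from .loop import ProgramSuite, learnability
from .metrics import ContingencyTable, derive_metrics

__all__ = [
    "EnsembleEntry",
    "EnsembleSuite",
    "ClassificationCall",
    "CONFIDENCE_CAVEAT",
    "build_ensemble",
    "classify_structure",
    "smarts_baseline",
]

CONFIDENCE_CAVEAT = (
    "Confidence is estimated from the training split and may not transfer to "
    "molecules drawn from a different distribution."
)


@dataclass
class EnsembleEntry:
    class_id: str
    class_name: str
    program: ClassifierProgram
    source_suite: str
    train_table: ContingencyTable
    train_f1: float


@dataclass
class EnsembleSuite:
    entries: dict[str, EnsembleEntry] = field(default_factory=dict)
    metadata: dict = field(default_factory=lambda: {"confidence_caveat": CONFIDENCE_CAVEAT})

    def macro_train_f1(self) -> float:
        if not self.entries:
            return 0.0
        return sum(e.train_f1 for e in self.entries.values()) / len(self.entries)


@dataclass
class ClassificationCall:
    class_id: str
    class_name: str
    m: bool
    e: str
    confidence: float | None  # None when the training table leaves it undefined
    errored: bool = False


def build_ensemble(suites: Sequence[ProgramSuite]) -> EnsembleSuite:
    """Per class, take the program with the maximal training F1 across the
    input suites (ties go to the first-listed suite).  Classes for which no
    suite produced a program are omitted."""
    if not suites:
        raise ValueError("build_ensemble needs at least one suite")
    ensemble = EnsembleSuite()
    class_ids: list[str] = []
    for suite in suites:
        for cid in suite.results:
            if cid not in class_ids:
                class_ids.append(cid)
    for cid in class_ids:
        best_entry: EnsembleEntry | None = None
        for suite in suites:
            result = suite.results.get(cid)
            if result is None:
                continue
            program = result.best_program
            if program is None:
                continue
            f1 = learnability(result)
            if best_entry is None or f1 > best_entry.train_f1:
                best_entry = EnsembleEntry(
                    class_id=cid,
                    class_name=result.class_name,
                    program=program,
                    source_suite=suite.label,
                    train_table=result.best.evaluation.table,
                    train_f1=f1,
                )
        if best_entry is not None:
            ensemble.entries[cid] = best_entry
    return ensemble


def _confidence(table: ContingencyTable, m: bool) -> float | None:
    metrics = derive_metrics(table)
    if m:
        return None if "precision" in metrics.undefined else metrics.precision
    return None if "npv" in metrics.undefined else metrics.npv


def classify_structure(
    suite: EnsembleSuite, smiles: str, timeout_s: float = 10.0
) -> list[ClassificationCall]:
    """Run every class program on one SMILES string.

    A contained per-example program error yields a negative call flagged
    ``errored``, with the error note as explanation and NPV confidence.
    """
    if not smiles:
        raise ValueError("empty SMILES")
    calls = []
    for cid in sorted(suite.entries):
        entry = suite.entries[cid]
        handle = ProgramHandle(entry.program, timeout_s=timeout_s)
        outcome = handle.classify_many([smiles])[0]
        if isinstance(outcome, str):  # contained error
            calls.append(
                ClassificationCall(
                    class_id=cid,
                    class_name=entry.class_name,
                    m=False,
                    e=f"program error: {outcome}",
                    confidence=_confidence(entry.train_table, False),
                    errored=True,
                )
            )
        else:
            calls.append(
                ClassificationCall(
                    class_id=cid,
                    class_name=entry.class_name,
                    m=outcome.m,
                    e=outcome.e,
                    confidence=_confidence(entry.train_table, outcome.m),
                )
            )
    return calls


def suite_programs(suite: ProgramSuite | EnsembleSuite) -> dict[str, ClassifierProgram]:
    """Best program per class from an experiment suite or an ensemble."""
    if isinstance(suite, EnsembleSuite):
        return {cid: e.program for cid, e in suite.entries.items()}
    programs = {}
    for cid, result in suite.results.items():
        program = result.best_program
        if program is not None:
            programs[cid] = program
    return programs


def evaluate_suite(
    suite: ProgramSuite | EnsembleSuite,
    benchmark,
    partition: str = "test",
    timeout_s: float = 10.0,
    strict_errors: bool = False,
) -> dict[str, ContingencyTable]:
    """Evaluate every class program against the positives and implicit
    universe negatives of one split partition; classes without a usable
    program score an all-miss table (their positives become false
    negatives)."""
    programs = suite_programs(suite)
    tables: dict[str, ContingencyTable] = {}
    benchmark_ids = {c.id for c in benchmark.classes}
    for cid in sorted(set(programs) & benchmark_ids):
        positives = benchmark.members(cid, partition)
        negatives = benchmark.non_members(cid, partition)
        evaluation = evaluate_program(
            programs[cid], positives, negatives,
            timeout_s=timeout_s, strict_errors=strict_errors,
        )
        if evaluation.fatal_error:
            tables[cid] = ContingencyTable(fn=len(positives), tn=len(negatives))
        else:
            tables[cid] = evaluation.table
    return tables


def smarts_baseline(class_smarts: str, smiles: str) -> bool:
    """Single-pattern baseline: does the structure contain a substructure
    match of the class's SMARTS pattern?

    Raises ``ValueError`` for an unparseable pattern (baseline unavailable
    for that class) or an unparseable structure.
    """
    from rdkit import Chem

    pattern = Chem.MolFromSmarts(class_smarts)
    if pattern is None:
        raise ValueError(f"unparseable SMARTS pattern: {class_smarts!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol.HasSubstructMatch(pattern)
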