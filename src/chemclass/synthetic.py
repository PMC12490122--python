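"""Deterministic synthetic fixtures: a toy ontology and benchmark, scripted
mock-backend corpora, and random contingency cases.

The toy ontology is built from five perfectly separable homologous series
(alkanes, alkanols, alkanoic acids, chloroalkanes, alkylbenzenes) — every
member is ``"C" * n`` plus a class-specific suffix, so membership is
decidable by a trivial regular expression and scripted "generated" programs
can hit any target score by bounding the chain length they accept.  Decoy
entries exercise every benchmark rule: a wildcard-SMILES leaf, a
definition-less class, an undersized class, a root grouping with no
definition, and a role-like entry that is never a superclass of a structure.

All expectations returned alongside the fixtures are computed by
straight-line construction arithmetic, independent of the modules under
test.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "ToyClassTemplate",
    "TOY_CLASSES",
    "ToyExpectation",
    "generate_toy_benchmark",
    "build_mock_corpus",
    "MOCK_CORPUS_KINDS",
    "random_contingency_cases",
]


@dataclass(frozen=True)
class ToyClassTemplate:
    id: str
    name: str
    definition: str
    suffix: str  # SMILES appended to the "C"*n backbone

    def member_smiles(self, n: int) -> str:
        return "C" * n + self.suffix

    def member_id(self, n: int) -> str:
        return f"{self.id}:{n:02d}"

    def rule_pattern(self, max_chain: int | None = None) -> str:
        """Regex over SMILES deciding membership; a finite ``max_chain``
        deliberately under-covers the series (for scripted partial programs)."""
        chain = "C+" if max_chain is None else f"C{{1,{max_chain}}}"
        return chain + re.escape(self.suffix)


TOY_CLASSES: tuple[ToyClassTemplate, ...] = (
    ToyClassTemplate("ALK", "alkane", "An acyclic saturated hydrocarbon.", ""),
    ToyClassTemplate("ALC", "alkanol", "An alkane bearing a single hydroxy group.", "O"),
    ToyClassTemplate(
        "ACID", "alkanoic acid", "An alkane bearing a single carboxylic acid group.", "C(=O)O"
    ),
    ToyClassTemplate("CLX", "chloroalkane", "An alkane bearing a single chlorine.", "Cl"),
    ToyClassTemplate(
        "ARO", "alkylbenzene", "A benzene ring bearing a single unbranched alkyl chain.",
        "c1ccccc1",
    ),
)

_SMALL_ID = "SMALL"  # undersized class: alkanes with short chains only
_NODEF_ID = "NODEF"  # definition-less duplicate parent of the alkanols
_ROOT_ID = "ROOT"  # root grouping, no definition
_WILD_ID = "DECOY_WILD"  # leaf with wildcard SMILES
_ROLE_ID = "DECOY_ROLE"  # never a superclass of a structure


@dataclass
class ToyExpectation:
    """Hand-computable ground truth for the generated toy ontology."""

    structure_ids: set[str]
    class_ids: set[str]
    discarded_ids: set[str]
    positives: dict[str, set[str]]
    filtered_class_ids: set[str]  # survivors of the default 25/5000/definition filters
    members_per_class: int


def _toy_rows(n_members: int) -> list[dict]:
    rows: list[dict] = []
    rows.append({"id": _ROOT_ID, "name": "chemical entity", "definition": "",
                 "smiles": "", "parents": [], "star_rating": "", "mappings": []})
    for template in TOY_CLASSES:
        mappings = ["KEGG:C00001"] if template.id in ("ALK", "ALC") else ["LOCAL:x"]
        rows.append({
            "id": template.id, "name": template.name, "definition": template.definition,
            "smiles": "", "parents": [_ROOT_ID], "star_rating": "", "mappings": mappings,
        })
    rows.append({"id": _SMALL_ID, "name": "short-chain alkane",
                 "definition": "An alkane with a short carbon chain.",
                 "smiles": "", "parents": ["ALK", _ROOT_ID], "star_rating": "",
                 "mappings": []})
    rows.append({"id": _NODEF_ID, "name": "hydroxy compound", "definition": "",
                 "smiles": "", "parents": [_ROOT_ID], "star_rating": "", "mappings": []})
    rows.append({"id": _ROLE_ID, "name": "solvent role", "definition": "A role, not a structure.",
                 "smiles": "", "parents": [_ROOT_ID], "star_rating": "", "mappings": []})
    rows.append({"id": _WILD_ID, "name": "generic alkyl fragment", "definition": "",
                 "smiles": "CC*", "parents": ["ALK"], "star_rating": "", "mappings": []})
    for template in TOY_CLASSES:
        for n in range(1, n_members + 1):
            parents = [template.id]
            if template.id == "ALK" and n <= 10:
                parents.append(_SMALL_ID)
            if template.id == "ALC":
                parents.append(_NODEF_ID)
            rows.append({
                "id": template.member_id(n),
                "name": f"{template.name}-{n:02d}",
                "definition": "",
                "smiles": template.member_smiles(n),
                "parents": parents,
                "star_rating": str(2 + n % 2),
                "mappings": [],
            })
    return rows


def _expectation(n_members: int) -> ToyExpectation:
    structures = {
        t.member_id(n) for t in TOY_CLASSES for n in range(1, n_members + 1)
    }
    positives = {t.id: {t.member_id(n) for n in range(1, n_members + 1)}
                 for t in TOY_CLASSES}
    positives[_SMALL_ID] = {TOY_CLASSES[0].member_id(n) for n in range(1, min(10, n_members) + 1)}
    positives[_NODEF_ID] = set(positives["ALC"])
    positives[_ROOT_ID] = set(structures)
    class_ids = {t.id for t in TOY_CLASSES} | {_SMALL_ID, _NODEF_ID, _ROOT_ID}
    discarded = {_WILD_ID, _ROLE_ID}
    filtered = {t.id for t in TOY_CLASSES if n_members >= 25}
    return ToyExpectation(
        structure_ids=structures,
        class_ids=class_ids,
        discarded_ids=discarded,
        positives=positives,
        filtered_class_ids=filtered,
        members_per_class=n_members,
    )


def generate_toy_benchmark(
    out_dir: str | Path,
    n_members: int = 30,
    seed: int = 0,
    dialect: str = "tsv",
) -> tuple[Path, ToyExpectation]:
    """Write the toy ontology document and return its path plus the
    independently computed expected partition.

    The construction is fully deterministic; ``seed`` is recorded in the
    file name stem only so callers can keep variants side by side.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    rows = _toy_rows(n_members)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dialect == "tsv":
        path = out / f"toy_ontology_s{seed}.tsv"
        lines = ["id\tname\tdefinition\tsmiles\tparents\tstar_rating\tmappings"]
        for row in rows:
            lines.append(
                "\t".join([
                    row["id"], row["name"], row["definition"], row["smiles"],
                    "|".join(row["parents"]), row["star_rating"],
                    "|".join(row["mappings"]),
                ])
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif dialect == "obograph-json":
        path = out / f"toy_ontology_s{seed}.json"
        nodes, edges = [], []
        for row in rows:
            meta: dict = {}
            if row["definition"]:
                meta["definition"] = {"val": row["definition"]}
            bpv = []
            if row["smiles"]:
                bpv.append({"pred": "chem/smiles", "val": row["smiles"]})
            if row["star_rating"]:
                bpv.append({"pred": "chem/star_rating", "val": row["star_rating"]})
            if bpv:
                meta["basicPropertyValues"] = bpv
            if row["mappings"]:
                meta["xrefs"] = [{"val": m} for m in row["mappings"]]
            node = {"id": row["id"], "lbl": row["name"]}
            if meta:
                node["meta"] = meta
            nodes.append(node)
            for parent in row["parents"]:
                edges.append({"sub": row["id"], "pred": "is_a", "obj": parent})
        path.write_text(
            json.dumps({"graphs": [{"nodes": nodes, "edges": edges}]}, indent=1),
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path, _expectation(n_members)


# ---------------------------------------------------------------------------
# Scripted mock-backend corpora

MOCK_CORPUS_KINDS = ("all_correct", "improving", "regressing", "all_broken", "crashy")

_BROKEN_SOURCE = "def broken(:\n    pass\n"


def _slug(name: str) -> str:
    return "is_" + re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


def _program_source(template: ToyClassTemplate, max_chain: int | None,
                    crash_on: str | None = None) -> str:
    pattern = template.rule_pattern(max_chain)
    crash_block = ""
    if crash_on:
        crash_block = (
            f"    if {crash_on!r} in smiles:\n"
            f"        raise ValueError('cannot handle {crash_on}-containing structures')\n"
        )
    return (
        "import re\n\n\n"
        f"def {_slug(template.name)}(smiles: str):\n"
        f"{crash_block}"
        f"    if re.fullmatch({pattern!r}, smiles):\n"
        f"        return True, \"matches the {template.name} series pattern\"\n"
        f"    return False, \"does not match the {template.name} series pattern\"\n"
    )


def _response(reasoning: str, source: str) -> str:
    return f"{reasoning}\n```python\n{source}```\n"


def build_mock_corpus(
    kind: str, max_attempts: int = 4
) -> dict[tuple[str, int], str]:
    """Scripted responses keyed by (class id, attempt index).

    * ``all_correct`` — the exact series rule at attempt 1.
    * ``improving`` — chain-length cutoffs 5, 12, then the full rule, so the
      training F1 rises across attempts and crosses an 0.8 threshold at
      attempt 3.
    * ``regressing`` — cutoffs 5, 12, a syntax-broken attempt, then cutoff
      6: the peak is the second attempt, never the last.
    * ``all_broken`` — a syntax error at every attempt.
    * ``crashy`` — the full rule, but raising on any chlorine-containing
      SMILES (contained per-example failures).
    """
    if kind not in MOCK_CORPUS_KINDS:
        raise ValueError(f"unknown corpus kind {kind!r}")
    script: dict[tuple[str, int], str] = {}
    for template in TOY_CLASSES:
        if kind == "all_correct":
            script[(template.id, 1)] = _response(
                f"The {template.name} series is fully characterised by its "
                "SMILES suffix; match the whole string.",
                _program_source(template, None),
            )
        elif kind == "improving":
            for attempt, cutoff in ((1, 5), (2, 12), (3, None)):
                note = (
                    "Covering the full homologous series now."
                    if cutoff is None
                    else f"Assuming chains up to {cutoff} carbons."
                )
                script[(template.id, attempt)] = _response(note, _program_source(template, cutoff))
        elif kind == "regressing":
            for attempt, cutoff in ((1, 5), (2, 12), (4, 6)):
                script[(template.id, attempt)] = _response(
                    f"Trying a chain cutoff of {cutoff}.",
                    _program_source(template, cutoff),
                )
            script[(template.id, 3)] = _response(
                "Refactoring the matcher.", _BROKEN_SOURCE
            )
        elif kind == "all_broken":
            for attempt in range(1, max_attempts + 1):
                script[(template.id, attempt)] = _response(
                    "Drafting the classifier.", _BROKEN_SOURCE
                )
        elif kind == "crashy":
            for attempt in range(1, max_attempts + 1):
                script[(template.id, attempt)] = _response(
                    "Full rule, but fragile on halogens.",
                    _program_source(template, None, crash_on="Cl"),
                )
    return script


# ---------------------------------------------------------------------------
# Random contingency cases (oracle feed for the metrics module)


@dataclass(frozen=True)
class ContingencyCase:
    labels: tuple[bool, ...]
    predictions: tuple[bool, ...]
    tp: int
    fp: int
    tn: int
    fn: int


def random_contingency_cases(n: int, seed: int = 0, max_len: int = 200) -> list[ContingencyCase]:
    """Seeded random label/prediction vectors with tables computed by direct
    per-example counting."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    cases = []
    for _ in range(n):
        length = rng.randint(1, max_len)
        labels = tuple(rng.random() < 0.5 for _ in range(length))
        predictions = tuple(rng.random() < 0.5 for _ in range(length))
        tp = fp = tn = fn = 0
        for lab, pred in zip(labels, predictions):
            if lab and pred:
                tp += 1
            elif lab and not pred:
                fn += 1
            elif not lab and pred:
                fp += 1
            else:
                tn += 1
        cases.append(ContingencyCase(labels, predictions, tp, fp, tn, fn))
    return cases
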