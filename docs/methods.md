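# Methods

## Benchmark construction

An ontology document (TSV or OBO-Graphs JSON) is partitioned into three
disjoint sets covering every entry:

* **structures** — entries with a SMILES containing no wildcard character
  `*` and with no is-a children. Keying on the `*` character alone is
  deliberate: R-group pseudo-atoms occur only in class-level formulae, which
  never enter the structure set because such entries have children.
* **classes** — entries that are a direct or indirect is-a superclass of at
  least one structure. Any SMILES attached to a class is ignored: class
  formulae are typically necessary-but-not-sufficient fragments, not
  definitions.
* **discarded** — everything else. Roles and obsolete terms fall out
  automatically because they are never superclasses of structures; there is
  no dedicated handling for them.

Positives follow the true path rule (all transitive structure descendants,
computed by BFS over the reverse is-a adjacency; a diamond contributes a
structure once). Negatives are implicit — every benchmark structure not a
positive — and are materialised lazily; `LearnConfig.negative_eval_cap`
optionally subsamples them (seeded) for learning-time evaluation, because at
real-ontology scale the negative pool is the whole corpus. The default is no
cap, matching evaluation on the full set; any cap used is recorded in suite
metadata.

Class filters: ≥ 25 members (enough held-out support), ≤ 5000 members
(drops very high-level groupings), and a nonempty textual definition.
Boundaries are inclusive. Curation star ratings are carried but not
filtered on; a restriction to 3-star entries is available as a config
switch. The train/test split is a single global seeded 80/20 shuffle over
structures, not stratified per class — the construction does not guarantee
every class training positives, and a class whose positives all land in
test is skipped with a recorded reason rather than failed. Slims (subsets
of classes) are selected by explicit id list or by cross-reference prefix
(e.g. KEGG), since the biologically-relevant subset is a curation choice,
not derivable from the graph.

## The learning loop

Per class: build prompt → generate → parse → execute → score → feedback,
until training F1 ≥ `f1_threshold` (default 0.8) or `max_attempts` (default
4) is exhausted; a stricter 0.9/6 variant is expressible through the same
config. Defaults that the loop's behaviour depends on:

| parameter | default | rationale |
|---|---|---|
| `f1_threshold` | 0.8 | stop criterion on training F1 |
| `max_attempts` | 4 | bound on generate/evaluate rounds |
| `positive_sample_size` / `negative_sample_size` | 50 / 50 | examples shown in the initial prompt; seeded sample, full sets are used for *scoring* |
| `feedback_example_cap` | 25 per direction | bounds prompt growth; seeded selection of fn/fp examples |
| `call_timeout_s` | 10 | wall-clock cap per classification call |
| `strict_errors` | off | see error semantics below |

Prompts are deterministic functions of (inputs, config, seed); the
per-class RNG stream is derived from the seed and the class id via CRC32 so
it is stable across interpreter runs. Responses are parsed by
concatenating fenced code blocks, with a compile-based heuristic fallback
for fence-free completions; a response with no recoverable code scores
F1 = 0 and consumes an attempt.

Feedback prompts are built from the immediately preceding attempt only (not
the cumulative history): bounded prompt size, and each attempt's repair
signal stays attributable. The retained program is the best attempt by
training F1, ties to the earlier attempt — a run may regress after its peak,
and the peak is what the suite keeps. That score is the class's
*learnability*, used downstream for filtering and ensembling.

The audit trail is a git repository with one commit per attempt (program
file per class; the model's reasoning and, from attempt 2 on, the verbatim
feedback text in the commit message; commit dates are fixed so reruns are
reproducible), with a JSONL fallback when git is unavailable. Trails can be
replayed: re-evaluating each committed program version reproduces the
recorded scores.

## Execution and error semantics

Candidate programs run in a child process per evaluation batch. The source
is exec'd with a restricted builtins dict: no `open`/`exec`/`eval`,
`print` routed to stderr (so it cannot corrupt the result protocol), and an
`__import__` that allows the chemistry toolkit (RDKit), numpy and
math/string stdlib modules while denying network, filesystem and process
modules. Each call is SIGALRM-capped. This contains accidental faults in
generated code — infinite loops, bad imports, exceptions on odd molecules —
it is not a security boundary against deliberately malicious code.

Two error tiers:

* **fatal** (syntax error, blocked import, missing function, worker death):
  the whole attempt scores F1 = 0 and the captured error text goes verbatim
  into the next feedback prompt.
* **per-example** (exception or timeout on one molecule): contained, and by
  default booked as a misclassification in the unfavorable direction
  (positive → fn, negative → fp) — fragility is penalised without
  discarding a partially working program. `strict_errors=True` escalates
  the first per-example error to fatal instead.

Invalid SMILES in an evaluation set are passed to the program unmodified;
programs are expected to handle parse failure themselves (each program
parses its own input — standalone by design, at a known cost in
efficiency).

## Metrics, ensembling, confidence

Precision tp/(tp+fp), recall tp/(tp+fn), F1 = 2PR/(P+R), accuracy,
NPV tn/(tn+fn). Any 0/0 is reported as 0 and flagged undefined — a program
that predicts nothing positive should not score precision 1; flagged zeros
enter macro means as 0. Macro = unweighted mean of per-class metrics;
micro = metrics on the element-wise pooled table. Method comparison labels
a class as favoring one method when the F1 difference exceeds 0.05;
performance groups cut at F1 < 0.5 (poor) and > 0.7 (good), with both
boundaries assigned to moderate.

Ensembles take, per class, the program with maximal training F1 across
input suites; ties go to the first-listed suite (deterministic and
recorded in provenance). Inference confidence is training precision for
positive calls and training NPV for negative calls; when the relevant
denominator is empty the confidence is reported as unavailable, never
fabricated. Outputs carry a caveat that confidence is conditional on the
training split: it is surfaced as metadata, not adjusted for. Hierarchical
consistency between classes is *not* enforced (programs are independent); a
child-positive/parent-negative disagreement is possible and left visible.

## Descriptors and enrichment

The registry holds exactly 37 descriptors in five categories. Every
descriptor that the method description names explicitly (molecular weight,
ring and aromatic-ring counts, HBD/HBA, TPSA, chiral centers, bridgehead
atoms, the glycerol backbone SMARTS `[OX2][CX4H2][CX4H]([OX2])[CX4H2][OX2]`,
acyl-glycerol linkages, the steroid four-ring system, pyranose/furanose and
glycosidic-bond markers, ester/amide/acid/hydroxyl/ether/amine/halogen/
phosphate/sulfur/nitro counts, net formal charge, longest aliphatic chain,
fused ring pairs) is flagged `named`; the panel is completed to 37 with
conventional property/functional-group descriptors flagged `reconstructed`.
The registry is the single source of truth and can be swapped wholesale if
an authoritative list becomes available.

Two custom algorithms:

* **longest aliphatic chain** — atom count of the longest *simple path* in
  the subgraph of non-aromatic carbons, by exhaustive DFS. A breadth-first
  traversal cannot find longest simple paths once that subgraph contains
  rings, so path enumeration is used deliberately; it is exponential in the
  worst case but cheap on drug-sized molecules.
* **fused ring pairs** — unordered SSSR ring pairs sharing ≥ 1 atom (a
  spiro junction therefore counts as a fused pair under this definition).
* The steroid flag is computed on the ring-fusion graph (a connected fused
  system of ≥ 4 rings with ≥ 3 six-membered and ≥ 1 five-membered ring)
  rather than a rigid SMARTS, to tolerate substituted skeletons.

Class profiles are the median of each descriptor over member structures
(all benchmark members by default; configurable to training members only).
Enrichment between two class groups: two-sided Mann-Whitney U per
descriptor — exact null distribution for untied samples with both sizes
≤ 8, normal approximation with tie correction otherwise; two identical
constant samples are reported as p = 1 rather than an error — then BH-FDR
across the 37 tests (α = 0.05), and Cliff's delta with the conventional
magnitude cuts (0.147/0.33/0.474). Positive delta means higher values in
the first group; when group A is the program-favored set, negative deltas
mark features on which the comparator method is stronger.

## Synthetic fixtures

The toy ontology contains five homologous series (30 members each, SMILES
`"C"*n` + a class suffix) under defined parent classes, plus decoys that
exercise every rule: a wildcard-SMILES leaf, a role-like entry, an
undersized class, a definition-less class, and an undefined root grouping.
The classes are perfectly separable by regular expressions over the SMILES
string, so scripted corpora can target any training score by bounding the
chain length a program accepts, and the all-correct corpus establishes a
macro-F1-1.0 smoke test distinguishable from harness bugs. All expectations
shipped with the fixtures are computed by straight-line construction
arithmetic, independent of the modules under test.

What the toy world deliberately does not model: molecules needing real
chemical perception (the membership rules are string rules), label noise,
class imbalance at ontology scale, overlapping classes, or a live
nondeterministic generator. Passing tests therefore validate the
*machinery* — partitioning, closure, filtering, splitting, loop
termination and retention, sandbox containment, metric identities,
statistics — not chemical generalisation of any particular backend.

## Problem sizes

The default test and reproduction runs use 150 structures / 5 classes, 4
learning attempts per class, 1000 random contingency vectors, 200-trial
statistics oracles, 100 random DAGs for the closure oracle, and a 20-vs-20
planted-effect simulation — sizes chosen so the whole pipeline, including
the per-attempt sandbox processes, runs comfortably on a single CPU while
still exercising every code path. All sizes are parameters.

## Known limitations

* Programs share no code across classes; refactoring shared motifs into
  modules is out of scope.
* The sandbox is an allowlist + process model, not a hardened jail.
* No live generation backend is bundled; the `Backend` protocol is the
  integration point and only the deterministic mock ships with the package.
* The slim's mapping-prefix list is configuration — there is no canonical
  enumeration of "biologically relevant" prefixes.
* Confidences are training-split estimates; no calibration against a
  held-out distribution is attempted.
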