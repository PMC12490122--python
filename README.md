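# chemclass

Chemical ontologies such as ChEBI organise molecules under grouping classes
("alkaloid", "glycerophosphocholine", ...) linked by is-a relations, but most
structures deposited in databases arrive unclassified. `chemclass` implements
an approach to automating that classification by *program synthesis*: for
every class it iteratively asks a text-generation model for a small Python
classifier function, executes the candidate in a sandbox against labeled
training structures, and feeds the misclassifications back until the program
is good enough or the attempt budget runs out. The result is a suite of
transparent, editable classifier programs — one per class — rather than an
opaque model.

It is aimed at cheminformaticians and ontology curators who want
per-class classifiers whose decisions come with a plain-text explanation,
and whose learning history is an auditable commit trail.

## The method

For a class *c* with positive structures *P* (all is-a descendants with a
ground, wildcard-free SMILES — the true path rule) and implicit negatives
*N* (all other benchmark structures), the loop synthesises a function
`is_<c>(smiles) -> (m, e)` returning a membership boolean *m* and an
explanation *e*:

1. **Prompt** — task instructions, the class name and (optionally) its
   textual definition, sampled `(name, SMILES)` positives and negatives, and
   an exemplar program with the required contract.
2. **Generate** — a pluggable backend (live API or a deterministic scripted
   mock) returns reasoning plus fenced code.
3. **Execute & score** — the candidate runs in an isolated process on the
   training split; precision, recall, accuracy and F1 = 2PR/(P+R) are
   derived from the contingency table. A compile/load failure scores F1 = 0.
4. **Iterate** — below the F1 threshold (default 0.8, at most 4 attempts)
   the next prompt carries the previous program, misclassified examples with
   the explanations the program gave, and any captured error text.

The best attempt by training F1 is retained; its score is the class's
*learnability*. Suites from several experiments can be **ensembled**
per class (argmax of training F1). At inference a positive call carries
confidence = training precision tp/(tp+fp), a negative call carries the
negative predictive value tn/(tn+fn). Macro metrics average per-class
scores; micro metrics pool the raw counts. A naive single-SMARTS baseline
(substructure match of a class-level pattern) is included for comparison.

A 37-descriptor panel (basic properties, drug-likeness, functional-group
SMARTS counts, structural complexity, lipid/carbohydrate/steroid markers)
supports enrichment analysis: per-class median profiles are compared between
groups of classes with two-sided Mann-Whitney U tests, Benjamini-Hochberg
FDR correction across the panel, and Cliff's delta effect sizes.

## Worked example

Everything is runnable offline: the `chemclass.synthetic` module generates a
toy ontology of five separable homologous series plus decoy entries, and
scripted mock-backend corpora. From `examples/learn_programs.py`:

```text
alkanoic acid   attempts: [0.167, 0.483, 1.000] converged=True learnability=1.000
alkanol         attempts: [0.214, 0.571, 1.000] converged=True learnability=1.000
alkane          attempts: [0.333, 0.529, 1.000] converged=True learnability=1.000
alkylbenzene    attempts: [0.345, 0.588, 1.000] converged=True learnability=1.000
chloroalkane    attempts: [0.222, 0.545, 1.000] converged=True learnability=1.000
```

Each line is one class learned with the "improving" corpus: the first two
programs under-cover the series (training F1 0.17–0.59), the feedback prompt
lists the missed molecules with the program's own explanations, and the
third attempt crosses the 0.8 threshold, stopping the loop. Classifying new
molecules (`examples/classify_smiles.py`):

```text
CCCCO:
  alkanol         member (confidence 1.00): matches the alkanol series pattern
```

The confidence 1.00 is the program's training precision; for a negative
call it would be the training NPV.

The `chemclass` command exposes the same pipeline from the shell:
`chemclass benchmark build`, `chemclass learn`, `chemclass ensemble`,
`chemclass classify`, `chemclass eval`, `chemclass descriptors compute`,
`chemclass enrich`, `chemclass smartifier`, `chemclass fixtures make`.

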