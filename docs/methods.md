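# Methods

This note documents the models and procedures implemented in `guideflow`,
the choices made where the design was genuinely open, and what the packaged
fixtures do and do not show about real deployments.

## Pipeline model

The compiler is a pipes-and-filters chain — pre-processing, combined
reasoning, post-processing — over a blackboard in the middle stage.

**Flow-chart dialect.** Editors export activity diagrams in many dialects;
the one read here is deliberately closed and documented (see
`flowchart_model`): `Model` elements with reserved attributes `id`,
`modelType`, `name`, `stereotype`, and `RelationshipRef` edges with `From`,
`To` and an optional `guard`. Branch conditions live on edges rather than
inside decision symbols, matching common activity-diagram exports; any
other placement can be adapted at import. Presentation stripping removes a
configurable attribute blacklist (default `x, y, width, height, color,
font, background, zorder`); pre-processing is pure and idempotent, and
the streaming symbol scanner is guaranteed (and tested) to yield the same
symbol sequence as the whole-document parse.

**Ontology fragment.** Full description logic is unnecessary for the
translation: the store implements named classes with subclass axioms (a
DAG), object/datatype properties with optional cardinality bounds,
individuals, a synonym table, and Horn rules with builtins
(`stringEqualIgnoreCase`, `multiply`, `divide`). The nonstandard zero-
cardinality atom `(p = 0)(?x)` is interpreted as negation as failure and
evaluated in a second stratum; rule bases where a head derives a property
read through such an atom are rejected as unstratified at load. This makes
the forward-chaining fixpoint finite, order-independent and monotone in the
individuals — all three are property-tested. Numeric literals compare with
1e-9 relative tolerance; case-insensitive string comparison uses Unicode
casefold. Division by zero skips the offending rule instance and logs it
rather than failing the whole evaluation.

**Coordinator policy.** Which knowledge source "brings the solution
closest" is underdetermined, so the coordinator uses a fixed priority —
diagram reasoner, then connection linker, then term matcher, then the
interaction source — and document order within a source. This makes
translation deterministic: the same chart, ontologies and transcript
reproduce the same model bit for bit, which the tests assert by comparing
serialized output across runs.

**Term matching.** Action names are tokenized on whitespace and
punctuation, except that dose strings (`1ml/h`, `20mg`) survive as single
tokens; matching is case-insensitive against class names and synonyms. A
matched drug class is narrowed to its leaf preparations; each dose token is
attributed to the nearest drug token in the text (ties to the earlier
drug), and leaves whose name does not contain the dose's amount part are
filtered out — unless that would eliminate every candidate, in which case
the qualifier is treated as uninformative (a rate such as `1ml/h` cannot
distinguish preparations labelled by concentration, which is precisely why
the morphine example stays ambiguous and becomes a question). Candidate
lists in questions are sorted by name. Generic mentions of the taxonomy
root ("medication") are not forced to a leaf.

**Transcripts.** The scripted expert is an ordered list of answers,
optionally pinned to question ids. The packaged sedation transcript is
*recorded* by running the translation once under an explicit policy (pick
the 10 mg/1 ml morphine preparation; model footnote symbols as work items)
and then replayed verbatim, so fixture compilation is reproducible. In
strict mode an unanswerable question aborts translation with the question
id and symbol; in non-strict mode the symbol falls back to a manually
modelled work item and the gap is logged.

**Post-processing.** Construct-to-node mapping is kind for kind. Every
split must end up with exactly one default (guard-less) branch: charts
lacking one have their last declared branch demoted to default with a
logged warning, so every "if" has an "else". Timer texts accept ISO-8601
style (`PT4H`) and plain English (`4 hours`, `every 30 minutes`);
durations are integer seconds internally and ISO strings in XML; a
schedule containing "every" is periodic. The "generated code" of a
deployment becomes declarative handler descriptors on work-item nodes (the
interpreted action: class, resolved preparations, derived parameters) —
language-neutral equivalents of generated interaction components, consumed
by whatever handler the embedding application supplies. Per split branch a
production rule is emitted (patterns binding the guard's fact types, the
guard as condition, a flow signal as consequence, salience by declared
branch order); these rules are what the engine's network is built from
when measuring structural scaling, while flow traversal evaluates the
same guards directly — one semantics, two consumers.

## Execution model

**Matching.** The network shares one alpha node per distinct
`(fact type, literal constraints)` pattern; per-rule joins form tokens, and
a rule condition (a three-valued expression over the bound facts) filters
them. The invariant — incremental activations equal a naive cross-product
match after every assert/retract/modify — is enforced by a randomized
oracle test (500 configurations of ≤6 rules, ≤4 patterns, ≤8 facts).
`naive_match` is kept deliberately independent of the incremental path.

**Conflict resolution.** Salience descending, then recency descending,
then rule id — a total order chosen for reproducibility. Refraction: an
activation fires once per (rule, fact bindings, fact versions); modifying a
participating fact bumps its version and re-enables firing. `fire_all`
takes a positive firing limit and reports the last 20 firings on overrun.

**Conditions.** Comparisons (`< ≤ = ≠ ≥ >`) over fact-attribute references
and literals combine with `and`/`or`/`not` under Kleene three-valued
semantics; a reference to a missing fact or attribute yields *unknown*, and
a split takes a branch only on a definite true, otherwise the default.
This realizes the rule that incomplete patient data must never pick a
clinical branch by accident.

**Flows.** Traversal is token-based on a simulated integer-second clock
(a wall-clock implementation satisfies the same interface but is untested
for timing values, which are hardware-bound). Split branches are tried in
declared order. Joins have two modes: `any` (XOR merge — what a chart
`MergeNode` compiles to, since the sedation charts merge *exclusive*
branches, where waiting for all would deadlock) and `all` (wait-for-all,
for parallel forks, from `JoinNode`). A periodic timer's k-th event fires
at exactly `t0 + k·p`. Work items block their branch until the handler
completes the ticket; sub-process nodes load the referenced flow on first
entry, so only the guideline variant actually in force is ever
materialized (the registry records load order). With no runnable branch
and no pending event, blocked work items produce a deadlock report.
Rules are loaded before facts; the attribution of load cost between the
two is a bookkeeping convention, not an observable of the semantics.

## Fixtures: what they emulate

**Sedation set.** The original five paper charts are images, so the
packaged set is a re-creation constrained by the published decomposition —
7 flows with node counts 28 / 32 / 28 / 22 / 30 / 5 / 4, 149 total — and
by every behavior the protocol names: goal-RASS entry at the start (with a
notification loop while missing), four-hourly re-assessment, comparison of
current to goal RASS with two-step titration ladders, database-entry
reminders, a footnote symbol resolved through an expert question, weaning
sub-flows entered at end of sedation, and combiner flows selecting by
sedation type. The short guideline is modelled as two flow documents plus
a 4-node chain combining them; the deep/long-term variant follows the
normal-guideline chart via the combiner's default branch. Titration doses
on branches the publication does not illustrate are placeholders; the
short-acting agents (propofol, remifentanil) are plausible vocabulary
additions, not published content. Node-count fidelity is asserted against
the printed numbers, never against pixel content.

**Scenarios.** `PatientScenario` is a branch-coverage driver, not
pharmacology: true RASS drifts upward slowly (default 0.05/h, SD 0.3),
each titration step moves it by 1.5 RASS points after a 1-hour lag, and
each 4-hour entry window is missed with probability 0.2 by default
(mirroring imperfect charting compliance). Values are clamped to integers
in [−5, 4]; identical seeds give identical trajectories. Defaults describe
a typical normally sedated adult (80 kg, 1.80 m, 60 y, goal RASS −2,
48 h of sedation). Passing tests therefore demonstrate control-flow and
timing correctness of the computerized guideline — not clinical validity
of titration decisions, which would need real patient data and clinical
evaluation.

**Split family.** `make_split_flow(n)` builds a balanced binary decision
tree with exactly `n` splits whose guards partition an integer input range
(verified by exhaustive sweep), the family used at n ∈ {1, 3, 7, 15, 19,
24, 28, 31} for the scaling analysis. Because branch rules share their
single alpha pattern, the compiled network size is exactly affine in the
split count; the test fits least squares and requires R² ≥ 0.99. This is
the structural counterpart of linear load-time growth; absolute
milliseconds are hardware-bound and out of scope.

**BMI example.** A 10-node flow computing BMI through the derived-
parameter ontology rule (weight/height², exercised to 1e-9 relative
accuracy) and categorizing it over configurable thresholds (defaults
18.5 / 25 / 30, the WHO adult cut-offs; the boundary value falls into the
higher category because guards use strict `<`).

## Numerical and degenerate-input choices

- Durations: integer seconds; negative delays and non-positive periods are
  validation errors.
- RASS validation rejects non-integers (including booleans) and values
  outside [−5, 4]; the validator accepts exactly the 10 legal scores.
- Ontology numeric equality: 1e-9 relative/absolute tolerance; taxonomy
  cycles and unstratified rule bases are load-time errors.
- Empty documents translate to empty models without error; a zero-symbol
  chart is valid input end to end.
- Tie-breaks are total everywhere (document order, sorted names, sorted
  serialization) so that every artifact is byte-reproducible.

## Known limitations

- The XML dialect is this package's own; real Visual-Paradigm/XMI exports
  need an import shim.
- The ontology fragment has no tableau reasoning, consistency checking
  beyond cycles/cardinalities, or OWL import; large external terminologies
  are represented by a small packaged vocabulary and synonym table.
- Term matching is token-based; it does not parse grammar, negation or
  misspellings (those become expert questions by design).
- The engine is single-session and in-memory: no truth maintenance,
  persistence, or distributed execution.
- Wall-clock execution shares the clock interface but is untested for
  absolute timing; all timing guarantees are about the simulated clock.
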