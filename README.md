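# guideflow

Semi-automatic computerization of clinical guidelines drawn as flow charts:
an ontology-driven compiler from activity-diagram XML to executable *rule
flows*, plus a forward-chaining production-rule engine that runs them with
timers and human-task work items.

## The problem

Clinical guidelines — for example the ICU sedation protocol that titrates
sedatives toward a target depth of consciousness on the Richmond
Agitation-Sedation Scale (RASS, integers from −5 *unarousable* to 4
*combative*) — are usually maintained as paper flow charts. They are
ambiguous, easy to skip under workload, and enforce nothing. Hand-coding
each guideline into decision-support software is slow and error-prone, and
every revision needs a developer.

`guideflow` closes that gap in three stages:

1. **Pre-processing** reads the flow-chart XML a diagram editor exports and
   strips presentation content, keeping symbol types, names, stereotypes and
   edges (`guideflow.flowchart_model`).
2. **Combined reasoning** translates the filtered chart into an intermediate
   language on a blackboard: a diagram reasoner classifies each symbol
   against a small diagram ontology using rules such as

   ```
   ActivityAction(?x) ∧ hasStereoType(?x, ?y) ∧ stringEqualIgnoreCase(?y, "wait") → TimeHandler(?x)
   ActivityAction(?x) ∧ (hasStereoType = 0)(?x) → WorkItem(?x)
   ```

   a term matcher interprets free-text action names against a hospital
   vocabulary (descending the medication taxonomy to a specific
   preparation, using dose qualifiers such as `1ml/h` for disambiguation),
   and a scripted "domain expert" transcript answers the questions the
   automatic sources cannot (`guideflow.mini_ontology`,
   `guideflow.translation`).
3. **Post-processing** compiles the intermediate model, kind for kind, into
   a rule-flow document — Start/End, Split/Join, Timer, WorkItem,
   SubProcess and Action nodes — plus generated production rules for every
   decision branch (`guideflow.ruleflow`).

The **engine** (`guideflow.engine`) executes the result: a Rete-style
network with shared alpha nodes matches facts to rules incrementally, a
salience-ordered agenda with refraction fires them, and a token-based flow
runner on a simulated clock routes splits on their branch conditions,
schedules timers in exact simulated seconds, blocks on work-item tickets
until a human (or scripted handler) completes them, and loads sub-flows
lazily on first entry. Every node entry and rule firing is logged with its
simulated timestamp, giving an auditable explanation chain for each
recommendation.

Derived clinical parameters are computed through ontology rules with
arithmetic builtins, e.g. body-mass index:

```
Patient(?x) ∧ hasWeight(?x, ?y) ∧ hasHeight(?x, ?z) ∧ multiply(?k, ?z, ?z) ∧ divide(?bmi, ?y, ?k) → hasBMI(?x, ?bmi)
```

## Worked example

The package ships generators for its example inputs, including a documented
re-creation of the five-chart ICU sedation guideline (the original charts
exist only as images; the re-creation is constrained by the published
structural decomposition and behaviors — see `docs/methods.md`).

```sh
$ guideflow fixtures --out fixtures
fixtures written to fixtures

$ guideflow compile fixtures/*sedation*.flowchart.xml \
    --transcript fixtures/sedation-transcript.json --out ruleflows
compiled fixtures/normal-sedation-guideline.flowchart.xml -> ruleflows/normal-sedation-guideline.rfx (28 nodes)
compiled fixtures/reduce-normal-sedation.flowchart.xml -> ruleflows/reduce-normal-sedation.rfx (22 nodes)
compiled fixtures/reduce-short-sedation.flowchart.xml -> ruleflows/reduce-short-sedation.rfx (30 nodes)
compiled fixtures/sedation-guideline.flowchart.xml -> ruleflows/sedation-guideline.rfx (5 nodes)
compiled fixtures/short-sedation-guideline-a.flowchart.xml -> ruleflows/short-sedation-guideline-a.rfx (32 nodes)
compiled fixtures/short-sedation-guideline-b.flowchart.xml -> ruleflows/short-sedation-guideline-b.rfx (28 nodes)
compiled fixtures/short-sedation-guideline.flowchart.xml -> ruleflows/short-sedation-guideline.rfx (4 nodes)
7 rule flow(s) written to ruleflows
```

The sedation protocol compiles into 7 executable rule flows totalling
149 nodes: the normal-titration flow (28), two flows for the short-acting
guideline (32 and 28), the two weaning flows (22 and 30), and two small
combiner flows (5 and 4) that select the variant by sedation type. Without
the transcript, compilation stops at the first genuine ambiguity — the text
`Add Morphine 1ml/h, Add Dormicum 2ml/h` matches two preparations,
`Morphine IV [10mg/1ml]` and `Morphine IV [20mg/1ml]`, because the `1ml/h`
rate qualifier cannot separate them — and exits with code 2 listing the
candidates.

Simulating two days of a normally sedated synthetic patient:

```sh
$ guideflow simulate ruleflows/*.rfx --flow sedation-guideline \
    --seed 1 --duration 48 --out sim
simulated 48.0 h: 263 trace events, 12 RASS prompts; outputs in sim
```

The 12 prompts sit at exactly 4-hour simulated intervals (hours 4, 8, …,
48), the cadence the guideline prescribes for RASS re-assessment; `sim/`
contains the full node-entry trace, the rule-firing log and the issued
work items as JSON, reproducible byte-for-byte under the same seed.

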