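"""Generators for all pipeline inputs: the re-created ICU sedation guideline
chart set, a BMI categorization chart, the split-scaling flow family, and
seeded patient scenarios — everything needed to exercise the compiler and
engine with no external downloads.

Sedation guideline re-creation
------------------------------
The original five paper charts exist only as images, so the set packaged
here is a documented re-creation, constrained by the published structural
decomposition — seven executable flows with node counts 28 (normal
titration), 32 and 28 (short-acting guideline, two flows), 22 (weaning off
the normal sedation), 30 (weaning off the short sedation), and 5 and 4
(combiner flows), 149 nodes in total — and by the behaviors the protocol
requires: a goal RASS entered at sedation start, four-hourly RASS
re-assessment, comparison of current versus goal RASS, medication-titration
work items (including "Add Morphine 1ml/h, Add Dormicum 2ml/h"),
database-entry reminders, and guideline selection by sedation type.
Titration steps and doses on branches the publication does not illustrate
are placeholders chosen for plausibility, not clinical content.

Patient scenarios are likewise mechanistic drivers for exercising flow
branches (drift toward goal under titration, missed entries), not a
pharmacokinetic model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .flowchart_model import (
    FlowChartDocument,
    RelationshipRecord,
    SymbolRecord,
    preprocess,
)
from .mini_ontology import default_ontologies
from .translation import Answer, InteractionTranscript, translate
from .ruleflow import postprocess
from .engine import RASS_MAX, RASS_MIN, WorkItemTicket

__all__ = [
    "SedationGuidelineSet",
    "PatientScenario",
    "EXPECTED_NODE_COUNTS",
    "make_sedation_flowcharts",
    "compile_sedation_set",
    "make_split_flow",
    "make_bmi_flowchart",
    "make_patient_scenario",
    "NodeScriptHandler",
    "ScenarioHandler",
    "coverage_runs",
]

#: Published decomposition of the sedation protocol into executable flows.
EXPECTED_NODE_COUNTS = {
    "normal-sedation-guideline": 28,
    "short-sedation-guideline-a": 32,
    "short-sedation-guideline-b": 28,
    "reduce-normal-sedation": 22,
    "reduce-short-sedation": 30,
    "sedation-guideline": 5,
    "short-sedation-guideline": 4,
}


def _chart(name: str, nodes: list[tuple], edges: list[tuple]) -> FlowChartDocument:
    symbols = []
    for spec in nodes:
        sid, mtype = spec[0], spec[1]
        sname = spec[2] if len(spec) > 2 else ""
        stereo = spec[3] if len(spec) > 3 else None
        symbols.append(
            SymbolRecord(symbol_id=sid, model_type=mtype, name=sname, stereotype=stereo,
                         extra={"x": "0", "y": "0"})
        )
    rels = []
    for i, spec in enumerate(edges, start=1):
        frm, to = spec[0], spec[1]
        guard = spec[2] if len(spec) > 2 else None
        rels.append(RelationshipRecord(rel_id=f"{name}-e{i:02d}", from_id=frm,
                                       to_id=to, guard_text=guard))
    doc = FlowChartDocument(symbols=symbols, relationships=rels, source_name=name)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# The seven sedation charts

def _normal_chart() -> FlowChartDocument:
    AA = "ActivityAction"
    nodes = [
        ("n01", "InitialNode"),
        ("n02", AA, "Enter patient information"),
        ("n03", AA, "Enter goal RASS"),
        ("n04", "DecisionNode", "goal RASS entered?"),
        ("n05", AA, "Notify physician: goal RASS missing"),
        ("n06", AA, "Wait 4 hours", "wait"),
        ("n07", AA, "Enter current RASS"),
        ("n08", "DecisionNode", "RASS entered?"),
        ("n09", AA, "Reminder: record the RASS score"),
        ("n10", "DecisionNode", "compare current RASS to goal RASS"),
        ("n11", "DecisionNode", "patient strongly agitated?"),
        ("n12", AA, "Add Morphine 2ml/h, Add Dormicum 4ml/h"),
        ("n13", AA, "Enter medication in database"),
        ("n14", AA, "Add Morphine 1ml/h, Add Dormicum 2ml/h"),
        ("n15", AA, "Enter medication in database"),
        ("n16", "MergeNode"),
        ("n17", "DecisionNode", "patient deeply sedated?"),
        ("n18", AA, "Reduce Morphine 2ml/h, Reduce Dormicum 4ml/h"),
        ("n19", AA, "Enter medication in database"),
        ("n20", AA, "Reduce Morphine 1ml/h, Reduce Dormicum 2ml/h"),
        ("n21", AA, "Enter medication in database"),
        ("n22", "MergeNode"),
        ("n23", AA, "Maintain current medication"),
        ("n24", "MergeNode"),
        ("n25", "DecisionNode", "end of sedation?"),
        ("n26", "Note", "If the patient is agitated, contact the physician on call"),
        ("n27", AA, "Reduce normal sedation", "subprocess"),
        ("n28", "FinalNode"),
    ]
    edges = [
        ("n01", "n02"), ("n02", "n03"), ("n03", "n04"),
        ("n04", "n05", "patient.goal_rass_entered = false"), ("n04", "n06"),
        ("n05", "n03"),
        ("n06", "n07"), ("n07", "n08"),
        ("n08", "n09", "patient.rass_entered = false"), ("n08", "n10"),
        ("n09", "n24"),
        ("n10", "n11", "patient.current_rass > patient.goal_rass"),
        ("n10", "n17", "patient.current_rass < patient.goal_rass"),
        ("n10", "n23"),
        ("n11", "n12", "patient.current_rass >= 2"), ("n11", "n14"),
        ("n12", "n13"), ("n13", "n16"), ("n14", "n15"), ("n15", "n16"),
        ("n16", "n24"),
        ("n17", "n18", "patient.current_rass <= -4"), ("n17", "n20"),
        ("n18", "n19"), ("n19", "n22"), ("n20", "n21"), ("n21", "n22"),
        ("n22", "n24"), ("n23", "n24"), ("n24", "n25"),
        ("n25", "n26", "patient.sedation_end = true"), ("n25", "n06"),
        ("n26", "n27"), ("n27", "n28"),
    ]
    return _chart("normal-sedation-guideline", nodes, edges)


def _short_a_chart() -> FlowChartDocument:
    AA = "ActivityAction"
    nodes = [
        ("s01", "InitialNode"),
        ("s02", AA, "Enter patient information"),
        ("s03", AA, "Enter goal RASS"),
        ("s04", "DecisionNode", "goal RASS entered?"),
        ("s05", AA, "Notify physician: goal RASS missing"),
        ("s06", AA, "Wait 2 hours", "wait"),
        ("s07", AA, "Enter current RASS"),
        ("s08", "DecisionNode", "RASS entered?"),
        ("s09", AA, "Reminder: record the RASS score"),
        ("s10", "DecisionNode", "compare current RASS to goal RASS"),
        ("s11", "DecisionNode", "patient strongly agitated?"),
        ("s12", AA, "Add Propofol 4ml/h, Add Remifentanil 2ml/h"),
        ("s13", AA, "Enter medication in database"),
        ("s14", AA, "Add Propofol 2ml/h, Add Remifentanil 1ml/h"),
        ("s15", AA, "Enter medication in database"),
        ("s16", "MergeNode"),
        ("s17", "DecisionNode", "patient deeply sedated?"),
        ("s18", AA, "Reduce Propofol 4ml/h, Reduce Remifentanil 2ml/h"),
        ("s19", AA, "Enter medication in database"),
        ("s20", AA, "Reduce Propofol 2ml/h, Reduce Remifentanil 1ml/h"),
        ("s21", AA, "Enter medication in database"),
        ("s22", "MergeNode"),
        ("s23", AA, "Maintain current medication"),
        ("s24", "MergeNode"),
        ("s25", "DecisionNode", "end of sedation?"),
        ("s26", AA, "Reduce short sedation", "subprocess"),
        ("s27", "FinalNode"),
        ("s28", "DecisionNode", "sedated longer than 48 hours?"),
        ("s29", AA, "Notify physician: consider switching to the normal sedation guideline"),
        ("s30", AA, "Enter decision in database"),
        ("s31", "MergeNode"),
        ("s32", AA, "Calculate sedation duration"),
    ]
    edges = [
        ("s01", "s02"), ("s02", "s03"), ("s03", "s04"),
        ("s04", "s05", "patient.goal_rass_entered = false"), ("s04", "s06"),
        ("s05", "s03"),
        ("s06", "s07"), ("s07", "s08"),
        ("s08", "s09", "patient.rass_entered = false"), ("s08", "s10"),
        ("s09", "s24"),
        ("s10", "s11", "patient.current_rass > patient.goal_rass"),
        ("s10", "s17", "patient.current_rass < patient.goal_rass"),
        ("s10", "s23"),
        ("s11", "s12", "patient.current_rass >= 2"), ("s11", "s14"),
        ("s12", "s13"), ("s13", "s16"), ("s14", "s15"), ("s15", "s16"),
        ("s16", "s24"),
        ("s17", "s18", "patient.current_rass <= -4"), ("s17", "s20"),
        ("s18", "s19"), ("s19", "s22"), ("s20", "s21"), ("s21", "s22"),
        ("s22", "s24"), ("s23", "s24"), ("s24", "s25"),
        ("s25", "s26", "patient.sedation_end = true"), ("s25", "s28"),
        ("s26", "s27"),
        ("s28", "s29", "patient.sedation_hours >= 48"), ("s28", "s31"),
        ("s29", "s30"), ("s30", "s31"),
        ("s31", "s32"), ("s32", "s06"),
    ]
    return _chart("short-sedation-guideline-a", nodes, edges)


def _short_b_chart() -> FlowChartDocument:
    AA = "ActivityAction"
    nodes = [
        ("b01", "InitialNode"),
        ("b02", AA, "Wait 24 hours", "wait"),
        ("b03", AA, "Stop Propofol, Stop Remifentanil"),
        ("b04", AA, "Enter medication in database"),
        ("b05", AA, "Wait 30 minutes", "wait"),
        ("b06", AA, "Enter current RASS"),
        ("b07", "DecisionNode", "RASS entered?"),
        ("b08", AA, "Reminder: record the RASS score"),
        ("b09", "DecisionNode", "patient awake?"),
        ("b10", AA, "Notify physician: patient awake, assess readiness for extubation"),
        ("b11", AA, "Enter assessment in database"),
        ("b12", "DecisionNode", "ready for extubation?"),
        ("b13", AA, "Reduce short sedation", "subprocess"),
        ("b14", "FinalNode"),
        ("b15", AA, "Add Propofol 2ml/h, Add Remifentanil 1ml/h"),
        ("b16", AA, "Enter medication in database"),
        ("b17", "DecisionNode", "patient deeply sedated?"),
        ("b18", AA, "Notify physician: patient deeply sedated after medication stop"),
        ("b19", AA, "Enter observation in database"),
        ("b20", AA, "Add Propofol 2ml/h, Add Remifentanil 1ml/h"),
        ("b21", AA, "Enter medication in database"),
        ("b22", "DecisionNode", "goal RASS entered?"),
        ("b23", AA, "Notify physician: goal RASS missing"),
        ("b24", AA, "Enter goal RASS"),
        ("b25", "MergeNode"),
        ("b26", "MergeNode"),
        ("b27", "DecisionNode", "end of sedation?"),
        ("b28", AA, "Record wake-up assessment in database"),
    ]
    edges = [
        ("b01", "b02"), ("b02", "b03"), ("b03", "b04"), ("b04", "b05"),
        ("b05", "b06"), ("b06", "b07"),
        ("b07", "b08", "patient.rass_entered = false"), ("b07", "b09"),
        ("b08", "b26"),
        ("b09", "b10", "patient.current_rass >= 0"), ("b09", "b17"),
        ("b10", "b11"), ("b11", "b12"),
        ("b12", "b13", "patient.extubation_ready = true"), ("b12", "b15"),
        ("b13", "b14"),
        ("b15", "b16"), ("b16", "b26"),
        ("b17", "b18", "patient.current_rass <= -4"), ("b17", "b20"),
        ("b18", "b19"), ("b19", "b25"),
        ("b20", "b21"), ("b21", "b22"),
        ("b22", "b23", "patient.goal_rass_entered = false"), ("b22", "b25"),
        ("b23", "b24"), ("b24", "b25"),
        ("b25", "b26"), ("b26", "b28"), ("b28", "b27"),
        ("b27", "b14", "patient.sedation_end = true"), ("b27", "b02"),
    ]
    return _chart("short-sedation-guideline-b", nodes, edges)


def _reduce_normal_chart() -> FlowChartDocument:
    AA = "ActivityAction"
    nodes = [
        ("r01", "InitialNode"),
        ("r02", AA, "Notify staff: start reducing the normal sedation"),
        ("r03", AA, "Wait 4 hours", "wait"),
        ("r04", AA, "Enter current RASS"),
        ("r05", "DecisionNode", "RASS entered?"),
        ("r06", AA, "Reminder: record the RASS score"),
        ("r07", "DecisionNode", "still below goal RASS?"),
        ("r08", "DecisionNode", "medication still running?"),
        ("r09", AA, "Reduce Morphine 1ml/h, Reduce Dormicum 2ml/h"),
        ("r10", AA, "Enter medication in database"),
        ("r11", AA, "Stop all sedative medication"),
        ("r12", "MergeNode"),
        ("r13", "DecisionNode", "patient agitated above goal?"),
        ("r14", AA, "Add Morphine 1ml/h, Add Dormicum 2ml/h"),
        ("r15", AA, "Enter medication in database"),
        ("r16", "MergeNode"),
        ("r17", AA, "Maintain current medication"),
        ("r18", "MergeNode"),
        ("r19", "DecisionNode", "sedation stopped?"),
        ("r20", AA, "Notify physician: sedation reduction complete"),
        ("r21", AA, "Enter end of sedation in database"),
        ("r22", "FinalNode"),
    ]
    edges = [
        ("r01", "r02"), ("r02", "r03"), ("r03", "r04"), ("r04", "r05"),
        ("r05", "r06", "patient.rass_entered = false"), ("r05", "r07"),
        ("r06", "r18"),
        ("r07", "r08", "patient.current_rass < patient.goal_rass"), ("r07", "r13"),
        ("r08", "r09", "patient.morphine_rate > 0"), ("r08", "r11"),
        ("r09", "r10"), ("r10", "r12"), ("r11", "r12"), ("r12", "r18"),
        ("r13", "r14", "patient.current_rass > patient.goal_rass"), ("r13", "r17"),
        ("r14", "r15"), ("r15", "r16"), ("r17", "r16"), ("r16", "r18"),
        ("r18", "r19"),
        ("r19", "r20", "patient.sedation_stopped = true"), ("r19", "r03"),
        ("r20", "r21"), ("r21", "r22"),
    ]
    return _chart("reduce-normal-sedation", nodes, edges)


def _reduce_short_chart() -> FlowChartDocument:
    AA = "ActivityAction"
    nodes = [
        ("q01", "InitialNode"),
        ("q02", AA, "Notify staff: start reducing the short sedation"),
        ("q03", AA, "Calculate reduction step"),
        ("q04", AA, "Wait 1 hour", "wait"),
        ("q05", AA, "Enter current RASS"),
        ("q06", "DecisionNode", "RASS entered?"),
        ("q07", AA, "Reminder: record the RASS score"),
        ("q08", "DecisionNode", "still below goal RASS?"),
        ("q09", "DecisionNode", "medication still running?"),
        ("q10", AA, "Reduce Propofol 2ml/h, Reduce Remifentanil 1ml/h"),
        ("q11", AA, "Enter medication in database"),
        ("q12", AA, "Stop all sedative medication"),
        ("q13", AA, "Enter medication in database"),
        ("q14", "MergeNode"),
        ("q15", "DecisionNode", "patient agitated above goal?"),
        ("q16", "DecisionNode", "patient strongly agitated?"),
        ("q17", AA, "Add Propofol 2ml/h, Add Remifentanil 1ml/h"),
        ("q18", AA, "Enter medication in database"),
        ("q19", AA, "Add Propofol 1ml/h, Add Remifentanil 1ml/h"),
        ("q20", AA, "Enter medication in database"),
        ("q21", "MergeNode"),
        ("q22", "DecisionNode", "off the ventilator?"),
        ("q23", AA, "Notify physician: patient ready for extubation assessment"),
        ("q24", AA, "Enter assessment in database"),
        ("q25", AA, "Maintain current medication"),
        ("q26", "MergeNode"),
        ("q27", "MergeNode"),
        ("q28", "DecisionNode", "sedation stopped?"),
        ("q29", AA, "Enter end of sedation in database"),
        ("q30", "FinalNode"),
    ]
    edges = [
        ("q01", "q02"), ("q02", "q03"), ("q03", "q04"), ("q04", "q05"),
        ("q05", "q06"),
        ("q06", "q07", "patient.rass_entered = false"), ("q06", "q08"),
        ("q07", "q27"),
        ("q08", "q09", "patient.current_rass < patient.goal_rass"), ("q08", "q15"),
        ("q09", "q10", "patient.propofol_rate > 0"), ("q09", "q12"),
        ("q10", "q11"), ("q11", "q14"), ("q12", "q13"), ("q13", "q14"),
        ("q14", "q27"),
        ("q15", "q16", "patient.current_rass > patient.goal_rass"), ("q15", "q22"),
        ("q16", "q17", "patient.current_rass >= 2"), ("q16", "q19"),
        ("q17", "q18"), ("q18", "q21"), ("q19", "q20"), ("q20", "q21"),
        ("q21", "q27"),
        ("q22", "q23", "patient.ventilated = false"), ("q22", "q25"),
        ("q23", "q24"), ("q24", "q26"), ("q25", "q26"), ("q26", "q27"),
        ("q27", "q28"),
        ("q28", "q29", "patient.sedation_stopped = true"), ("q28", "q04"),
        ("q29", "q30"),
    ]
    return _chart("reduce-short-sedation", nodes, edges)


def _combiner_main_chart() -> FlowChartDocument:
    nodes = [
        ("c01", "InitialNode"),
        ("c02", "DecisionNode", "which sedation guideline?"),
        ("c03", "ActivityAction", "Short sedation guideline", "subprocess"),
        ("c04", "ActivityAction", "Normal sedation guideline", "subprocess"),
        ("c05", "FinalNode"),
    ]
    edges = [
        ("c01", "c02"),
        ("c02", "c03", "patient.sedation_type = 'short'"),
        ("c02", "c04"),  # normal and deep/long-term sedation
        ("c03", "c05"), ("c04", "c05"),
    ]
    return _chart("sedation-guideline", nodes, edges)


def _combiner_short_chart() -> FlowChartDocument:
    nodes = [
        ("d01", "InitialNode"),
        ("d02", "ActivityAction", "Short sedation guideline a", "subprocess"),
        ("d03", "ActivityAction", "Short sedation guideline b", "subprocess"),
        ("d04", "FinalNode"),
    ]
    edges = [("d01", "d02"), ("d02", "d03"), ("d03", "d04")]
    return _chart("short-sedation-guideline", nodes, edges)


@dataclass
class SedationGuidelineSet:
    """The re-created chart set plus the scripted expert transcript that
    resolves its questions (medication disambiguation and the footnote
    symbol), and the documented mapping to the published node counts."""

    charts: dict[str, FlowChartDocument]
    transcript: InteractionTranscript
    expected_node_counts: dict[str, int] = field(
        default_factory=lambda: dict(EXPECTED_NODE_COUNTS)
    )


class _ExpertPolicy:
    """Auto-answering stand-in for the domain expert, used once to record the
    packaged transcript: picks the 10mg/1ml morphine preparation wherever the
    dose qualifier leaves two candidates, and models footnote symbols as
    work items."""

    strict = True

    def __init__(self) -> None:
        self.recorded: list[Answer] = []

    def consume(self, question) -> dict:
        if question.kind == "choose":
            pick = next((o for o in question.options if "10mg/1ml" in o),
                        question.options[0])
            payload = {"choice": pick}
        elif question.kind == "define_symbol":
            payload = {"kind": "WorkItem"}
        else:
            payload = {}
        self.recorded.append(Answer(payload=payload))
        return payload


def make_sedation_flowcharts() -> SedationGuidelineSet:
    """Build the seven charts and record their interaction transcript."""
    charts = {}
    for builder in (
        _normal_chart, _short_a_chart, _short_b_chart,
        _reduce_normal_chart, _reduce_short_chart,
        _combiner_main_chart, _combiner_short_chart,
    ):
        doc = builder()
        charts[doc.source_name] = doc
    policy = _ExpertPolicy()
    ontos = default_ontologies()
    for doc in charts.values():
        translate(preprocess(doc), ontos, policy)
    return SedationGuidelineSet(
        charts=charts,
        transcript=InteractionTranscript(policy.recorded, strict=True),
    )


def compile_sedation_set(gset: SedationGuidelineSet | None = None) -> dict:
    """Compile every chart of the set; returns ``{flow_id: (doc, rules)}``.

    The shared transcript is consumed across charts in set order, exactly as
    the packaged transcript file is consumed by the compile command.
    """
    if gset is None:
        gset = make_sedation_flowcharts()
    ontos = default_ontologies()
    transcript = InteractionTranscript(list(gset.transcript.answers), strict=True)
    out = {}
    for name, chart in gset.charts.items():
        model, _ = translate(preprocess(chart), ontos, transcript)
        out[name] = postprocess(model)
    return out


# ---------------------------------------------------------------------------
# Split-scaling family

def make_split_flow(n_splits: int, domain: int = 64) -> FlowChartDocument:
    """A binary-tree decision chart with exactly ``n_splits`` decision
    symbols whose branch guards partition the integer range ``[0, domain)``
    on the fact attribute ``patient.value`` — every input reaches exactly one
    leaf.  Used to study how compiled network size grows with the number of
    decision nodes.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if domain < 2 * (n_splits + 1):
        domain = 2 * (n_splits + 1)
    nodes: list[tuple] = [("t00", "InitialNode")]
    edges: list[tuple] = []
    counter = [0]

    def fresh(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]:02d}"

    def build(lo: int, hi: int, remaining: int) -> str:
        """Create the subtree handling [lo, hi); return its root symbol id."""
        if remaining == 0:
            leaf = fresh("L")
            nodes.append((leaf, "ActivityAction",
                          f"Notify category {lo} to {hi}"))
            edges.append((leaf, "tEND"))
            return leaf
        mid = (lo + hi) // 2
        split = fresh("S")
        nodes.append((split, "DecisionNode", f"value below {mid}?"))
        left_n = (remaining - 1) // 2
        right_n = remaining - 1 - left_n
        left = build(lo, mid, left_n)
        right = build(mid, hi, right_n)
        edges.append((split, left, f"patient.value < {mid}"))
        edges.append((split, right))
        return split

    root = build(0, domain, n_splits)
    nodes.append(("tEND", "FinalNode"))
    edges.insert(0, ("t00", root))
    return _chart(f"split-family-{n_splits}", nodes, edges)


# ---------------------------------------------------------------------------
# BMI example

def make_bmi_flowchart(thresholds: tuple = (18.5, 25.0, 30.0)) -> FlowChartDocument:
    """Flow computing BMI through the derived-parameter rule (weight/height²)
    and categorizing it via split guards over the given thresholds."""
    t1, t2, t3 = thresholds
    AA = "ActivityAction"
    nodes = [
        ("m01", "InitialNode"),
        ("m02", AA, "Enter weight and height"),
        ("m03", AA, "Calculate BMI"),
        ("m04", "DecisionNode", "BMI category?"),
        ("m05", AA, "Notify category underweight"),
        ("m06", AA, "Notify category normal weight"),
        ("m07", AA, "Notify category overweight"),
        ("m08", AA, "Notify category obese"),
        ("m09", "MergeNode"),
        ("m10", "FinalNode"),
    ]
    edges = [
        ("m01", "m02"), ("m02", "m03"), ("m03", "m04"),
        ("m04", "m05", f"patient.bmi < {t1}"),
        ("m04", "m06", f"patient.bmi < {t2}"),
        ("m04", "m07", f"patient.bmi < {t3}"),
        ("m04", "m08"),
        ("m05", "m09"), ("m06", "m09"), ("m07", "m09"), ("m08", "m09"),
        ("m09", "m10"),
    ]
    return _chart("bmi-categorization", nodes, edges)


# ---------------------------------------------------------------------------
# Patient scenarios

@dataclass
class PatientScenario:
    """Mechanistic driver of the sedation flows: a sedated patient whose RASS
    drifts and responds to titration steps, with entries sometimes missed.

    Units: weight kg, height m, age years, durations hours, RASS integer
    steps on [-5, 4].  Defaults describe a typical normally sedated ICU
    patient; the dynamics exist to exercise branches, not to model
    pharmacology.
    """

    seed: int = 0
    weight: float = 80.0
    height: float = 1.80
    age: int = 60
    sex: str = "m"
    sedation_type: str = "normal"  # short | normal | deep/long-term
    goal_rass: int = -2
    initial_rass: int = 1
    drift_per_hour: float = 0.05   # mean upward RASS drift (lightening)
    drift_sd: float = 0.3
    effect_per_step: float = 1.5   # expected |RASS change| per titration step
    effect_lag_hours: float = 1.0
    missing_probability: float = 0.2  # per 4-hour entry window
    sedation_hours: float = 48.0   # sedation_end raised after this long
    entry_interval_hours: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_probability <= 1.0:
            raise ValueError("missing_probability must be in [0, 1]")
        if not RASS_MIN <= self.goal_rass <= RASS_MAX:
            raise ValueError(f"goal_rass outside [{RASS_MIN}, {RASS_MAX}]")
        if not RASS_MIN <= self.initial_rass <= RASS_MAX:
            raise ValueError("initial_rass outside RASS range")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")

    def demographics(self) -> dict:
        return {
            "weight": self.weight, "height": self.height, "age": self.age,
            "sex": self.sex, "sedation_type": self.sedation_type,
        }

    def fact_stream(self, horizon_hours: float = 24.0) -> list[dict]:
        """Passive timed fact stream: demographics at t=0, then one RASS
        observation per entry window unless the entry is missed.  Identical
        seeds yield identical streams."""
        rng = random.Random(self.seed)
        state = float(self.initial_rass)
        out = [{"time": 0, "fact_type": "patient",
                "attributes": {**self.demographics(),
                               "goal_rass": self.goal_rass,
                               "goal_rass_entered": True}}]
        t = self.entry_interval_hours
        while t <= horizon_hours:
            state += self.drift_per_hour * self.entry_interval_hours \
                + rng.gauss(0.0, self.drift_sd)
            if rng.random() >= self.missing_probability:
                out.append({
                    "time": int(t * 3600),
                    "fact_type": "rass_observation",
                    "attributes": {"current_rass": _clamp_rass(state)},
                })
            t += self.entry_interval_hours
        return out


def _clamp_rass(value: float) -> int:
    return max(RASS_MIN, min(RASS_MAX, round(value)))


def make_patient_scenario(seed: int = 0, **params) -> PatientScenario:
    return PatientScenario(seed=seed, **params)


class ScenarioHandler:
    """Work-item handler driven by a :class:`PatientScenario`.

    Answers RASS-entry prompts from the simulated trajectory (or marks the
    window missed), enters the goal RASS and demographics when asked,
    applies titration effects with a lag when medication work items
    complete, and raises the end-of-sedation flag after the scenario's
    sedation duration.
    """

    def __init__(self, scenario: PatientScenario, clock) -> None:
        self.scenario = scenario
        self.clock = clock
        self.rng = random.Random(scenario.seed)
        self.state = float(scenario.initial_rass)
        self.last_update = 0
        self.pending_effects: list[tuple[int, float]] = []  # (apply_at, delta)
        self.morphine_rate = 2.0
        self.propofol_rate = 2.0
        self.issued: list[WorkItemTicket] = []

    def _advance_state(self) -> None:
        now = self.clock.now
        dt_h = (now - self.last_update) / 3600.0
        if dt_h > 0:
            self.state += self.scenario.drift_per_hour * dt_h \
                + self.rng.gauss(0.0, self.scenario.drift_sd) * dt_h ** 0.5
        for due, delta in [e for e in self.pending_effects if e[0] <= now]:
            self.state += delta
            self.pending_effects.remove((due, delta))
        self.last_update = now

    def issue(self, ticket: WorkItemTicket) -> dict:
        self.issued.append(ticket)
        text = (ticket.action or {}).get("text", "").lower()
        action_class = (ticket.action or {}).get("action_class")
        sc = self.scenario
        now_h = self.clock.now / 3600.0
        self._advance_state()
        if "patient information" in text:
            return {"set": sc.demographics()}
        if "goal rass" in text and action_class == "EnterData":
            return {"set": {"goal_rass": sc.goal_rass, "goal_rass_entered": True}}
        if "current rass" in text:
            if self.rng.random() < sc.missing_probability:
                return {"set": {"rass_entered": False}}
            updates = {
                "rass_entered": True,
                "current_rass": _clamp_rass(self.state),
            }
            if now_h >= sc.sedation_hours:
                updates["sedation_end"] = True
                updates["sedation_stopped"] = (
                    self.morphine_rate <= 0 and self.propofol_rate <= 0
                )
            updates["sedation_hours"] = now_h
            updates["morphine_rate"] = self.morphine_rate
            updates["propofol_rate"] = self.propofol_rate
            return {"set": updates}
        lag = int(sc.effect_lag_hours * 3600)
        if action_class == "AddMedication":
            self.pending_effects.append((self.clock.now + lag, -sc.effect_per_step))
            return {}
        if action_class == "ReduceMedication":
            self.pending_effects.append((self.clock.now + lag, +sc.effect_per_step))
            self.morphine_rate = max(0.0, self.morphine_rate - 1.0)
            self.propofol_rate = max(0.0, self.propofol_rate - 1.0)
            return {}
        if action_class == "StopMedication":
            self.morphine_rate = 0.0
            self.propofol_rate = 0.0
            self.pending_effects.append((self.clock.now + lag, +sc.effect_per_step))
            return {}
        return {}


class NodeScriptHandler:
    """Deterministic handler answering work items from per-node payload
    queues (falling back to ``default``) — used to steer a flow through
    specific branches."""

    def __init__(self, scripts: dict[str, list[dict]], default: dict | None = None) -> None:
        self.scripts = {k: list(v) for k, v in scripts.items()}
        self.default = default if default is not None else {}
        self.issued: list[WorkItemTicket] = []

    def issue(self, ticket: WorkItemTicket) -> dict:
        self.issued.append(ticket)
        queue = self.scripts.get(ticket.node_id)
        if queue:
            return queue.pop(0)
        return dict(self.default)


def coverage_runs() -> list[dict]:
    """Scripted runs that jointly drive every node of all seven compiled
    sedation flows: per run, the entry flow, per-node work-item scripts, the
    initial patient attributes, and the simulated horizon in hours."""
    demo = {"weight": 80, "height": 1.8, "age": 60, "sex": "m"}
    return [
        {   # normal guideline, every branch, then the full weaning flow
            "flow": "normal-sedation-guideline",
            "initial": {},
            "horizon_hours": 24 * 14,
            "scripts": {
                "n02": [{"set": {**demo, "sedation_type": "normal"}}],
                "n03": [{"set": {"goal_rass_entered": False}},
                        {"set": {"goal_rass_entered": True, "goal_rass": -2}}],
                "n07": [{"set": {"rass_entered": False}},
                        {"set": {"rass_entered": True, "current_rass": 2}},
                        {"set": {"current_rass": 0}},
                        {"set": {"current_rass": -5}},
                        {"set": {"current_rass": -3}},
                        {"set": {"current_rass": -2}},
                        {"set": {"current_rass": -2, "sedation_end": True}}],
                "r04": [{"set": {"rass_entered": False}},
                        {"set": {"rass_entered": True, "current_rass": -4,
                                 "morphine_rate": 2}},
                        {"set": {"current_rass": -4, "morphine_rate": 0}},
                        {"set": {"current_rass": 0}},
                        {"set": {"current_rass": -2}},
                        {"set": {"current_rass": -2, "sedation_stopped": True}}],
            },
        },
        {   # short guideline A, every branch incl. the 48 h switch advice,
            # then the full short weaning flow
            "flow": "short-sedation-guideline-a",
            "initial": {},
            "horizon_hours": 24 * 14,
            "scripts": {
                "s02": [{"set": {**demo, "sedation_type": "short"}}],
                "s03": [{"set": {"goal_rass_entered": False}},
                        {"set": {"goal_rass_entered": True, "goal_rass": -2}}],
                "s07": [{"set": {"rass_entered": False}},
                        {"set": {"rass_entered": True, "current_rass": 2}},
                        {"set": {"current_rass": 0}},
                        {"set": {"current_rass": -5}},
                        {"set": {"current_rass": -3}},
                        {"set": {"current_rass": -2, "sedation_hours": 50}},
                        {"set": {"current_rass": -2, "sedation_end": True}}],
                "q05": [{"set": {"rass_entered": False}},
                        {"set": {"rass_entered": True, "current_rass": -4,
                                 "propofol_rate": 2}},
                        {"set": {"current_rass": -4, "propofol_rate": 0}},
                        {"set": {"current_rass": 2}},
                        {"set": {"current_rass": 1}},
                        {"set": {"current_rass": -2, "ventilated": False}},
                        {"set": {"current_rass": -2, "ventilated": True}},
                        {"set": {"current_rass": -2, "sedation_stopped": True}}],
            },
        },
        {   # short guideline B: wake-up call branches, ending in weaning
            "flow": "short-sedation-guideline-b",
            "initial": {**demo, "sedation_type": "short", "goal_rass": -2,
                        "goal_rass_entered": True},
            "horizon_hours": 24 * 14,
            "scripts": {
                "b06": [{"set": {"rass_entered": False}},
                        {"set": {"rass_entered": True, "current_rass": 0,
                                 "extubation_ready": False}},
                        {"set": {"current_rass": -5}},
                        {"set": {"current_rass": -2, "goal_rass_entered": False}},
                        {"set": {"current_rass": -2, "goal_rass_entered": True}},
                        {"set": {"current_rass": 0, "extubation_ready": True}}],
                "b24": [{"set": {"goal_rass_entered": True, "goal_rass": -2}}],
                "q05": [{"set": {"rass_entered": True, "current_rass": -2,
                                 "sedation_stopped": True}}],
            },
        },
        {   # combiner, short branch: chains both short flows (quick paths)
            "flow": "sedation-guideline",
            "initial": {**demo, "sedation_type": "short", "goal_rass": -2,
                        "goal_rass_entered": True},
            "horizon_hours": 24 * 7,
            "scripts": {
                "s07": [{"set": {"rass_entered": True, "current_rass": -2,
                                 "sedation_end": True}}],
                "b06": [{"set": {"rass_entered": True, "current_rass": 0,
                                 "extubation_ready": True}}],
                "q05": [{"set": {"rass_entered": True, "current_rass": -2,
                                 "sedation_stopped": True}}],
            },
        },
        {   # combiner, default branch: normal guideline (quick path)
            "flow": "sedation-guideline",
            "initial": {**demo, "sedation_type": "normal", "goal_rass": -2,
                        "goal_rass_entered": True},
            "horizon_hours": 24 * 7,
            "scripts": {
                "n07": [{"set": {"rass_entered": True, "current_rass": -2,
                                 "sedation_end": True}}],
                "r04": [{"set": {"rass_entered": True, "current_rass": -2,
                                 "sedation_stopped": True}}],
            },
        },
    ]
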