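"""Post-processing, condition expressions, XML round-trip, validation."""

import random

import pytest

from guideflow.ruleflow import (
    ConditionExpression,
    ExpressionError,
    RuleFlowDocument,
    RuleFlowError,
    RuleFlowNode,
    canonicalize,
    format_duration,
    parse_duration,
    postprocess,
    read_ruleflow,
    validate_ruleflow,
    write_ruleflow,
)
from guideflow.translation import IntermediateConstruct, IntermediateModel


def model_of(nodes, conns):
    constructs = [IntermediateConstruct(k, cid, dict(attrs)) for k, cid, attrs in nodes]
    for i, (frm, to, guard) in enumerate(conns, 1):
        constructs.append(
            IntermediateConstruct("Connection", f"e{i}",
                                  {"from": frm, "to": to, "guard": guard}))
    return IntermediateModel(constructs=constructs, source_name="test-flow")


class TestDurations:
    @pytest.mark.parametrize("text,seconds", [
        ("PT4H", 14400), ("PT30M", 1800), ("PT1H30M", 5400), ("PT45S", 45),
        ("4 hours", 14400), ("Wait 30 minutes", 1800), ("every 2 hours", 7200),
        ("1 hour", 3600),
    ])
    def test_parse(self, text, seconds):
        assert parse_duration(text) == seconds

    def test_round_trip(self):
        for s in (45, 1800, 5400, 14400, 90000):
            assert parse_duration(format_duration(s)) == s

    def test_unparseable(self):
        with pytest.raises(RuleFlowError, match="cannot parse duration"):
            parse_duration("soonish")


class TestConditionExpression:
    def test_comparison_and_boolean_operators(self):
        expr = ConditionExpression.parse(
            "patient.current_rass > patient.goal_rass and not patient.paused = true")
        facts = {"patient": {"current_rass": 1, "goal_rass": -2, "paused": False}}
        assert expr.evaluate(facts) is True
        facts["patient"]["paused"] = True
        assert expr.evaluate(facts) is False

    def test_missing_attribute_is_unknown(self):
        expr = ConditionExpression.parse("patient.current_rass >= 2")
        assert expr.evaluate({"patient": {}}) is None
        assert expr.evaluate({}) is None

    def test_unknown_propagates_through_not_and_or(self):
        expr = ConditionExpression.parse("not patient.x = 1")
        assert expr.evaluate({}) is None
        expr = ConditionExpression.parse("patient.x = 1 or patient.y = 2")
        assert expr.evaluate({"patient": {"y": 2}}) is True

    def test_string_literals(self):
        expr = ConditionExpression.parse("patient.sedation_type = 'short'")
        assert expr.evaluate({"patient": {"sedation_type": "short"}}) is True
        assert expr.evaluate({"patient": {"sedation_type": "normal"}}) is False

    def test_parse_error(self):
        with pytest.raises(ExpressionError):
            ConditionExpression.parse("patient.x >")
        with pytest.raises(ExpressionError):
            ConditionExpression.parse("(patient.x = 1")


class TestPostprocess:
    def test_minimal_kind_for_kind_mapping(self):
        model = model_of(
            [("Start", "a", {}),
             ("WorkItem", "b", {"action": {"text": "x", "action_class": "AddMedication",
                                           "medications": ["Dormicum IV [5mg/1ml]"],
                                           "observations": [], "derives": []}}),
             ("End", "c", {})],
            [("a", "b", None), ("b", "c", None)],
        )
        doc, rules = postprocess(model)
        assert doc.node_count == 3 and len(doc.edges) == 2
        assert doc.nodes["b"].kind == "WorkItem"
        assert doc.nodes["b"].action["medications"] == ["Dormicum IV [5mg/1ml]"]
        assert rules == []

    def test_six_node_split_join_example_round_trips(self):
        # start, split, two actions, join, end
        model = model_of(
            [("Start", "s", {}), ("Split", "d", {}),
             ("WorkItem", "x", {}), ("WorkItem", "y", {}),
             ("Join", "j", {"source_type": "MergeNode"}), ("End", "e", {})],
            [("s", "d", None), ("d", "x", "patient.bmi < 25"), ("d", "y", None),
             ("x", "j", None), ("y", "j", None), ("j", "e", None)],
        )
        doc, rules = postprocess(model)
        assert doc.node_count == 6
        again = read_ruleflow(write_ruleflow(doc))
        assert write_ruleflow(canonicalize(again)) == write_ruleflow(canonicalize(doc))
        # one guarded branch plus one default rule for the single split
        assert [r.rule_id for r in rules] == \
            ["test-flow/d/branch-0", "test-flow/d/default"]
        assert rules[0].salience > rules[1].salience

    def test_timer_parses_delay_and_periodicity(self):
        model = model_of(
            [("Start", "s", {}),
             ("TimeHandler", "t", {"schedule_text": "every 4 hours"}),
             ("End", "e", {})],
            [("s", "t", None), ("t", "e", None)],
        )
        doc, _ = postprocess(model)
        assert doc.nodes["t"].kind == "Timer"
        assert doc.nodes["t"].delay == 14400 and doc.nodes["t"].period == 14400

    def test_unparseable_guard_cites_text(self):
        model = model_of(
            [("Start", "s", {}), ("Split", "d", {}),
             ("End", "e", {}), ("End", "f", {})],
            [("s", "d", None), ("d", "e", "??!"), ("d", "f", None)],
        )
        with pytest.raises(RuleFlowError, match=r"cannot compile guard '\?\?!'"):
            postprocess(model)

    def test_unreachable_node_fails_validation(self):
        model = model_of(
            [("Start", "s", {}), ("End", "e", {}), ("WorkItem", "w", {}),
             ("End", "e2", {})],
            [("s", "e", None), ("w", "e2", None)],
        )
        with pytest.raises(RuleFlowError, match="unreachable"):
            postprocess(model)

    def test_split_without_default_demotes_last_branch_with_warning(self):
        model = model_of(
            [("Start", "s", {}), ("Split", "d", {}),
             ("End", "e", {}), ("End", "f", {})],
            [("s", "d", None), ("d", "e", "patient.x = 1"), ("d", "f", "patient.x = 2")],
        )
        doc, _ = postprocess(model)
        assert doc.nodes["d"].default_to == "f"
        assert len(doc.nodes["d"].branches) == 1
        assert any("demoted" in w for w in doc.metadata["warnings"])

    def test_node_count_equals_non_connection_constructs(self, compiled_sedation,
                                                         sedation_set):
        from guideflow.flowchart_model import preprocess
        from guideflow.translation import InteractionTranscript, Answer, translate
        from guideflow.mini_ontology import default_ontologies

        transcript = InteractionTranscript(
            [Answer(dict(a.payload)) for a in sedation_set.transcript.answers])
        ontos = default_ontologies()
        for name, chart in sedation_set.charts.items():
            model, _ = translate(preprocess(chart), ontos, transcript)
            doc, _ = compiled_sedation[name]
            assert doc.node_count == len(model.nodes())


def random_flow(seed: int) -> RuleFlowDocument:
    rng = random.Random(seed)
    doc = RuleFlowDocument(flow_id=f"rand-{seed}")
    doc.add_node(RuleFlowNode("n0", "Start"))
    kinds = ["WorkItem", "Action", "Timer", "Join", "SubProcess"]
    n = rng.randint(1, 6)
    for i in range(1, n + 1):
        kind = rng.choice(kinds)
        node = RuleFlowNode(f"n{i}", kind)
        if kind == "Timer":
            node.delay = rng.randint(1, 9999)
            if rng.random() < 0.5:
                node.period = rng.randint(1, 999)
        elif kind == "WorkItem":
            node.action = {"text": f"do {i}", "action_class": None,
                           "medications": [], "observations": [], "derives": []}
        elif kind == "SubProcess":
            node.flow_ref = f"sub-{rng.randint(0, 3)}"
        elif kind == "Action":
            node.updates = [{"set": "x", "value": rng.randint(0, 9)}]
        elif kind == "Join":
            node.mode = rng.choice(["any", "all"])
        doc.add_node(node)
    doc.add_node(RuleFlowNode(f"n{n + 1}", "End"))
    for i in range(n + 1):
        doc.edges.append((f"n{i}", f"n{i + 1}"))
    if rng.random() < 0.5:
        split = RuleFlowNode("sp", "Split", default_to="n1")
        split.branches = [("n0x", ConditionExpression.parse("patient.x < 3"))]
        doc.add_node(RuleFlowNode("n0x", "End"))
        doc.add_node(split)
        doc.edges += [("n0", "sp"), ("sp", "n0x"), ("sp", "n1")]
    return doc


class TestSerialization:
    def test_minimal_start_end_round_trip(self):
        doc = RuleFlowDocument(flow_id="mini")
        doc.add_node(RuleFlowNode("a", "Start"))
        doc.add_node(RuleFlowNode("b", "End"))
        doc.edges.append(("a", "b"))
        again = read_ruleflow(write_ruleflow(doc))
        assert again.node_count == 2 and again.edges == [("a", "b")]

    @pytest.mark.parametrize("seed", range(25))
    def test_random_flows_round_trip_bit_identically(self, seed):
        doc = random_flow(seed)
        text = write_ruleflow(canonicalize(doc))
        again = read_ruleflow(text)
        assert write_ruleflow(canonicalize(again)) == text

    def test_schema_violation_reports_element_path(self):
        with pytest.raises(RuleFlowError, match="Nodes/Node"):
            read_ruleflow('<RuleFlow id="x"><Nodes><Node kind="Start"/></Nodes></RuleFlow>')
        with pytest.raises(RuleFlowError, match="root element"):
            read_ruleflow("<NotARuleFlow/>")


class TestValidator:
    def well_formed(self):
        doc = RuleFlowDocument(flow_id="ok")
        doc.add_node(RuleFlowNode("a", "Start"))
        split = RuleFlowNode("d", "Split", default_to="c")
        split.branches = [("b", ConditionExpression.parse("patient.x < 1"))]
        doc.add_node(split)
        timer = RuleFlowNode("t", "Timer")
        timer.delay = 60
        timer.period = 60
        doc.add_node(timer)
        doc.add_node(RuleFlowNode("b", "End"))
        doc.add_node(RuleFlowNode("c", "End"))
        doc.edges = [("a", "d"), ("d", "b"), ("d", "c"), ("a", "t"), ("t", "c")]
        return doc

    def test_well_formed_flows_have_empty_report(self, compiled_sedation):
        assert validate_ruleflow(self.well_formed()) == []
        for doc, _ in compiled_sedation.values():
            assert validate_ruleflow(doc) == []

    def test_mutations_are_each_detected(self):
        # two Start nodes
        doc = self.well_formed()
        doc.add_node(RuleFlowNode("a2", "Start"))
        doc.edges.append(("a2", "b"))
        assert any("exactly one Start" in v for v in validate_ruleflow(doc))
        # dangling edge
        doc = self.well_formed()
        doc.edges.append(("a", "ghost"))
        assert any("unknown node 'ghost'" in v for v in validate_ruleflow(doc))
        # split without default
        doc = self.well_formed()
        doc.nodes["d"].default_to = None
        assert any("no default branch" in v for v in validate_ruleflow(doc))
        # non-positive timer period
        doc = self.well_formed()
        doc.nodes["t"].period = 0
        assert any("non-positive period" in v for v in validate_ruleflow(doc))
        # unreachable node
        doc = self.well_formed()
        doc.add_node(RuleFlowNode("u", "End"))
        assert any("unreachable" in v for v in validate_ruleflow(doc))
        # missing outgoing edge
        doc = self.well_formed()
        doc.edges.remove(("t", "c"))
        assert any("no outgoing edge" in v for v in validate_ruleflow(doc))
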