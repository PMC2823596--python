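"""Production system and flow executor: matching, agenda, timers, traversal."""

import itertools
import random

import pytest

from guideflow.engine import (
    DeadlockError,
    Engine,
    Fact,
    FactError,
    FlowRegistry,
    FlowRunner,
    ReteNetwork,
    RunawayError,
    ScriptedHandler,
    SimulatedClock,
    naive_match,
    validate_rass,
)
from guideflow.ruleflow import (
    ConditionExpression,
    Pattern,
    RuleDefinition,
    RuleFlowDocument,
    RuleFlowNode,
)


def rule(rule_id, patterns, consequence=None, salience=0, condition=None):
    return RuleDefinition(
        rule_id=rule_id,
        patterns=patterns,
        consequence=consequence or [],
        salience=salience,
        condition=ConditionExpression.parse(condition) if condition else None,
    )


class TestRassBounds:
    def test_all_ten_integer_values_accepted(self):
        assert [validate_rass(v) for v in range(-5, 5)] == list(range(-5, 5))

    @pytest.mark.parametrize("bad", [-6, 5, 42, 0.5, "0", None, True])
    def test_out_of_range_or_non_integer_rejected(self, bad):
        with pytest.raises(FactError):
            validate_rass(bad)

    def test_fact_validation_covers_current_and_goal_rass(self):
        with pytest.raises(FactError):
            Fact("f1", "patient", {"current_rass": -6})
        with pytest.raises(FactError):
            Fact("f1", "patient", {"goal_rass": 5})
        Fact("f1", "patient", {"current_rass": 4, "goal_rass": -5})


class TestNetworkConstruction:
    def test_one_rule_one_pattern(self):
        net = ReteNetwork([rule("r1", [Pattern("a", "A")])])
        stats = net.stats()
        assert stats["alpha_nodes"] == 1 and stats["terminal_nodes"] == 1

    def test_shared_pattern_shares_alpha_node(self):
        shared = Pattern("a", "A", (("x", ">", 1),))
        net = ReteNetwork([
            rule("r1", [shared, Pattern("b", "B")]),
            rule("r2", [shared]),
        ])
        stats = net.stats()
        assert stats["alpha_nodes"] == 2  # three pattern uses, two alphas
        assert stats["alpha_nodes"] < stats["pattern_count"]

    def test_unknown_fact_type_rejected_at_load(self):
        eng = Engine()
        with pytest.raises(Exception, match="unknown fact type"):
            eng.load_production_memory([rule("r", [Pattern("z", "Zed")])],
                                       known_fact_types={"a", "b"})

    def test_duplicate_rule_id_rejected(self):
        with pytest.raises(Exception, match="duplicate rule id"):
            ReteNetwork([rule("r", [Pattern("a", "A")]),
                         rule("r", [Pattern("b", "B")])])


class TestIncrementalMatching:
    def test_single_pattern_activation_lifecycle(self):
        eng = Engine()
        eng.load_production_memory([rule("r1", [Pattern("a", "A", (("x", ">", 2),))])])
        eng.assert_fact(Fact("f1", "A", {"x": 5}))
        assert eng.activation_set() == {("r1", ("f1",))}
        eng.retract_fact("f1")
        assert eng.activation_set() == set()

    def test_retract_unknown_fact_errors(self):
        eng = Engine()
        eng.load_production_memory([])
        with pytest.raises(FactError, match="unknown fact"):
            eng.retract_fact("nope")

    def test_modify_updates_matches(self):
        eng = Engine()
        eng.load_production_memory([rule("r1", [Pattern("a", "A", (("x", ">", 2),))])])
        eng.assert_fact(Fact("f1", "A", {"x": 1}))
        assert eng.activation_set() == set()
        eng.modify_fact("f1", {"x": 9})
        assert eng.activation_set() == {("r1", ("f1",))}

    def random_rules(self, rng):
        rules = []
        for i in range(rng.randint(1, 6)):
            patterns = []
            for j in range(rng.randint(1, 4)):
                ftype = rng.choice("AB")
                constraints = tuple(
                    (rng.choice("xy"), rng.choice(["<", "<=", "=", ">=", ">"]),
                     rng.randint(0, 3))
                    for _ in range(rng.randint(0, 2))
                )
                patterns.append(Pattern(f"v{j}", ftype, constraints))
            condition = None
            if rng.random() < 0.3 and len(patterns) >= 2:
                condition = ConditionExpression.parse(
                    f"v0.{rng.choice('xy')} <= v1.{rng.choice('xy')}")
            rules.append(RuleDefinition(f"r{i}", patterns, [], rng.randint(0, 5),
                                        condition))
        return rules

    @pytest.mark.parametrize("block", range(4))
    def test_random_sequences_match_naive_oracle(self, block):
        """Incremental Rete activations equal the brute-force cross-product
        match after every assert/retract/modify (randomized)."""
        rng = random.Random(1000 + block)
        for _ in range(50):
            rules = self.random_rules(rng)
            eng = Engine()
            eng.load_production_memory(rules)
            alive = []
            for step in range(rng.randint(3, 10)):
                op = rng.random()
                if op < 0.55 or not alive:
                    fid = f"f{step}"
                    eng.assert_fact(Fact(fid, rng.choice("AB"),
                                         {"x": rng.randint(0, 3),
                                          "y": rng.randint(0, 3)}))
                    alive.append(fid)
                    if len(alive) > 8:
                        eng.retract_fact(alive.pop(0))
                elif op < 0.8:
                    eng.modify_fact(rng.choice(alive),
                                    {rng.choice("xy"): rng.randint(0, 3)})
                else:
                    eng.retract_fact(alive.pop(rng.randrange(len(alive))))
                assert eng.activation_set() == \
                    naive_match(rules, eng.facts.values())


class TestNaiveMatch:
    def test_empty_working_memory(self):
        assert naive_match([rule("r", [Pattern("a", "A")])], []) == set()

    def test_fact_order_irrelevant(self):
        rules = [rule("r", [Pattern("a", "A"), Pattern("b", "B")],
                      condition="a.x <= b.x")]
        facts = [Fact("f1", "A", {"x": 1}), Fact("f2", "B", {"x": 2}),
                 Fact("f3", "A", {"x": 3})]
        results = {frozenset(naive_match(rules, perm))
                   for perm in itertools.permutations(facts)}
        assert len(results) == 1


class TestFiring:
    def test_salience_order(self):
        eng = Engine()
        eng.load_production_memory([
            rule("low", [Pattern("a", "A")], [{"notify": {"message": "low"}}], 5),
            rule("high", [Pattern("a", "A")], [{"notify": {"message": "high"}}], 10),
        ])
        eng.assert_fact(Fact("f1", "A", {}))
        eng.fire_all()
        assert [e["rule"] for e in eng.firing_log] == ["high", "low"]

    def test_cascade_is_logged_in_order(self):
        eng = Engine()
        eng.load_production_memory([
            rule("A", [Pattern("s", "Seed")],
                 [{"assert": {"fact_type": "Derived", "attributes": {}}}]),
            rule("B", [Pattern("d", "Derived")], [{"notify": {"message": "done"}}]),
        ])
        eng.assert_fact(Fact("f1", "Seed", {}))
        eng.fire_all()
        assert [e["rule"] for e in eng.firing_log] == ["A", "B"]
        assert eng.notifications[0]["message"] == "done"

    def test_refraction_until_fact_modified(self):
        eng = Engine()
        eng.load_production_memory(
            [rule("r", [Pattern("a", "A")], [{"notify": {"message": "hit"}}])])
        eng.assert_fact(Fact("f1", "A", {"x": 0}))
        eng.fire_all()
        eng.fire_all()
        assert len(eng.firing_log) == 1
        eng.modify_fact("f1", {"x": 1})
        eng.fire_all()
        assert len(eng.firing_log) == 2

    def test_runaway_guard(self):
        eng = Engine()
        eng.load_production_memory([
            rule("loop", [Pattern("a", "A")],
                 [{"assert": {"fact_type": "A", "attributes": {}}}]),
        ])
        eng.assert_fact(Fact("f1", "A", {}))
        with pytest.raises(RunawayError, match="limit 10"):
            eng.fire_all(limit=10)

    def test_stratified_random_rule_sets_reach_naive_fixpoint(self):
        # one-way derivation chains A -> B -> C cannot loop; the final working
        # memory must contain each derived type exactly as naive chaining does
        rng = random.Random(5)
        for _ in range(20):
            n_seed = rng.randint(1, 3)
            eng = Engine()
            eng.load_production_memory([
                rule("a2b", [Pattern("a", "A")],
                     [{"assert": {"fact_type": "B", "attributes": {}}}]),
                rule("b2c", [Pattern("b", "B")],
                     [{"assert": {"fact_type": "C", "attributes": {}}}]),
            ])
            for i in range(n_seed):
                eng.assert_fact(Fact(f"s{i}", "A", {}))
            eng.fire_all()
            counts = {}
            for f in eng.facts.values():
                counts[f.fact_type] = counts.get(f.fact_type, 0) + 1
            assert counts == {"A": n_seed, "B": n_seed, "C": n_seed}


def flow_doc(nodes, edges, flow_id="f"):
    doc = RuleFlowDocument(flow_id=flow_id)
    for node in nodes:
        doc.add_node(node)
    doc.edges = list(edges)
    return doc


class TestFlowExecution:
    def test_trivial_start_end_trace(self):
        doc = flow_doc([RuleFlowNode("a", "Start"), RuleFlowNode("b", "End")],
                       [("a", "b")])
        reg = FlowRegistry()
        reg.register("f", doc)
        runner = FlowRunner(Engine(), reg)
        trace = runner.run("f")
        entries = [(e["node"], e["time"]) for e in trace if e["event"] == "enter"]
        assert entries == [("a", 0), ("b", 0)]

    def test_periodic_timer_fires_at_exact_multiples(self):
        timer = RuleFlowNode("t", "Timer")
        timer.delay = 14400
        timer.period = 14400
        doc = flow_doc(
            [RuleFlowNode("a", "Start"), timer, RuleFlowNode("w", "WorkItem"),
             RuleFlowNode("e", "End")],
            [("a", "t"), ("t", "w"), ("w", "e")])
        reg = FlowRegistry()
        reg.register("f", doc)
        handler = ScriptedHandler(default={})
        runner = FlowRunner(Engine(), reg, handler=handler)
        runner.run("f", until=10 * 14400)
        assert [t.issued_at for t in handler.issued] == \
            [k * 14400 for k in range(1, 11)]

    def test_split_routes_first_true_then_default(self):
        split = RuleFlowNode("d", "Split", default_to="c")
        split.branches = [
            ("b1", ConditionExpression.parse("patient.x >= 2")),
            ("b2", ConditionExpression.parse("patient.x >= 1")),
        ]
        doc = flow_doc(
            [RuleFlowNode("a", "Start"), split, RuleFlowNode("b1", "End"),
             RuleFlowNode("b2", "End"), RuleFlowNode("c", "End")],
            [("a", "d"), ("d", "b1"), ("d", "b2"), ("d", "c")])
        for x, expected in ((5, "b1"), (1, "b2"), (0, "c")):
            reg = FlowRegistry()
            reg.register("f", doc)
            eng = Engine()
            eng.assert_fact(Fact("p", "patient", {"x": x}))
            runner = FlowRunner(eng, reg)
            trace = runner.run("f")
            (route,) = [e for e in trace if e["event"] == "route"]
            assert route["target"] == expected

    def test_unknown_condition_routes_to_default(self):
        split = RuleFlowNode("d", "Split", default_to="c")
        split.branches = [("b1", ConditionExpression.parse("patient.missing > 0"))]
        doc = flow_doc(
            [RuleFlowNode("a", "Start"), split, RuleFlowNode("b1", "End"),
             RuleFlowNode("c", "End")],
            [("a", "d"), ("d", "b1"), ("d", "c")])
        reg = FlowRegistry()
        reg.register("f", doc)
        runner = FlowRunner(Engine(), reg)
        trace = runner.run("f")
        (route,) = [e for e in trace if e["event"] == "route"]
        assert route["target"] == "c"

    def test_all_join_waits_for_both_branches(self):
        join = RuleFlowNode("j", "Join")
        join.mode = "all"
        doc = flow_doc(
            [RuleFlowNode("a", "Start"), RuleFlowNode("x", "Action"),
             RuleFlowNode("y", "Action"), join, RuleFlowNode("e", "End")],
            [("a", "x"), ("a", "y"), ("x", "j"), ("y", "j"), ("j", "e")])
        reg = FlowRegistry()
        reg.register("f", doc)
        runner = FlowRunner(Engine(), reg)
        trace = runner.run("f")
        ends = [e for e in trace if e["node"] == "e" and e["event"] == "enter"]
        assert len(ends) == 1  # fired once, after both arrivals

    def test_blocking_work_item_deadlocks_without_completion(self):
        doc = flow_doc(
            [RuleFlowNode("a", "Start"), RuleFlowNode("w", "WorkItem"),
             RuleFlowNode("e", "End")],
            [("a", "w"), ("w", "e")])
        reg = FlowRegistry()
        reg.register("f", doc)
        runner = FlowRunner(Engine(), reg, handler=ScriptedHandler(default=None))
        with pytest.raises(DeadlockError, match="work item t1"):
            runner.run("f")

    def test_explicit_ticket_completion_resumes_branch(self):
        doc = flow_doc(
            [RuleFlowNode("a", "Start"), RuleFlowNode("w", "WorkItem"),
             RuleFlowNode("e", "End")],
            [("a", "w"), ("w", "e")])
        reg = FlowRegistry()
        reg.register("f", doc)
        eng = Engine()
        runner = FlowRunner(eng, reg, handler=ScriptedHandler(default=None))
        with pytest.raises(DeadlockError):
            runner.run("f")
        runner.complete_ticket("t1", {"set": {"x": 1}})
        runner.resume()
        assert any(e["node"] == "e" for e in runner.trace)
        assert eng.singleton("patient").attributes == {"x": 1}

    def test_missing_subflow_is_an_error(self):
        sub = RuleFlowNode("s", "SubProcess")
        sub.flow_ref = "ghost"
        doc = flow_doc(
            [RuleFlowNode("a", "Start"), sub, RuleFlowNode("e", "End")],
            [("a", "s"), ("s", "e")])
        reg = FlowRegistry()
        reg.register("f", doc)
        with pytest.raises(Exception, match="'ghost' is not registered"):
            FlowRunner(Engine(), reg).run("f")

    def test_subflows_load_lazily(self, sedation_registry):
        reg = sedation_registry()
        eng = Engine()
        eng.assert_fact(Fact("p", "patient", {
            "sedation_type": "short", "goal_rass": -2, "goal_rass_entered": True}))
        from guideflow.fixtures import NodeScriptHandler

        handler = NodeScriptHandler({
            "s07": [{"set": {"rass_entered": True, "current_rass": -2,
                             "sedation_end": True}}],
            "b06": [{"set": {"rass_entered": True, "current_rass": 0,
                             "extubation_ready": True}}],
            "q05": [{"set": {"rass_entered": True, "current_rass": -2,
                             "sedation_stopped": True}}],
        })
        runner = FlowRunner(eng, reg, handler=handler)
        runner.run("sedation-guideline", until=14 * 24 * 3600)
        assert reg.load_order[0] == "sedation-guideline"
        assert "normal-sedation-guideline" not in reg.load_order
        assert "short-sedation-guideline-a" in reg.load_order

    def test_identical_inputs_give_identical_traces(self, sedation_registry):
        import json

        from guideflow.fixtures import ScenarioHandler, make_patient_scenario

        outputs = []
        for _ in range(2):
            eng = Engine()
            scenario = make_patient_scenario(seed=42)
            clock = SimulatedClock()
            eng.assert_fact(Fact("p1", "patient", {
                **scenario.demographics(), "goal_rass": scenario.goal_rass,
                "goal_rass_entered": True}))
            runner = FlowRunner(eng, sedation_registry(),
                                handler=ScenarioHandler(scenario, clock),
                                clock=clock)
            runner.run("sedation-guideline", until=72 * 3600)
            outputs.append(json.dumps({"trace": runner.trace,
                                       "firings": eng.firing_log},
                                      sort_keys=True))
        assert outputs[0] == outputs[1]
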