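"""Production system and rule-flow executor.

The matcher is a Rete-style network built once from the loaded rule
definitions (*production memory*): one **alpha node** per distinct
``(fact type, literal constraints)`` pattern — shared between rules that use
the same pattern — each holding the memory of facts currently matching it,
joined per rule into terminal tokens.  Asserting, retracting or modifying a
fact (*working memory*) propagates incrementally: only tokens involving the
changed fact are recomputed, and after any sequence of operations the set of
complete tokens equals a naive cross-product match (:func:`naive_match`,
kept as the reference semantics and test oracle).

Matched tokens become **agenda** activations ordered by salience
(descending), then recency (descending), then rule id.  Refraction: an
activation fires at most once for the same facts unless a participating
fact is modified.  Firing a rule executes its consequence (assert / modify /
retract facts, emit a notification, signal the flow), which may cascade.

Flow execution is token-based traversal of a :class:`RuleFlowDocument` on a
simulated clock: splits route on their branch conditions (first definite
true in declared order, otherwise the default branch — an unknown outcome
also routes to default), merges pass tokens through (``any``) or wait for
all incoming branches (``all``), timers schedule continuations in simulated
seconds, work items issue tickets through the handler contract and block
their branch until completed, and sub-processes load the referenced flow
lazily on first entry.  Every node entry is traced with its simulated
timestamp, and every firing is logged with rule and bindings — the
explanation chain for a recommendation.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .ruleflow import ConditionExpression, RuleDefinition, RuleFlowDocument

__all__ = [
    "Fact",
    "FactError",
    "validate_rass",
    "Engine",
    "ReteNetwork",
    "naive_match",
    "SimulatedClock",
    "WallClock",
    "WorkItemTicket",
    "FlowRegistry",
    "ScriptedHandler",
    "FlowRunner",
    "EngineError",
    "RunawayError",
    "DeadlockError",
]

RASS_MIN, RASS_MAX = -5, 4
_RASS_ATTRS = ("current_rass", "goal_rass")


class EngineError(RuntimeError):
    pass


class FactError(EngineError):
    pass


class RunawayError(EngineError):
    def __init__(self, limit: int, tail: list[dict]) -> None:
        self.tail = tail
        super().__init__(
            f"firing limit {limit} exceeded; last firings: "
            + ", ".join(e["rule"] for e in tail)
        )


class DeadlockError(EngineError):
    def __init__(self, report: list[str]) -> None:
        self.report = report
        super().__init__("deadlock: " + "; ".join(report))


def validate_rass(value) -> int:
    """RASS scores are integers on the agitation-sedation scale [-5, 4]."""
    if isinstance(value, bool) or not isinstance(value, int):
        raise FactError(f"RASS score must be an integer, got {value!r}")
    if not RASS_MIN <= value <= RASS_MAX:
        raise FactError(f"RASS score {value} outside [{RASS_MIN}, {RASS_MAX}]")
    return value


@dataclass
class Fact:
    fact_id: str
    fact_type: str
    attributes: dict = field(default_factory=dict)
    version: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for attr in _RASS_ATTRS:
            if attr in self.attributes and self.attributes[attr] is not None:
                validate_rass(self.attributes[attr])


# ---------------------------------------------------------------------------
# Matching

_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "=": lambda a, b: a == b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


def _fact_matches_pattern(fact: Fact, pattern) -> bool:
    if fact.fact_type.casefold() != pattern.fact_type.casefold():
        return False
    for attr, op, value in pattern.constraints:
        if attr not in fact.attributes:
            return False
        try:
            if not _OPS[op](fact.attributes[attr], value):
                return False
        except TypeError:
            return False
    return True


def _token_env(rule: RuleDefinition, facts: Sequence[Fact]) -> dict:
    env: dict = {}
    for pattern, fact in zip(rule.patterns, facts):
        env.setdefault(pattern.fact_type.casefold(), fact.attributes)
        env[pattern.var.casefold()] = fact.attributes
    return env


def _token_ok(rule: RuleDefinition, facts: Sequence[Fact]) -> bool:
    if rule.condition is None:
        return True
    return rule.condition.evaluate(_token_env(rule, facts)) is True


def naive_match(rules: Iterable[RuleDefinition], facts: Iterable[Fact]) -> set[tuple]:
    """Reference matcher: exhaustively test every rule against every tuple of
    facts.  Returns ``{(rule_id, (fact_id, ...)), ...}`` — set semantics, so
    the result is independent of fact order."""
    facts = list(facts)
    out: set[tuple] = set()
    for rule in rules:
        pools = [
            [f for f in facts if _fact_matches_pattern(f, p)] for p in rule.patterns
        ]
        for combo in itertools.product(*pools):
            if len({f.fact_id for f in combo}) < len(combo):
                continue  # a fact binds at most one pattern per activation
            if _token_ok(rule, combo):
                out.add((rule.rule_id, tuple(f.fact_id for f in combo)))
    return out


class ReteNetwork:
    """Shared alpha memories plus per-rule join/terminal bookkeeping."""

    def __init__(self, rules: Sequence[RuleDefinition], known_fact_types: set[str] | None = None):
        self.rules = list(rules)
        seen = set()
        for rule in self.rules:
            if rule.rule_id in seen:
                raise EngineError(f"duplicate rule id {rule.rule_id!r}")
            seen.add(rule.rule_id)
            if known_fact_types is not None:
                for p in rule.patterns:
                    if p.fact_type.casefold() not in known_fact_types:
                        raise EngineError(
                            f"rule {rule.rule_id!r} references unknown fact type "
                            f"{p.fact_type!r}"
                        )
        # alpha nodes shared by (fact_type, constraints)
        self.alpha_keys: dict[tuple, int] = {}
        self.alpha_memory: list[set[str]] = []
        self.rule_alphas: dict[str, list[int]] = {}
        for rule in self.rules:
            idxs = []
            for pattern in rule.patterns:
                key = (pattern.fact_type.casefold(), tuple(pattern.constraints))
                if key not in self.alpha_keys:
                    self.alpha_keys[key] = len(self.alpha_memory)
                    self.alpha_memory.append(set())
                idxs.append(self.alpha_keys[key])
            self.rule_alphas[rule.rule_id] = idxs

    def stats(self) -> dict:
        """Network size: shared alpha nodes, per-rule beta joins, terminals."""
        n_alpha = len(self.alpha_memory)
        n_beta = sum(max(len(r.patterns) - 1, 0) for r in self.rules)
        n_term = len(self.rules)
        return {
            "alpha_nodes": n_alpha,
            "beta_nodes": n_beta,
            "terminal_nodes": n_term,
            "total_nodes": n_alpha + n_beta + n_term,
            "pattern_count": sum(len(r.patterns) for r in self.rules),
        }


@dataclass
class Activation:
    rule: RuleDefinition
    fact_ids: tuple
    recency: int

    @property
    def key(self) -> tuple:
        return (self.rule.rule_id, self.fact_ids)


@dataclass
class WorkItemTicket:
    ticket_id: str
    action: dict
    node_id: str = ""
    flow_id: str = ""
    issued_at: int = 0
    completed: bool = False
    payload: dict | None = None


class Engine:
    """Working memory + Rete network + salience agenda.

    ``load_production_memory`` builds the network; facts are then asserted
    into it (rules-then-facts load order, by convention).
    """

    def __init__(self) -> None:
        self.network: ReteNetwork | None = None
        self.facts: dict[str, Fact] = {}
        self.activations: dict[tuple, Activation] = {}
        self.fired: set[tuple] = set()
        self.firing_log: list[dict] = []
        self.notifications: list[dict] = []
        self.signals: list[dict] = []
        self._recency = 0
        self._next_fact = 0
        self.clock: "SimulatedClock | WallClock" = SimulatedClock()

    # -- production memory --------------------------------------------------

    def load_production_memory(
        self, rules: Sequence[RuleDefinition], known_fact_types: set[str] | None = None
    ) -> ReteNetwork:
        self.network = ReteNetwork(rules, known_fact_types)
        # (re)propagate existing working memory through the new network
        existing = list(self.facts.values())
        self.facts.clear()
        self.activations.clear()
        for fact in existing:
            self.assert_fact(fact)
        return self.network

    # -- working memory -----------------------------------------------------

    def new_fact_id(self) -> str:
        while True:
            self._next_fact += 1
            fid = f"f{self._next_fact}"
            if fid not in self.facts:
                return fid

    def assert_fact(self, fact: Fact) -> None:
        if self.network is None:
            self.network = ReteNetwork([])
        if fact.fact_id in self.facts:
            raise FactError(f"fact id {fact.fact_id!r} already asserted")
        fact.validate()
        self.facts[fact.fact_id] = fact
        for key, idx in self.network.alpha_keys.items():
            if _fact_matches_pattern(fact, _KeyPattern(*key)):
                self.network.alpha_memory[idx].add(fact.fact_id)
        self._recompute_for(fact.fact_id)

    def retract_fact(self, fact_id: str) -> None:
        if fact_id not in self.facts:
            raise FactError(f"cannot retract unknown fact {fact_id!r}")
        del self.facts[fact_id]
        for mem in self.network.alpha_memory:
            mem.discard(fact_id)
        for key in [k for k in self.activations if fact_id in k[1]]:
            del self.activations[key]

    def modify_fact(self, fact_id: str, updates: dict) -> None:
        fact = self.facts.get(fact_id)
        if fact is None:
            raise FactError(f"cannot modify unknown fact {fact_id!r}")
        fact.attributes.update(updates)
        fact.validate()
        fact.version += 1
        for key, idx in self.network.alpha_keys.items():
            mem = self.network.alpha_memory[idx]
            if _fact_matches_pattern(fact, _KeyPattern(*key)):
                mem.add(fact_id)
            else:
                mem.discard(fact_id)
        # drop stale activations involving the fact, then recompute
        for key in [k for k in self.activations if fact_id in k[1]]:
            del self.activations[key]
        self._recompute_for(fact_id)

    def _recompute_for(self, fact_id: str) -> None:
        """Re-derive activations whose token involves the given fact."""
        net = self.network
        for rule in net.rules:
            idxs = net.rule_alphas[rule.rule_id]
            if not idxs:
                self._add_activation(rule, ())
                continue
            memories = [net.alpha_memory[i] for i in idxs]
            if not any(fact_id in m for m in memories):
                continue
            for positions in itertools.product(*memories):
                if fact_id not in positions:
                    continue
                if len(set(positions)) < len(positions):
                    continue
                combo = [self.facts[fid] for fid in positions]
                if _token_ok(rule, combo):
                    self._add_activation(rule, tuple(positions))

    def _add_activation(self, rule: RuleDefinition, fact_ids: tuple) -> None:
        key = (rule.rule_id, fact_ids)
        if key not in self.activations:
            self._recency += 1
            self.activations[key] = Activation(rule, fact_ids, self._recency)

    def activation_set(self) -> set[tuple]:
        """Current matches as ``{(rule_id, fact_ids)}`` — comparable with
        :func:`naive_match`."""
        out = set(self.activations)
        if self.network is not None:
            # zero-pattern rules are permanently active
            for rule in self.network.rules:
                if not rule.patterns:
                    out.add((rule.rule_id, ()))
        return out

    # -- agenda / firing ----------------------------------------------------

    def _refraction_key(self, act: Activation) -> tuple:
        versions = tuple(self.facts[fid].version for fid in act.fact_ids)
        return (act.rule.rule_id, act.fact_ids, versions)

    def _next_activation(self) -> Activation | None:
        best = None
        for act in self.activations.values():
            if any(fid not in self.facts for fid in act.fact_ids):
                continue
            if self._refraction_key(act) in self.fired:
                continue
            rank = (-act.rule.salience, -act.recency, act.rule.rule_id)
            if best is None or rank < best[0]:
                best = (rank, act)
        return best[1] if best else None

    def fire_all(self, limit: int = 10_000) -> list[dict]:
        """Fire activations in agenda order until quiescence; returns the
        (cumulative) firing log.  ``limit`` guards against runaway loops."""
        if limit <= 0:
            raise EngineError("firing limit must be positive")
        fired_now = 0
        while True:
            act = self._next_activation()
            if act is None:
                return self.firing_log
            if fired_now >= limit:
                raise RunawayError(limit, self.firing_log[-20:])
            self.fired.add(self._refraction_key(act))
            entry = {
                "rule": act.rule.rule_id,
                "bindings": dict(zip((p.var for p in act.rule.patterns), act.fact_ids)),
                "time": self.clock.now,
                "salience": act.rule.salience,
            }
            self.firing_log.append(entry)
            fired_now += 1
            self._execute(act)

    def _execute(self, act: Activation) -> None:
        var_to_fact = dict(zip((p.var for p in act.rule.patterns), act.fact_ids))
        for action in act.rule.consequence:
            if "assert" in action:
                spec = action["assert"]
                self.assert_fact(
                    Fact(self.new_fact_id(), spec["fact_type"],
                         dict(spec.get("attributes", {})))
                )
            elif "modify" in action:
                spec = action["modify"]
                self.modify_fact(var_to_fact[spec["var"]], dict(spec.get("set", {})))
            elif "retract" in action:
                self.retract_fact(var_to_fact[action["retract"]])
            elif "notify" in action:
                payload = action["notify"]
                message = payload.get("message") if isinstance(payload, dict) else payload
                self.notifications.append(
                    {"message": message, "time": self.clock.now, "rule": act.rule.rule_id}
                )
            elif "signal" in action:
                self.signals.append(
                    {**action["signal"], "time": self.clock.now, "rule": act.rule.rule_id}
                )

    # -- convenience --------------------------------------------------------

    def facts_by_type(self) -> dict[str, dict]:
        """Latest fact attributes per (casefolded) fact type, for condition
        evaluation during flow traversal."""
        out: dict[str, dict] = {}
        for fact in self.facts.values():
            out[fact.fact_type.casefold()] = fact.attributes
        return out

    def singleton(self, fact_type: str) -> Fact | None:
        found = None
        for fact in self.facts.values():
            if fact.fact_type.casefold() == fact_type.casefold():
                found = fact
        return found


_DERIVE_STORE = None


def _derivation_vocabulary():
    """The packaged hospital vocabulary, loaded once, for derived-parameter
    rules executed by Action nodes."""
    global _DERIVE_STORE
    if _DERIVE_STORE is None:
        from importlib import resources

        from .mini_ontology import parse_ontology

        data = resources.files("guideflow") / "data"
        _DERIVE_STORE = parse_ontology((data / "hospital.onto").read_text(), "hospital")
    return _DERIVE_STORE


class _KeyPattern:
    __slots__ = ("fact_type", "constraints")

    def __init__(self, fact_type, constraints):
        self.fact_type = fact_type
        self.constraints = constraints


# ---------------------------------------------------------------------------
# Clocks

class SimulatedClock:
    """Integer simulated seconds; advanced by the flow runner."""

    def __init__(self, start: int = 0) -> None:
        self.now = start
        self.mode = "simulated"

    def advance_to(self, t: int) -> None:
        if t < self.now:
            raise EngineError(f"clock cannot go backwards ({t} < {self.now})")
        self.now = t


class WallClock:
    """Wall-clock variant of the same contract (untested for timing values)."""

    mode = "wall"

    @property
    def now(self) -> float:
        import time

        return time.time()

    def advance_to(self, t) -> None:  # real time advances itself
        pass


# ---------------------------------------------------------------------------
# Flow execution

class FlowRegistry:
    """Lazily loaded rule-flow documents, keyed by flow id.

    Flows are parsed only on first use (mirroring on-demand loading of the
    guideline variant actually in force); ``load_order`` records when each
    flow was materialized.
    """

    def __init__(self) -> None:
        self._sources: dict[str, Callable[[], RuleFlowDocument]] = {}
        self._loaded: dict[str, RuleFlowDocument] = {}
        self.load_order: list[str] = []

    def register(self, flow_id: str, source) -> None:
        """``source``: a RuleFlowDocument, XML text, a path, or a callable."""
        if isinstance(source, RuleFlowDocument):
            self._sources[flow_id] = lambda doc=source: doc
        elif callable(source):
            self._sources[flow_id] = source
        else:
            def _load(src=source):
                from .ruleflow import read_ruleflow

                text = src if isinstance(src, str) and src.lstrip().startswith("<") \
                    else open(src, "r", encoding="utf-8").read()
                return read_ruleflow(text)

            self._sources[flow_id] = _load

    def load(self, flow_id: str) -> RuleFlowDocument:
        if flow_id not in self._loaded:
            if flow_id not in self._sources:
                raise EngineError(f"referenced flow {flow_id!r} is not registered")
            self._loaded[flow_id] = self._sources[flow_id]()
            self.load_order.append(flow_id)
        return self._loaded[flow_id]

    def ids(self) -> list[str]:
        return sorted(self._sources)


class ScriptedHandler:
    """Work-item handler completing tickets from a scripted answer list.

    ``script`` is a list of payload dicts consumed in issue order; when the
    script is exhausted, ``default`` is used (``None`` leaves the ticket
    pending, blocking its branch).  Payload keys understood by the runner:
    ``{"set": {attr: value}}`` updates the patient fact; ``{"fact_type": t,
    "attributes": {...}}`` asserts a new fact; ``{"after": seconds}`` delays
    the completion.
    """

    def __init__(self, script: Sequence[dict] = (), default: dict | None = None) -> None:
        self.script = list(script)
        self.default = default
        self.issued: list[WorkItemTicket] = []

    def issue(self, ticket: WorkItemTicket) -> dict | None:
        self.issued.append(ticket)
        if self.script:
            return self.script.pop(0)
        return dict(self.default) if self.default is not None else None


@dataclass
class _FlowInstance:
    instance_id: int
    doc: RuleFlowDocument
    parent: tuple | None = None  # (instance, node_id) to resume on completion
    join_arrivals: dict = field(default_factory=dict)
    done: bool = False


class FlowRunner:
    """Executes rule flows on an engine and a simulated clock."""

    def __init__(
        self,
        engine: Engine,
        registry: FlowRegistry,
        handler=None,
        clock: SimulatedClock | None = None,
    ) -> None:
        self.engine = engine
        self.registry = registry
        self.handler = handler or ScriptedHandler()
        self.clock = clock or SimulatedClock()
        engine.clock = self.clock
        self.trace: list[dict] = []
        self.tickets: dict[str, WorkItemTicket] = {}
        self._pending: dict[str, tuple] = {}  # ticket -> (instance, node_id)
        self._queue: list[tuple] = []  # (time, seq, instance, node_id)
        self._seq = 0
        self._instances = 0

    # -- public -------------------------------------------------------------

    def run(self, flow_id: str, until: int | None = None, max_steps: int = 100_000) -> list[dict]:
        """Run a flow to completion (or to the simulated horizon ``until``).

        Returns the trace: one record per node entry with simulated time.
        Raises :class:`DeadlockError` when no branch can advance and no
        event is pending, and :class:`RunawayError` past ``max_steps``.
        """
        doc = self.registry.load(flow_id)
        instance = self._new_instance(doc)
        start = [n for n in doc.nodes.values() if n.kind == "Start"]
        if len(start) != 1:
            raise EngineError(f"flow {flow_id!r} must have exactly one Start node")
        self._schedule(self.clock.now, instance, start[0].node_id)
        return self.resume(until=until, max_steps=max_steps)

    def resume(self, until: int | None = None, max_steps: int = 100_000) -> list[dict]:
        """Drain the event queue (e.g. after :meth:`complete_ticket`)."""
        steps = 0
        while self._queue:
            t, _, instance, node_id = heapq.heappop(self._queue)
            if until is not None and t > until:
                return self.trace  # horizon reached; drop later events
            steps += 1
            if steps > max_steps:
                raise RunawayError(max_steps, self.trace[-20:])
            self.clock.advance_to(t)
            self._enter(instance, node_id)
        if self._pending:
            blocked = [
                f"work item {tid} at node {self._pending[tid][1]!r}"
                for tid in sorted(self._pending)
            ]
            raise DeadlockError(["no runnable branch"] + blocked)
        return self.trace

    def complete_ticket(self, ticket_id: str, payload: dict | None = None) -> None:
        ticket = self.tickets.get(ticket_id)
        if ticket is None or ticket.completed:
            raise EngineError(f"unknown or already-completed ticket {ticket_id!r}")
        ticket.completed = True
        ticket.payload = payload
        self._apply_payload(payload)
        instance, node_id = self._pending.pop(ticket_id)
        self._schedule(self.clock.now, instance, node_id, after=True)

    # -- internals ----------------------------------------------------------

    def _new_instance(self, doc: RuleFlowDocument, parent=None) -> _FlowInstance:
        self._instances += 1
        return _FlowInstance(self._instances, doc, parent)

    def _schedule(self, t: int, instance: _FlowInstance, node_id: str, after: bool = False) -> None:
        self._seq += 1
        key = ("after:" + node_id) if after else node_id
        heapq.heappush(self._queue, (t, self._seq, instance, key))

    def _record(self, instance: _FlowInstance, node_id: str, event: str, **extra) -> None:
        self.trace.append(
            {
                "time": self.clock.now,
                "flow": instance.doc.flow_id,
                "instance": instance.instance_id,
                "node": node_id,
                "event": event,
                **extra,
            }
        )

    def _successors(self, instance: _FlowInstance, node_id: str) -> list[str]:
        return instance.doc.outgoing(node_id)

    def _proceed(self, instance: _FlowInstance, node_id: str) -> None:
        for nxt in self._successors(instance, node_id):
            self._schedule(self.clock.now, instance, nxt)

    def _enter(self, instance: _FlowInstance, node_id: str) -> None:
        if node_id.startswith("after:"):
            real = node_id[len("after:"):]
            self._record(instance, real, "resume")
            node = instance.doc.nodes.get(real)
            if node is not None and node.kind == "Timer" and node.period:
                # periodic timers re-arm on each firing: the k-th event fires
                # at exactly t0 + k*period (integer simulated seconds)
                self._schedule(self.clock.now + node.period, instance, real, after=True)
            self._proceed(instance, real)
            return
        node = instance.doc.nodes.get(node_id)
        if node is None:
            raise EngineError(
                f"flow {instance.doc.flow_id!r}: edge to unknown node {node_id!r}"
            )
        self._record(instance, node_id, "enter")

        if node.kind in ("Start",):
            self._proceed(instance, node_id)
        elif node.kind == "End":
            instance.done = True
            if instance.parent is not None:
                parent, parent_node = instance.parent
                self._record(parent, parent_node, "subflow-complete",
                             subflow=instance.doc.flow_id)
                self._schedule(self.clock.now, parent, parent_node, after=True)
        elif node.kind == "Split":
            facts = self.engine.facts_by_type()
            target = node.default_to
            for branch_target, expr in node.branches:
                if expr.evaluate(facts) is True:
                    target = branch_target
                    break
            self._record(instance, node_id, "route", target=target)
            self._schedule(self.clock.now, instance, target)
        elif node.kind == "Join":
            if node.mode == "any":
                self._proceed(instance, node_id)
            else:
                seen = instance.join_arrivals.setdefault(node_id, 0) + 1
                instance.join_arrivals[node_id] = seen
                if seen >= len(instance.doc.incoming(node_id)):
                    instance.join_arrivals[node_id] = 0
                    self._proceed(instance, node_id)
        elif node.kind == "Timer":
            due = self.clock.now + (node.delay or 0)
            self._record(instance, node_id, "timer-armed", due=due)
            self._schedule(due, instance, node_id, after=True)
        elif node.kind == "WorkItem":
            ticket = WorkItemTicket(
                ticket_id=f"t{len(self.tickets) + 1}",
                action=node.action or {},
                node_id=node_id,
                flow_id=instance.doc.flow_id,
                issued_at=self.clock.now,
            )
            self.tickets[ticket.ticket_id] = ticket
            self._pending[ticket.ticket_id] = (instance, node_id)
            self._record(instance, node_id, "workitem-issued", ticket=ticket.ticket_id)
            payload = self.handler.issue(ticket)
            if payload is not None:
                delay = payload.get("after", 0)
                ticket.completed = True
                ticket.payload = payload
                del self._pending[ticket.ticket_id]
                if delay:
                    self._schedule(self.clock.now + delay, instance, node_id, after=True)
                    self._apply_payload(payload)
                else:
                    self._apply_payload(payload)
                    self._schedule(self.clock.now, instance, node_id, after=True)
        elif node.kind == "SubProcess":
            child_doc = self.registry.load(node.flow_ref)
            child = self._new_instance(child_doc, parent=(instance, node_id))
            starts = [n for n in child_doc.nodes.values() if n.kind == "Start"]
            self._record(instance, node_id, "subflow-start", subflow=node.flow_ref)
            self._schedule(self.clock.now, child, starts[0].node_id)
        elif node.kind == "Action":
            self._apply_updates(node.updates)
            self.engine.fire_all()
            self._proceed(instance, node_id)
        else:
            raise EngineError(f"node kind {node.kind!r} not executable")

    def _apply_payload(self, payload: dict | None) -> None:
        if not payload:
            return
        if "fact_type" in payload:
            self.engine.assert_fact(
                Fact(self.engine.new_fact_id(), payload["fact_type"],
                     dict(payload.get("attributes", {})))
            )
        if "set" in payload:
            target = payload.get("target_type", "patient")
            fact = self.engine.singleton(target)
            if fact is None:
                self.engine.assert_fact(
                    Fact(self.engine.new_fact_id(), target, dict(payload["set"]))
                )
            else:
                self.engine.modify_fact(fact.fact_id, dict(payload["set"]))
        self.engine.fire_all()

    def _apply_updates(self, updates: list[dict]) -> None:
        for upd in updates:
            if "derive" in upd:
                self._derive(upd["derive"])
            elif "set" in upd:
                target = upd.get("target_type", "patient")
                fact = self.engine.singleton(target)
                if fact is None:
                    self.engine.assert_fact(
                        Fact(self.engine.new_fact_id(), target,
                             {upd["set"]: upd["value"]})
                    )
                else:
                    self.engine.modify_fact(fact.fact_id, {upd["set"]: upd["value"]})

    def _derive(self, prop: str) -> None:
        """Evaluate a derived-parameter ontology rule (e.g. BMI) against the
        patient fact and write the result back as a fact attribute."""
        import copy

        fact = self.engine.singleton("patient")
        if fact is None:
            return
        store = copy.deepcopy(_derivation_vocabulary())
        store.add_individual("p", ["Patient"])
        for attr, value in fact.attributes.items():
            cand = "has" + attr.capitalize()
            for known in store.properties:
                if known.casefold() == cand.casefold() and isinstance(value, (int, float)):
                    store.set_value("p", known, value)
        store.eval_rules()
        values = store.individuals["p"].values(prop)
        if values:
            stem = prop[3:].casefold() if prop.startswith("has") else prop.casefold()
            self.engine.modify_fact(fact.fact_id, {stem: values[-1]})
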