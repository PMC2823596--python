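"""Executable rule flows: post-processing, XML serialization, validation.

The post-processor turns a completed intermediate model into a
:class:`RuleFlowDocument` — a flow-chart-shaped orchestration of typed nodes
(Start, End, Split, Join, Timer, WorkItem, SubProcess, Action) — plus the
:class:`RuleDefinition` production rules generated for its decision
branches.  The mapping is kind for kind; branch guard texts are compiled to
:class:`ConditionExpression` trees, and every split is given an explicit
default branch (a guard-less outgoing edge; if a chart has none, the last
declared branch is demoted to default with a logged warning, so that every
"if" is accompanied by an "else").

Rule-flow XML is the package's own documented schema and round-trips
losslessly; elements are written in sorted order for diff-ability.
Durations appear in the XML as ISO-8601-style strings (``PT4H``) and are
integer seconds internally.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Iterable

__all__ = [
    "ConditionExpression",
    "ExpressionError",
    "RuleFlowNode",
    "RuleDefinition",
    "Pattern",
    "RuleFlowDocument",
    "RuleFlowError",
    "postprocess",
    "write_ruleflow",
    "read_ruleflow",
    "validate_ruleflow",
    "parse_duration",
    "format_duration",
]


class RuleFlowError(ValueError):
    pass


class ExpressionError(RuleFlowError):
    pass


# ---------------------------------------------------------------------------
# Durations

_ISO_RE = re.compile(r"PT(?:(\d+)H)?(?:(\d+)M)?(?:(\d+)S)?$", re.IGNORECASE)
_TEXT_RE = re.compile(
    r"(\d+)\s*(hours?|hrs?|h|minutes?|mins?|m|seconds?|secs?|s)\b", re.IGNORECASE
)
_UNIT_SECONDS = {"h": 3600, "m": 60, "s": 1}


def parse_duration(text: str) -> int:
    """Parse ``PT4H`` / ``4 hours`` / ``90 min`` style durations to seconds."""
    text = text.strip()
    m = _ISO_RE.fullmatch(text)
    if m:
        h, mi, s = (int(g) if g else 0 for g in m.groups())
        return h * 3600 + mi * 60 + s
    total = 0
    for num, unit in _TEXT_RE.findall(text):
        total += int(num) * _UNIT_SECONDS[unit[0].lower()]
    if total == 0:
        raise RuleFlowError(f"cannot parse duration from {text!r}")
    return total


def format_duration(seconds: int) -> str:
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    out = "PT"
    if h:
        out += f"{h}H"
    if m:
        out += f"{m}M"
    if s or not (h or m):
        out += f"{s}S"
    return out


# ---------------------------------------------------------------------------
# Condition expressions
#
# Grammar (three-valued: a comparison over a missing fact or attribute
# evaluates to "unknown", and a branch is taken only on a definite true):
#
#   expr    := term ("or" term)*
#   term    := factor ("and" factor)*
#   factor  := "not" factor | "(" expr ")" | comparison
#   compare := operand ("<"|"<="|"="|"!="|">="|">") operand
#   operand := IDENT ("." IDENT)? | NUMBER | STRING | "true" | "false"

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>-?\d+(?:\.\d+)?)|(?P<str>'[^']*'|\"[^\"]*\")"
    r"|(?P<op><=|>=|!=|=|<|>|\(|\))|(?P<word>[A-Za-z_][\w.]*))"
)


@dataclass(frozen=True)
class _Cmp:
    left: object
    op: str
    right: object


@dataclass(frozen=True)
class _Bool:
    op: str  # "and" | "or" | "not"
    args: tuple


@dataclass(frozen=True)
class ConditionExpression:
    """A parsed boolean condition over fact attributes.

    ``evaluate`` takes a mapping of fact-type name (casefolded) to an
    attribute mapping and returns ``True``, ``False`` or ``None`` (unknown —
    some referenced fact or attribute is absent).
    """

    text: str
    root: object = field(compare=False, default=None)

    @classmethod
    def parse(cls, text: str) -> "ConditionExpression":
        tokens = _tokenize(text)
        parser = _Parser(tokens, text)
        root = parser.expr()
        if parser.pos != len(tokens):
            raise ExpressionError(f"trailing tokens in condition {text!r}")
        return cls(text=text, root=root)

    def evaluate(self, facts: dict) -> bool | None:
        return _eval(self.root, facts)

    def referenced_fact_types(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            if isinstance(node, _Bool):
                for a in node.args:
                    walk(a)
            elif isinstance(node, _Cmp):
                for side in (node.left, node.right):
                    if isinstance(side, tuple) and side[0] == "ref" and side[1] not in out:
                        out.append(side[1])

        walk(self.root)
        return out


def _tokenize(text: str) -> list[tuple[str, object]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ExpressionError(f"bad token at {text[pos:]!r} in condition {text!r}")
            break
        pos = m.end()
        if m.group("num"):
            num = m.group("num")
            tokens.append(("lit", float(num) if "." in num else int(num)))
        elif m.group("str"):
            tokens.append(("lit", m.group("str")[1:-1]))
        elif m.group("op"):
            tokens.append(("op", m.group("op")))
        else:
            word = m.group("word")
            low = word.lower()
            if low in ("and", "or", "not"):
                tokens.append(("kw", low))
            elif low == "true":
                tokens.append(("lit", True))
            elif low == "false":
                tokens.append(("lit", False))
            else:
                tokens.append(("word", word))
    return tokens


class _Parser:
    def __init__(self, tokens, text):
        self.tokens = tokens
        self.text = text
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expr(self):
        node = self.term()
        while self.peek() == ("kw", "or"):
            self.take()
            node = _Bool("or", (node, self.term()))
        return node

    def term(self):
        node = self.factor()
        while self.peek() == ("kw", "and"):
            self.take()
            node = _Bool("and", (node, self.factor()))
        return node

    def factor(self):
        kind, val = self.peek()
        if (kind, val) == ("kw", "not"):
            self.take()
            return _Bool("not", (self.factor(),))
        if (kind, val) == ("op", "("):
            self.take()
            node = self.expr()
            if self.take() != ("op", ")"):
                raise ExpressionError(f"missing ')' in condition {self.text!r}")
            return node
        return self.comparison()

    def operand(self):
        kind, val = self.take()
        if kind == "lit":
            return ("lit", val)
        if kind == "word":
            if "." in val:
                fact_type, attr = val.split(".", 1)
                return ("ref", fact_type.casefold(), attr)
            return ("ref", None, val)  # unqualified: attribute on any fact
        raise ExpressionError(f"expected operand in condition {self.text!r}, got {val!r}")

    def comparison(self):
        left = self.operand()
        kind, op = self.take()
        if kind != "op" or op in ("(", ")"):
            raise ExpressionError(f"expected comparison operator in {self.text!r}")
        right = self.operand()
        return _Cmp(left, op, right)


_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "=": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


def _resolve(side, facts):
    if side[0] == "lit":
        return side[1], True
    _, fact_type, attr = side
    if fact_type is None:
        for attrs in facts.values():
            if attr in attrs:
                return attrs[attr], True
        return None, False
    attrs = facts.get(fact_type)
    if attrs is None or attr not in attrs:
        return None, False
    return attrs[attr], True


def _eval(node, facts) -> bool | None:
    if isinstance(node, _Cmp):
        left, ok_l = _resolve(node.left, facts)
        right, ok_r = _resolve(node.right, facts)
        if not (ok_l and ok_r):
            return None
        try:
            return bool(_OPS[node.op](left, right))
        except TypeError:
            return None
    if node.op == "not":
        inner = _eval(node.args[0], facts)
        return None if inner is None else not inner
    vals = [_eval(a, facts) for a in node.args]
    if node.op == "and":
        if any(v is False for v in vals):
            return False
        return None if any(v is None for v in vals) else True
    if any(v is True for v in vals):
        return True
    return None if any(v is None for v in vals) else False


# ---------------------------------------------------------------------------
# Rule flows

VALID_KINDS = ("Start", "End", "Split", "Join", "Loop", "Timer",
               "WorkItem", "SubProcess", "Action")


@dataclass
class RuleFlowNode:
    node_id: str
    kind: str
    # Split
    branches: list[tuple[str, ConditionExpression]] = field(default_factory=list)
    default_to: str | None = None
    # Join
    mode: str = "any"  # "any" = XOR merge, "all" = wait-for-all
    # Timer
    delay: int | None = None
    period: int | None = None
    # WorkItem
    action: dict | None = None
    blocking: bool = True
    # SubProcess
    flow_ref: str | None = None
    # Action
    updates: list[dict] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise RuleFlowError(f"unknown node kind {self.kind!r}")


@dataclass(frozen=True)
class Pattern:
    var: str
    fact_type: str
    constraints: tuple = ()  # (attr, op, literal) triples


@dataclass
class RuleDefinition:
    rule_id: str
    patterns: list[Pattern]
    consequence: list[dict]
    salience: int = 0
    condition: ConditionExpression | None = None

    def __post_init__(self) -> None:
        bound = {p.var for p in self.patterns}
        for action in self.consequence:
            target = action.get("modify", {}).get("var") or action.get("retract")
            if target and target not in bound:
                raise RuleFlowError(
                    f"rule {self.rule_id}: consequence references unbound {target!r}"
                )


@dataclass
class RuleFlowDocument:
    flow_id: str
    nodes: dict[str, RuleFlowNode] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)
    rules: list[RuleDefinition] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def add_node(self, node: RuleFlowNode) -> None:
        if node.node_id in self.nodes:
            raise RuleFlowError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node

    def outgoing(self, node_id: str) -> list[str]:
        return [t for f, t in self.edges if f == node_id]

    def incoming(self, node_id: str) -> list[str]:
        return [f for f, t in self.edges if t == node_id]


# ---------------------------------------------------------------------------
# Post-processing

def postprocess(model) -> tuple[RuleFlowDocument, list[RuleDefinition]]:
    """Compile an intermediate model into a rule-flow document plus the rule
    definitions generated for its split branches.

    Pure: the same model always compiles to byte-identical XML.  Raises on
    unparseable guards and on structural violations (reported by
    :func:`validate_ruleflow`).
    """
    flow_id = model.source_name or "flow"
    doc = RuleFlowDocument(flow_id=flow_id)
    warnings: list[str] = []

    for construct in model.nodes():
        kind = construct.kind
        attrs = construct.attrs
        node = RuleFlowNode(node_id=construct.construct_id,
                            kind={"TimeHandler": "Timer"}.get(kind, kind),
                            name=attrs.get("name", ""))
        if node.kind == "Timer":
            text = attrs.get("schedule_text") or attrs.get("name") or ""
            try:
                seconds = parse_duration(text)
            except RuleFlowError as exc:
                raise RuleFlowError(
                    f"{flow_id}: timer {construct.construct_id!r}: {exc}"
                ) from None
            node.delay = seconds
            if "every" in text.lower() or attrs.get("periodic"):
                node.period = seconds
        elif node.kind == "Join":
            node.mode = "all" if attrs.get("source_type") == "JoinNode" else "any"
        elif node.kind == "WorkItem":
            node.action = attrs.get("action") or {"text": attrs.get("name", "")}
            node.blocking = True
        elif node.kind == "SubProcess":
            node.flow_ref = attrs.get("flow_ref")
        elif node.kind == "Action":
            node.updates = list(attrs.get("updates", []))
            if attrs.get("action"):
                node.action = attrs["action"]
        doc.add_node(node)

    # connections; split branches keep declared (document) order
    for conn in model.connections():
        doc.edges.append((conn.attrs["from"], conn.attrs["to"]))

    for conn in model.connections():
        src = doc.nodes.get(conn.attrs["from"])
        if src is None or src.kind != "Split":
            continue
        guard = conn.attrs.get("guard")
        if guard is None or guard.strip().lower() == "default":
            if src.default_to is not None:
                raise RuleFlowError(
                    f"{flow_id}: split {src.node_id!r} has two default branches"
                )
            src.default_to = conn.attrs["to"]
        else:
            try:
                expr = ConditionExpression.parse(guard)
            except ExpressionError as exc:
                raise RuleFlowError(
                    f"{flow_id}: split {src.node_id!r}: cannot compile guard "
                    f"{guard!r}: {exc}"
                ) from None
            src.branches.append((conn.attrs["to"], expr))

    for node in doc.nodes.values():
        if node.kind == "Split" and node.default_to is None and node.branches:
            target, _ = node.branches.pop()  # demote last declared branch
            node.default_to = target
            warnings.append(
                f"split {node.node_id!r} had no default branch; "
                f"last branch to {target!r} demoted to default"
            )
    doc.metadata["warnings"] = warnings

    rules = _generate_rules(doc)
    doc.rules = rules

    report = validate_ruleflow(doc)
    if report:
        raise RuleFlowError(f"{flow_id}: structural validation failed: " + "; ".join(report))
    return doc, rules


def _generate_rules(doc: RuleFlowDocument) -> list[RuleDefinition]:
    """One production rule per split branch: its patterns bind the fact types
    the guard references, the guard is the join condition, and the
    consequence signals the flow which branch was selected.  Salience follows
    declared branch order (earlier branches win)."""
    rules: list[RuleDefinition] = []
    for node_id in sorted(doc.nodes):
        node = doc.nodes[node_id]
        if node.kind != "Split":
            continue
        n = len(node.branches)
        for i, (target, expr) in enumerate(node.branches):
            fact_types = expr.referenced_fact_types() or ["fact"]
            rules.append(
                RuleDefinition(
                    rule_id=f"{doc.flow_id}/{node_id}/branch-{i}",
                    patterns=[Pattern(var=ft, fact_type=ft) for ft in fact_types],
                    condition=expr,
                    consequence=[
                        {"signal": {"flow": doc.flow_id, "node": node_id, "branch": target}}
                    ],
                    salience=(n - i) * 10,
                )
            )
        rules.append(
            RuleDefinition(
                rule_id=f"{doc.flow_id}/{node_id}/default",
                patterns=[],
                condition=None,
                consequence=[
                    {"signal": {"flow": doc.flow_id, "node": node_id,
                                "branch": node.default_to}}
                ],
                salience=0,
            )
        )
    return rules


# ---------------------------------------------------------------------------
# XML serialization

def write_ruleflow(doc: RuleFlowDocument) -> str:
    root = ET.Element("RuleFlow", {"id": doc.flow_id})
    nodes_el = ET.SubElement(root, "Nodes")
    for node_id in sorted(doc.nodes):
        node = doc.nodes[node_id]
        attrs = {"id": node.node_id, "kind": node.kind}
        if node.name:
            attrs["name"] = node.name
        if node.kind == "Split" and node.default_to:
            attrs["default"] = node.default_to
        if node.kind == "Join":
            attrs["mode"] = node.mode
        if node.kind == "Timer":
            attrs["delay"] = format_duration(node.delay or 0)
            if node.period is not None:
                attrs["period"] = format_duration(node.period)
        if node.kind == "WorkItem":
            attrs["blocking"] = "true" if node.blocking else "false"
        if node.kind == "SubProcess" and node.flow_ref:
            attrs["flowRef"] = node.flow_ref
        el = ET.SubElement(nodes_el, "Node", attrs)
        for target, expr in node.branches:
            ET.SubElement(el, "Branch", {"to": target, "guard": expr.text})
        if node.action is not None:
            act = ET.SubElement(el, "ActionSpec", {"text": node.action.get("text", "")})
            if node.action.get("action_class"):
                act.set("actionClass", node.action["action_class"])
            for med in node.action.get("medications", []):
                ET.SubElement(act, "Medication", {"name": med})
            for obs in node.action.get("observations", []):
                ET.SubElement(act, "Observation", {"name": obs})
            for der in node.action.get("derives", []):
                ET.SubElement(act, "Derive", {"property": der})
        for upd in node.updates:
            if "derive" in upd:
                ET.SubElement(el, "Update", {"derive": upd["derive"]})
            else:
                ET.SubElement(el, "Update",
                              {"set": upd["set"], "value": repr(upd["value"])})
    edges_el = ET.SubElement(root, "Edges")
    for f, t in sorted(doc.edges):
        ET.SubElement(edges_el, "Edge", {"from": f, "to": t})
    rules_el = ET.SubElement(root, "Rules")
    for rule in sorted(doc.rules, key=lambda r: r.rule_id):
        r_el = ET.SubElement(rules_el, "Rule",
                             {"id": rule.rule_id, "salience": str(rule.salience)})
        for pat in rule.patterns:
            p_el = ET.SubElement(r_el, "Pattern",
                                 {"var": pat.var, "factType": pat.fact_type})
            for attr, op, value in pat.constraints:
                ET.SubElement(p_el, "Constraint",
                              {"attr": attr, "op": op, "value": repr(value)})
        if rule.condition is not None:
            ET.SubElement(r_el, "Condition").text = rule.condition.text
        cons = ET.SubElement(r_el, "Consequence")
        for action in rule.consequence:
            for key, payload in action.items():
                a_el = ET.SubElement(cons, key.capitalize())
                if isinstance(payload, dict):
                    for k, v in sorted(payload.items()):
                        a_el.set(k, str(v))
                else:
                    a_el.set("value", str(payload))
    buf = io.BytesIO()
    ET.indent(ET.ElementTree(root))
    ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
    return buf.getvalue().decode("utf-8")


def _read_literal(text: str):
    try:
        import ast

        return ast.literal_eval(text)
    except (ValueError, SyntaxError):
        return text


def read_ruleflow(xml_text: str) -> RuleFlowDocument:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise RuleFlowError(f"malformed rule-flow XML: {exc}") from exc
    if root.tag != "RuleFlow" or "id" not in root.attrib:
        raise RuleFlowError("root element must be <RuleFlow id=...>")
    doc = RuleFlowDocument(flow_id=root.get("id"))
    for el in root.findall("./Nodes/Node"):
        for req in ("id", "kind"):
            if req not in el.attrib:
                raise RuleFlowError(f"Node missing {req!r} at Nodes/Node")
        node = RuleFlowNode(node_id=el.get("id"), kind=el.get("kind"),
                            name=el.get("name", ""))
        node.default_to = el.get("default")
        node.mode = el.get("mode", "any")
        if el.get("delay"):
            node.delay = parse_duration(el.get("delay"))
        if el.get("period"):
            node.period = parse_duration(el.get("period"))
        node.blocking = el.get("blocking", "true") == "true"
        node.flow_ref = el.get("flowRef")
        for b in el.findall("Branch"):
            node.branches.append((b.get("to"), ConditionExpression.parse(b.get("guard"))))
        act = el.find("ActionSpec")
        if act is not None:
            node.action = {
                "text": act.get("text", ""),
                "action_class": act.get("actionClass"),
                "medications": [m.get("name") for m in act.findall("Medication")],
                "observations": [o.get("name") for o in act.findall("Observation")],
                "derives": [d.get("property") for d in act.findall("Derive")],
            }
        for upd in el.findall("Update"):
            if upd.get("derive"):
                node.updates.append({"derive": upd.get("derive")})
            else:
                node.updates.append(
                    {"set": upd.get("set"), "value": _read_literal(upd.get("value"))}
                )
        doc.add_node(node)
    for el in root.findall("./Edges/Edge"):
        doc.edges.append((el.get("from"), el.get("to")))
    for el in root.findall("./Rules/Rule"):
        patterns = [
            Pattern(
                var=p.get("var"),
                fact_type=p.get("factType"),
                constraints=tuple(
                    (c.get("attr"), c.get("op"), _read_literal(c.get("value")))
                    for c in p.findall("Constraint")
                ),
            )
            for p in el.findall("Pattern")
        ]
        cond_el = el.find("Condition")
        consequence = []
        cons_el = el.find("Consequence")
        if cons_el is not None:
            for a_el in cons_el:
                key = a_el.tag.lower()
                attrs = dict(a_el.attrib)
                consequence.append({key: attrs if attrs else a_el.get("value")})
        doc.rules.append(
            RuleDefinition(
                rule_id=el.get("id"),
                patterns=patterns,
                condition=ConditionExpression.parse(cond_el.text) if cond_el is not None else None,
                consequence=consequence,
                salience=int(el.get("salience", "0")),
            )
        )
    return doc


# ---------------------------------------------------------------------------
# Validation

def validate_ruleflow(doc: RuleFlowDocument) -> list[str]:
    """Structural report: empty iff the document satisfies the node
    invariants.  Report-only — never raises."""
    report: list[str] = []
    starts = [n for n in doc.nodes.values() if n.kind == "Start"]
    if len(starts) != 1:
        report.append(f"expected exactly one Start node, found {len(starts)}")
    node_ids = set(doc.nodes)
    for f, t in doc.edges:
        for end in (f, t):
            if end not in node_ids:
                report.append(f"edge ({f!r}, {t!r}) references unknown node {end!r}")
    for node in doc.nodes.values():
        out = doc.outgoing(node.node_id)
        if node.kind != "End" and not out:
            report.append(f"non-End node {node.node_id!r} has no outgoing edge")
        if node.kind == "Split":
            if node.default_to is None:
                report.append(f"split {node.node_id!r} has no default branch")
            for target, _ in node.branches:
                if target not in node_ids:
                    report.append(
                        f"split {node.node_id!r} branch targets unknown node {target!r}"
                    )
        if node.kind == "Timer":
            if node.delay is None or node.delay < 0:
                report.append(f"timer {node.node_id!r} has no (or negative) delay")
            if node.period is not None and node.period <= 0:
                report.append(f"timer {node.node_id!r} has non-positive period")
    if starts and len(starts) == 1:
        reachable = _reachable(doc, starts[0].node_id)
        for missing in sorted(node_ids - reachable):
            report.append(f"node {missing!r} unreachable from Start")
    return report


def _reachable(doc: RuleFlowDocument, start: str) -> set[str]:
    seen, stack = {start}, [start]
    while stack:
        for nxt in doc.outgoing(stack.pop()):
            if nxt in doc.nodes and nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def canonicalize(doc: RuleFlowDocument) -> RuleFlowDocument:
    """Sorted-copy used to compare documents independent of insertion order."""
    out = RuleFlowDocument(flow_id=doc.flow_id, metadata=dict(doc.metadata))
    for node_id in sorted(doc.nodes):
        out.nodes[node_id] = replace(doc.nodes[node_id])
    out.edges = sorted(doc.edges)
    out.rules = sorted(doc.rules, key=lambda r: r.rule_id)
    return out
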