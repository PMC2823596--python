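"""A small ontology store: taxonomy, properties, individuals and rules.

The translator reasons over two kinds of knowledge: a *diagram ontology*
describing flow-chart symbol types and the intermediate-language constructs
they map to, and a *hospital vocabulary* (medication taxonomy, action
classes, patient attributes).  Full description-logic reasoning is not
needed for that: the fragment implemented here is named classes with
subclass axioms, object/datatype properties with cardinality bounds,
individuals, a synonym table, and Horn rules with builtin predicates —
exactly the expressivity the translation uses.

Ontology definition files (``.onto``) are a documented line-based text
format::

    class Morphine < Medication
    class "Morphine IV [10mg/1ml]" < Morphine
    property hasStereoType : datatype UMLSymbol -> string
    connections Start in 0 0 out 1 -
    individual ID16 : ActivityAction
      hasStereoType = "wait"
    synonym midazolam = Dormicum
    rule stereo-wait: ActivityAction(?x), hasStereoType(?x, ?y), \
        stringEqualIgnoreCase(?y, "wait") -> TimeHandler(?x)

Rule atoms are class atoms ``C(?x)``, property atoms ``p(?x, ?y)``, the
builtins ``stringEqualIgnoreCase``, ``multiply`` and ``divide`` (the first
argument of an arithmetic builtin is bound to the result when unbound,
otherwise tested to 1e-9), and the no-value atom written ``noValue(p, ?x)``
or in the ``(p = 0)(?x)`` notation, which matches individuals carrying no
value for ``p``.  No-value atoms are negation as failure and are evaluated
in a second stratum: a rule base in which some rule head asserts a property
that another rule reads through ``noValue`` is rejected as unstratified.

Forward chaining runs to fixpoint; with a stratified rule base and finitely
many individuals the fixpoint is finite and independent of rule order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "OntoClass",
    "OntoProperty",
    "Individual",
    "OntoRule",
    "Atom",
    "OntologyStore",
    "OntologyError",
    "load_ontology",
    "parse_rule",
]

NUMERIC_TOL = 1e-9


class OntologyError(ValueError):
    """Raised for unknown names, cycles, parse errors and unstratified rules."""


@dataclass
class OntoClass:
    name: str
    parents: set[str] = field(default_factory=set)
    changed_flag: bool = False  # set for expert-added vocabulary


@dataclass
class OntoProperty:
    name: str
    kind: str = "datatype"  # "object" | "datatype"
    domain: str | None = None
    range: str | None = None
    min_in: int | None = None
    max_in: int | None = None
    min_out: int | None = None
    max_out: int | None = None

    def __post_init__(self) -> None:
        for lo, hi in ((self.min_in, self.max_in), (self.min_out, self.max_out)):
            if lo is not None and hi is not None and lo > hi:
                raise OntologyError(f"property {self.name}: min > max cardinality")


@dataclass
class Individual:
    name: str
    asserted_classes: set[str] = field(default_factory=set)
    property_values: dict[str, list] = field(default_factory=dict)

    def values(self, prop: str) -> list:
        return self.property_values.get(prop, [])


# ---------------------------------------------------------------------------
# Rules

@dataclass(frozen=True)
class Atom:
    """One rule atom.  ``pred`` is a class name, property name or builtin;
    ``args`` are variables (``?x``), strings, numbers or individual names."""

    kind: str  # "class" | "prop" | "builtin" | "novalue"
    pred: str
    args: tuple

    def variables(self) -> set[str]:
        return {a for a in self.args if isinstance(a, str) and a.startswith("?")}


@dataclass(frozen=True)
class OntoRule:
    name: str
    body: tuple[Atom, ...]
    head: tuple[Atom, ...]

    def __post_init__(self) -> None:
        bound = set()
        for atom in self.body:
            bound |= atom.variables()
        for atom in self.head:
            unbound = atom.variables() - bound
            if unbound:
                raise OntologyError(
                    f"rule {self.name}: head variables {sorted(unbound)} "
                    "do not appear in the body"
                )


BUILTINS = {"stringEqualIgnoreCase", "multiply", "divide", "add", "subtract"}

_ATOM_RE = re.compile(
    r"""
    (?: \( \s* (?P<nvprop>[\w.-]+) \s* = \s* 0 \s* \) \s* \( (?P<nvargs>[^)]*) \)
      | (?P<pred>"[^"]+"|[\w.:-]+) \s* \( (?P<args>[^)]*) \)
    )
    """,
    re.VERBOSE,
)


def _parse_term(tok: str):
    tok = tok.strip()
    if tok.startswith("?"):
        return tok
    if tok.startswith('"') and tok.endswith('"'):
        return tok[1:-1]
    try:
        return float(tok) if ("." in tok or "e" in tok.lower()) else int(tok)
    except ValueError:
        return tok  # bare individual/class name


def parse_rule(name: str, text: str, known_classes: Iterable[str] = ()) -> OntoRule:
    """Parse ``body -> head`` rule text into an :class:`OntoRule`.

    Atom kind is resolved later against the store (class vs property); here
    builtins and no-value atoms are recognized syntactically and everything
    else is left as kind ``"class"`` for unary atoms and ``"prop"`` for
    binary ones.
    """
    if "->" not in text:
        raise OntologyError(f"rule {name}: missing '->'")
    body_text, head_text = text.split("->", 1)

    def parse_side(side: str) -> tuple[Atom, ...]:
        atoms = []
        for m in _ATOM_RE.finditer(side):
            if m.group("nvprop"):
                args = tuple(_parse_term(t) for t in m.group("nvargs").split(",") if t.strip())
                atoms.append(Atom("novalue", m.group("nvprop"), args))
                continue
            pred = m.group("pred").strip('"')
            # strip optional swrlb: namespace prefix
            if ":" in pred:
                pred = pred.split(":", 1)[1]
            args = tuple(_parse_term(t) for t in m.group("args").split(",") if t.strip())
            if pred == "noValue":
                atoms.append(Atom("novalue", str(args[0]), args[1:]))
            elif pred in BUILTINS:
                atoms.append(Atom("builtin", pred, args))
            elif len(args) == 1:
                atoms.append(Atom("class", pred, args))
            elif len(args) == 2:
                atoms.append(Atom("prop", pred, args))
            else:
                raise OntologyError(f"rule {name}: cannot parse atom {pred}{args}")
        if not atoms:
            raise OntologyError(f"rule {name}: empty atom list in {side!r}")
        return tuple(atoms)

    return OntoRule(name=name, body=parse_side(body_text), head=parse_side(head_text))


# ---------------------------------------------------------------------------
# Store

class OntologyStore:
    """Classes, properties, individuals, synonyms and rules, with reasoning.

    Reasoning services: subclass subsumption (:meth:`subsumes`), leaf
    enumeration (:meth:`leaves_under`), forward-chaining rule evaluation to
    fixpoint (:meth:`eval_rules`) and individual classification
    (:meth:`classify_individual`).
    """

    def __init__(self, name: str = "") -> None:
        self.name = name
        self.classes: dict[str, OntoClass] = {}
        self.properties: dict[str, OntoProperty] = {}
        self.individuals: dict[str, Individual] = {}
        self.rules: list[OntoRule] = []
        self.synonyms: dict[str, str] = {}  # casefolded term -> class name
        self.conn_card: dict[str, tuple] = {}  # class -> (min_in,max_in,min_out,max_out)
        self.skipped_rule_instances: list[str] = []  # division-by-zero log

    # -- construction -------------------------------------------------------

    def add_class(self, name: str, parents: Iterable[str] = (), changed: bool = False) -> OntoClass:
        parents = set(parents)
        for p in parents:
            if p not in self.classes:
                raise OntologyError(f"unknown parent class {p!r} for {name!r}")
        if name in self.classes:
            self.classes[name].parents |= parents
        else:
            self.classes[name] = OntoClass(name, parents, changed_flag=changed)
        self._check_acyclic(name)
        return self.classes[name]

    def _check_acyclic(self, start: str) -> None:
        seen, stack = set(), [start]
        while stack:
            cur = stack.pop()
            for p in self.classes[cur].parents:
                if p == start:
                    raise OntologyError(f"subclass cycle through {start!r}")
                if p not in seen:
                    seen.add(p)
                    stack.append(p)

    def add_property(self, prop: OntoProperty) -> None:
        self.properties[prop.name] = prop

    def add_synonym(self, term: str, target: str, changed: bool = True) -> None:
        """Register a synonym.  When ``changed`` is true the target class must
        already exist and is flagged as expert-modified; file-loaded synonyms
        may reference classes supplied by a later :meth:`merge`."""
        if changed and target not in self.classes:
            raise OntologyError(f"synonym target {target!r} is not a known class")
        self.synonyms[term.casefold()] = target
        if changed:
            self.classes[target].changed_flag = True

    def add_individual(self, name: str, classes: Iterable[str] = ()) -> Individual:
        ind = self.individuals.setdefault(name, Individual(name))
        for cls in classes:
            if cls not in self.classes:
                raise OntologyError(f"unknown class {cls!r} asserted for {name!r}")
            ind.asserted_classes.add(cls)
        return ind

    def set_value(self, ind_name: str, prop: str, value) -> None:
        ind = self.individuals[ind_name]
        vals = ind.property_values.setdefault(prop, [])
        if not _value_in(vals, value):
            vals.append(value)

    def add_rule(self, rule: OntoRule) -> None:
        self.rules.append(rule)
        self._check_stratified()

    def merge(self, other: "OntologyStore") -> "OntologyStore":
        """Merge another store into this one (classes first, then the rest)."""
        for cls in other.classes.values():
            if cls.name not in self.classes:
                self.classes[cls.name] = OntoClass(cls.name, set(), cls.changed_flag)
        for cls in other.classes.values():
            self.classes[cls.name].parents |= cls.parents
            self._check_acyclic(cls.name)
        self.properties.update(other.properties)
        for ind in other.individuals.values():
            mine = self.add_individual(ind.name, ind.asserted_classes)
            for prop, vals in ind.property_values.items():
                for v in vals:
                    self.set_value(mine.name, prop, v)
        self.rules.extend(other.rules)
        self.synonyms.update(other.synonyms)
        self.conn_card.update(other.conn_card)
        self._check_stratified()
        return self

    # -- taxonomy queries ----------------------------------------------------

    def _require_class(self, name: str) -> OntoClass:
        try:
            return self.classes[name]
        except KeyError:
            raise OntologyError(f"unknown class {name!r}") from None

    def superclosure(self, name: str) -> set[str]:
        """Transitive-reflexive superclass closure of a class."""
        self._require_class(name)
        out, stack = {name}, [name]
        while stack:
            for p in self.classes[stack.pop()].parents:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def subsumes(self, ancestor: str, descendant: str) -> bool:
        self._require_class(ancestor)
        return ancestor in self.superclosure(descendant)

    def children(self, name: str) -> list[str]:
        self._require_class(name)
        return sorted(c.name for c in self.classes.values() if name in c.parents)

    def descendants(self, name: str) -> set[str]:
        self._require_class(name)
        out, stack = {name}, [name]
        while stack:
            for c in self.children(stack.pop()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def is_leaf(self, name: str) -> bool:
        return not self.children(name)

    def leaves_under(self, name: str) -> list[str]:
        return sorted(c for c in self.descendants(name) if self.is_leaf(c))

    def resolve_term(self, token: str) -> str | None:
        """Map a text token to a class name via exact name or synonym.

        Synonyms whose target class is absent (e.g. a synonym table loaded
        without its companion vocabulary) resolve to nothing.
        """
        folded = token.casefold()
        for cls in self.classes:
            if cls.casefold() == folded:
                return cls
        target = self.synonyms.get(folded)
        return target if target in self.classes else None

    # -- rule evaluation -----------------------------------------------------

    def _check_stratified(self) -> None:
        nv_props = {a.pred for r in self.rules for a in r.body if a.kind == "novalue"}
        head_props = {a.pred for r in self.rules for a in r.head if len(a.args) == 2}
        bad = nv_props & head_props
        if bad:
            raise OntologyError(
                f"unstratified rule base: properties {sorted(bad)} are both "
                "derived by rule heads and read through no-value atoms"
            )

    def _classes_of(self, ind: Individual) -> set[str]:
        out = set()
        for cls in ind.asserted_classes:
            out |= self.superclosure(cls)
        return out

    def _match_atom(self, atom: Atom, env: dict) -> list[dict]:
        """All binding environments extending ``env`` that satisfy the atom."""

        def subst(term):
            return env.get(term, term) if isinstance(term, str) and term.startswith("?") else term

        if atom.kind == "class":
            (arg,) = atom.args
            val = subst(arg)
            if isinstance(val, str) and val.startswith("?"):
                return [
                    {**env, arg: ind.name}
                    for ind in self.individuals.values()
                    if atom.pred in self._classes_of(ind)
                ]
            ind = self.individuals.get(val)
            return [env] if ind is not None and atom.pred in self._classes_of(ind) else []

        if atom.kind == "prop":
            subj, obj = (subst(a) for a in atom.args)
            subjects = (
                [self.individuals[subj]]
                if not (isinstance(subj, str) and subj.startswith("?"))
                and subj in self.individuals
                else list(self.individuals.values())
                if isinstance(subj, str) and subj.startswith("?")
                else []
            )
            out = []
            for ind in subjects:
                for val in ind.values(atom.pred):
                    env2 = dict(env)
                    if isinstance(subj, str) and subj.startswith("?"):
                        env2[atom.args[0]] = ind.name
                    if isinstance(obj, str) and obj.startswith("?"):
                        env2[atom.args[1]] = val
                    elif not _literal_eq(obj, val):
                        continue
                    out.append(env2)
            return out

        if atom.kind == "novalue":
            (arg,) = atom.args
            val = subst(arg)
            candidates = (
                [v for v in self.individuals.values() if not v.values(atom.pred)]
                if isinstance(val, str) and val.startswith("?")
                else [self.individuals[val]]
                if val in self.individuals and not self.individuals[val].values(atom.pred)
                else []
            )
            if isinstance(val, str) and val.startswith("?"):
                return [{**env, arg: c.name} for c in candidates]
            return [env] if candidates else []

        # builtin
        args = [subst(a) for a in atom.args]
        if atom.pred == "stringEqualIgnoreCase":
            a, b = args
            if any(isinstance(v, str) and v.startswith("?") for v in (a, b)):
                return []  # both operands must be bound
            return [env] if str(a).casefold() == str(b).casefold() else []
        # arithmetic: first argument is result
        result, *operands = args
        if any(isinstance(v, str) and v.startswith("?") for v in operands):
            return []
        try:
            if atom.pred == "multiply":
                value = math.prod(operands)
            elif atom.pred == "divide":
                value = operands[0] / operands[1]
            elif atom.pred == "add":
                value = sum(operands)
            else:  # subtract
                value = operands[0] - sum(operands[1:])
        except ZeroDivisionError:
            self.skipped_rule_instances.append(
                f"division by zero in {atom.pred}{tuple(args)}"
            )
            return []
        if isinstance(result, str) and result.startswith("?"):
            return [{**env, atom.args[0]: value}]
        return [env] if _literal_eq(result, value) else []

    def _run_stratum(self, rules: list[OntoRule]) -> set[tuple]:
        derived: set[tuple] = set()
        changed = True
        while changed:
            changed = False
            for rule in rules:
                envs = [{}]
                for atom in rule.body:
                    envs = [e2 for e in envs for e2 in self._match_atom(atom, e)]
                    if not envs:
                        break
                for env in envs:
                    for atom in rule.head:
                        args = [
                            env.get(a, a) if isinstance(a, str) and a.startswith("?") else a
                            for a in atom.args
                        ]
                        if len(args) == 1:
                            key = ("class", args[0], atom.pred)
                            ind = self.individuals.get(args[0])
                            if ind is not None and atom.pred not in ind.asserted_classes:
                                if key not in derived:
                                    derived.add(key)
                                    self.add_individual(args[0], [atom.pred])
                                    changed = True
                        else:
                            subj, val = args
                            ind = self.individuals.get(subj)
                            if ind is not None and not _value_in(ind.values(atom.pred), val):
                                derived.add(("prop", subj, atom.pred, val))
                                self.set_value(subj, atom.pred, val)
                                changed = True
        return derived

    def eval_rules(self) -> set[tuple]:
        """Forward-chain all rules to fixpoint; return the derived assertions.

        Assertions are tuples ``("class", individual, class)`` or
        ``("prop", individual, property, value)`` and are also applied to the
        store.  Rules whose body contains a no-value atom run in a second
        stratum, after the positive fixpoint.
        """
        self._check_stratified()
        positive = [r for r in self.rules if all(a.kind != "novalue" for a in r.body)]
        negative = [r for r in self.rules if any(a.kind == "novalue" for a in r.body)]
        derived = self._run_stratum(positive)
        derived |= self._run_stratum(negative)
        # a second-stratum head may enable further positive rules
        if negative:
            derived |= self._run_stratum(positive)
        return derived

    def classify_individual(self, ind_name: str) -> set[str]:
        """Asserted plus rule-derived classes plus their superclass closure."""
        self.eval_rules()
        ind = self.individuals.get(ind_name)
        if ind is None:
            return set()
        return self._classes_of(ind)

    def check_cardinality(self, ind_name: str) -> list[str]:
        """Property-count violations for one individual (report strings)."""
        ind = self.individuals[ind_name]
        problems = []
        for prop in self.properties.values():
            if prop.domain and prop.domain not in self._classes_of(ind):
                continue
            n = len(ind.values(prop.name))
            if prop.min_out is not None and n < prop.min_out:
                problems.append(f"{ind_name}.{prop.name}: {n} < min {prop.min_out}")
            if prop.max_out is not None and n > prop.max_out:
                problems.append(f"{ind_name}.{prop.name}: {n} > max {prop.max_out}")
        return problems


def _literal_eq(a, b) -> bool:
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return math.isclose(a, b, rel_tol=NUMERIC_TOL, abs_tol=NUMERIC_TOL)
    return a == b


def _value_in(values: list, value) -> bool:
    return any(_literal_eq(v, value) for v in values)


# ---------------------------------------------------------------------------
# Text format

_CLASS_RE = re.compile(r'^class\s+("(?P<qname>[^"]+)"|(?P<name>[\w.\[\]/ -]+?))\s*(?:<\s*("(?P<qparent>[^"]+)"|(?P<parent>\S+)))?$')
_PROP_RE = re.compile(
    r'^property\s+(?P<name>[\w-]+)\s*:\s*(?P<kind>object|datatype)\s+'
    r'(?P<domain>"[^"]+"|[\w-]+)\s*->\s*(?P<range>"[^"]+"|[\w-]+)'
    r'(?:\s*\[(?P<card>[^\]]*)\])?$'
)
_CONN_RE = re.compile(
    r'^connections\s+(?P<cls>"[^"]+"|[\w-]+)\s+in\s+(?P<mi>\d+|-)\s+(?P<xi>\d+|-)'
    r'\s+out\s+(?P<mo>\d+|-)\s+(?P<xo>\d+|-)$'
)
_IND_RE = re.compile(r'^individual\s+(?P<name>[\w.-]+)\s*(?::\s*(?P<cls>.+))?$')
_SYN_RE = re.compile(r'^synonym\s+(?P<term>"[^"]+"|[\S]+)\s*=\s*(?P<target>"[^"]+"|.+)$')
_RULE_RE = re.compile(r'^rule\s+(?P<name>[\w-]+)\s*:\s*(?P<text>.+)$')
_VALUE_RE = re.compile(r'^(?P<prop>[\w-]+)\s*=\s*(?P<val>.+)$')


def _unq(s: str) -> str:
    s = s.strip()
    return s[1:-1] if s.startswith('"') and s.endswith('"') else s


def _card(tok: str) -> int | None:
    return None if tok == "-" else int(tok)


def parse_ontology(text: str, name: str = "") -> OntologyStore:
    """Parse the ``.onto`` text format into a store."""
    store = OntologyStore(name)
    current_ind: str | None = None
    pending = ""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if pending:
            line = pending + " " + line.strip()
            pending = ""
        if line.rstrip().endswith("\\"):
            pending = line.rstrip()[:-1].strip()
            continue
        indented = line[0] in " \t"
        line = line.strip()
        try:
            if indented and current_ind is not None:
                m = _VALUE_RE.match(line)
                if not m:
                    raise OntologyError(f"bad individual value line: {line!r}")
                store.set_value(current_ind, m.group("prop"), _parse_term(m.group("val")))
                continue
            current_ind = None
            if line.startswith("ontology "):
                store.name = line.split(None, 1)[1]
            elif m := _CLASS_RE.match(line):
                cname = m.group("qname") or m.group("name")
                parent = m.group("qparent") or m.group("parent")
                store.add_class(cname.strip(), [parent] if parent else [])
            elif m := _PROP_RE.match(line):
                card = dict(
                    p.split("=") for p in (m.group("card") or "").split() if "=" in p
                )
                store.add_property(
                    OntoProperty(
                        name=m.group("name"),
                        kind=m.group("kind"),
                        domain=_unq(m.group("domain")),
                        range=_unq(m.group("range")),
                        min_in=_card(card.get("min_in", "-")),
                        max_in=_card(card.get("max_in", "-")),
                        min_out=_card(card.get("min_out", "-")),
                        max_out=_card(card.get("max_out", "-")),
                    )
                )
            elif m := _CONN_RE.match(line):
                store.conn_card[_unq(m.group("cls"))] = (
                    _card(m.group("mi")),
                    _card(m.group("xi")),
                    _card(m.group("mo")),
                    _card(m.group("xo")),
                )
            elif m := _IND_RE.match(line):
                classes = [
                    _unq(c) for c in (m.group("cls") or "").split(",") if c.strip()
                ]
                store.add_individual(m.group("name"), classes)
                current_ind = m.group("name")
            elif m := _SYN_RE.match(line):
                store.add_synonym(_unq(m.group("term")), _unq(m.group("target")), changed=False)
            elif m := _RULE_RE.match(line):
                store.rules.append(parse_rule(m.group("name"), m.group("text")))
            else:
                raise OntologyError(f"unrecognized line: {line!r}")
        except OntologyError as exc:
            raise OntologyError(f"{store.name or '<onto>'}:{lineno}: {exc}") from None
    store._check_stratified()
    return store


def load_ontology(path) -> OntologyStore:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_ontology(fh.read(), name=str(path))


def packaged_ontology(name: str) -> OntologyStore:
    """Load one of the ontologies shipped with the package
    (``diagram``, ``hospital``, ``language``)."""
    from importlib import resources

    data = resources.files("guideflow") / "data" / f"{name}.onto"
    return parse_ontology(data.read_text(encoding="utf-8"), name=name)


def default_ontologies() -> list[OntologyStore]:
    """The packaged diagram ontology, hospital vocabulary and synonym table,
    in merge order."""
    return [packaged_ontology(n) for n in ("diagram", "hospital", "language")]
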