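"""Blackboard translation of flow charts into the intermediate language.

Translation is cooperative: a coordinator repeatedly asks a fixed-priority
list of *knowledge sources* to contribute to a shared blackboard until the
whole document is consumed.  The sources are

1. the **diagram reasoner** — creates an ontology individual per symbol,
   classifies it against the diagram ontology (subclass matching plus the
   stereotype rules) and emits the mapped intermediate construct;
2. the **connection linker** — turns each edge into a ``Connection``
   construct, creating placeholder individuals for endpoints that have not
   been translated yet;
3. the **term matcher** — interprets free-text action names against the
   hospital vocabulary and synonym table, descending the medication taxonomy
   to a specific preparation and picking the action class;
4. the **interaction source** — when the others are stuck it poses a
   question (choose a candidate, define an unknown symbol, extend the
   vocabulary, or model manually) and consumes an answer from the scripted
   expert transcript.

Within a source, work proceeds in document order, so translation is
deterministic given the document, ontologies and transcript: replaying the
same transcript reproduces the same model bit for bit.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from typing import Sequence

from .mini_ontology import OntologyError, OntologyStore

__all__ = [
    "IntermediateConstruct",
    "IntermediateModel",
    "Question",
    "Answer",
    "InteractionTranscript",
    "ActionSpec",
    "Blackboard",
    "TranslationError",
    "UnansweredQuestion",
    "translate",
    "diagram_reason",
    "interpret_action_text",
    "link_symbols",
    "extend_vocabulary",
    "tokenize_action_text",
    "slugify",
]

CONSTRUCT_KINDS = (
    "Start", "End", "Split", "Join", "TimeHandler",
    "SubProcess", "WorkItem", "Action", "Connection",
)

MEDICATION_ROOT = "Medication"
ACTION_ROOT = "Action"


class TranslationError(RuntimeError):
    pass


class UnansweredQuestion(TranslationError):
    def __init__(self, question: "Question") -> None:
        self.question = question
        super().__init__(
            f"unanswered question {question.qid} ({question.kind}) "
            f"for symbol {question.symbol_id!r}: {question.prompt}"
        )


@dataclass
class IntermediateConstruct:
    kind: str
    construct_id: str
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CONSTRUCT_KINDS:
            raise TranslationError(f"unknown construct kind {self.kind!r}")


@dataclass
class IntermediateModel:
    constructs: list[IntermediateConstruct] = field(default_factory=list)
    source_name: str = ""

    def by_id(self, construct_id: str) -> IntermediateConstruct:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(construct_id)

    def connections(self) -> list[IntermediateConstruct]:
        return [c for c in self.constructs if c.kind == "Connection"]

    def nodes(self) -> list[IntermediateConstruct]:
        return [c for c in self.constructs if c.kind != "Connection"]


@dataclass
class Question:
    qid: str
    kind: str  # choose | define_symbol | rename | extend_vocabulary | model_manually
    prompt: str
    options: list[str] = field(default_factory=list)
    symbol_id: str = ""

    def to_json(self) -> dict:
        return {
            "qid": self.qid, "kind": self.kind, "prompt": self.prompt,
            "options": list(self.options), "symbol_id": self.symbol_id,
        }


@dataclass
class Answer:
    payload: dict
    qid: str | None = None


class InteractionTranscript:
    """Scripted expert answers, matched by qid when pinned, else by order."""

    def __init__(self, answers: Sequence[Answer] = (), strict: bool = True) -> None:
        self.answers = list(answers)
        self.strict = strict
        self._cursor = 0

    @classmethod
    def from_json(cls, data) -> "InteractionTranscript":
        if isinstance(data, str):
            data = json.loads(data)
        return cls(
            answers=[Answer(payload=a["answer"], qid=a.get("qid")) for a in data.get("answers", [])],
            strict=data.get("strict", True),
        )

    def to_json(self) -> dict:
        return {
            "strict": self.strict,
            "answers": [
                {**({"qid": a.qid} if a.qid else {}), "answer": a.payload}
                for a in self.answers
            ],
        }

    def consume(self, question: Question) -> dict | None:
        for i in range(self._cursor, len(self.answers)):
            a = self.answers[i]
            if a.qid == question.qid:
                self.answers.pop(i)
                return a.payload
        if self._cursor < len(self.answers) and self.answers[self._cursor].qid is None:
            return self.answers.pop(self._cursor).payload
        return None


@dataclass
class ActionSpec:
    """Interpretation of a free-text action name."""

    text: str
    action_class: str | None = None
    medications: list[str] = field(default_factory=list)
    observations: list[str] = field(default_factory=list)
    derives: list[str] = field(default_factory=list)  # derived-parameter properties

    def to_json(self) -> dict:
        return {
            "text": self.text, "action_class": self.action_class,
            "medications": list(self.medications),
            "observations": list(self.observations), "derives": list(self.derives),
        }


@dataclass
class Blackboard:
    filtered_doc: object  # FlowChartDocument
    store: OntologyStore
    model: IntermediateModel
    placeholders: set[str] = field(default_factory=set)
    question_log: list[dict] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)
    transcript: InteractionTranscript | None = None
    _qcount: int = 0
    steps: int = 0

    def contribute(self, source: str, subject: str, produced: list[str]) -> None:
        self.steps += 1
        self.log.append(
            {"step": self.steps, "source": source, "subject": subject, "produced": produced}
        )

    def next_qid(self) -> str:
        self._qcount += 1
        return f"Q{self._qcount:03d}"

    def ask(self, question: Question) -> dict | None:
        """Route a question to the interaction source; return the answer
        payload, or ``None`` in non-strict mode when the transcript is
        exhausted (strict mode raises)."""
        payload = self.transcript.consume(question) if self.transcript else None
        self.question_log.append({**question.to_json(), "answer": payload})
        self.contribute("interaction", question.qid, [])
        if payload is None and (self.transcript is None or self.transcript.strict):
            raise UnansweredQuestion(question)
        return payload


def slugify(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", text.casefold()).strip("-")


# ---------------------------------------------------------------------------
# Tokenization

DOSE_RE = re.compile(r"\d+(?:\.\d+)?\s?(?:mg|ml|g|mcg|µg)(?:/(?:h|ml|kg|min|1ml))?", re.IGNORECASE)
WORD_RE = re.compile(r"[A-Za-z][A-Za-z0-9-]*")


def tokenize_action_text(name: str) -> list[str]:
    """Split an action name on whitespace/punctuation, keeping dose strings
    (``1ml/h``, ``20mg``) intact as single tokens, in text order."""
    tokens: list[tuple[int, str]] = []
    taken: list[tuple[int, int]] = []
    for m in DOSE_RE.finditer(name):
        tokens.append((m.start(), m.group(0).replace(" ", "")))
        taken.append(m.span())
    for m in WORD_RE.finditer(name):
        if any(a <= m.start() < b for a, b in taken):
            continue
        tokens.append((m.start(), m.group(0)))
    return [t for _, t in sorted(tokens)]


def _is_dose(token: str) -> bool:
    return bool(DOSE_RE.fullmatch(token))


def _normalize_dose(token: str) -> str:
    """Strip a trailing rate suffix: the qualifier ``1ml/h`` narrows
    candidates via its amount part ``1ml``."""
    return token.split("/")[0].casefold()


# ---------------------------------------------------------------------------
# Knowledge sources

def diagram_reason(symbol, board: Blackboard) -> list[IntermediateConstruct]:
    """Translate one symbol via the diagram ontology.

    Creates an individual named by the symbol id, asserts the matched
    ``UMLSymbol`` subclass and its stereotype, classifies it (running the
    stereotype rules), and emits the mapped construct.  Unknown model types
    and unmapped stereotypes become ``define_symbol`` questions.
    """
    store = board.store
    sym_classes = {c.casefold(): c for c in store.descendants("UMLSymbol")}
    matched = sym_classes.get(symbol.model_type.casefold())

    kinds: set[str] = set()
    if matched is not None:
        if symbol.symbol_id in board.placeholders:
            board.placeholders.discard(symbol.symbol_id)
        store.add_individual(symbol.symbol_id, [matched])
        if symbol.stereotype:
            store.set_value(symbol.symbol_id, "hasStereoType", symbol.stereotype)
        classification = store.classify_individual(symbol.symbol_id)
        kinds = classification & set(CONSTRUCT_KINDS) - {"Connection"}

    if not kinds:
        reason = (
            f"unknown symbol type {symbol.model_type!r}"
            if matched is None
            else f"no intermediate mapping for {symbol.model_type!r} "
            f"with stereotype {symbol.stereotype!r}"
        )
        analyzed = interpret_action_text(symbol.name, store, board, ask=False) if symbol.name else None
        question = Question(
            qid=board.next_qid(),
            kind="define_symbol",
            prompt=(
                f"{reason} for symbol {symbol.symbol_id!r} "
                f"(name: {symbol.name!r}"
                + (f"; analysis: {analyzed.to_json()}" if isinstance(analyzed, ActionSpec) else "")
                + "). Which construct should be created?"
            ),
            options=sorted(set(CONSTRUCT_KINDS) - {"Connection"}),
            symbol_id=symbol.symbol_id,
        )
        payload = board.ask(question)
        if payload is None:
            payload = {"kind": "WorkItem", "manual": True}  # abort-to-manual
        kinds = {payload["kind"]}
        board.placeholders.discard(symbol.symbol_id)
        store.add_individual(symbol.symbol_id, [])

    produced = []
    for kind in sorted(kinds):
        attrs: dict = {"name": symbol.name, "source_type": symbol.model_type}
        if symbol.stereotype:
            attrs["stereotype"] = symbol.stereotype
        if kind == "TimeHandler":
            attrs["schedule_text"] = symbol.name
        elif kind == "SubProcess":
            attrs["flow_ref"] = slugify(symbol.name)
        elif kind in ("WorkItem", "Action") and symbol.name:
            spec = interpret_action_text(symbol.name, store, board, ask=True)
            attrs["action"] = spec.to_json()
            if spec.derives and kind == "WorkItem":
                kind = "Action"  # derived-parameter computations are engine actions
                attrs["updates"] = [{"derive": prop} for prop in spec.derives]
        produced.append(IntermediateConstruct(kind, symbol.symbol_id, attrs))
        board.model.constructs.append(produced[-1])
    board.contribute("diagram_reasoner", symbol.symbol_id, [c.construct_id for c in produced])
    return produced


def interpret_action_text(
    name: str, vocabulary: OntologyStore, board: Blackboard, ask: bool = True
) -> ActionSpec:
    """Interpret a free-text action name against the hospital vocabulary.

    Tokens are matched case-insensitively (after punctuation stripping)
    against class names and synonyms.  A matched medication class that is a
    proper subclass of ``Medication`` is narrowed to its leaf preparations;
    dose qualifiers are attributed to the nearest drug token and used to
    filter the leaves.  If several leaves remain, a ``choose`` question is
    posed (when ``ask``); the expert's choice resolves the mention.
    """
    tokens = tokenize_action_text(name)
    matches: list[tuple[int, str, str]] = []  # (index, token, class)
    for i, tok in enumerate(tokens):
        if _is_dose(tok):
            continue
        cls = vocabulary.resolve_term(tok)
        if cls is None:
            continue
        matches.append((i, tok, cls))
    # two-word synonyms ("sedation score", "body mass index")
    for two in (2, 3):
        for i in range(len(tokens) - two + 1):
            phrase = " ".join(tokens[i:i + two])
            cls = vocabulary.resolve_term(phrase)
            if cls is not None:
                matches.append((i, phrase, cls))

    dose_positions = [i for i, t in enumerate(tokens) if _is_dose(t)]

    spec = ActionSpec(text=name)
    drug_indices: list[int] = []
    for i, tok, cls in matches:
        in_medication = vocabulary.subsumes(MEDICATION_ROOT, cls)
        in_action = vocabulary.subsumes(ACTION_ROOT, cls)
        if in_medication and cls != MEDICATION_ROOT:
            drug_indices.append(i)
            candidates = vocabulary.leaves_under(cls)
            if len(candidates) > 1:
                # dose qualifiers attributed to the nearest drug token
                my_doses = [
                    tokens[d] for d in dose_positions
                    if _nearest(d, [j for j, _, c in matches
                                    if vocabulary.subsumes(MEDICATION_ROOT, c)
                                    and c != MEDICATION_ROOT]) == i
                ]
                for dose in my_doses:
                    narrowed = [
                        leaf for leaf in candidates
                        if _normalize_dose(dose) in leaf.casefold()
                    ]
                    if narrowed:
                        candidates = narrowed
            if len(candidates) > 1:
                if not ask:
                    spec.medications.extend(candidates)
                    continue
                question = Question(
                    qid=board.next_qid(),
                    kind="choose",
                    prompt=f"Several preparations match {tok!r} in {name!r}; which one?",
                    options=sorted(candidates),
                    symbol_id="",
                )
                payload = board.ask(question)
                candidates = [payload["choice"]] if payload else [sorted(candidates)[0]]
            spec.medications.append(candidates[0])
        elif in_action and cls != ACTION_ROOT:
            if spec.action_class is None:
                spec.action_class = cls
        elif cls in vocabulary.classes and vocabulary.subsumes("Observation", cls) \
                and cls != "Observation":
            spec.observations.append(cls)
        # a token naming a derived property (e.g. "BMI" -> hasBMI with a rule)
        prop = _derived_property_for(tok, vocabulary)
        if prop and prop not in spec.derives:
            spec.derives.append(prop)

    if spec.action_class is None and not spec.medications and not spec.observations \
            and not spec.derives:
        if not ask:
            return spec
        question = Question(
            qid=board.next_qid(),
            kind="extend_vocabulary",
            prompt=f"No vocabulary class matches any word of {name!r}; "
                   "extend the vocabulary or model manually.",
            options=[],
            symbol_id="",
        )
        payload = board.ask(question)
        if payload and "extend" in payload:
            ext = payload["extend"]
            extend_vocabulary(
                ext["term"],
                {k: v for k, v in ext.items() if k != "term"},
                vocabulary,
            )
            return interpret_action_text(name, vocabulary, board, ask=ask)
        spec.action_class = None  # modelled manually
    _ = drug_indices
    return spec


def _derived_property_for(token: str, vocabulary: OntologyStore) -> str | None:
    """Property whose name matches the token (``bmi`` -> ``hasBMI``) and that
    is derived by some rule head."""
    folded = token.casefold()
    heads = {a.pred for r in vocabulary.rules for a in r.head if len(a.args) == 2}
    for prop in vocabulary.properties:
        stem = prop[3:] if prop.startswith("has") else prop
        if stem.casefold() == folded and prop in heads:
            return prop
    return None


def _nearest(pos: int, anchors: list[int]) -> int | None:
    if not anchors:
        return None
    return min(anchors, key=lambda a: (abs(a - pos), a))


def link_symbols(rel, board: Blackboard) -> IntermediateConstruct:
    """Translate one edge into a ``Connection`` construct.

    Endpoints that do not exist in the ontology yet are created as instances
    of the high-level ``Symbol`` class and recorded as placeholders, refined
    when their ``Model`` element is translated.
    """
    store = board.store
    for end in (rel.from_id, rel.to_id):
        if end not in store.individuals:
            store.add_individual(end, ["Symbol"])
            board.placeholders.add(end)
    conn = IntermediateConstruct(
        "Connection",
        rel.rel_id,
        {"from": rel.from_id, "to": rel.to_id, "guard": rel.guard_text},
    )
    board.model.constructs.append(conn)
    board.contribute("connection_linker", rel.rel_id, [rel.rel_id])
    return conn


def extend_vocabulary(term: str, placement: dict, vocabulary: OntologyStore) -> OntologyStore:
    """Add an expert-provided definition: a synonym of an existing class or a
    new subclass.  The touched class is flagged for the ontology engineer."""
    if "synonym_of" in placement:
        vocabulary.add_synonym(term, placement["synonym_of"], changed=True)
    elif "subclass_of" in placement:
        vocabulary.add_class(term, [placement["subclass_of"]], changed=True)
    else:
        raise OntologyError(f"placement for {term!r} must name synonym_of or subclass_of")
    return vocabulary


# ---------------------------------------------------------------------------
# Coordinator

def _check_cardinalities(board: Blackboard) -> None:
    indeg: dict[str, int] = {}
    outdeg: dict[str, int] = {}
    for conn in board.model.connections():
        outdeg[conn.attrs["from"]] = outdeg.get(conn.attrs["from"], 0) + 1
        indeg[conn.attrs["to"]] = indeg.get(conn.attrs["to"], 0) + 1
    for node in board.model.nodes():
        card = board.store.conn_card.get(node.kind)
        if card is None:
            continue
        mi, xi, mo, xo = card
        n_in = indeg.get(node.construct_id, 0)
        n_out = outdeg.get(node.construct_id, 0)
        for label, n, lo, hi in (("incoming", n_in, mi, xi), ("outgoing", n_out, mo, xo)):
            if lo is not None and n < lo:
                raise TranslationError(
                    f"{node.kind} {node.construct_id!r}: {n} {label} connections, "
                    f"minimum {lo}"
                )
            if hi is not None and n > hi:
                raise TranslationError(
                    f"{node.kind} {node.construct_id!r}: {n} {label} connections, "
                    f"maximum {hi}"
                )


def translate(
    doc,
    ontologies: Sequence[OntologyStore],
    transcript: InteractionTranscript | None = None,
) -> tuple[IntermediateModel, list[dict]]:
    """Translate a pre-processed flow chart into an intermediate model.

    Returns the model and the question log (each posed question with its
    answer).  Deterministic given ``(doc, ontologies, transcript)``; the
    packaged ontology stores are not mutated (a merged working copy is).
    """
    if not getattr(doc, "preprocessed", False):
        raise TranslationError("document must be pre-processed before translation")
    store = OntologyStore("working")
    for onto in ontologies:
        store.merge(copy.deepcopy(onto))
    board = Blackboard(
        filtered_doc=doc,
        store=store,
        model=IntermediateModel(source_name=doc.source_name),
        transcript=transcript,
    )
    for symbol in doc.symbols:
        diagram_reason(symbol, board)
    for rel in doc.relationships:
        link_symbols(rel, board)
    unresolved = board.placeholders - {s.symbol_id for s in doc.symbols}
    if unresolved:
        raise TranslationError(
            "translation stalled; unresolved placeholder symbols: "
            + ", ".join(sorted(unresolved))
        )
    board.placeholders.clear()
    _check_cardinalities(board)
    return board.model, board.question_log
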