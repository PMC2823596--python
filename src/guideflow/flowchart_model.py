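"""Flow-chart documents in the activity-diagram XML dialect.

Clinical guidelines enter the pipeline as flow charts drawn by medical staff
in a diagram editor and exported as XML.  The dialect understood here is
deliberately small and fully documented:

.. code-block:: xml

    <FlowChart name="normal-sedation">
      <Model id="ID34" modelType="InitialNode" name="" x="10" y="20"/>
      <Model id="ID16" modelType="ActivityAction"
             name="Add Morphine 1ml/h, Add Dormicum 2ml/h"/>
      <RelationshipRef id="R1" From="ID34" To="ID16"/>
    </FlowChart>

``Model`` elements describe diagram symbols.  The reserved attributes are
``id`` (required, unique), ``modelType`` (required: ``InitialNode``,
``ActivityAction``, ``DecisionNode``, ``MergeNode``, ``FinalNode``,
``Note``, ...), ``name`` (free text) and ``stereotype`` (an annotation such
as ``wait`` or ``subprocess``).  Every other attribute — position, size,
colour and similar presentation content — is retained verbatim in
:attr:`SymbolRecord.extra` until :func:`preprocess` strips it.

``RelationshipRef`` elements are directed edges between symbols, with an
optional ``guard`` attribute holding the branch condition label of edges
leaving decision symbols.

All documents are UTF-8; identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

__all__ = [
    "SymbolRecord",
    "RelationshipRecord",
    "FlowChartDocument",
    "FlowChartError",
    "read_flowchart",
    "write_flowchart",
    "preprocess",
    "iter_symbols",
    "SymbolScanner",
    "PRESENTATION_KEYS",
]

#: Attribute names treated as presentation-only content, removed by
#: :func:`preprocess`.  The set is configurable per call.
PRESENTATION_KEYS = frozenset(
    {"x", "y", "width", "height", "color", "font", "background", "zorder"}
)

_RESERVED = ("id", "modelType", "name", "stereotype")


class FlowChartError(ValueError):
    """Raised for malformed or structurally invalid flow-chart documents."""


@dataclass(frozen=True)
class SymbolRecord:
    """One diagram symbol (a ``Model`` element)."""

    symbol_id: str
    model_type: str
    name: str = ""
    stereotype: str | None = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.model_type:
            raise FlowChartError(f"symbol {self.symbol_id!r} has empty modelType")


@dataclass(frozen=True)
class RelationshipRecord:
    """One directed edge (a ``RelationshipRef`` element)."""

    rel_id: str
    from_id: str
    to_id: str
    guard_text: str | None = None
    self_loop: bool = False

    def __post_init__(self) -> None:
        if self.from_id == self.to_id and not self.self_loop:
            raise FlowChartError(
                f"relationship {self.rel_id!r} connects {self.from_id!r} to itself "
                "without being flagged as a self-loop"
            )


@dataclass
class FlowChartDocument:
    """A parsed flow chart: symbols plus relationships.

    ``preprocessed`` records whether presentation content has been stripped;
    translation requires a pre-processed document.
    """

    symbols: list[SymbolRecord] = field(default_factory=list)
    relationships: list[RelationshipRecord] = field(default_factory=list)
    preprocessed: bool = False
    source_name: str = ""

    def symbol_ids(self) -> set[str]:
        return {s.symbol_id for s in self.symbols}

    def dangling_references(self) -> list[str]:
        """Relationship endpoints that do not resolve to any symbol id."""
        ids = self.symbol_ids()
        out = []
        for rel in self.relationships:
            for end in (rel.from_id, rel.to_id):
                if end not in ids:
                    out.append(f"{rel.rel_id}:{end}")
        return out

    def validate(self) -> None:
        seen: set[str] = set()
        for sym in self.symbols:
            if sym.symbol_id in seen:
                raise FlowChartError(f"duplicate symbol id {sym.symbol_id!r}")
            seen.add(sym.symbol_id)
        dangling = self.dangling_references()
        if dangling:
            raise FlowChartError(
                "dangling relationship endpoints: " + ", ".join(sorted(dangling))
            )


def _symbol_from_attrs(attrs: Mapping[str, str], where: str) -> SymbolRecord:
    if "id" not in attrs:
        raise FlowChartError(f"Model element missing 'id' at {where}")
    if "modelType" not in attrs or not attrs["modelType"]:
        raise FlowChartError(f"Model element missing 'modelType' at {where}")
    extra = {k: v for k, v in attrs.items() if k not in _RESERVED}
    return SymbolRecord(
        symbol_id=attrs["id"],
        model_type=attrs["modelType"],
        name=attrs.get("name", ""),
        stereotype=attrs.get("stereotype") or None,
        extra=extra,
    )


def read_flowchart(stream) -> FlowChartDocument:
    """Parse a flow-chart document from XML text, a path, or a file object.

    Raises :class:`FlowChartError` for malformed XML (with line information),
    duplicate symbol ids, and relationship endpoints that resolve to no
    symbol.
    """
    if isinstance(stream, (str,)) and stream.lstrip().startswith("<"):
        text = stream
        source = "<string>"
    elif hasattr(stream, "read"):
        text = stream.read()
        source = getattr(stream, "name", "<stream>")
    else:  # a path
        with open(stream, "r", encoding="utf-8") as fh:
            text = fh.read()
        source = str(stream)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise FlowChartError(f"{source}: malformed XML: {exc}") from exc

    doc = FlowChartDocument(source_name=root.get("name", source))
    for elem in root:
        if elem.tag == "Model":
            doc.symbols.append(_symbol_from_attrs(elem.attrib, source))
        elif elem.tag == "RelationshipRef":
            attrs = elem.attrib
            for req in ("id", "From", "To"):
                if req not in attrs:
                    raise FlowChartError(
                        f"{source}: RelationshipRef missing {req!r}"
                    )
            doc.relationships.append(
                RelationshipRecord(
                    rel_id=attrs["id"],
                    from_id=attrs["From"],
                    to_id=attrs["To"],
                    guard_text=attrs.get("guard") or None,
                    self_loop=attrs.get("selfLoop", "") == "true",
                )
            )
        # unknown elements are ignored: editors may add metadata sections
    doc.validate()
    return doc


def write_flowchart(doc: FlowChartDocument) -> str:
    """Serialize a document back to the XML dialect (inverse of read)."""
    root = ET.Element("FlowChart")
    if doc.source_name:
        root.set("name", doc.source_name)
    for sym in doc.symbols:
        attrs = {"id": sym.symbol_id, "modelType": sym.model_type}
        if sym.name:
            attrs["name"] = sym.name
        if sym.stereotype:
            attrs["stereotype"] = sym.stereotype
        attrs.update(sym.extra)
        ET.SubElement(root, "Model", attrs)
    for rel in doc.relationships:
        attrs = {"id": rel.rel_id, "From": rel.from_id, "To": rel.to_id}
        if rel.guard_text:
            attrs["guard"] = rel.guard_text
        if rel.self_loop:
            attrs["selfLoop"] = "true"
        ET.SubElement(root, "RelationshipRef", attrs)
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
    return buf.getvalue().decode("utf-8")


def preprocess(
    doc: FlowChartDocument, presentation_keys: frozenset[str] = PRESENTATION_KEYS
) -> FlowChartDocument:
    """Strip presentation content, keeping symbol types, names and edges.

    Pure and idempotent: symbol ids, model types, names, stereotypes and the
    full relationship list are preserved verbatim; only ``extra`` keys in
    ``presentation_keys`` are dropped.
    """
    symbols = [
        replace(
            sym,
            extra={k: v for k, v in sym.extra.items() if k not in presentation_keys},
        )
        for sym in doc.symbols
    ]
    return FlowChartDocument(
        symbols=symbols,
        relationships=list(doc.relationships),
        preprocessed=True,
        source_name=doc.source_name,
    )


_MODEL_RE = re.compile(r"<Model\b")
_ATTR_RE = re.compile(r'([A-Za-z_][\w:-]*)\s*=\s*"([^"]*)"')


class SymbolScanner:
    """Streaming scanner that reads the XML text word by word and stops at
    each ``<Model`` construct, yielding its symbol without building a tree.

    Mirrors the translator's incremental reading of exported diagrams; the
    whole-document :func:`read_flowchart` parse yields the same symbol
    multiset (a tested invariant).
    """

    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def next_symbol(self) -> SymbolRecord | None:
        """Return the next symbol, advancing the cursor; ``None`` at end."""
        match = _MODEL_RE.search(self.text, self.pos)
        if match is None:
            self.pos = len(self.text)
            return None
        start = match.start()
        end = self.text.find(">", start)
        if end == -1:
            raise FlowChartError(f"unterminated Model construct at offset {start}")
        attrs = dict(_ATTR_RE.findall(self.text[start:end]))
        if "id" not in attrs or not attrs.get("modelType"):
            missing = "id" if "id" not in attrs else "modelType"
            raise FlowChartError(
                f"Model construct at offset {start} missing {missing!r}"
            )
        # XML attribute values may carry character references
        attrs = {
            k: v.replace("&quot;", '"')
            .replace("&lt;", "<")
            .replace("&gt;", ">")
            .replace("&amp;", "&")
            for k, v in attrs.items()
        }
        self.pos = end + 1
        return _symbol_from_attrs(attrs, f"offset {start}")


def iter_symbols(text: str) -> Iterator[SymbolRecord]:
    """Iterate symbols of an XML document via the streaming scanner."""
    scanner = SymbolScanner(text)
    while (sym := scanner.next_symbol()) is not None:
        yield sym
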