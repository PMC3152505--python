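"""HL7 CDA clinical statements: ontology, XML reader, instance-graph builder.

The clinical statement pattern covers the RIM act classes that occur inside
CDA entries — Observation, SubstanceAdministration, Supply, Procedure,
Encounter, Organizer and Act.  Each statement is translated to a small star
of individuals (Tables of the RIM translation): one individual for the act
itself, typed with its statement class, plus one filler individual per coded
attribute (classCode, moodCode, code, value), typed with the concept the
attribute carries.  SNOMED-coded attributes may hold post-coordinated
expressions, which are translated to EL + RoleGroup concept expressions.

actRelationship structure is deliberately dropped: the vocabulary-domain
rules are scoped to isolated statements, so nested statements are flattened
into independent ones and the translation is not lossless.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from . import snomed_ct
from .terminology_core import (
    ConceptExpression,
    Named,
    TBox,
    UnknownConceptError,
    expression_to_str,
    subclass_of,
    Some,
)

__all__ = [
    "SNOMED_OID",
    "ACT_CODE_OID",
    "ACT_CLASS_OID",
    "ACT_MOOD_OID",
    "STATEMENT_KINDS",
    "CdaParseError",
    "TerminologyAttachmentError",
    "CodedValue",
    "ClinicalStatement",
    "CdaDocument",
    "InstanceGraph",
    "TypingIssue",
    "StructuralCheckSpec",
    "STRUCTURAL_CHECKS",
    "build_cda_ontology",
    "attach_terminology",
    "parse_cda",
    "to_instance_graph",
    "instance_graph_to_json",
]

#: SNOMED CT code system OID.  One section of the source guideline prints the
#: corrupted form "2.16.840.1.11388.3.6.96"; the XML fragments use the real
#: OID, which is the one honoured here.
SNOMED_OID = "2.16.840.1.113883.6.96"
ACT_CODE_OID = "2.16.840.1.113883.5.4"
ACT_CLASS_OID = "2.16.840.1.113883.5.6"
ACT_MOOD_OID = "2.16.840.1.113883.5.1001"

HL7_NS = "urn:hl7-org:v3"
XSI_TYPE = "{http://www.w3.org/2001/XMLSchema-instance}type"

#: element name -> (statement kind, individual-id prefix, RIM class code)
STATEMENT_KINDS: dict[str, tuple[str, str, str]] = {
    "observation": ("Observation", "obs", "OBS"),
    "substanceAdministration": ("SubstanceAdministration", "sbadm", "SBADM"),
    "supply": ("Supply", "sply", "SPLY"),
    "procedure": ("Procedure", "proc", "PROC"),
    "encounter": ("Encounter", "enc", "ENC"),
    "organizer": ("Organizer", "org", "ORGANIZER"),
    "act": ("Act", "act", "ACT"),
}

ACT_MOOD_CODES = ("DEF", "EVN", "GOL", "INT", "PRMS", "PRP", "RQO")
X_ACT_MOOD_DOC_OBS = "x_ActMoodDocumentObservation"


class CdaParseError(ValueError):
    pass


class TerminologyAttachmentError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class CodedValue:
    """A coded attribute: a code (possibly post-coordinated) plus its system."""

    code: str
    codeSystem: str
    codeSystemName: str | None = None
    displayName: str | None = None
    dataType: str | None = None


@dataclass(frozen=True, slots=True)
class ClinicalStatement:
    kind: str
    classCode: str | None
    moodCode: str | None
    code: CodedValue | None
    value: CodedValue | None
    statementId: int
    sourcePath: str


@dataclass(frozen=True, slots=True)
class CdaDocument:
    statements: tuple[ClinicalStatement, ...]


@dataclass(frozen=True, slots=True)
class TypingIssue:
    """A code whose concept is absent from the attached terminology/ontology.

    Kept apart from guideline violations: a missing concept is a data or
    terminology gap, not a breach of the usage rules.
    """

    statementId: int
    sourcePath: str
    attribute: str
    missing: tuple[str, ...]


@dataclass
class InstanceGraph:
    individuals: list[str] = field(default_factory=list)
    type_assertions: dict[str, ConceptExpression] = field(default_factory=dict)
    role_assertions: list[tuple[str, str, str]] = field(default_factory=list)
    #: statement individual id -> attribute -> filler individual id
    fillers: dict[str, dict[str, str]] = field(default_factory=dict)
    statement_individuals: dict[int, str] = field(default_factory=dict)
    typing_issues: list[TypingIssue] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CDA ontology
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class StructuralCheckSpec:
    """Closed-world reading of the universal ('only') statement-class axioms.

    EL has no universal restriction, and under integrity-constraint semantics
    the intent of those axioms is exactly a check on what the document
    asserts: every classCode filler must be subsumed by the stated class
    code, every moodCode filler must belong to the stated mood value set.
    """

    kind: str
    required_class_code: str
    mood_value_set: str


STRUCTURAL_CHECKS: dict[str, StructuralCheckSpec] = {
    kind: StructuralCheckSpec(
        kind=kind,
        required_class_code=class_code,
        mood_value_set=X_ACT_MOOD_DOC_OBS if kind == "Observation" else "ActMood",
    )
    for kind, _prefix, class_code in STATEMENT_KINDS.values()
}


def build_cda_ontology() -> TBox:
    """The clinical-statement ontology: act classes, code systems, value sets.

    Code systems hang under ``HL7SupportedCodeSystems`` (ActClass, ActCode,
    ActMood, SNOMEDClinicalTerms), value sets under ``HL7ValueSets``.  The
    disjunctive value-set definition of ``x_ActMoodDocumentObservation`` is
    encoded in the member-to-set direction only (one SubClassOf per member),
    which keeps the TBox in EL; the set-to-member direction is never needed.
    Statement classes get the existential classCode/moodCode axioms; their
    universal counterparts live in :data:`STRUCTURAL_CHECKS`.
    """
    tbox = TBox()
    for role in ("classCode", "moodCode", "hasCode", "hasValue", "codeSystem"):
        tbox.declare_role(role)

    tbox.declare_concept("HL7SupportedCodeSystems")
    tbox.declare_concept("HL7ValueSets")
    for system in ("ActClass", "ActCode", "ActMood", "SNOMEDClinicalTerms"):
        tbox.add_axiom(subclass_of(Named(system), Named("HL7SupportedCodeSystems")))

    # ActClass: OBS SubClassOf ACT SubClassOf ActClass, and the siblings.
    tbox.add_axiom(subclass_of(Named("ACT"), Named("ActClass")))
    for _elem, (_kind, _prefix, class_code) in STATEMENT_KINDS.items():
        if class_code != "ACT":
            tbox.add_axiom(subclass_of(Named(class_code), Named("ACT")))

    tbox.add_axiom(subclass_of(Named("ASSERTION"), Named("ActCode")))

    for mood in ACT_MOOD_CODES:
        tbox.add_axiom(subclass_of(Named(mood), Named("ActMood")))
        tbox.add_axiom(subclass_of(Named(mood), Named(X_ACT_MOOD_DOC_OBS)))
    tbox.add_axiom(subclass_of(Named(X_ACT_MOOD_DOC_OBS), Named("VSUsingActMood")))
    tbox.add_axiom(subclass_of(Named("VSUsingActMood"), Named("HL7ValueSets")))

    # Statement classes with their existential classCode / moodCode axioms.
    for kind, _prefix, class_code in STATEMENT_KINDS.values():
        spec = STRUCTURAL_CHECKS[kind]
        tbox.add_axiom(subclass_of(Named(kind), Some("classCode", Named(class_code))))
        tbox.add_axiom(subclass_of(Named(kind), Some("moodCode", Named(spec.mood_value_set))))
    return tbox


def attach_terminology(
    cda_ontology: TBox, terminology: TBox, root: str | None = None
) -> TBox:
    """Merge the terminology, grafting its root under ``SNOMEDClinicalTerms``.

    The root is auto-detected as the unique concept without a stated named
    parent; pass ``root`` explicitly when the terminology has several
    top-level concepts.  Idempotent: re-attaching changes nothing.
    """
    if root is None:
        candidates = sorted(
            cid for cid in terminology.concepts if not terminology.stated_parents(cid)
        )
        if len(candidates) != 1:
            raise TerminologyAttachmentError(
                f"cannot determine a unique terminology root (candidates: {candidates}); "
                "pass root= explicitly"
            )
        root = candidates[0]
    elif root not in terminology.concepts:
        raise UnknownConceptError(root)
    merged = cda_ontology.merged_with(terminology)
    graft = subclass_of(Named(root), Named("SNOMEDClinicalTerms"))
    if graft not in merged.axioms:
        merged.axioms.append(graft)
    return merged


# ---------------------------------------------------------------------------
# CDA XML reader
# ---------------------------------------------------------------------------


def _local_name(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_coded(elem: ET.Element) -> CodedValue | None:
    code = elem.get("code")
    code_system = elem.get("codeSystem")
    if code is None or code_system is None:
        return None
    data_type = elem.get(XSI_TYPE) or elem.get("xsi:type")
    return CodedValue(
        code=code.strip(),
        codeSystem=code_system.strip(),
        codeSystemName=elem.get("codeSystemName"),
        displayName=elem.get("displayName"),
        dataType=data_type,
    )


def parse_cda(source: str) -> CdaDocument:
    """Read clinical-statement elements out of a CDA XML fragment.

    Both ``urn:hl7-org:v3``-qualified and namespace-free fragments are
    accepted; an undeclared ``xsi:`` prefix (as in informally printed
    fragments) is tolerated.  Nested statements are flattened in document
    order; text, ids, status, times and actRelationship structure are
    ignored.
    """
    try:
        root = ET.fromstring(source)
    except ET.ParseError as exc:
        if "unbound prefix" in str(exc):
            # Printed fragments routinely use xsi:type without declaring the
            # namespace; declare it on the fly and retry.
            patched = source.replace(
                "xsi:type=", "xmlns:xsi='http://www.w3.org/2001/XMLSchema-instance' xsi:type=", 1
            )
            try:
                root = ET.fromstring(patched)
            except ET.ParseError:
                raise CdaParseError(f"malformed XML: {exc}") from exc
        else:
            raise CdaParseError(f"malformed XML: {exc}") from exc

    statements: list[ClinicalStatement] = []

    def walk(elem: ET.Element, path: str) -> None:
        counters: dict[str, int] = {}
        for child in elem:
            name = _local_name(child.tag)
            counters[name] = counters.get(name, 0) + 1
            child_path = f"{path}/{name}[{counters[name]}]"
            if name in STATEMENT_KINDS:
                statements.append(_read_statement(child, child_path, len(statements) + 1))
            walk(child, child_path)

    root_name = _local_name(root.tag)
    root_path = f"/{root_name}[1]"
    if root_name in STATEMENT_KINDS:
        statements.append(_read_statement(root, root_path, 1))
    walk(root, root_path)
    return CdaDocument(statements=tuple(statements))


def _read_statement(elem: ET.Element, path: str, ordinal: int) -> ClinicalStatement:
    kind, _prefix, _cc = STATEMENT_KINDS[_local_name(elem.tag)]
    code = value = None
    for child in elem:
        name = _local_name(child.tag)
        if name == "code" and code is None:
            code = _read_coded(child)
        elif name == "value" and value is None:
            value = _read_coded(child)
    return ClinicalStatement(
        kind=kind,
        classCode=elem.get("classCode"),
        moodCode=elem.get("moodCode"),
        code=code,
        value=value,
        statementId=ordinal,
        sourcePath=path,
    )


# ---------------------------------------------------------------------------
# Instance graph
# ---------------------------------------------------------------------------


def _code_concept(coded: CodedValue, tbox: TBox) -> tuple[ConceptExpression, tuple[str, ...]]:
    """Concept expression for a coded attribute, plus any missing concept ids."""
    if coded.codeSystem == SNOMED_OID:
        expr = snomed_ct.to_concept_expression(snomed_ct.parse_expression(coded.code))
    else:
        expr = Named(coded.code)
    missing = tuple(sorted(c for c in expr.named_concepts() if c not in tbox.concepts))
    return expr, missing


def to_instance_graph(doc: CdaDocument, tbox: TBox, strict: bool = False) -> InstanceGraph:
    """Translate a parsed document into typed individuals and role assertions.

    Per statement: one act individual typed with its statement class, one
    filler individual per present coded attribute, typed with that
    attribute's concept (compositional-grammar SNOMED codes expanded to
    concept expressions).  Coded fillers carry a ``codeSystem`` literal
    assertion.  Codes whose concepts are absent from the attached terminology
    become :class:`TypingIssue` entries (or errors under ``strict``).
    """
    graph = InstanceGraph()
    prefix_of = {kind: prefix for kind, prefix, _cc in STATEMENT_KINDS.values()}
    for stmt in doc.statements:
        ind = f"{prefix_of[stmt.kind]}{stmt.statementId}"
        graph.individuals.append(ind)
        graph.type_assertions[ind] = Named(stmt.kind)
        graph.statement_individuals[stmt.statementId] = ind
        graph.fillers[ind] = {}

        def add_filler(attribute: str, role: str, filler_id: str,
                       expr: ConceptExpression, missing: tuple[str, ...] = (),
                       code_system: str | None = None) -> None:
            if missing:
                if strict:
                    raise UnknownConceptError(missing[0])
                graph.typing_issues.append(
                    TypingIssue(stmt.statementId, stmt.sourcePath, attribute, missing)
                )
                return
            graph.individuals.append(filler_id)
            graph.type_assertions[filler_id] = expr
            graph.role_assertions.append((ind, role, filler_id))
            graph.fillers[ind][attribute] = filler_id
            if code_system is not None:
                graph.role_assertions.append((filler_id, "codeSystem", code_system))

        if stmt.classCode:
            missing = () if stmt.classCode in tbox.concepts else (stmt.classCode,)
            add_filler("classCode", "classCode", f"class_code_{ind}",
                       Named(stmt.classCode), missing)
        if stmt.moodCode:
            missing = () if stmt.moodCode in tbox.concepts else (stmt.moodCode,)
            add_filler("moodCode", "moodCode", f"mood_code_{ind}",
                       Named(stmt.moodCode), missing)
        if stmt.code is not None:
            expr, missing = _code_concept(stmt.code, tbox)
            add_filler("code", "hasCode", f"code_{ind}", expr, missing,
                       code_system=stmt.code.codeSystem)
        if stmt.value is not None:
            expr, missing = _code_concept(stmt.value, tbox)
            add_filler("value", "hasValue", f"value_{ind}", expr, missing,
                       code_system=stmt.value.codeSystem)
    return graph


def instance_graph_to_json(graph: InstanceGraph) -> str:
    """Deterministic JSON serialization of the instance graph."""
    payload = {
        "individuals": list(graph.individuals),
        "types": {ind: expression_to_str(expr) for ind, expr in graph.type_assertions.items()},
        "roleAssertions": [
            {"subject": s, "role": r, "object": o} for s, r, o in graph.role_assertions
        ],
        "typingIssues": [
            {
                "statementId": t.statementId,
                "sourcePath": t.sourcePath,
                "attribute": t.attribute,
                "missing": list(t.missing),
            }
            for t in graph.typing_issues
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)
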