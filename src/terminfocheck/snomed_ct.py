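"""SNOMED CT support: compositional grammar, stated relationships, fixture.

Covers the post-coordination subset actually used in CDA attributes: focus
concepts joined with ``+``, a ``:`` refinement section with ``attribute=value``
pairs separated by ``,``, attribute groups in ``{...}``, and parenthesized
nested expressions as values.  Embedded ``|label|`` tokens are stored for
display but never used for identity.

Stated is-a rows translate to SubClassOf axioms; attribute rows translate to
``source SubClassOf RoleGroup some (type some destination)``, with rows that
share a non-zero relationship group sharing one RoleGroup over a conjunctive
filler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .terminology_core import (
    Axiom,
    ConceptExpression,
    Named,
    TBox,
    make_and,
    role_group,
    Some,
    subclass_of,
)

__all__ = [
    "SNOMED_ROOT",
    "ExpressionParseError",
    "Concept",
    "Refinement",
    "PostcoordinatedExpression",
    "parse_expression",
    "serialize_expression",
    "to_concept_expression",
    "StatedRelationshipRow",
    "IS_A_TYPE_ID",
    "stated_relationships_to_axioms",
    "read_rf2_stated_relationships",
    "generate_fixture_terminology",
]

#: 138875005 |SNOMED CT Concept (SNOMED RT+CTV3)| — the hierarchy root.
SNOMED_ROOT = "138875005"

#: 116680003 |Is a (attribute)| — the RF2 type id of is-a rows.
IS_A_TYPE_ID = "116680003"


class ExpressionParseError(ValueError):
    """Malformed compositional-grammar text; carries the character offset."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"offset {offset}: {message}")


@dataclass(frozen=True, slots=True)
class Concept:
    identifier: str
    label: str | None = None


@dataclass(frozen=True, slots=True)
class Refinement:
    attribute: Concept
    value: "PostcoordinatedExpression"


@dataclass(frozen=True, slots=True)
class PostcoordinatedExpression:
    focus: tuple[Concept, ...]
    refinements: tuple[Refinement, ...] = ()
    groups: tuple[tuple[Refinement, ...], ...] = ()

    def normalized(self) -> "PostcoordinatedExpression":
        """Canonical order: focus and refinements sorted by identifier."""
        return PostcoordinatedExpression(
            focus=tuple(sorted(self.focus, key=lambda c: c.identifier)),
            refinements=tuple(
                sorted(
                    (Refinement(r.attribute, r.value.normalized()) for r in self.refinements),
                    key=lambda r: (r.attribute.identifier, serialize_expression(r.value)),
                )
            ),
            groups=tuple(
                sorted(
                    (
                        tuple(
                            sorted(
                                (Refinement(r.attribute, r.value.normalized()) for r in grp),
                                key=lambda r: (r.attribute.identifier, serialize_expression(r.value)),
                            )
                        )
                        for grp in self.groups
                    ),
                    key=lambda grp: tuple(
                        (r.attribute.identifier, serialize_expression(r.value)) for r in grp
                    ),
                )
            ),
        )


# ---------------------------------------------------------------------------
# Parser (recursive descent with character offsets)
# ---------------------------------------------------------------------------


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, char: str) -> None:
        if self.peek() != char:
            raise ExpressionParseError(f"expected {char!r}", self.pos)
        self.pos += 1

    def concept(self) -> Concept:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isalnum() or self.text[self.pos] in "._-"
        ):
            self.pos += 1
        ident = self.text[start : self.pos].strip()
        if not ident:
            raise ExpressionParseError("expected a concept identifier", start)
        label = None
        self.skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == "|":
            bar = self.pos
            end = self.text.find("|", self.pos + 1)
            if end < 0:
                raise ExpressionParseError("unbalanced '|'", bar)
            label = self.text[self.pos + 1 : end].strip() or None
            self.pos = end + 1
        return Concept(ident, label)

    def value(self) -> PostcoordinatedExpression:
        if self.peek() == "(":
            self.expect("(")
            expr = self.expression()
            self.expect(")")
            return expr
        return PostcoordinatedExpression(focus=(self.concept(),))

    def refinement(self) -> Refinement:
        attribute = self.concept()
        if self.peek() != "=":
            raise ExpressionParseError("expected '=' after attribute", self.pos)
        self.pos += 1
        return Refinement(attribute, self.value())

    def group(self) -> tuple[Refinement, ...]:
        self.expect("{")
        refs = [self.refinement()]
        while self.peek() == ",":
            self.pos += 1
            refs.append(self.refinement())
        self.expect("}")
        return tuple(refs)

    def expression(self) -> PostcoordinatedExpression:
        focus = [self.concept()]
        while self.peek() == "+":
            self.pos += 1
            focus.append(self.concept())
        refinements: list[Refinement] = []
        groups: list[tuple[Refinement, ...]] = []
        if self.peek() == ":":
            self.pos += 1
            while True:
                if self.peek() == "{":
                    groups.append(self.group())
                else:
                    refinements.append(self.refinement())
                if self.peek() == ",":
                    self.pos += 1
                    continue
                break
        return PostcoordinatedExpression(tuple(focus), tuple(refinements), tuple(groups))


def parse_expression(text: str) -> PostcoordinatedExpression:
    """Parse compositional-grammar text into a post-coordinated expression."""
    if not text or not text.strip():
        raise ExpressionParseError("empty expression", 0)
    scanner = _Scanner(text)
    expr = scanner.expression()
    scanner.skip_ws()
    if scanner.pos != len(text):
        raise ExpressionParseError(
            f"unexpected trailing input {text[scanner.pos:]!r}", scanner.pos
        )
    return expr


def _concept_text(c: Concept) -> str:
    return f"{c.identifier}|{c.label}|" if c.label else c.identifier


def _value_text(v: PostcoordinatedExpression) -> str:
    if not v.refinements and not v.groups and len(v.focus) == 1:
        return _concept_text(v.focus[0])
    return f"({serialize_expression(v)})"


def serialize_expression(expr: PostcoordinatedExpression) -> str:
    """Write an expression back to compositional-grammar text."""
    out = "+".join(_concept_text(c) for c in expr.focus)
    parts = [f"{_concept_text(r.attribute)}={_value_text(r.value)}" for r in expr.refinements]
    parts += [
        "{" + ",".join(f"{_concept_text(r.attribute)}={_value_text(r.value)}" for r in grp) + "}"
        for grp in expr.groups
    ]
    if parts:
        out += ":" + ",".join(parts)
    return out


def to_concept_expression(expr: PostcoordinatedExpression) -> ConceptExpression:
    """Translate to the EL + RoleGroup form used by the terminology layer.

    Each ungrouped refinement becomes its own
    ``RoleGroup some (attribute some value)`` conjunct; a ``{...}`` group
    becomes one RoleGroup over the conjunction of its restrictions.  A single
    focus concept with no refinements stays a plain named concept.
    """
    conjuncts: list[ConceptExpression] = [Named(c.identifier) for c in expr.focus]
    for ref in expr.refinements:
        conjuncts.append(
            role_group(Some(ref.attribute.identifier, to_concept_expression(ref.value)))
        )
    for grp in expr.groups:
        inner = make_and(
            Some(r.attribute.identifier, to_concept_expression(r.value)) for r in grp
        )
        conjuncts.append(role_group(inner))
    return make_and(conjuncts)


# ---------------------------------------------------------------------------
# Stated relationships
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class StatedRelationshipRow:
    source: str
    type: str
    destination: str
    group: int = 0


def stated_relationships_to_axioms(rows: list[StatedRelationshipRow]) -> list[Axiom]:
    """Translate stated-relationship rows to SubClassOf axioms.

    Is-a rows map directly; attribute rows map to RoleGroup-wrapped
    existentials.  Rows of one source sharing a non-zero group number share a
    single RoleGroup with a conjunctive filler.
    """
    axioms: list[Axiom] = []
    grouped: dict[tuple[str, int], list[StatedRelationshipRow]] = {}
    for row in rows:
        if row.group < 0:
            raise ValueError(f"negative relationship group on {row.source}")
        if row.type in (IS_A_TYPE_ID, "IsA"):
            axioms.append(subclass_of(Named(row.source), Named(row.destination)))
        elif row.group == 0:
            axioms.append(
                subclass_of(
                    Named(row.source), role_group(Some(row.type, Named(row.destination)))
                )
            )
        else:
            grouped.setdefault((row.source, row.group), []).append(row)
    for (source, _g), members in sorted(grouped.items()):
        filler = make_and(Some(m.type, Named(m.destination)) for m in members)
        axioms.append(subclass_of(Named(source), role_group(filler)))
    return axioms


def read_rf2_stated_relationships(source: str) -> list[StatedRelationshipRow]:
    """Read an RF2-style stated-relationship snapshot (tab-separated).

    Accepts either full RF2 snapshot columns (with header naming sourceId,
    destinationId, relationshipGroup, typeId) or bare 4-column
    ``source  destination  type  group`` rows.
    """
    lines = [ln for ln in source.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    rows: list[StatedRelationshipRow] = []
    if "sourceId" in header:
        idx = {name: header.index(name) for name in
               ("sourceId", "destinationId", "relationshipGroup", "typeId")}
        active_idx = header.index("active") if "active" in header else None
        for ln in lines[1:]:
            cols = ln.split("\t")
            if active_idx is not None and cols[active_idx] == "0":
                continue
            rows.append(
                StatedRelationshipRow(
                    source=cols[idx["sourceId"]],
                    type=cols[idx["typeId"]],
                    destination=cols[idx["destinationId"]],
                    group=int(cols[idx["relationshipGroup"]]),
                )
            )
        return rows
    for ln in lines:
        cols = ln.split("\t")
        if len(cols) != 4:
            raise ValueError(f"expected 4 tab-separated fields, got {len(cols)}: {ln!r}")
        rows.append(StatedRelationshipRow(cols[0], cols[2], cols[1], int(cols[3])))
    return rows


# ---------------------------------------------------------------------------
# Fixture terminology
# ---------------------------------------------------------------------------

#: (id, label, parent id) — is-a rows of the built-in SNOMED fragment.
_FIXTURE_ISA: tuple[tuple[str, str, str], ...] = (
    ("404684003", "Clinical finding", SNOMED_ROOT),
    ("413350009", "Finding with explicit context", "404684003"),
    ("272379006", "Event", SNOMED_ROOT),
    ("363787002", "Observable entity", SNOMED_ROOT),
    ("71388002", "Procedure", SNOMED_ROOT),
    ("386053000", "Evaluation procedure", "71388002"),
    ("362981000", "Qualifier value", SNOMED_ROOT),
    ("281296001", "Result comments", "362981000"),
    ("260245000", "Findings values", "362981000"),
    ("105590001", "Substance", SNOMED_ROOT),
    ("64572001", "Condition", "404684003"),
    ("37796009", "Migraine", "64572001"),
    # Placed under finding-with-explicit-context so that the manifestation
    # observation of the worked example stays conformant when the
    # clinical-finding disjunct is dropped from the Observation.value rule.
    ("247472004", "Hives", "413350009"),
    ("106190000", "Allergy", "404684003"),
    ("91936005", "Allergy to penicillin", "106190000"),
    ("373270004", "Penicillin - class of antibiotic", "105590001"),
    ("Aminopenicillin", "Aminopenicillin", "373270004"),
    ("372687004", "Amoxicillin", "Aminopenicillin"),
    ("350162003", "Oral form Amoxicillin", "372687004"),
    ("433181003", "Amoxicillin 775 mg extended release tablet", "350162003"),
)

#: (source, role, destination) attribute rows.
_FIXTURE_ATTRS: tuple[tuple[str, str, str], ...] = (
    ("91936005", "246075003", "373270004"),   # allergy to penicillin: causative agent
    ("433181003", "127489000", "372687004"),  # amoxicillin tablet: has active ingredient
)

_FIXTURE_ROLES: tuple[tuple[str, str], ...] = (
    ("246075003", "Causative agent"),
    ("127489000", "Has active ingredient"),
)


def generate_fixture_terminology() -> TBox:
    """The built-in tailored SNOMED fragment used by the worked examples.

    A deterministic miniature of the hierarchy the validation rules touch:
    the clinical-finding / event / observable-entity / evaluation-procedure /
    result-comments / findings-values subtrees, the Condition–Migraine chain,
    and the penicillin/amoxicillin chains with their causative-agent and
    active-ingredient attributes.  Bit-identical across runs.
    """
    tbox = TBox()
    tbox.declare_concept(SNOMED_ROOT, "SNOMED CT Concept")
    for rid, rlabel in _FIXTURE_ROLES:
        tbox.declare_role(rid, rlabel)
    for cid, label, parent in _FIXTURE_ISA:
        tbox.declare_concept(cid, label)
        tbox.add_axiom(subclass_of(Named(cid), Named(parent)))
    for source, role, destination in _FIXTURE_ATTRS:
        tbox.add_axiom(subclass_of(Named(source), role_group(Some(role, Named(destination)))))
    return tbox
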