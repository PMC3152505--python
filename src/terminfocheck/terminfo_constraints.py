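"""Vocabulary-domain constraints: guarded allowed-value-set rules.

Each rule targets one coded attribute (``code`` or ``value``) of one clinical
statement kind, applies only when the attribute carries a SNOMED CT
expression, optionally guards on the statement's code being (or not being)
the HL7 ActCode ``ASSERTION``, and allows a disjunction of ``<<root``
descendant-or-self value sets.

The packaged default library holds the eight rules of the guideline's §5
vocabulary-domain set, grouped into five classes.  The three Observation
rules are printed in the guideline and are reproduced here; the value-set
roots of the remaining five are distributed only in the guideline's
machine-readable annex, so they ship as explicit permissive placeholders
(the SNOMED root) and are meant to be overridden via ``load_constraints``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cda import ACT_CODE_OID, SNOMED_OID, ClinicalStatement, STATEMENT_KINDS
from .snomed_ct import SNOMED_ROOT

__all__ = [
    "GUARDS",
    "GROUPS",
    "ValueSetRef",
    "IntegrityConstraint",
    "ConstraintLibrary",
    "ConstraintConfigError",
    "default_library",
    "load_constraints",
    "applicable",
]

GUARDS = ("always", "code_is_assertion", "code_is_not_assertion")
GROUPS = ("Observation", "Entity", "Procedure", "SubstanceAdministration", "Organizer")
_KINDS = tuple(kind for kind, _p, _c in STATEMENT_KINDS.values())
_ATTRIBUTES = ("code", "value")


class ConstraintConfigError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class ValueSetRef:
    """``<<root``: the concept ``root`` and everything subsumed by it."""

    root: str
    operator: str = "<<"

    def __str__(self) -> str:
        return f"{self.operator}{self.root}"


@dataclass(frozen=True, slots=True)
class IntegrityConstraint:
    id: str
    group: str
    targetKind: str
    targetAttribute: str  # "code" | "value"
    guard: str  # one of GUARDS
    allowed: tuple[ValueSetRef, ...]
    narrative: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConstraintConfigError(f"{self.id}: unknown group {self.group!r}")
        if self.targetKind not in _KINDS:
            raise ConstraintConfigError(f"{self.id}: unknown kind {self.targetKind!r}")
        if self.targetAttribute not in _ATTRIBUTES:
            raise ConstraintConfigError(
                f"{self.id}: target_attribute must be 'code' or 'value'"
            )
        if self.guard not in GUARDS:
            raise ConstraintConfigError(f"{self.id}: unknown guard {self.guard!r}")
        if not self.allowed:
            raise ConstraintConfigError(f"{self.id}: allowed value sets must be non-empty")


@dataclass(frozen=True)
class ConstraintLibrary:
    constraints: tuple[IntegrityConstraint, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.constraints]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConstraintConfigError(f"duplicate constraint ids: {dupes}")

    @property
    def groups(self) -> dict[str, tuple[IntegrityConstraint, ...]]:
        out: dict[str, list[IntegrityConstraint]] = {}
        for c in self.constraints:
            out.setdefault(c.group, []).append(c)
        return {g: tuple(cs) for g, cs in out.items()}

    def get(self, constraint_id: str) -> IntegrityConstraint:
        for c in self.constraints:
            if c.id == constraint_id:
                return c
        raise KeyError(constraint_id)


def _vs(*roots: str) -> tuple[ValueSetRef, ...]:
    return tuple(ValueSetRef(r) for r in roots)


_PLACEHOLDER_NOTE = (
    "Allowed roots not printed in the guideline's main text; permissive "
    "placeholder (SNOMED root) — override via configuration."
)


def default_library() -> ConstraintLibrary:
    """The packaged library: 8 constraints in 5 groups, 3 for Observations.

    The Supply rule is filed under the SubstanceAdministration group, the
    minimal layout consistent with the published counts (8 rules, 5 groups,
    3 Observation rules).
    """
    return ConstraintLibrary(
        constraints=(
            IntegrityConstraint(
                id="OBS-1",
                group="Observation",
                targetKind="Observation",
                targetAttribute="value",
                guard="code_is_assertion",
                allowed=_vs("404684003", "413350009", "272379006"),
                narrative=(
                    "Where Observation.code = ASSERTION, Observation.value must be "
                    "<<404684003 |clinical finding| OR <<413350009 |finding with "
                    "explicit context| OR <<272379006 |event|."
                ),
            ),
            IntegrityConstraint(
                id="OBS-2",
                group="Observation",
                targetKind="Observation",
                targetAttribute="code",
                guard="code_is_not_assertion",
                allowed=_vs("386053000", "363787002"),
                narrative=(
                    "A SNOMED-coded Observation.code (other than ASSERTION) must be "
                    "<<386053000 |evaluation procedure| OR <<363787002 |observable "
                    "entity|."
                ),
            ),
            IntegrityConstraint(
                id="OBS-3",
                group="Observation",
                targetKind="Observation",
                targetAttribute="value",
                guard="code_is_not_assertion",
                allowed=_vs("281296001", "260245000"),
                narrative=(
                    "Where Observation.code is not ASSERTION, a SNOMED-coded "
                    "Observation.value must be <<281296001 |result comments| OR "
                    "<<260245000 |findings values|."
                ),
            ),
            IntegrityConstraint(
                id="ENT-1",
                group="Entity",
                targetKind="Act",
                targetAttribute="code",
                guard="always",
                allowed=_vs(SNOMED_ROOT),
                narrative="Entity code value set. " + _PLACEHOLDER_NOTE,
            ),
            IntegrityConstraint(
                id="PROC-1",
                group="Procedure",
                targetKind="Procedure",
                targetAttribute="code",
                guard="always",
                allowed=_vs(SNOMED_ROOT),
                narrative="Procedure code value set. " + _PLACEHOLDER_NOTE,
            ),
            IntegrityConstraint(
                id="SBADM-1",
                group="SubstanceAdministration",
                targetKind="SubstanceAdministration",
                targetAttribute="code",
                guard="always",
                allowed=_vs(SNOMED_ROOT),
                narrative="SubstanceAdministration code value set. " + _PLACEHOLDER_NOTE,
            ),
            IntegrityConstraint(
                id="SPLY-1",
                group="SubstanceAdministration",
                targetKind="Supply",
                targetAttribute="code",
                guard="always",
                allowed=_vs(SNOMED_ROOT),
                narrative="Supply code value set. " + _PLACEHOLDER_NOTE,
            ),
            IntegrityConstraint(
                id="ORG-1",
                group="Organizer",
                targetKind="Organizer",
                targetAttribute="code",
                guard="always",
                allowed=_vs(SNOMED_ROOT),
                narrative="Organizer code value set. " + _PLACEHOLDER_NOTE,
            ),
        )
    )


_ALLOWED_FIELDS = {
    "id", "group", "target_kind", "target_attribute", "guard", "allowed", "narrative",
}


def _constraint_from_dict(entry: dict, path: str) -> IntegrityConstraint:
    if not isinstance(entry, dict):
        raise ConstraintConfigError(f"{path}: expected an object")
    unknown = set(entry) - _ALLOWED_FIELDS
    if unknown:
        raise ConstraintConfigError(f"{path}: unknown fields {sorted(unknown)}")
    missing = {"id", "group", "target_kind", "target_attribute", "allowed"} - set(entry)
    if missing:
        raise ConstraintConfigError(f"{path}: missing fields {sorted(missing)}")
    allowed_raw = entry["allowed"]
    if not isinstance(allowed_raw, list) or not allowed_raw:
        raise ConstraintConfigError(f"{path}.allowed: expected a non-empty list")
    allowed: list[ValueSetRef] = []
    for i, ref in enumerate(allowed_raw):
        if not isinstance(ref, str) or not ref.startswith("<<") or len(ref) <= 2:
            raise ConstraintConfigError(
                f"{path}.allowed[{i}]: expected '<<conceptId', got {ref!r}"
            )
        allowed.append(ValueSetRef(ref[2:].strip()))
    try:
        return IntegrityConstraint(
            id=str(entry["id"]),
            group=str(entry["group"]),
            targetKind=str(entry["target_kind"]),
            targetAttribute=str(entry["target_attribute"]),
            guard=str(entry.get("guard", "always")),
            allowed=tuple(allowed),
            narrative=str(entry.get("narrative", "")),
        )
    except ConstraintConfigError as exc:
        raise ConstraintConfigError(f"{path}: {exc}") from exc


def load_constraints(config_text: str) -> ConstraintLibrary:
    """Load a JSON constraint config, overriding/extending the default library.

    Schema: ``{"constraints": [{id, group, target_kind, target_attribute,
    guard?, allowed: ["<<conceptId", ...], narrative?}, ...],
    "extends_default": bool?}``.  With ``extends_default`` true (the
    default), entries whose id matches a packaged rule replace it and new ids
    are appended; ids may not repeat within the config.  An empty config
    yields the default library unchanged.
    """
    text = config_text.strip()
    if not text:
        return default_library()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConstraintConfigError(f"config is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConstraintConfigError("top level: expected an object")
    unknown = set(data) - {"constraints", "extends_default"}
    if unknown:
        raise ConstraintConfigError(f"top level: unknown fields {sorted(unknown)}")
    entries = data.get("constraints", [])
    if not isinstance(entries, list):
        raise ConstraintConfigError("constraints: expected a list")
    parsed = [
        _constraint_from_dict(entry, f"constraints[{i}]") for i, entry in enumerate(entries)
    ]
    ids = [c.id for c in parsed]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConstraintConfigError(f"duplicate constraint ids in config: {dupes}")
    if not data.get("extends_default", True):
        return ConstraintLibrary(constraints=tuple(parsed))
    by_id = {c.id: c for c in parsed}
    merged = [by_id.pop(c.id, c) for c in default_library().constraints]
    merged.extend(by_id[c.id] for c in parsed if c.id in by_id)
    return ConstraintLibrary(constraints=tuple(merged))


def _code_is_assertion(statement: ClinicalStatement) -> bool:
    return (
        statement.code is not None
        and statement.code.code == "ASSERTION"
        and statement.code.codeSystem == ACT_CODE_OID
    )


def applicable(constraint: IntegrityConstraint, statement: ClinicalStatement) -> bool:
    """Does this rule bind this statement?

    Requires a kind match, the target attribute to be present, that
    attribute to be SNOMED-coded (the rules only govern SNOMED CT usage),
    and the ASSERTION guard to hold.  Pure function of the statement —
    the rules are scoped to isolated statements by construction.
    """
    if statement.kind != constraint.targetKind:
        return False
    target = statement.code if constraint.targetAttribute == "code" else statement.value
    if target is None or target.codeSystem != SNOMED_OID:
        return False
    if constraint.guard == "code_is_assertion":
        return _code_is_assertion(statement)
    if constraint.guard == "code_is_not_assertion":
        return not _code_is_assertion(statement)
    return True
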