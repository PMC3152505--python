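"""Integrity-constraint validation of CDA documents.

The evaluation intertwines two semantics deliberately: subsumption over the
attached terminology is open-world (entailment via the EL reasoner), while
constraint satisfaction is closed-world — a statement satisfies a rule only
if the expression it actually asserts is entailed to fall inside one of the
allowed value sets.  Nothing is ever assumed about a filler beyond what the
document states plus what the terminology entails about it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cda import (
    STRUCTURAL_CHECKS,
    CdaDocument,
    ClinicalStatement,
    InstanceGraph,
    to_instance_graph,
)
from .terminfo_constraints import (
    ConstraintLibrary,
    GROUPS,
    IntegrityConstraint,
    ValueSetRef,
    applicable,
)
from .terminology_core import (
    Named,
    SubsumptionIndex,
    TBox,
    expression_to_str,
    is_subsumed,
)

__all__ = [
    "Violation",
    "StructuralFinding",
    "ValidationReport",
    "check_constraint",
    "validate",
    "summarize",
    "render_report",
    "report_to_dict",
    "report_from_dict",
]


@dataclass(frozen=True, slots=True)
class Violation:
    constraintId: str
    statementId: int
    sourcePath: str
    attribute: str
    found: str  # serialized expression actually asserted, never a repair
    allowed: tuple[ValueSetRef, ...]
    message: str


@dataclass(frozen=True, slots=True)
class StructuralFinding:
    """Result of a closed-world classCode/moodCode membership check."""

    statementId: int
    sourcePath: str
    check: str  # "classCode" | "moodCode"
    ok: bool
    message: str


@dataclass(frozen=True)
class ValidationReport:
    documentRef: str
    violations: tuple[Violation, ...]
    structuralFindings: tuple[StructuralFinding, ...]
    typingIssues: tuple[dict, ...]
    #: per constraint group: statements with an applicable rule / violated ones
    counters: dict[str, dict[str, int]] = field(default_factory=dict)


def check_constraint(
    constraint: IntegrityConstraint,
    statement: ClinicalStatement,
    graph: InstanceGraph,
    tbox: TBox,
    index: SubsumptionIndex,
) -> Violation | None:
    """Evaluate one applicable rule against one statement.

    The target filler's asserted expression must be entailed to lie under at
    least one allowed root; otherwise the rule is violated.  Satisfaction is
    never achieved by inventing types the document does not assert.
    """
    ind = graph.statement_individuals[statement.statementId]
    filler = graph.fillers[ind].get(constraint.targetAttribute)
    if filler is None:
        # Filler suppressed by a typing issue: surfaced separately, not here.
        return None
    expr = graph.type_assertions[filler]
    for ref in constraint.allowed:
        if is_subsumed(expr, Named(ref.root), tbox, index):
            return None
    found = expression_to_str(expr)
    allowed_text = " OR ".join(str(ref) for ref in constraint.allowed)
    return Violation(
        constraintId=constraint.id,
        statementId=statement.statementId,
        sourcePath=statement.sourcePath,
        attribute=constraint.targetAttribute,
        found=found,
        allowed=constraint.allowed,
        message=(
            f"{constraint.targetKind}.{constraint.targetAttribute} is {found}, "
            f"which is not subsumed by any of {allowed_text}. {constraint.narrative}"
        ),
    )


def _structural_findings(
    statement: ClinicalStatement,
    graph: InstanceGraph,
    tbox: TBox,
    index: SubsumptionIndex,
) -> list[StructuralFinding]:
    spec = STRUCTURAL_CHECKS[statement.kind]
    ind = graph.statement_individuals[statement.statementId]
    out: list[StructuralFinding] = []
    for check, expected in (
        ("classCode", spec.required_class_code),
        ("moodCode", spec.mood_value_set),
    ):
        filler = graph.fillers[ind].get(check)
        if filler is None:
            out.append(
                StructuralFinding(
                    statement.statementId, statement.sourcePath, check, False,
                    f"{statement.kind} has no {check}; expected one of type {expected}",
                )
            )
            continue
        expr = graph.type_assertions[filler]
        ok = is_subsumed(expr, Named(expected), tbox, index)
        detail = "is" if ok else "is not"
        out.append(
            StructuralFinding(
                statement.statementId, statement.sourcePath, check, ok,
                f"{statement.kind}.{check} {expression_to_str(expr)} {detail} of type {expected}",
            )
        )
    return out


def validate(
    doc: CdaDocument,
    library: ConstraintLibrary,
    tbox: TBox,
    index: SubsumptionIndex,
    document_ref: str = "",
    strict: bool = False,
) -> ValidationReport:
    """Check every statement against every applicable rule.

    ``tbox``/``index`` are the merged CDA-plus-terminology ontology and its
    classification.  Structural classCode/moodCode checks are evaluated for
    every statement; their results are reported apart from the
    vocabulary-domain violations.  Ordering is deterministic: statements in
    document order, constraints in library order.
    """
    graph = to_instance_graph(doc, tbox, strict=strict)
    violations: list[Violation] = []
    findings: list[StructuralFinding] = []
    counters = {g: {"usages": 0, "violated": 0} for g in GROUPS}

    for stmt in doc.statements:
        findings.extend(_structural_findings(stmt, graph, tbox, index))
        groups_applicable: set[str] = set()
        groups_violated: set[str] = set()
        for constraint in library.constraints:
            if not applicable(constraint, stmt):
                continue
            groups_applicable.add(constraint.group)
            violation = check_constraint(constraint, stmt, graph, tbox, index)
            if violation is not None:
                violations.append(violation)
                groups_violated.add(constraint.group)
        for g in groups_applicable:
            counters[g]["usages"] += 1
        for g in groups_violated:
            counters[g]["violated"] += 1

    violations.sort(key=lambda v: (v.statementId, v.constraintId))
    return ValidationReport(
        documentRef=document_ref,
        violations=tuple(violations),
        structuralFindings=tuple(findings),
        typingIssues=tuple(
            {
                "statementId": t.statementId,
                "sourcePath": t.sourcePath,
                "attribute": t.attribute,
                "missing": list(t.missing),
            }
            for t in graph.typing_issues
        ),
        counters=counters,
    )


def _percent(violated: int, usages: int) -> int:
    """Nearest-integer percentage, half rounded up; 0 when there are no usages."""
    if usages == 0:
        return 0
    return int((100 * violated / usages) + 0.5)


def summarize(reports: list[ValidationReport]) -> list[dict]:
    """Per-group tally across reports: usages, violated statements, percent.

    A statement counts once per group even when several of the group's rules
    flag it.
    """
    totals = {g: {"usages": 0, "violated": 0} for g in GROUPS}
    for report in reports:
        for g, counts in report.counters.items():
            totals[g]["usages"] += counts["usages"]
            totals[g]["violated"] += counts["violated"]
    return [
        {
            "group": g,
            "usages": totals[g]["usages"],
            "violated": totals[g]["violated"],
            "percent": _percent(totals[g]["violated"], totals[g]["usages"]),
        }
        for g in GROUPS
    ]


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def report_to_dict(report: ValidationReport) -> dict:
    return {
        "documentRef": report.documentRef,
        "violations": [
            {
                "constraintId": v.constraintId,
                "statementId": v.statementId,
                "sourcePath": v.sourcePath,
                "attribute": v.attribute,
                "found": v.found,
                "allowed": [str(ref) for ref in v.allowed],
                "message": v.message,
            }
            for v in report.violations
        ],
        "structuralFindings": [
            {
                "statementId": f.statementId,
                "sourcePath": f.sourcePath,
                "check": f.check,
                "ok": f.ok,
                "message": f.message,
            }
            for f in report.structuralFindings
        ],
        "typingIssues": list(report.typingIssues),
        "counters": report.counters,
    }


def report_from_dict(data: dict) -> ValidationReport:
    return ValidationReport(
        documentRef=data["documentRef"],
        violations=tuple(
            Violation(
                constraintId=v["constraintId"],
                statementId=v["statementId"],
                sourcePath=v["sourcePath"],
                attribute=v["attribute"],
                found=v["found"],
                allowed=tuple(ValueSetRef(ref[2:]) for ref in v["allowed"]),
                message=v["message"],
            )
            for v in data["violations"]
        ),
        structuralFindings=tuple(
            StructuralFinding(
                statementId=f["statementId"],
                sourcePath=f["sourcePath"],
                check=f["check"],
                ok=f["ok"],
                message=f["message"],
            )
            for f in data["structuralFindings"]
        ),
        typingIssues=tuple(data["typingIssues"]),
        counters=data["counters"],
    )


def render_report(report: ValidationReport, format: str = "text") -> str:
    """Render for terminals (``text``) or machines (``structured`` JSON)."""
    if format == "structured":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown report format: {format!r}")
    lines: list[str] = []
    ref = report.documentRef or "<document>"
    if not report.violations:
        lines.append(f"{ref}: no violations")
    else:
        lines.append(f"{ref}: {len(report.violations)} violation(s)")
        for v in report.violations:
            allowed_text = " OR ".join(str(ref_) for ref_ in v.allowed)
            lines.append(f"  [{v.constraintId}] statement {v.statementId} ({v.sourcePath})")
            lines.append(f"    found:   {v.found}")
            lines.append(f"    allowed: {allowed_text}")
            lines.append(f"    {v.message}")
    failures = [f for f in report.structuralFindings if not f.ok]
    for f in failures:
        lines.append(f"  [structural:{f.check}] statement {f.statementId}: {f.message}")
    for issue in report.typingIssues:
        lines.append(
            f"  [typing] statement {issue['statementId']} {issue['attribute']}: "
            f"unknown concept(s) {', '.join(issue['missing'])}"
        )
    return "\n".join(lines) + "\n"
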