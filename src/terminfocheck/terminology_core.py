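"""EL-style terminology: concept expressions, axioms, and subsumption reasoning.

The terminology layer represents a description-logic TBox in the EL fragment
(named concepts, conjunction, existential restriction) plus the reserved
``RoleGroup`` role used by the SNOMED CT stated-relationship translation.
Subsumption between possibly complex concept expressions is decided by
rewriting the TBox into EL normal form and saturating the standard EL
completion rules to a fixpoint.  EL classification is polynomial and the
computed relation is sound and complete for this fragment.

Design notes
------------
* ``RoleGroup`` is an ordinary role: two expressions that differ only in
  RoleGroup nesting are *not* equated.
* Fresh names introduced by normalization or by complex-expression queries
  are namespaced ``__n0``/``__q0`` and never leak into query results.
* All fixpoint computations iterate in sorted order, so outputs are
  deterministic regardless of axiom order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ROLE_GROUP",
    "ConceptExpression",
    "Named",
    "And",
    "Some",
    "role_group",
    "make_and",
    "Axiom",
    "TBox",
    "SubsumptionIndex",
    "TerminologyParseError",
    "UnknownConceptError",
    "parse_terminology",
    "serialize_terminology",
    "normalize",
    "classify",
    "is_subsumed",
    "descendants_or_self",
]

#: Reserved role id bundling attribute restrictions in the SNOMED translation.
ROLE_GROUP = "RoleGroup"

_SYNTHETIC_PREFIXES = ("__n", "__q")


def _is_synthetic(name: str) -> bool:
    return name.startswith(_SYNTHETIC_PREFIXES)


class TerminologyParseError(ValueError):
    """Malformed terminology-dialect input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class UnknownConceptError(KeyError):
    """A concept or role id was referenced but never declared."""

    def __init__(self, identifier: str):
        self.identifier = identifier
        super().__init__(f"unknown concept or role id: {identifier!r}")


# ---------------------------------------------------------------------------
# Concept expressions
# ---------------------------------------------------------------------------


class ConceptExpression:
    """Base class for EL concept expressions (Named / And / Some)."""

    __slots__ = ()

    def named_concepts(self) -> set[str]:
        """All named concept ids occurring in this expression."""
        out: set[str] = set()
        _collect_names(self, out)
        return out

    def __str__(self) -> str:  # pragma: no cover - delegated
        return expression_to_str(self)


@dataclass(frozen=True, slots=True)
class Named(ConceptExpression):
    concept: str

    def __post_init__(self) -> None:
        if not self.concept:
            raise ValueError("concept id must be non-empty")


@dataclass(frozen=True, slots=True)
class And(ConceptExpression):
    conjuncts: tuple[ConceptExpression, ...]

    def __post_init__(self) -> None:
        if len(self.conjuncts) < 2:
            raise ValueError("And requires at least two conjuncts")


@dataclass(frozen=True, slots=True)
class Some(ConceptExpression):
    role: str
    filler: ConceptExpression


def role_group(inner: ConceptExpression) -> Some:
    """RoleGroup(inner), represented as an existential over the reserved role."""
    return Some(ROLE_GROUP, inner)


def _sort_key(expr: ConceptExpression) -> str:
    return expression_to_str(expr)


def make_and(conjuncts: Iterable[ConceptExpression]) -> ConceptExpression:
    """Canonical conjunction: flattens nested Ands, drops duplicates, sorts.

    A single remaining conjunct collapses to that conjunct.
    """
    flat: list[ConceptExpression] = []
    for c in conjuncts:
        if isinstance(c, And):
            flat.extend(c.conjuncts)
        else:
            flat.append(c)
    unique = sorted(set(flat), key=_sort_key)
    if not unique:
        raise ValueError("empty conjunction")
    if len(unique) == 1:
        return unique[0]
    return And(tuple(unique))


def canonicalize(expr: ConceptExpression) -> ConceptExpression:
    """Recursively apply the And canonical form (flatten/dedupe/sort)."""
    if isinstance(expr, Named):
        return expr
    if isinstance(expr, Some):
        return Some(expr.role, canonicalize(expr.filler))
    if isinstance(expr, And):
        return make_and(canonicalize(c) for c in expr.conjuncts)
    raise TypeError(f"not a concept expression: {expr!r}")


def expression_to_str(expr: ConceptExpression) -> str:
    """Deterministic Manchester-like serialization, used in reports."""
    if isinstance(expr, Named):
        return expr.concept
    if isinstance(expr, Some):
        return f"({expr.role} some {expression_to_str(expr.filler)})"
    if isinstance(expr, And):
        return "(" + " and ".join(expression_to_str(c) for c in expr.conjuncts) + ")"
    raise TypeError(f"not a concept expression: {expr!r}")


def _collect_names(expr: ConceptExpression, out: set[str]) -> None:
    if isinstance(expr, Named):
        out.add(expr.concept)
    elif isinstance(expr, Some):
        _collect_names(expr.filler, out)
    elif isinstance(expr, And):
        for c in expr.conjuncts:
            _collect_names(c, out)


def _subexpressions(expr: ConceptExpression) -> Iterator[ConceptExpression]:
    yield expr
    if isinstance(expr, Some):
        yield from _subexpressions(expr.filler)
    elif isinstance(expr, And):
        for c in expr.conjuncts:
            yield from _subexpressions(c)


# ---------------------------------------------------------------------------
# Axioms and TBox
# ---------------------------------------------------------------------------

SUBCLASS_OF = "SubClassOf"
EQUIVALENT_TO = "EquivalentTo"


@dataclass(frozen=True, slots=True)
class Axiom:
    kind: str  # SUBCLASS_OF | EQUIVALENT_TO
    left: ConceptExpression
    right: ConceptExpression

    def as_subclass_pairs(self) -> tuple[tuple[ConceptExpression, ConceptExpression], ...]:
        """EquivalentTo(A, B) is the pair of SubClassOf axioms A⊑B, B⊑A."""
        if self.kind == EQUIVALENT_TO:
            return ((self.left, self.right), (self.right, self.left))
        return ((self.left, self.right),)


def subclass_of(left: ConceptExpression, right: ConceptExpression) -> Axiom:
    return Axiom(SUBCLASS_OF, left, right)


def equivalent_to(left: ConceptExpression, right: ConceptExpression) -> Axiom:
    return Axiom(EQUIVALENT_TO, left, right)


@dataclass
class TBox:
    """Stated terminology: declared concepts/roles with their axioms.

    ``concepts`` and ``roles`` map ids to optional human-readable labels;
    only ids are semantic.
    """

    concepts: dict[str, str | None] = field(default_factory=dict)
    roles: dict[str, str | None] = field(default_factory=dict)
    axioms: list[Axiom] = field(default_factory=list)

    def declare_concept(self, identifier: str, label: str | None = None) -> None:
        if not identifier:
            raise ValueError("concept id must be non-empty")
        if identifier not in self.concepts or label is not None:
            self.concepts.setdefault(identifier, None)
            if label is not None:
                self.concepts[identifier] = label

    def declare_role(self, identifier: str, label: str | None = None) -> None:
        if not identifier:
            raise ValueError("role id must be non-empty")
        if identifier not in self.roles or label is not None:
            self.roles.setdefault(identifier, None)
            if label is not None:
                self.roles[identifier] = label

    def add_axiom(self, axiom: Axiom, declare: bool = True) -> None:
        if declare:
            for expr in (axiom.left, axiom.right):
                for sub in _subexpressions(expr):
                    if isinstance(sub, Named):
                        self.declare_concept(sub.concept)
                    elif isinstance(sub, Some):
                        self.declare_role(sub.role)
        else:
            self.validate_expression(axiom.left)
            self.validate_expression(axiom.right)
        self.axioms.append(axiom)

    def validate_expression(self, expr: ConceptExpression) -> None:
        """Raise :class:`UnknownConceptError` for any undeclared id."""
        for sub in _subexpressions(expr):
            if isinstance(sub, Named) and sub.concept not in self.concepts:
                raise UnknownConceptError(sub.concept)
            if isinstance(sub, Some) and sub.role not in self.roles and sub.role != ROLE_GROUP:
                raise UnknownConceptError(sub.role)

    def copy(self) -> "TBox":
        return TBox(dict(self.concepts), dict(self.roles), list(self.axioms))

    def merged_with(self, other: "TBox") -> "TBox":
        out = self.copy()
        for cid, label in other.concepts.items():
            out.declare_concept(cid, label)
        for rid, label in other.roles.items():
            out.declare_role(rid, label)
        seen = set(out.axioms)
        for ax in other.axioms:
            if ax not in seen:
                out.axioms.append(ax)
                seen.add(ax)
        return out

    def label(self, identifier: str) -> str | None:
        return self.concepts.get(identifier) or self.roles.get(identifier)

    def stated_parents(self, identifier: str) -> set[str]:
        """Named concepts that `identifier` is stated (directly) to be a subclass of."""
        out: set[str] = set()
        for ax in self.axioms:
            for left, right in ax.as_subclass_pairs():
                if isinstance(left, Named) and left.concept == identifier and isinstance(right, Named):
                    out.add(right.concept)
        return out


# ---------------------------------------------------------------------------
# Terminology dialect
# ---------------------------------------------------------------------------


def _parse_token(token: str, lineno: int) -> tuple[str, str | None]:
    """A token is either a bare id or ``id|label|``."""
    token = token.strip()
    if "|" in token:
        if token.count("|") != 2 or not token.endswith("|"):
            raise TerminologyParseError(f"unbalanced '|' in token {token!r}", lineno)
        ident, label, _ = token.split("|")
        ident = ident.strip()
        label = label.strip()
        if not ident:
            raise TerminologyParseError(f"empty id in token {token!r}", lineno)
        return ident, label or None
    if not token:
        raise TerminologyParseError("empty token", lineno)
    return token, None


def parse_terminology(source: str) -> TBox:
    """Parse the tab-separated terminology dialect into a TBox.

    Lines: ``@role<TAB>id<TAB>label`` declares an attribute role;
    ``child<TAB>IsA<TAB>parent`` states an is-a; ``child<TAB>role<TAB>target``
    states an attribute relationship, translated to
    ``child SubClassOf RoleGroup some (role some target)``.
    ``#`` starts a comment; blank lines are ignored.  Concept tokens may carry
    labels as ``id|label|``.
    """
    tbox = TBox()
    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.split("\t") if p.strip()]
        if parts[0] == "@role":
            if len(parts) < 2:
                raise TerminologyParseError("@role requires an id", lineno)
            rid, rlabel = _parse_token(parts[1], lineno)
            if rlabel is None and len(parts) >= 3:
                rlabel = parts[2].strip() or None
            tbox.declare_role(rid, rlabel)
            continue
        if parts[0] == "@concept":
            if len(parts) < 2:
                raise TerminologyParseError("@concept requires an id", lineno)
            cid, clabel = _parse_token(parts[1], lineno)
            if clabel is None and len(parts) >= 3:
                clabel = parts[2].strip() or None
            tbox.declare_concept(cid, clabel)
            continue
        if len(parts) != 3:
            raise TerminologyParseError(
                f"expected 'child<TAB>relation<TAB>parent', got {len(parts)} fields", lineno
            )
        child_id, child_label = _parse_token(parts[0], lineno)
        rel_id, _rel_label = _parse_token(parts[1], lineno)
        target_id, target_label = _parse_token(parts[2], lineno)
        tbox.declare_concept(child_id, child_label)
        tbox.declare_concept(target_id, target_label)
        if rel_id == "IsA":
            tbox.add_axiom(subclass_of(Named(child_id), Named(target_id)))
        else:
            if rel_id not in tbox.roles:
                raise TerminologyParseError(
                    f"role {rel_id!r} used before declaration (@role)", lineno
                )
            tbox.add_axiom(
                subclass_of(Named(child_id), role_group(Some(rel_id, Named(target_id))))
            )
    return tbox


def serialize_terminology(tbox: TBox) -> str:
    """Write a TBox of IsA / single-attribute axioms back to the dialect.

    Only the axiom shapes produced by :func:`parse_terminology` are
    serializable; anything else raises ``ValueError``.
    """
    lines: list[str] = []

    def tok(cid: str) -> str:
        label = tbox.concepts.get(cid) or tbox.roles.get(cid)
        return f"{cid}|{label}|" if label else cid

    for rid in sorted(tbox.roles):
        label = tbox.roles[rid] or ""
        lines.append(f"@role\t{rid}\t{label}".rstrip("\t"))
    referenced: set[str] = set()
    body: list[str] = []
    for ax in tbox.axioms:
        if ax.kind != SUBCLASS_OF or not isinstance(ax.left, Named):
            raise ValueError(f"axiom not serializable in the dialect: {ax}")
        child = ax.left.concept
        if isinstance(ax.right, Named):
            body.append(f"{tok(child)}\tIsA\t{tok(ax.right.concept)}")
            referenced.update((child, ax.right.concept))
        elif (
            isinstance(ax.right, Some)
            and ax.right.role == ROLE_GROUP
            and isinstance(ax.right.filler, Some)
            and isinstance(ax.right.filler.filler, Named)
        ):
            inner = ax.right.filler
            body.append(f"{tok(child)}\t{tok(inner.role)}\t{tok(inner.filler.concept)}")
            referenced.update((child, inner.filler.concept))
        else:
            raise ValueError(f"axiom not serializable in the dialect: {ax}")
    for cid in sorted(tbox.concepts):
        if cid not in referenced:
            lines.append(f"@concept\t{tok(cid)}")
    lines.extend(body)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class _FreshNames:
    def __init__(self, prefix: str = "__n"):
        self.prefix = prefix
        self.counter = 0
        self.table: dict[ConceptExpression, str] = {}

    def get(self, expr: ConceptExpression) -> str:
        if expr not in self.table:
            self.table[expr] = f"{self.prefix}{self.counter}"
            self.counter += 1
        return self.table[expr]


def _normalize_pair(
    left: ConceptExpression,
    right: ConceptExpression,
    fresh: _FreshNames,
    out: list[tuple[ConceptExpression, ConceptExpression]],
) -> None:
    """Rewrite left ⊑ right into EL normal forms, appending to ``out``.

    Normal forms: A ⊑ B; A1 ⊓ ... ⊓ An ⊑ B (named conjuncts); A ⊑ ∃r.B;
    ∃r.A ⊑ B — with A, B named.
    """
    # Right side first: split conjunctions, name complex fillers.
    if isinstance(right, And):
        for conj in right.conjuncts:
            _normalize_pair(left, conj, fresh, out)
        return
    if isinstance(right, Some) and not isinstance(right.filler, Named):
        fresh_name = Named(fresh.get(right.filler))
        _normalize_pair(left, Some(right.role, fresh_name), fresh, out)
        _normalize_pair(fresh_name, right.filler, fresh, out)
        return
    # Complex ⊑ ∃r.B needs an intermediate name: left ⊑ X, X ⊑ ∃r.B.
    if isinstance(right, Some) and not isinstance(left, Named):
        fresh_name = Named(fresh.get(left))
        _normalize_pair(left, fresh_name, fresh, out)
        out.append((fresh_name, right))
        return
    # Left side: name complex conjuncts and complex existential fillers.
    if isinstance(left, And):
        named_conjs: list[ConceptExpression] = []
        for conj in left.conjuncts:
            if isinstance(conj, Named):
                named_conjs.append(conj)
            else:
                fresh_name = Named(fresh.get(conj))
                _normalize_pair(conj, fresh_name, fresh, out)
                named_conjs.append(fresh_name)
        out.append((make_and(named_conjs), right))
        return
    if isinstance(left, Some):
        if not isinstance(left.filler, Named):
            fresh_name = Named(fresh.get(left.filler))
            _normalize_pair(left.filler, fresh_name, fresh, out)
            out.append((Some(left.role, fresh_name), right))
        else:
            out.append((left, right))
        return
    out.append((left, right))


def normalize(tbox: TBox) -> TBox:
    """Return an equivalent TBox in EL normal form.

    Fresh synthetic concepts (``__n*``) are introduced for complex
    subexpressions; the result entails exactly the same subsumptions between
    the original named concepts.
    """
    fresh = _FreshNames()
    pairs: list[tuple[ConceptExpression, ConceptExpression]] = []
    for ax in tbox.axioms:
        for left, right in ax.as_subclass_pairs():
            _normalize_pair(canonicalize(left), canonicalize(right), fresh, pairs)
    out = TBox(dict(tbox.concepts), dict(tbox.roles), [])
    for expr, name in fresh.table.items():
        out.declare_concept(name)
    for left, right in pairs:
        out.axioms.append(subclass_of(left, right))
    return out


# ---------------------------------------------------------------------------
# Classification (EL completion rules)
# ---------------------------------------------------------------------------


@dataclass
class SubsumptionIndex:
    """Computed subsumption closure over named concepts.

    ``subsumers[C]`` is the set of all named, non-synthetic D with
    TBox ⊨ C ⊑ D (reflexive and transitively closed).  Synthetic
    normalization names are kept in the internal table only.
    """

    subsumers: dict[str, set[str]]
    _all_subsumers: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def subsumes(self, sup: str, sub: str) -> bool:
        """True iff sup subsumes sub (sub ⊑ sup)."""
        table = self._all_subsumers or self.subsumers
        if sub not in table:
            raise UnknownConceptError(sub)
        return sup in table[sub]


def _saturate(normal_axioms: list[Axiom], concept_ids: Iterable[str]) -> dict[str, set[str]]:
    """Run the EL completion rules to fixpoint.

    S(C) collects named subsumers of C; R(r) collects role successors.
    Rules (with all names atomic after normalization):
      CR1  D ∈ S(C), D ⊑ E             ⇒ E ∈ S(C)
      CR2  D1..Dn ∈ S(C), D1⊓..⊓Dn ⊑ E ⇒ E ∈ S(C)
      CR3  D ∈ S(C), D ⊑ ∃r.E          ⇒ (C,E) ∈ R(r)
      CR4  (C,D) ∈ R(r), D' ∈ S(D), ∃r.D' ⊑ E ⇒ E ∈ S(C)
    """
    atomic_subs: dict[str, set[str]] = {}
    conj_axioms: list[tuple[frozenset[str], str]] = []
    exists_rhs: dict[str, set[tuple[str, str]]] = {}
    exists_lhs: dict[tuple[str, str], set[str]] = {}

    for ax in normal_axioms:
        left, right = ax.left, ax.right
        if isinstance(left, Named) and isinstance(right, Named):
            atomic_subs.setdefault(left.concept, set()).add(right.concept)
        elif isinstance(left, And) and isinstance(right, Named):
            conj = frozenset(c.concept for c in left.conjuncts)  # type: ignore[union-attr]
            conj_axioms.append((conj, right.concept))
        elif isinstance(left, Named) and isinstance(right, Some):
            exists_rhs.setdefault(left.concept, set()).add(
                (right.role, right.filler.concept)  # type: ignore[union-attr]
            )
        elif isinstance(left, Some) and isinstance(right, Named):
            key = (left.role, left.filler.concept)  # type: ignore[union-attr]
            exists_lhs.setdefault(key, set()).add(right.concept)
        else:  # pragma: no cover - normalize() guarantees the forms above
            raise ValueError(f"axiom not in normal form: {ax}")

    S: dict[str, set[str]] = {c: {c} for c in sorted(concept_ids)}
    R: dict[str, set[tuple[str, str]]] = {}

    changed = True
    while changed:
        changed = False
        for c in sorted(S):
            sc = S[c]
            new: set[str] = set()
            for d in sorted(sc):
                new |= atomic_subs.get(d, set()) - sc
            for conj, e in conj_axioms:
                if e not in sc and conj <= sc:
                    new.add(e)
            for role, pairs in sorted(R.items()):
                for (x, d) in pairs:
                    if x != c:
                        continue
                    for dprime in sorted(S.get(d, ())):
                        for e in exists_lhs.get((role, dprime), ()):
                            if e not in sc:
                                new.add(e)
            if new:
                sc |= new
                changed = True
            for d in sorted(sc):
                for role, filler in exists_rhs.get(d, ()):
                    pair = (c, filler)
                    bucket = R.setdefault(role, set())
                    if pair not in bucket:
                        bucket.add(pair)
                        changed = True
    return S


def classify(tbox: TBox) -> SubsumptionIndex:
    """Compute the full named-concept subsumption closure of a TBox."""
    normal = normalize(tbox)
    full = _saturate(normal.axioms, normal.concepts)
    public = {
        c: {d for d in subs if not _is_synthetic(d)}
        for c, subs in full.items()
        if not _is_synthetic(c)
    }
    return SubsumptionIndex(subsumers=public, _all_subsumers=full)


def is_subsumed(
    sub: ConceptExpression,
    sup: ConceptExpression,
    tbox: TBox,
    index: SubsumptionIndex | None = None,
) -> bool:
    """Decide TBox ⊨ sub ⊑ sup for possibly complex expressions.

    Named-versus-named queries are answered from ``index`` when supplied;
    complex expressions are handled by introducing fresh definitional names
    and re-saturating a copy.  The base index is never mutated.
    """
    tbox.validate_expression(sub)
    tbox.validate_expression(sup)
    sub = canonicalize(sub)
    sup = canonicalize(sup)
    if sub == sup:
        return True
    if isinstance(sub, Named) and isinstance(sup, Named) and index is not None:
        return index.subsumes(sup.concept, sub.concept)
    work = tbox.copy()
    query_names: list[str] = []
    for tag, expr in (("__q_sub", sub), ("__q_sup", sup)):
        if isinstance(expr, Named):
            query_names.append(expr.concept)
        else:
            work.declare_concept(tag)
            work.add_axiom(equivalent_to(Named(tag), expr))
            query_names.append(tag)
    normal = normalize(work)
    full = _saturate(normal.axioms, normal.concepts)
    return query_names[1] in full[query_names[0]]


def descendants_or_self(root: str, index: SubsumptionIndex) -> set[str]:
    """The ``<<`` operator: root plus every named concept subsumed by it."""
    if root not in index.subsumers:
        raise UnknownConceptError(root)
    return {c for c, subs in index.subsumers.items() if root in subs} | {root}
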