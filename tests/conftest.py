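"""Shared fixtures plus an independent brute-force entailment oracle.

The oracle decides EL subsumption by saturating a Gentzen-style set of
derivation rules (reflexivity, stated axioms, transitivity, conjunction
elimination/introduction, existential monotonicity) over the universe of all
subexpressions of the unnormalized axioms and the query.  It never
normalizes, introduces fresh names, or runs completion rules, so it shares
no code path with the package's classifier.
"""

from __future__ import annotations

import itertools
import random

import pytest

from terminfocheck.terminology_core import (
    And,
    Axiom,
    ConceptExpression,
    Named,
    Some,
    TBox,
    canonicalize,
    subclass_of,
)


def _subexprs(expr: ConceptExpression) -> set[ConceptExpression]:
    out = {expr}
    if isinstance(expr, Some):
        out |= _subexprs(expr.filler)
    elif isinstance(expr, And):
        for c in expr.conjuncts:
            out |= _subexprs(c)
    return out


def oracle_entailed_pairs(
    axioms: list[Axiom],
    extra_exprs: tuple[ConceptExpression, ...] = (),
) -> set[tuple[ConceptExpression, ConceptExpression]]:
    """All pairs (E, F) with E ⊑ F derivable over the subexpression universe."""
    universe: set[ConceptExpression] = set()
    stated: set[tuple[ConceptExpression, ConceptExpression]] = set()
    for ax in axioms:
        for left, right in ax.as_subclass_pairs():
            left, right = canonicalize(left), canonicalize(right)
            stated.add((left, right))
            universe |= _subexprs(left) | _subexprs(right)
    for expr in extra_exprs:
        universe |= _subexprs(canonicalize(expr))

    pairs: set[tuple[ConceptExpression, ConceptExpression]] = set(stated)
    pairs |= {(e, e) for e in universe}
    # Conjunction elimination is static: And(E...) ⊑ each conjunct.
    for e in universe:
        if isinstance(e, And):
            for c in e.conjuncts:
                pairs.add((e, c))

    ands = [e for e in universe if isinstance(e, And)]
    somes = [e for e in universe if isinstance(e, Some)]
    changed = True
    while changed:
        changed = False
        before = len(pairs)
        # transitivity
        by_left: dict[ConceptExpression, set[ConceptExpression]] = {}
        for a, b in pairs:
            by_left.setdefault(a, set()).add(b)
        for a, bs in list(by_left.items()):
            derived = set()
            for b in bs:
                derived |= by_left.get(b, set())
            new = {(a, c) for c in derived} - pairs
            if new:
                pairs |= new
        # conjunction introduction: E ⊑ every conjunct of A  ⇒  E ⊑ A
        for a in ands:
            for e in universe:
                if (e, a) not in pairs and all((e, c) in pairs for c in a.conjuncts):
                    pairs.add((e, a))
        # existential monotonicity: E ⊑ F ⇒ ∃r.E ⊑ ∃r.F (both in universe)
        for s1, s2 in itertools.product(somes, somes):
            if s1.role == s2.role and (s1, s2) not in pairs and (s1.filler, s2.filler) in pairs:
                pairs.add((s1, s2))
        changed = len(pairs) != before
    return pairs


def oracle_is_subsumed(
    sub: ConceptExpression, sup: ConceptExpression, axioms: list[Axiom]
) -> bool:
    sub, sup = canonicalize(sub), canonicalize(sup)
    return (sub, sup) in oracle_entailed_pairs(axioms, extra_exprs=(sub, sup))


# ---------------------------------------------------------------------------
# Seeded random TBox generator for the reasoner-vs-oracle sweeps
# ---------------------------------------------------------------------------

_CONCEPTS = [f"A{i}" for i in range(8)]
_ROLES = ["r0", "r1", "RoleGroup"]


def _random_expr(rng: random.Random, depth: int) -> ConceptExpression:
    if depth <= 0 or rng.random() < 0.5:
        return Named(rng.choice(_CONCEPTS))
    if rng.random() < 0.5:
        return Some(rng.choice(_ROLES), _random_expr(rng, depth - 1))
    n = rng.randint(2, 3)
    conjuncts = {_random_expr(rng, depth - 1) for _ in range(n)}
    conjuncts.add(Named(rng.choice(_CONCEPTS)))
    if len(conjuncts) == 1:
        return conjuncts.pop()
    return canonicalize(And(tuple(conjuncts)))


def random_tbox(seed: int, max_axioms: int = 15) -> TBox:
    """A small random EL TBox; identical seed gives an identical TBox."""
    rng = random.Random(seed)
    tbox = TBox()
    for c in _CONCEPTS:
        tbox.declare_concept(c)
    for r in _ROLES:
        tbox.declare_role(r)
    for _ in range(rng.randint(1, max_axioms)):
        left = _random_expr(rng, 2)
        right = _random_expr(rng, 2)
        tbox.add_axiom(subclass_of(left, right))
    return tbox


# ---------------------------------------------------------------------------
# Seeded random post-coordinated expressions (round-trip sweeps)
# ---------------------------------------------------------------------------

_LABELS = [None, "Allergy", "Causative agent", "finding (x)", "event - y"]


def random_postcoordinated(rng: random.Random, depth: int = 2):
    from terminfocheck.snomed_ct import (
        Concept,
        PostcoordinatedExpression,
        Refinement,
    )

    def concept():
        return Concept(
            identifier=str(rng.randint(10000, 999999999)),
            label=rng.choice(_LABELS),
        )

    def refinement(d):
        value = (
            random_postcoordinated(rng, d - 1)
            if d > 0 and rng.random() < 0.3
            else PostcoordinatedExpression(focus=(concept(),))
        )
        return Refinement(attribute=concept(), value=value)

    focus = tuple(concept() for _ in range(rng.randint(1, 3)))
    refinements = tuple(refinement(depth) for _ in range(rng.randint(0, 2)))
    groups = tuple(
        tuple(refinement(depth) for _ in range(rng.randint(1, 2)))
        for _ in range(rng.randint(0, 1))
    )
    return PostcoordinatedExpression(focus=focus, refinements=refinements, groups=groups)


@pytest.fixture(scope="session")
def fixture_terminology():
    from terminfocheck.snomed_ct import generate_fixture_terminology

    return generate_fixture_terminology()


@pytest.fixture(scope="session")
def merged_ontology(fixture_terminology):
    from terminfocheck.cda import attach_terminology, build_cda_ontology

    return attach_terminology(build_cda_ontology(), fixture_terminology)


@pytest.fixture(scope="session")
def merged_index(merged_ontology):
    from terminfocheck.terminology_core import classify

    return classify(merged_ontology)
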