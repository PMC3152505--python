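# Methods

## The validation model

A CDA document is valid with respect to the TermInfo §5 vocabulary-domain
constraints when every clinical statement that uses a SNOMED CT expression in
a governed attribute can be *proven* to use it from an allowed value set.
Formally, for a rule with guard *g* and allowed roots R₁…Rₙ, a statement *s*
with target-attribute expression *E* satisfies the rule iff

    applicable(g, s)  ⇒  ∃ i : T ⊨ E ⊑ Rᵢ

where T is the merged ontology (clinical-statement classes + code systems +
attached terminology). The two halves of this test run under different
assumptions on purpose:

* **Open world** for `⊨`: terminology subsumption is classical entailment.
  `Allergy ⊓ ∃RoleGroup.(∃causativeAgent.Penicillin) ⊑ ClinicalFinding`
  holds because `Allergy ⊑ ClinicalFinding` is stated.
* **Closed world** for satisfaction: only the expression the document
  *asserts* counts. If the allowed set is `{FindingWithExplicitContext,
  Event}` and only `E ⊑ ClinicalFinding` is entailed, the rule is violated —
  a classical reasoner would instead happily *assume* the missing type.
  This is what distinguishes integrity-constraint validation from ontology
  consistency checking, and it is why a value typed by a concept with no
  terminology axioms violates every applicable rule.

## The reasoner

The expression language is EL — named concepts, conjunction, existential
restriction — plus the reserved `RoleGroup` role from the SNOMED
stated-relationship translation. Disjunction appears only on the right-hand
side of constraints and is evaluated as "some allowed root is entailed",
never pushed into the terminology; universal restrictions appear only in the
clinical-statement ontology and are realized as closed-world structural
checks (below). This keeps classification sound, complete and polynomial.

Classification rewrites axioms to EL normal form (`A ⊑ B`, `A₁⊓…⊓Aₙ ⊑ B`,
`A ⊑ ∃r.B`, `∃r.A ⊑ B`; fresh names `__n*` for complex subexpressions) and
saturates the four standard completion rules to a fixpoint. Queries between
complex expressions introduce definitional names `__q*` and re-saturate a
copy; the base index is immutable, and synthetic names never appear in
results. All fixpoint loops iterate in sorted order, so outputs are
deterministic regardless of axiom or rule-application order.

`RoleGroup` is an ordinary role: `∃RoleGroup.(∃r.C)` and `∃r.C` are
deliberately not equated, mirroring the stated-relationship translation.
Each ungrouped attribute refinement gets its own RoleGroup; rows or
refinements sharing an explicit group share one RoleGroup over a conjunctive
filler (which entails strictly more about the joint filler).

The test suite checks the classifier against an independent brute-force
oracle: a Gentzen-style saturation (reflexivity, stated axioms,
transitivity, conjunction elimination/introduction, existential
monotonicity) over the subexpression universe of the *unnormalized* axioms.
The two routes share no code.

## The clinical-statement ontology

Statement classes get existential `classCode`/`moodCode` axioms
(`Observation ⊑ ∃classCode.OBS`, `Observation ⊑
∃moodCode.x_ActMoodDocumentObservation`). Their universal ("only")
counterparts are outside EL; under integrity-constraint semantics their
intent is exactly a check on what the document asserts, so they are realized
as structural checks: every asserted classCode filler must be subsumed by the
stated class code, every moodCode filler must belong to the stated mood value
set. Structural findings are reported alongside, but separately from,
vocabulary-domain violations.

The disjunctive value-set definition (`x_ActMoodDocumentObservation ≡ DEF ⊔
EVN ⊔ …`) is encoded in the member→set direction only, as seven `SubClassOf`
axioms; the set→member direction is never needed for validation. The
terminology is attached by grafting its root (auto-detected as the unique
concept without a stated parent, or given explicitly) under
`SNOMEDClinicalTerms ⊑ HL7SupportedCodeSystems`.

Each coded filler carries the `codeSystem` OID from its XML attribute rather
than inheriting it from the placeholder concept — observably equivalent,
simpler, and robust to the corrupted SNOMED OID (`2.16.840.1.11388.3.6.96`)
that circulates in one prose rendering of these rules; the real OID
`2.16.840.1.113883.6.96` is used throughout. Nested statements are
flattened and `actRelationship` attributes discarded: the rules are scoped
to isolated statements, so the translation is intentionally lossy about
document structure.

## The constraint library

Eight rules in five groups. The published counts ("8 constraints, 5 groups,
3 for Observations, the other groups 1 each") only sum to 8 if one group
holds two rules; the Supply rule is filed under the SubstanceAdministration
group (3+1+1+2+1), the minimal consistent layout.

| id | kind.attribute | guard | allowed |
|----|----------------|-------|---------|
| OBS-1 | Observation.value | code = ASSERTION | `<<404684003` OR `<<413350009` OR `<<272379006` |
| OBS-2 | Observation.code | code ≠ ASSERTION | `<<386053000` OR `<<363787002` |
| OBS-3 | Observation.value | code ≠ ASSERTION | `<<281296001` OR `<<260245000` |
| ENT-1, PROC-1, SBADM-1, SPLY-1, ORG-1 | kind.code | always | placeholder `<<138875005` |

Every rule additionally requires its target attribute to be SNOMED-coded
(OID match) — the rules govern SNOMED usage only, so `ASSERTION` itself (an
ActCode) is always acceptable as an `Observation.code`. The five
non-Observation value-set roots are distributed only in the guideline's
machine-readable annex, which is not reproduced here; they default to the
permissive SNOMED root (never inventing violations) and are meant to be
replaced via the JSON constraint config (`load_constraints`), which can
override any rule by id or replace the library outright.

## The fixture terminology

`generate_fixture_terminology()` is a deterministic ~20-concept miniature of
the tailored SNOMED fragment the rules touch: the clinical-finding, event,
observable-entity, evaluation-procedure, result-comments and findings-values
subtrees; the Condition → Migraine chain; Allergy with the causative-agent
attribute; and the Penicillin → Aminopenicillin → Amoxicillin → tablet chain
with has-active-ingredient. It emulates hierarchy placement and stated
attributes; it does **not** emulate SNOMED's scale (≈300 k concepts), its
fully-defined concepts, role hierarchies, or GCI axioms — a green test
establishes correctness of the validation logic, not performance or coverage
on a full release (an RF2-style stated-relationship reader is provided for
supplying real fragments).

One placement is a modelling choice rather than release-faithful: Hives
(247472004) sits under Finding with explicit context (413350009) — itself
under Clinical finding, as in the real release — so that when the
clinical-finding disjunct is removed from OBS-1 (the "weakened" rule used to
demonstrate closed-world semantics), only the penicillin-allergy value
becomes non-inferable and exactly one violation results. In the real release
Hives is a plain clinical finding.

## Numerical and edge-case conventions

* Group percentages in `summarize` are rounded half-up to integers; zero
  usages render as 0 %.
* A statement violated by several rules of one group counts once in that
  group's violated-statements tally.
* Unknown codes are *typing issues*, a separate report category (errors
  under `--strict`): a missing concept is a terminology gap, not a guideline
  breach. Structural classCode/moodCode findings are likewise kept out of
  the violation tallies.
* Reports, instance graphs, fixture files and CLI output are byte-identical
  across runs; there is no randomness anywhere in the pipeline.

## Known limitations

* EL only: no disjunction, negation or universals inside the terminology;
  no concrete domains; no equivalence-class extraction.
* Compositional-grammar coverage is the subset used in CDA attributes
  (focus `+`, `:` refinements, `,`, `{...}` groups, parenthesized nested
  values); the SNOMED Expression Constraint Language beyond `<<` is out of
  scope.
* CDA coverage is the clinical-statement pattern only — no header, no
  narrative block, no templateId conformance, no context conduction; only
  code-bearing attributes are modelled.
* The RIM-overlap guidelines (TermInfo §2) are not modelled: they hinge on
  authorial intent and are not mechanically checkable.
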