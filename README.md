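# terminfocheck

Automatic validation of SNOMED CT usage in HL7 CDA clinical documents.

## The problem

HL7's Clinical Document Architecture (CDA) fixes the *structure* of clinical
documents, and SNOMED CT standardizes the *codes* they carry — but the two
overlap semantically, and the TermInfo implementation guide ("Using SNOMED CT
in HL7 Version 3") exists to say which SNOMED concepts may populate which
attribute of which clinical-statement class. For example: when
`Observation.code` is the HL7 `ASSERTION` code, `Observation.value` must be a
clinical finding, a finding with explicit context, or an event — written in
the guide as

```
((<<404684003 |clinical finding|) OR (<<413350009 |finding with explicit context|) OR (<<272379006 |event|))
```

where `<<` is descendant-or-self over the SNOMED hierarchy. The guide is
human-readable prose; `terminfocheck` makes its §5 vocabulary-domain
constraints machine-checkable for anyone authoring or receiving CDA
documents.

## How it works

1. **Terminology** (`terminology_core`, `snomed_ct`): stated SNOMED CT
   relationships become EL description-logic axioms (is-a → `SubClassOf`,
   attributes → `RoleGroup some (attribute some target)`), and
   post-coordinated compositional-grammar expressions such as
   `106190000|Allergy|:246075003|Causative agent|=373270004` become concept
   expressions `Allergy ⊓ ∃RoleGroup.(∃causativeAgent.Penicillin)`.
   Subsumption `C ⊑ D` is decided by normalizing to EL normal form and
   saturating the standard EL completion rules — sound, complete, and
   polynomial for this fragment.
2. **CDA translation** (`cda`): each clinical statement (observation,
   substanceAdministration, supply, procedure, encounter, organizer, act)
   becomes a star of typed individuals — the act itself plus one filler per
   coded attribute (`classCode`, `moodCode`, `hasCode`, `hasValue`) — over a
   clinical-statement ontology whose code systems and value sets hang under
   `HL7SupportedCodeSystems` / `HL7ValueSets`.
3. **Constraints** (`terminfo_constraints`, `ic_validator`): each rule is a
   guard (e.g. "code is ASSERTION") plus a disjunction of `<<root` value
   sets. Evaluation is deliberately two-faced: subsumption over the
   terminology is **open-world** (entailment), but rule satisfaction is
   **closed-world** — the expression the document actually asserts must be
   entailed to lie in an allowed set; nothing is ever assumed to make a rule
   pass. A document whose value is typed only by a concept the terminology
   knows nothing about violates every applicable rule.

The packaged default library holds 8 constraints in 5 groups (Observation ×3,
Entity, Procedure, SubstanceAdministration ×2 incl. Supply, Organizer); the
three Observation rules are fully specified, the others ship as configurable
placeholders (see `docs/methods.md`).

## Worked example

```sh
$ terminfocheck fixtures --out fx          # built-in terminology + example docs
$ terminfocheck validate fx/pcn_allergy.xml
fx/pcn_allergy.xml: no violations          # exit code 0
```

The allergy observation passes because its value,
`Allergy ⊓ ∃RoleGroup.(∃causativeAgent.Penicillin)`, is entailed to be a
clinical finding (`Allergy ⊑ ClinicalFinding`). A document that puts a
disorder in `Observation.code` and a finding in `Observation.value` fails
two rules at once:

```sh
$ terminfocheck validate fx/migraine.xml
fx/migraine.xml: 2 violation(s)
  [OBS-2] statement 1 (/observation[1])
    found:   64572001
    allowed: <<386053000 OR <<363787002
    Observation.code is 64572001, which is not subsumed by any of <<386053000 OR <<363787002. ...
  [OBS-3] statement 1 (/observation[1])
    found:   37796009
    allowed: <<281296001 OR <<260245000
    Observation.value is 37796009, which is not subsumed by any of <<281296001 OR <<260245000. ...
```

`64572001` (Condition) is neither an evaluation procedure nor an observable
entity, and `37796009` (Migraine) is neither a result comment nor a findings
value — the idiomatic fix is `code="ASSERTION"`. Exit codes: 0 clean, 1
violations, 2 errors. `--format json` emits the structured report,
`terminfocheck convert` prints the typed instance graph, and

```sh
$ terminfocheck classify --query "37796009 << 404684003"
true
```

answers raw subsumption queries against a terminology file.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch: it regenerates the fixture
terminology, classifies the merged ontology, validates the conformant and
violating example documents (and the weakened-rule variant that demonstrates
closed-world semantics), sweeps the classifier for reflexivity and
transitivity over seeded random terminologies, round-trips 500 seeded
compositional-grammar expressions, and writes the results JSON to `--out`,
exiting non-zero if any expectation fails.
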