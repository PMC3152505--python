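"""Closed-world constraint checking over the instance graph."""

import json

import pytest

from conftest import oracle_is_subsumed
from terminfocheck.cda import (
    CdaDocument,
    attach_terminology,
    build_cda_ontology,
    parse_cda,
    to_instance_graph,
)
from terminfocheck.fixtures import (
    MIGRAINE_XML,
    PCN_ALLERGY_XML,
    WEAKENED_OBS1_CONFIG,
)
from terminfocheck.ic_validator import (
    check_constraint,
    render_report,
    report_from_dict,
    report_to_dict,
    summarize,
    validate,
)
from terminfocheck.snomed_ct import generate_fixture_terminology
from terminfocheck.terminfo_constraints import (
    applicable,
    default_library,
    load_constraints,
)
from terminfocheck.terminology_core import Named, classify, subclass_of


@pytest.fixture(scope="module")
def library():
    return default_library()


class TestCheckConstraint:
    def test_pcn_allergy_satisfies_obs1(self, merged_ontology, merged_index, library):
        doc = parse_cda(PCN_ALLERGY_XML)
        graph = to_instance_graph(doc, merged_ontology)
        stmt = doc.statements[0]
        constraint = library.get("OBS-1")
        assert applicable(constraint, stmt)
        assert (
            check_constraint(constraint, stmt, graph, merged_ontology, merged_index)
            is None
        )

    def test_weakened_obs1_violated(self, merged_ontology, merged_index):
        weak = load_constraints(WEAKENED_OBS1_CONFIG).get("OBS-1")
        doc = parse_cda(PCN_ALLERGY_XML)
        graph = to_instance_graph(doc, merged_ontology)
        violation = check_constraint(
            weak, doc.statements[0], graph, merged_ontology, merged_index
        )
        assert violation is not None
        assert violation.constraintId == "OBS-1"
        # The report shows what the document asserts, never a repaired type.
        assert "106190000" in violation.found
        assert [str(ref) for ref in violation.allowed] == ["<<413350009", "<<272379006"]

    def test_migraine_value_violates_obs3(self, merged_ontology, merged_index, library):
        doc = parse_cda(MIGRAINE_XML)
        graph = to_instance_graph(doc, merged_ontology)
        violation = check_constraint(
            library.get("OBS-3"), doc.statements[0], graph, merged_ontology, merged_index
        )
        assert violation is not None
        assert violation.attribute == "value"
        assert violation.found == "37796009"


class TestValidate:
    def test_pcn_fragment_is_clean(self, merged_ontology, merged_index, library):
        report = validate(
            parse_cda(PCN_ALLERGY_XML), library, merged_ontology, merged_index
        )
        assert report.violations == ()
        assert all(f.ok for f in report.structuralFindings)
        assert report.counters["Observation"] == {"usages": 2, "violated": 0}

    def test_migraine_fragment_flags_both_observation_rules(
        self, merged_ontology, merged_index, library
    ):
        report = validate(
            parse_cda(MIGRAINE_XML), library, merged_ontology, merged_index
        )
        assert [(v.constraintId, v.statementId) for v in report.violations] == [
            ("OBS-2", 1),
            ("OBS-3", 1),
        ]
        assert report.counters["Observation"] == {"usages": 1, "violated": 1}

    def test_empty_document(self, merged_ontology, merged_index, library):
        report = validate(CdaDocument(()), library, merged_ontology, merged_index)
        assert report.violations == ()
        assert report.structuralFindings == ()
        assert all(
            counts == {"usages": 0, "violated": 0}
            for counts in report.counters.values()
        )

    def test_structural_check_catches_wrong_mood(
        self, merged_ontology, merged_index, library
    ):
        xml = '<observation classCode="OBS" moodCode="CRT"/>'
        report = validate(parse_cda(xml), library, merged_ontology, merged_index)
        failed = [f for f in report.structuralFindings if not f.ok]
        assert [f.check for f in failed] == ["moodCode"]

    def test_removing_a_constraint_never_adds_violations(
        self, merged_ontology, merged_index, library
    ):
        doc = parse_cda(MIGRAINE_XML)
        full = validate(doc, library, merged_ontology, merged_index)
        from terminfocheck.terminfo_constraints import ConstraintLibrary

        smaller = ConstraintLibrary(
            constraints=tuple(c for c in library.constraints if c.id != "OBS-2")
        )
        reduced = validate(doc, smaller, merged_ontology, merged_index)
        assert len(reduced.violations) <= len(full.violations)
        assert {v.constraintId for v in reduced.violations} <= {
            v.constraintId for v in full.violations
        }

    def test_adding_terminology_axioms_never_adds_violations(self, library):
        # Grafting Migraine under result comments satisfies OBS-3 — more
        # entailments can only satisfy more constraints.
        base_term = generate_fixture_terminology()
        doc = parse_cda(MIGRAINE_XML)
        base = attach_terminology(build_cda_ontology(), base_term)
        before = validate(doc, library, base, classify(base))
        richer_term = generate_fixture_terminology()
        richer_term.add_axiom(subclass_of(Named("37796009"), Named("281296001")))
        richer_term.add_axiom(subclass_of(Named("64572001"), Named("363787002")))
        richer = attach_terminology(build_cda_ontology(), richer_term)
        after = validate(doc, library, richer, classify(richer))
        assert len(after.violations) < len(before.violations)
        assert after.violations == ()

    def test_closed_world_fresh_concept_always_violates(self, library):
        # A value typed by a concept with no terminology axioms beyond root
        # placement satisfies nothing: membership is entailed, never assumed.
        term = generate_fixture_terminology()
        term.declare_concept("999000999")
        term.add_axiom(subclass_of(Named("999000999"), Named("138875005")))
        tbox = attach_terminology(build_cda_ontology(), term)
        index = classify(tbox)
        xml = (
            '<observation classCode="OBS" moodCode="EVN">'
            '<code code="ASSERTION" codeSystem="2.16.840.1.113883.5.4"/>'
            '<value code="999000999" codeSystem="2.16.840.1.113883.6.96"/>'
            "</observation>"
        )
        report = validate(parse_cda(xml), library, tbox, index)
        assert [v.constraintId for v in report.violations] == ["OBS-1"]

    def test_statement_order_only_permutes_violations(
        self, merged_ontology, merged_index, library
    ):
        combined = (
            "<section>"
            + MIGRAINE_XML.replace('<?xml version="1.0"?>', "")
            + PCN_ALLERGY_XML
            + "</section>"
        )
        flipped = (
            "<section>"
            + PCN_ALLERGY_XML
            + MIGRAINE_XML
            + "</section>"
        )
        r1 = validate(parse_cda(combined), library, merged_ontology, merged_index)
        r2 = validate(parse_cda(flipped), library, merged_ontology, merged_index)
        key = lambda v: (v.constraintId, v.found)
        assert sorted(map(key, r1.violations)) == sorted(map(key, r2.violations))
        assert r1.counters == r2.counters

    def test_agrees_with_brute_force_oracle(
        self, merged_ontology, merged_index, library, fixture_terminology
    ):
        # Re-derive each verdict by testing every allowed disjunct through the
        # independent entailment oracle on the unnormalized axioms.
        doc = parse_cda(
            "<section>" + PCN_ALLERGY_XML + MIGRAINE_XML + "</section>"
        )
        graph = to_instance_graph(doc, merged_ontology)
        report = validate(doc, library, merged_ontology, merged_index)
        flagged = {(v.statementId, v.constraintId) for v in report.violations}
        for stmt in doc.statements:
            for constraint in library.constraints:
                if not applicable(constraint, stmt):
                    assert (stmt.statementId, constraint.id) not in flagged
                    continue
                ind = graph.statement_individuals[stmt.statementId]
                expr = graph.type_assertions[
                    graph.fillers[ind][constraint.targetAttribute]
                ]
                satisfied = any(
                    oracle_is_subsumed(expr, Named(ref.root), merged_ontology.axioms)
                    for ref in constraint.allowed
                )
                assert ((stmt.statementId, constraint.id) in flagged) == (not satisfied)


class TestSummarize:
    def test_tally_arithmetic(self, merged_ontology, merged_index, library):
        # 3 of 4 and 1 of 2 violated observation statements -> 6, 4, 67%.
        def fake_report(usages, violated):
            from terminfocheck.ic_validator import ValidationReport

            counters = {
                g: {"usages": 0, "violated": 0}
                for g in ("Observation", "Entity", "Procedure",
                          "SubstanceAdministration", "Organizer")
            }
            counters["Observation"] = {"usages": usages, "violated": violated}
            return ValidationReport("", (), (), (), counters)

        rows = summarize([fake_report(4, 3), fake_report(2, 1)])
        obs = next(r for r in rows if r["group"] == "Observation")
        assert obs == {"group": "Observation", "usages": 6, "violated": 4, "percent": 67}

    def test_no_reports_gives_zero_table(self):
        rows = summarize([])
        assert all(r["usages"] == 0 and r["percent"] == 0 for r in rows)
        assert len(rows) == 5

    def test_single_migraine_report(self, merged_ontology, merged_index, library):
        report = validate(
            parse_cda(MIGRAINE_XML), library, merged_ontology, merged_index
        )
        obs = next(r for r in summarize([report]) if r["group"] == "Observation")
        assert (obs["usages"], obs["violated"], obs["percent"]) == (1, 1, 100)

    def test_percent_rounds_half_up(self):
        from terminfocheck.ic_validator import _percent

        assert _percent(1, 3) == 33
        assert _percent(2, 3) == 67
        assert _percent(1, 2) == 50
        assert _percent(175, 239) == 73


class TestRenderReport:
    def test_migraine_text_report_names_both_rules(
        self, merged_ontology, merged_index, library
    ):
        report = validate(
            parse_cda(MIGRAINE_XML), library, merged_ontology, merged_index,
            document_ref="migraine.xml",
        )
        text = render_report(report, "text")
        assert "OBS-2" in text and "OBS-3" in text
        assert "37796009" in text

    def test_empty_report_text(self, merged_ontology, merged_index, library):
        report = validate(CdaDocument(()), library, merged_ontology, merged_index)
        assert "no violations" in render_report(report, "text")

    def test_structured_round_trip(self, merged_ontology, merged_index, library):
        report = validate(
            parse_cda(MIGRAINE_XML), library, merged_ontology, merged_index,
            document_ref="migraine.xml",
        )
        data = json.loads(render_report(report, "structured"))
        assert report_from_dict(data) == report
        assert report_to_dict(report_from_dict(data)) == data

    def test_unknown_format_rejected(self, merged_ontology, merged_index, library):
        report = validate(CdaDocument(()), library, merged_ontology, merged_index)
        with pytest.raises(ValueError):
            render_report(report, "yaml")
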