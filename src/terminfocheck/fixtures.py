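"""Packaged worked-example documents and fixture writers.

Two miniature CDA fragments exercise the Observation rules end to end: a
conformant penicillin-allergy observation (with its hives manifestation
nested in an actRelationship) and a non-conformant condition/migraine
observation that puts a disorder code in ``Observation.code`` and a finding
in ``Observation.value``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .snomed_ct import generate_fixture_terminology
from .terminology_core import serialize_terminology

__all__ = [
    "PCN_ALLERGY_XML",
    "MIGRAINE_XML",
    "WEAKENED_OBS1_CONFIG",
    "write_fixtures",
]

PCN_ALLERGY_XML = """\
<observation xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance"
             classCode="OBS" moodCode="EVN">
  <code code="ASSERTION" codeSystem="2.16.840.1.113883.5.4"/>
  <text>Allergy to PCN manifesting as hives</text>
  <value xsi:type="CD"
         code="106190000|Allergy|:246075003|Causative agent|=373270004|Penicillin - class of antibiotic - (substance)|"
         codeSystem="2.16.840.1.113883.6.96"/>
  <actRelationship typeCode="MFST" inversionInd="true" contextConductionInd="true">
    <observation classCode="OBS" moodCode="EVN">
      <code code="ASSERTION" codeSystem="2.16.840.1.113883.5.4"/>
      <value xsi:type="CD" code="247472004|Hives|" codeSystem="2.16.840.1.113883.6.96">
        <displayName value="Hives"/>
      </value>
    </observation>
  </actRelationship>
</observation>
"""

MIGRAINE_XML = """\
<observation xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance"
             classCode="OBS" moodCode="EVN">
  <templateId root="2.16.840.1.113883.10.20.1.28" assigningAuthorityName="HL7 SDTC CCD"/>
  <templateId root="1.3.6.1.4.1.19376.1.5.3.1.4.5" assigningAuthorityName="IHE PCC"/>
  <id root="0fdf994f-2839-482d-bb92-f9b9d1a1786f"/>
  <code code="64572001" displayName="Condition" codeSystemName="SNOMED CT"
        codeSystem="2.16.840.1.113883.6.96"/>
  <text>
    <reference value="cond001"/>
  </text>
  <statusCode code="completed"/>
  <effectiveTime>
    <low value="1999"/>
    <high value="1999"/>
  </effectiveTime>
  <value xsi:type="CD" code="37796009" displayName="Migraine" codeSystemName="SNOMED CT"
         codeSystem="2.16.840.1.113883.6.96"/>
</observation>
"""

#: Constraint config dropping the clinical-finding disjunct from OBS-1 —
#: the "weakened" Observation.value rule used to demonstrate that
#: satisfaction is closed-world: membership must be entailed, never assumed.
WEAKENED_OBS1_CONFIG = json.dumps(
    {
        "constraints": [
            {
                "id": "OBS-1",
                "group": "Observation",
                "target_kind": "Observation",
                "target_attribute": "value",
                "guard": "code_is_assertion",
                "allowed": ["<<413350009", "<<272379006"],
                "narrative": (
                    "Weakened Observation.value rule: finding-with-explicit-context "
                    "or event only (clinical finding deliberately left out)."
                ),
            }
        ]
    },
    indent=2,
)


def write_fixtures(output_dir: str | Path) -> list[Path]:
    """Write the terminology, example documents and weakened config to disk.

    Byte-identical across runs.  Returns the written paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "fixture_terminology.tsv": serialize_terminology(generate_fixture_terminology()),
        "pcn_allergy.xml": PCN_ALLERGY_XML,
        "migraine.xml": MIGRAINE_XML,
        "weakened_obs1.json": WEAKENED_OBS1_CONFIG + "\n",
    }
    written = []
    for name, content in files.items():
        path = out / name
        path.write_text(content, encoding="utf-8")
        written.append(path)
    return written
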