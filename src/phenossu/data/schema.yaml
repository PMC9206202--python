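# Default PhenoSSU schema: 10 attribute categories, 7 phrase-based + 3 logic-based.
# Value sets are closed but user-extensible: copy this file, edit, pass via --schema.
version: "1.0"
attributes:
  - name: assertion
    subtype: phrase-based
    default: present
    values:
      - {label: present, snomed: "373573001"}
      - {label: absent, snomed: "2667000"}
  - name: severity
    subtype: phrase-based
    values:
      - {label: mild, snomed: "255604002"}
      - {label: moderate, snomed: "6736007"}
      - {label: severe, snomed: "24484000"}
  - name: temporal pattern
    subtype: phrase-based
    values:
      - {label: acute, snomed: "373933003"}
      - {label: chronic, snomed: "90734009"}
      - {label: recurrent, snomed: "255227004"}
      - {label: occasional, snomed: "84638005"}
      - {label: persistent, snomed: "255238004"}
  - name: laterality
    subtype: phrase-based
    values:
      - {label: left, snomed: "7771000"}
      - {label: right, snomed: "24028007"}
      - {label: bilateral, snomed: "51440002"}
  - name: spatial pattern
    subtype: phrase-based
    values:
      - {label: diffuse, snomed: "19648000"}
      - {label: localized, snomed: "255471001"}
      - {label: radiating, snomed: "8711009"}
  - name: quadrant pattern
    subtype: phrase-based
    values:
      - {label: right-lower, snomed: "48544008"}
      - {label: right-upper, snomed: "50960005"}
      - {label: left-lower, snomed: "68505006"}
      - {label: left-upper, snomed: "86367003"}
  - name: body location
    subtype: phrase-based
    values:
      - {label: abdomen, snomed: "818983003"}
      - {label: chest, snomed: "51185008"}
      - {label: head, snomed: "69536005"}
      - {label: back, snomed: "77568009"}
      - {label: throat, snomed: "54066008"}
      - {label: limb, snomed: "66019005"}
  - name: specimen
    subtype: logic-based
    values:
      - {label: blood, snomed: "119297000"}
      - {label: urine, snomed: "122575003"}
      - {label: sputum, snomed: "119334006"}
  - name: analyte
    subtype: logic-based
    values:
      - {label: WBC}
      - {label: RBC}
      - {label: hemoglobin}
      - {label: platelet}
      - {label: glucose}
      - {label: CRP}
      - {label: ALT}
      - {label: body temperature}
  - name: abnormality
    subtype: logic-based
    values:
      - {label: higher}
      - {label: lower}
      - {label: normal}
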