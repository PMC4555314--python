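# Crosswalk from rehabilitation questionnaire items to ICF categories.
#
# The Barthel feeding row (10 -> 0, 5 -> 2, 0 -> 4 onto d550 "eating") is
# the canonical worked example of the standardization method.  All other
# rows are illustrative fixtures chosen so the pipeline runs end-to-end on
# synthetic cohorts; they are plausible but are NOT clinically validated
# crosswalks for those instruments.
#
# Convention: ICF qualifiers increase with severity (0 = no problem,
# 4 = complete problem), so instruments scored "higher = better" invert
# explicitly in the value map.  Raw-value keys are exact matches or closed
# intervals written "lo..hi".
version: abi-demo-1
instruments:
  - instrument: Barthel
    items:
      - item: feeding
        icf_code: d550
        values: {10: 0, 5: 2, 0: 4}
      - item: dressing
        icf_code: d540
        values: {10: 0, 5: 2, 0: 4}
      - item: toileting
        icf_code: d530
        values: {10: 0, 5: 2, 0: 4}
  - instrument: CIQ
    items:
      - item: home_feeding
        icf_code: d550
        values: {2: 0, 1: 2, 0: 4}
      - item: social_leisure
        icf_code: d920
        values: {2: 0, 1: 2, 0: 4}
  - instrument: PCRS
    items:
      - item: emotional_control
        icf_code: b152
        values: {5: 0, 4: 1, 3: 2, 2: 3, 1: 4}
      - item: organization_planning
        icf_code: b1641
        values: {5: 0, 4: 1, 3: 2, 2: 3, 1: 4}
      - item: daily_routine
        icf_code: d230
        values: {5: 0, 4: 1, 3: 2, 2: 3, 1: 4}
  - instrument: PCRSi
    items:
      - item: executive_functions
        icf_code: b164
        values: {5: 0, 4: 1, 3: 2, 2: 3, 1: 4}
  - instrument: DRS
    items:
      - item: total
        icf_code: d230
        values: {"0..1": 0, "2..3": 1, "4..6": 2, "7..11": 3, "12..29": 4}
  - instrument: GOSE
    items:
      - item: score
        icf_code: d8502
        values: {"7..8": 0, "5..6": 1, "4..4": 2, "3..3": 3, "1..2": 4}
  - instrument: Rancho
    items:
      - item: level
        icf_code: b110
        values: {"8..8": 0, "7..7": 1, "5..6": 2, "3..4": 3, "1..2": 4}
  - instrument: ESIG
    items:
      - item: social_integration
        icf_code: d760
        values: {5: 0, 4: 1, 3: 2, 2: 3, 1: 4}
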