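# Era-dependent classification rules for the synthetic-register dialect.
# Authoritative national code lists differ across eras and are not shipped;
# supply your own file with the same structure for real register extracts.

service_types:
  # Before this year every register entry pertained to inpatient care.
  inpatient_all_before: 1998
  eras:
    - from: 1998
      to: 2018
      codes:
        "1": inpatient
        "2": day_hospital
        "83": outpatient
        "91": emergency
        "92": primary_care
        "5": other_contact
    - from: 2019
      to: 9999
      # Old-dialect codes still seen in 2019 entries (mixture handling: the
      # old column is tried first, then the new column).
      codes:
        "1": inpatient
        "2": day_hospital
        "83": outpatient
        "91": emergency
        "92": primary_care
        "5": other_contact
      codes_new:
        "R10": inpatient
        "R20": outpatient
        "R30": emergency
        "R40": primary_care
        "R50": day_hospital
        "R60": other_contact

psychiatric:
  # Before uniform specialty coding, mental-hospital provider class alone
  # marks psychiatric care.
  uniform_coding_from: 1987
  mental_hospital_provider_classes: ["mental_hospital"]
  eras:
    - from: 0
      to: 1986
      specialties: ["70"]
    - from: 1987
      to: 1993
      specialties: ["70", "75"]
    - from: 1994
      to: 9999
      specialties: ["70", "70F", "70Z", "74", "75"]

census:
  # Year-end open-entry reporting starts from this year.
  reported_from: 1996
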