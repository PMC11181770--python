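# ICD-10 mental-disorder reporting categories with earliest plausible age
# of onset (years).  A diagnosis record recorded before the floor age of
# its most specific matching category is treated as implausible and dropped.
default_age_floor: 5
any_label: "Any mental disorder"
groups:
  - name: "Organic mental disorders (F0)"
    prefixes: [F0]
    age_floor: 5
  - name: "Dementias (F00-03)"
    prefixes: [F00, F01, F02, F03]
    age_floor: 35
  - name: "Other organic (F04-09)"
    prefixes: [F04, F05, F06, F07, F08, F09]
    age_floor: 5
  - name: "Substance use disorders (F1)"
    prefixes: [F1]
    age_floor: 5
  - name: "Schizophrenia spectrum (F2)"
    prefixes: [F2]
    age_floor: 5
  - name: "Schizophrenia (F20)"
    prefixes: [F20]
    age_floor: 5
  - name: "Other psychotic (F21-29)"
    prefixes: [F21, F22, F23, F24, F25, F26, F27, F28, F29]
    age_floor: 5
  - name: "Mood disorders (F3)"
    prefixes: [F3]
    age_floor: 5
  - name: "Mania and bipolar disorder (F30-31)"
    prefixes: [F30, F31]
    age_floor: 5
  - name: "Depressive disorders (F32-33)"
    prefixes: [F32, F33]
    age_floor: 5
  - name: "Other mood (F34-39)"
    prefixes: [F34, F35, F36, F37, F38, F39]
    age_floor: 5
  - name: "Neurotic and stress-related (F4)"
    prefixes: [F4]
    age_floor: 5
  - name: "Anxiety disorders (F40-41)"
    prefixes: [F40, F41]
    age_floor: 5
  - name: "Obsessive-compulsive disorder (F42)"
    prefixes: [F42]
    age_floor: 5
  - name: "Behavioral syndromes (F5)"
    prefixes: [F5]
    age_floor: 5
  - name: "Personality disorders (F6)"
    prefixes: [F6]
    age_floor: 5
  - name: "Mental retardation (F7)"
    prefixes: [F7]
    age_floor: 1
  - name: "Disorders of psychological development (F8)"
    prefixes: [F8]
    age_floor: 1
  - name: "Behavioral and emotional disorders (F90-98)"
    prefixes: [F90, F91, F92, F93, F94, F95, F96, F97, F98]
    age_floor: 1
  - name: "ADHD (F90)"
    prefixes: [F90]
    age_floor: 1
  - name: "Other behavioral (F91-98)"
    prefixes: [F91, F92, F93, F94, F95, F96, F97, F98]
    age_floor: 1
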