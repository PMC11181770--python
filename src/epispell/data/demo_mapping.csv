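system,code_prefix,icd10_category
ICD10,F00,F00
ICD10,F01,F01
ICD10,F02,F02
ICD10,F03,F03
ICD10,F05,F05
ICD10,F06,F06
ICD10,F10,F10
ICD10,F20,F20
ICD10,F21,F21
ICD10,F22,F22
ICD10,F23,F23
ICD10,F24,F24
ICD10,F25,F25
ICD10,F28,F28
ICD10,F29,F29
ICD10,F30,F30
ICD10,F31,F31
ICD10,F32,F32
ICD10,F33,F33
ICD10,F34,F34
ICD10,F40,F40
ICD10,F41,F41
ICD10,F42,F42
ICD10,F43,F43
ICD10,F50,F50
ICD10,F60,F60
ICD10,F70,F70
ICD10,F84,F84
ICD10,F90,F90
ICD10,F91,F91
ICD8,290,F03
ICD8,295,F20
ICD8,296,F31
ICD8,298,F29
ICD8,300,F40
ICD8,303,F10
ICD9,290,F03
ICD9,295,F20
ICD9,296,F31
ICD9,298,F29
ICD9,300,F40
ICD9,303,F10
ICD9,311,F32
ICPC2,P15,F10
ICPC2,P72,F20
ICPC2,P73,F31
ICPC2,P74,F41
ICPC2,P76,F32
ICPC2,P79,F43
ICPC2,P85,F70
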