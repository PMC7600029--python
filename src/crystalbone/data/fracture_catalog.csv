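code_pattern,site
ICD10:S72,hip
ICD10:S52,wrist/forearm
ICD10:S42,humerus
ICD10:S32.3,pelvis
ICD10:S32.4,pelvis
ICD10:S32.5,pelvis
ICD10:S32.8,pelvis
ICD10:S22.0,vertebral
ICD10:S32.0,vertebral
ICD10:M48.4,vertebral
ICD10:S82,clinical-other
ICD9:820,hip
ICD9:813,wrist/forearm
ICD9:812,humerus
ICD9:808,pelvis
ICD9:805,vertebral
ICD9:823,clinical-other
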