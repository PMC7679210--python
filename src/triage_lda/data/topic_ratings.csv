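topic,rater,confidence_label,similarity_label
T1,A,moderately confident,moderately similar
T1,B,moderately confident,very similar
T2,A,moderately confident,very similar
T2,B,moderately confident,very similar
T3,A,moderately confident,very similar
T3,B,moderately confident,very similar
T4,A,moderately confident,moderately similar
T4,B,somewhat confident,very similar
T5,A,moderately confident,very similar
T5,B,moderately confident,very similar
T6,A,moderately confident,very similar
T6,B,somewhat confident,very similar
T7,A,moderately confident,very dissimilar
T7,B,slightly confident,moderately dissimilar
T8,A,moderately confident,moderately similar
T8,B,somewhat confident,slightly similar
T9,A,somewhat confident,moderately similar
T9,B,slightly confident,very similar
T10,A,somewhat confident,very similar
T10,B,slightly confident,very similar
T11,A,moderately confident,very dissimilar
T11,B,slightly confident,very dissimilar
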