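gene	family
CDK1	Protein kinases
PRKCB	Protein kinases
PRKCZ	Protein kinases
MTOR	Protein kinases
MAPK1	Protein kinases
MAPK3	Protein kinases
PPARD	Transcription factors
PPARA	Transcription factors
PPARG	Transcription factors
STAT3	Transcription factors
THRA	Transcription factors
TP53	Transcription factors
CCL2	Cytokines and growth factors/receptors
CCR2	Cytokines and growth factors/receptors
TNF	Cytokines and growth factors/receptors
EGFR	Cytokines and growth factors/receptors
IL6	Cytokines and growth factors/receptors
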