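"""Shared constants: feature and TF panels, time points, score threshold."""

#: Epigenomic / transcriptomic feature tracks, in canonical column order.
FEATURES = ("H3K27me3", "H3K4me1", "H3K4me3", "TSS")

#: The six principal transcription factors whose pre-stimulation binding
#: defines the enhancer classes, in canonical column order.
PRINCIPAL_TFS = ("PU.1", "CEBPB", "ATF3", "IRF4", "JUNB", "CTCF")

#: ChIP-seq peak-score binding-call threshold carried over from the source
#: TF-binding dataset; scores are capped at this value before clustering.
SCORE_CAP = 26.9

#: Time points (hours after stimulation) at which TF peak tables exist.
TF_TIME_POINTS = (0.0, 0.5, 1.0, 2.0)

#: Time points (hours) of the expression (RNA-seq) data.
EXPR_TIME_POINTS = (0.0, 1.0, 4.0)

#: Chromatin-state labels for the four-way region clustering.
CHROMATIN_STATES = ("active_promoter", "enhancer", "repressed_1", "repressed_2")
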