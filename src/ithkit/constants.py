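"""Shared vocabulary: SCNA status codes and probe annotation categories."""

STATUS_DEL = 0
STATUS_LOH = 1
STATUS_NEUTRAL = 2
STATUS_AMP = 3

STATUS_LABELS = {
    STATUS_DEL: "DEL",
    STATUS_LOH: "LOH",
    STATUS_NEUTRAL: "NEUTRAL",
    STATUS_AMP: "AMP",
}
STATUS_CODES = {v: k for k, v in STATUS_LABELS.items()}

CPG_CONTEXTS = ("island", "shore", "shelf", "open-sea")
GENE_CONTEXTS = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "first-exon",
    "body",
    "3'UTR",
    "intergenic",
)
#: gene contexts counted as promoter (used for CIMP and driver-methylation calls)
PROMOTER_CONTEXTS = ("TSS1500", "TSS200", "5'UTR", "first-exon")

DRIVER_CLASSES = ("oncogene", "TSG", "other")
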