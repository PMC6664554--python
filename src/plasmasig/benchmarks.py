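"""Published benchmark confusion matrices and cut-offs from the clinical
thoracic-surgery plasma-profiling cohort that the synthetic generator
emulates (144 lung adenocarcinomas, 68 benign lung diseases, 83 colorectal
metastases, 48 typical carcinoids; 92-protein oncology panel).

These counts are *inputs*: they let the metric arithmetic of this package be
checked against independently published numbers even though the underlying
plasma data are not public. Note two quirks of the published tables, kept
as printed: the ERBB3 matrix's benign row sums to 90 rather than 68, and the
pooled-tumors-versus-benign analysis reports its metrics with *benign* as
the positive class.
"""

from __future__ import annotations

from .single_marker import ConfusionMatrix
from .signature import SignatureRule, TripleSignature

#: Single-protein median-cut-off classifiers, LAC vs benign.
#: The published CEACAM5 sensitivity (0.26) disagrees with its own printed
#: matrix (31/144 ≈ 0.22, likely below-LOD exclusions); everything computed
#: here is matrix-consistent.
SINGLE_MARKER_MATRICES: dict[str, ConfusionMatrix] = {
    "CEACAM5": ConfusionMatrix(tp=31, fn=113, tn=68, fp=0, positive_class="LAC"),
    "CXCL17": ConfusionMatrix(tp=86, fn=58, tn=45, fp=23, positive_class="LAC"),
    "VEGFR2": ConfusionMatrix(tp=57, fn=87, tn=24, fp=44, positive_class="LAC"),
    "ERBB3": ConfusionMatrix(tp=63, fn=81, tn=36, fp=54, positive_class="LAC"),
}

#: Three-protein signature (CEACAM5/WFDC2/TCL1A, all "above") applied to the
#: full cohort: tumors (LAC + CRC met) vs benign, and LAC vs CRC met.
SIGNATURE_VS_BENIGN = ConfusionMatrix(tp=65, fn=79, tn=68, fp=0, positive_class="tumor")
SIGNATURE_VS_CRC_MET = ConfusionMatrix(tp=65, fn=79, tn=68, fp=15, positive_class="LAC")

#: Bagged-tree validation matrices: stage-I LAC vs all benign (29 validation
#: samples), stage-I LAC vs non-inflammatory benign (21), and pooled tumors
#: vs benign (59; positive class = benign as printed).
STAGE1_VS_BENIGN = ConfusionMatrix(tp=13, fn=2, tn=13, fp=1, positive_class="LAC")
STAGE1_VS_NONINFLAMMATORY = ConfusionMatrix(tp=14, fn=1, tn=4, fp=2, positive_class="LAC")
TUMORS_VS_BENIGN = ConfusionMatrix(tp=2, fn=12, tn=44, fp=1, positive_class="benign")

#: The published three-protein signature cut-offs (NPX scale).
PUBLISHED_SIGNATURE = TripleSignature(
    rules=(
        SignatureRule("CEACAM5", 4.92, "above"),
        SignatureRule("WFDC2", 75.57, "above"),
        SignatureRule("TCL1A", 8.34, "above"),
    ),
    positive_class="tumor",
)

#: QC headline of the emulated cohort: 5 of 92 proteins had ≥1 value below
#: the limit of detection, i.e. 95% of proteins fully detected.
QC_N_PROTEINS = 92
QC_N_CENSORED_PROTEINS = 5
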