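"""Built-in marker panels, phenotype definitions, and ligand-receptor pairs.

The defaults mirror the cell populations that dominate the lymphocyte-rich
classic Hodgkin lymphoma (LR-CHL) microenvironment: rare malignant CD30+
Hodgkin/Reed-Sternberg (HRS) cells, a CXCL13-producing PD-1+ CD4 T-helper
population that lacks CXCR5, CXCR5+ B cells, and the remaining T/B
background.  They can be replaced wholesale by user-supplied JSON.
"""

from __future__ import annotations

from .phenotyping import PhenotypeDef

#: Markers measured by the default multicolor-IF panel.
DEFAULT_MARKERS = ["CD30", "CD4", "PD1", "CXCL13", "CXCR5", "CD20"]

#: Priority-ordered phenotype definitions (first match wins).
DEFAULT_PHENOTYPES = [
    PhenotypeDef("HRS", required_pos=("CD30",), required_neg=()),
    PhenotypeDef(
        "TFH_CXCL13",
        required_pos=("CD4", "PD1", "CXCL13"),
        required_neg=("CXCR5",),
    ),
    PhenotypeDef("B_CXCR5", required_pos=("CD20", "CXCR5"), required_neg=()),
    PhenotypeDef("T_CD4", required_pos=("CD4",), required_neg=()),
    PhenotypeDef("B", required_pos=("CD20",), required_neg=()),
]

#: Ligand-receptor panel used by interaction scoring.  CXCL13->CXCR5 is the
#: axis of interest; the rest are common immune signaling pairs that serve
#: as the comparison background.
DEFAULT_LR_PAIRS = [
    ("CXCL13", "CXCR5"),
    ("CD40LG", "CD40"),
    ("IL2", "IL2RA"),
    ("TGFB1", "TGFBR2"),
    ("CD274", "PDCD1"),
    ("CCL19", "CCR7"),
    ("CCL21", "CCR7"),
    ("IL21", "IL21R"),
    ("IL4", "IL4R"),
    ("IL6", "IL6R"),
    ("IL10", "IL10RA"),
    ("TNF", "TNFRSF1A"),
    ("LTA", "LTBR"),
    ("ICOSLG", "ICOS"),
    ("CD86", "CD28"),
    ("CD80", "CTLA4"),
    ("CXCL12", "CXCR4"),
    ("CCL5", "CCR5"),
    ("IL7", "IL7R"),
    ("IL15", "IL15RA"),
]

#: Pathological subtype labels accepted in cell annotations.
SUBTYPE_LABELS = ("LR", "NS", "MC", "RLN", "otherCHL")
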