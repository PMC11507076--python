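"""Published summary statistics of the three-cell-line translatome study.

These are the printed dataset-level counts for the HBE, A549 and MCF-7
cell lines (detection at RPKM > 0 against a 20,423-gene reviewed
protein-coding universe, proteome at LFQ intensity > 0).  They serve two
purposes: worked-example arithmetic (recomputing coverage percentages
and Venn intersections from the printed counts) and calibrating the
synthetic generator's default study conditions.  They are inputs, never
outputs, of the pipeline.
"""

from __future__ import annotations

__all__ = [
    "UNIVERSE_SIZE",
    "DETECTED_COUNTS",
    "MCF7_VENN",
]

#: Reviewed protein-coding gene universe size.
UNIVERSE_SIZE = 20423

#: Detected protein-coding genes per cell line and method at cutoff > 0.
#: Proteome was not acquired for HBE.
DETECTED_COUNTS: dict[str, dict[str, int]] = {
    "HBE": {"RNA-seq": 16375, "RNC-seq": 16300, "Ribo-seq": 15815},
    "A549": {"RNA-seq": 16807, "RNC-seq": 15999, "Ribo-seq": 16112, "LC-MS/MS": 5850},
    "MCF-7": {"RNA-seq": 16655, "RNC-seq": 16622, "Ribo-seq": 16641, "LC-MS/MS": 6843},
}

#: Printed MCF-7 Venn figures for RNC-seq vs Ribo-seq at RPKM > 0:
#: union of translated-transcript lists and the method-unique counts.
#: The intersection follows as union - unique_rnc - unique_ribo = 15,676.
MCF7_VENN = {"union": 17039, "unique_rnc": 675, "unique_ribo": 688}
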