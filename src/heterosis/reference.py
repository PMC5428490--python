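"""Published reference counts for the oil palm Dura x Pisifera x Tenera trio.

Per-class gene counts of the 59,078-unigene fruit transcriptome at the key
oil-synthesis stages (endosperm 2.5 MAF, mesocarp 3.5 MAF), as
(total, non-additive) per expression class, plus the AW-box census of the
lipid-synthesis gene set.  These printed counts serve as fixture inputs for
arithmetic over class unions and reporting percentages; the underlying raw
reads are not required.
"""

from __future__ import annotations

from .core import ClassSummary

# class_id -> (total genes, non-additive genes)
ENDOSPERM_CLASS_COUNTS: dict[int, tuple[int, int]] = {
    1: (459, 223),
    2: (8040, 8040),
    3: (5211, 0),
    4: (41500, 6015),
    5: (2478, 2478),
    6: (283, 283),
    7: (464, 0),
    8: (643, 0),
}

MESOCARP_CLASS_COUNTS: dict[int, tuple[int, int]] = {
    1: (404, 181),
    2: (6904, 6904),
    3: (4512, 0),
    4: (42358, 13082),
    5: (3794, 3794),
    6: (876, 876),
    7: (116, 0),
    8: (114, 0),
}

TOTAL_UNIGENES = 59078

# AW-box census over the identified lipid-synthesis genes
LIPID_SYNTHESIS_GENES = 338
LIPID_GENES_WITH_AW_BOX = 207


def _summary(tissue: str, stage: str, counts: dict[int, tuple[int, int]]) -> ClassSummary:
    return ClassSummary(
        tissue=tissue,
        stage=stage,
        total_count={c: t for c, (t, _) in counts.items()},
        nonadditive_count={c: n for c, (_, n) in counts.items()},
    )


def endosperm_summary() -> ClassSummary:
    """Published endosperm (2.5 MAF) per-class counts as a ClassSummary."""
    return _summary("endosperm", "2.5MAF", ENDOSPERM_CLASS_COUNTS)


def mesocarp_summary() -> ClassSummary:
    """Published mesocarp (3.5 MAF) per-class counts as a ClassSummary."""
    return _summary("mesocarp", "3.5MAF", MESOCARP_CLASS_COUNTS)
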