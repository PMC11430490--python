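"""Canonical 37-gene mitogenome layout used as the package's reference fixture.

This is the standard vertebrate mitochondrial gene complement -- 13
protein-coding genes, 22 tRNAs, 2 rRNAs and an origin-spanning control
region -- with the coordinates, strands, gaps and overlaps of a published
16,541 bp douc langur mitogenome.  Coordinates are 1-based inclusive; the
control region wraps through the origin (start 15,584, stop 136, 1094 bp).
"""

from __future__ import annotations

from .core import CONTROL_REGION, PCG, RRNA, TRNA, GeneFeature, MitogenomeAnnotation

__all__ = [
    "GENOME_LENGTH",
    "GENE_ROWS",
    "CONTROL_REGION_ROW",
    "reference_annotation",
]

GENOME_LENGTH = 16541

#: (name, feature_class, start, stop, strand) for the 37 genes, genome order.
GENE_ROWS: tuple[tuple[str, str, int, int, str], ...] = (
    ("trnF(ttc)", TRNA, 137, 207, "+"),
    ("rrnS", RRNA, 208, 1156, "+"),
    ("trnV(gta)", TRNA, 1157, 1222, "+"),
    ("rrnL", RRNA, 1221, 2785, "+"),
    ("trnL2(tta)", TRNA, 2786, 2860, "+"),
    ("nad1", PCG, 2863, 3813, "+"),
    ("trnI(atc)", TRNA, 3818, 3887, "+"),
    ("trnQ(caa)", TRNA, 3885, 3956, "-"),
    ("trnM(atg)", TRNA, 3957, 4024, "+"),
    ("nad2", PCG, 4025, 5062, "+"),
    ("trnW(tga)", TRNA, 5067, 5133, "+"),
    ("trnA(gca)", TRNA, 5141, 5209, "-"),
    ("trnN(aac)", TRNA, 5211, 5283, "-"),
    ("trnC(tgc)", TRNA, 5316, 5381, "-"),
    ("trnY(tac)", TRNA, 5382, 5446, "-"),
    ("cox1", PCG, 5448, 6989, "+"),
    ("trnS2(tca)", TRNA, 6990, 7058, "-"),
    ("trnD(gac)", TRNA, 7062, 7130, "+"),
    ("cox2", PCG, 7132, 7791, "+"),
    ("trnK(aaa)", TRNA, 7860, 7927, "+"),
    ("atp8", PCG, 7929, 8111, "+"),
    ("atp6", PCG, 8090, 8764, "+"),
    ("cox3", PCG, 8770, 9552, "+"),
    ("trnG(gga)", TRNA, 9554, 9620, "+"),
    ("nad3", PCG, 9621, 9965, "+"),
    ("trnR(cga)", TRNA, 9967, 10031, "+"),
    ("nad4l", PCG, 10032, 10325, "+"),
    ("nad4", PCG, 10322, 11689, "+"),
    ("trnH(cac)", TRNA, 11700, 11768, "+"),
    ("trnS1(agc)", TRNA, 11769, 11827, "+"),
    ("trnL1(cta)", TRNA, 11828, 11898, "+"),
    ("nad5", PCG, 11902, 13701, "+"),
    ("nad6", PCG, 13717, 14235, "-"),
    ("trnE(gaa)", TRNA, 14236, 14304, "-"),
    ("cob", PCG, 14309, 15442, "+"),
    ("trnT(aca)", TRNA, 15450, 15514, "+"),
    ("trnP(cca)", TRNA, 15517, 15583, "-"),
)

#: The origin-spanning control region: one record with stop < start.
CONTROL_REGION_ROW = ("control_region", CONTROL_REGION, 15584, 136, "+")


def reference_annotation(include_control_region: bool = True) -> MitogenomeAnnotation:
    """The canonical annotation (37 genes, optionally plus control region)."""
    rows = GENE_ROWS + ((CONTROL_REGION_ROW,) if include_control_region else ())
    return MitogenomeAnnotation(
        features=[GeneFeature(*row) for row in rows],
        genome_length=GENOME_LENGTH,
    )
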