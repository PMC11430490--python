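"""Pairwise mitogenome comparison: anchored rotation, global alignment,
variant calling, and codon-level consequence annotation.

Circular genomes deposited by different groups rarely share a sequence
origin, so before a global alignment both molecules are rotated to a common
anchor (typically the first bases of trnF or the reference's own start).
Differences are then called column-by-column from a global affine-gap
alignment: runs of adjacent gap columns merge into single indel records,
indels are left-aligned against the reference, and every record is assigned
to the covering annotated feature.  Substitutions inside protein-coding
genes are re-evaluated on the coding strand under the vertebrate
mitochondrial code to classify them as synonymous or missense; indels whose
length is not a codon multiple are frameshifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .codons import VERTEBRATE_MITO, GeneticCode, translate_cds
from .core import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    CircularSequence,
    GeneFeature,
    MitogenomeAnnotation,
    extract_feature_sequence,
    feature_length,
    reverse_complement,
)

__all__ = [
    "Scoring",
    "AlignmentResult",
    "VariantRecord",
    "ConsequenceRecord",
    "DiffSummary",
    "rotate",
    "rotate_to_anchor",
    "global_align",
    "call_variants",
    "annotate_consequences",
    "apply_variants",
    "diff_summary",
]

GAP = "-"
#: Allele placeholder: "." marks the absent side of an indel.
MISSING = "."


@dataclass(frozen=True)
class Scoring:
    """Affine-gap alignment scores.  A gap of length k costs
    ``gap_open + (k - 1) * gap_extend``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignmentResult:
    aligned_ref: str
    aligned_query: str
    score: float
    scoring: Scoring

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned strings differ in length")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace(GAP, "")

    @property
    def query(self) -> str:
        return self.aligned_query.replace(GAP, "")


@dataclass(frozen=True)
class VariantRecord:
    """One difference between two genomes, in reference coordinates.

    Substitutions carry equal-length alleles.  An insertion (extra bases in
    the query) has ``ref_allele == "."`` and sits after ``ref_position``; a
    deletion has ``alt_allele == "."`` and ``ref_position`` is its first
    deleted base.
    """

    ref_position: int
    type: str  # substitution | insertion | deletion
    ref_allele: str
    alt_allele: str
    feature_name: str = "intergenic"

    def __post_init__(self) -> None:
        if self.type == "substitution":
            if (
                self.ref_allele == MISSING
                or self.alt_allele == MISSING
                or len(self.ref_allele) != len(self.alt_allele)
            ):
                raise ValueError("substitution requires equal-length non-missing alleles")
        elif self.type == "insertion":
            if self.ref_allele != MISSING or self.alt_allele == MISSING:
                raise ValueError('insertion requires ref_allele "."')
        elif self.type == "deletion":
            if self.alt_allele != MISSING or self.ref_allele == MISSING:
                raise ValueError('deletion requires alt_allele "."')
        else:
            raise ValueError(f"unknown variant type {self.type!r}")


@dataclass(frozen=True)
class ConsequenceRecord:
    variant: VariantRecord
    gene: str
    codon_index: int | None  # 1-based within gene; None outside PCGs
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | missense | frameshift | inframe | noncoding | rna


@dataclass(frozen=True)
class DiffSummary:
    n_total: int
    n_substitutions: int
    n_insertions: int
    n_deletions: int
    by_feature_class: dict[str, int]
    n_aa_changing: int


# ---------------------------------------------------------------------------
# Rotation

def rotate(g: CircularSequence, offset: int) -> CircularSequence:
    """Rotate so that 1-based position ``offset + 1`` becomes the first base."""
    offset %= g.length
    return CircularSequence(
        identifier=g.identifier,
        residues=g.residues[offset:] + g.residues[:offset],
    )


def rotate_annotation(ann: MitogenomeAnnotation, offset: int) -> MitogenomeAnnotation:
    """Shift annotation coordinates to match a rotation by ``offset`` bases."""
    L = ann.genome_length

    def shift(pos: int) -> int:
        return (pos - 1 - offset) % L + 1

    return MitogenomeAnnotation(
        features=[
            GeneFeature(f.name, f.feature_class, shift(f.start), shift(f.stop), f.strand)
            for f in ann
        ],
        genome_length=L,
    )


def rotate_to_anchor(
    g: CircularSequence,
    anchor: str,
    ann: MitogenomeAnnotation | None = None,
) -> tuple[CircularSequence, MitogenomeAnnotation | None, int]:
    """Rotate a circular genome so it starts at a unique anchor sequence.

    The anchor is searched with wrap-around on the forward strand first; a
    unique forward hit wins.  Only when the forward strand has no hit is the
    reverse complement searched, and a unique hit there flips the genome to
    the anchor's strand before rotating.  Zero or multiple candidate
    occurrences raise an error listing the counts.  Returns (rotated genome,
    shifted annotation or None, offset).
    """
    anchor = anchor.upper()
    if not anchor or len(anchor) > g.length:
        raise ValueError("anchor must be non-empty and no longer than the genome")
    doubled = g.residues + g.residues[: len(anchor) - 1]
    fwd = [i for i in range(g.length) if doubled.startswith(anchor, i)]
    if len(fwd) == 1:
        return rotate(g, fwd[0]), (rotate_annotation(ann, fwd[0]) if ann else None), fwd[0]
    if len(fwd) > 1:
        raise ValueError(
            f"anchor must occur exactly once; found {len(fwd)} forward-strand "
            f"occurrences at {[i + 1 for i in fwd]}"
        )
    rc = reverse_complement(g.residues)
    doubled_rc = rc + rc[: len(anchor) - 1]
    rev = [i for i in range(g.length) if doubled_rc.startswith(anchor, i)]
    if len(rev) != 1:
        raise ValueError(
            f"anchor must occur exactly once; found 0 forward and {len(rev)} "
            f"reverse-strand occurrence(s)"
        )
    if ann is not None:
        raise ValueError(
            "anchor found on the minus strand; annotation shifting across a "
            "strand flip is not supported -- flip the genome first"
        )
    flipped = CircularSequence(identifier=g.identifier, residues=rc)
    return rotate(flipped, rev[0]), None, rev[0]


# ---------------------------------------------------------------------------
# Alignment

def global_align(a: str, b: str, scoring: Scoring = Scoring()) -> AlignmentResult:
    """Optimal global alignment under affine-gap scoring (Needleman-Wunsch).

    Backed by Biopython's PairwiseAligner; the first optimal alignment it
    enumerates is taken, which is deterministic for fixed inputs and scores.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(a, b)[0]
    return AlignmentResult(
        aligned_ref=str(aln[0]),
        aligned_query=str(aln[1]),
        score=float(aln.score),
        scoring=scoring,
    )


# ---------------------------------------------------------------------------
# Variant calling

def _left_align_deletion(ref: str, pos: int, length: int) -> int:
    """Shift a deletion of ``length`` bases at 1-based ``pos`` leftwards while
    the preceding reference base equals the last deleted base."""
    while pos > 1 and ref[pos - 2] == ref[pos + length - 2]:
        pos -= 1
    return pos


def _left_align_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Left-align an insertion of ``seq`` placed after 1-based ``pos``
    (``pos == 0`` = before the first base)."""
    while pos >= 1 and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def _feature_at(ann: MitogenomeAnnotation | None, position: int) -> str:
    if ann is None:
        return "intergenic"
    hits = ann.covering(position)
    return hits[0].name if hits else "intergenic"


def call_variants(
    aln: AlignmentResult, ann: MitogenomeAnnotation | None = None
) -> list[VariantRecord]:
    """Variant records from an alignment of query against reference.

    Substitutions are per-column; runs of adjacent gap columns merge into one
    indel, left-aligned against the reference.  Each record is assigned to
    the covering annotated feature, or "intergenic".
    """
    ref_aln, qry_aln = aln.aligned_ref, aln.aligned_query
    ref = aln.ref
    raw: list[tuple[int, str, str, str]] = []  # (pos, type, ref_allele, alt)
    ref_pos = 0
    i = 0
    n = len(ref_aln)
    while i < n:
        r, q = ref_aln[i], qry_aln[i]
        if r != GAP and q != GAP:
            ref_pos += 1
            if r != q:
                raw.append((ref_pos, "substitution", r, q))
            i += 1
        elif q == GAP:  # deletion run in query
            j = i
            while j < n and qry_aln[j] == GAP and ref_aln[j] != GAP:
                j += 1
            deleted = ref_aln[i:j]
            start = ref_pos + 1
            ref_pos += len(deleted)
            raw.append((start, "deletion", deleted, MISSING))
            i = j
        else:  # insertion run in query
            j = i
            while j < n and ref_aln[j] == GAP and qry_aln[j] != GAP:
                j += 1
            inserted = qry_aln[i:j]
            raw.append((ref_pos, "insertion", MISSING, inserted))
            i = j
    variants = []
    for pos, vtype, ref_allele, alt in raw:
        if vtype == "deletion":
            pos = _left_align_deletion(ref, pos, len(ref_allele))
            ref_allele = ref[pos - 1 : pos - 1 + len(ref_allele)]
        elif vtype == "insertion":
            pos, alt = _left_align_insertion(ref, pos, alt)
        anchor_pos = pos if vtype != "insertion" else max(pos, 1)
        variants.append(
            VariantRecord(
                ref_position=pos,
                type=vtype,
                ref_allele=ref_allele,
                alt_allele=alt,
                feature_name=_feature_at(ann, anchor_pos),
            )
        )
    return variants


def apply_variants(ref: str, variants: list[VariantRecord]) -> str:
    """Apply called variants to the reference, reconstructing the query."""
    out = ref
    for v in sorted(variants, key=lambda v: v.ref_position, reverse=True):
        p = v.ref_position
        if v.type == "substitution":
            out = out[: p - 1] + v.alt_allele + out[p - 1 + len(v.ref_allele) :]
        elif v.type == "deletion":
            out = out[: p - 1] + out[p - 1 + len(v.ref_allele) :]
        else:  # insertion after position p
            out = out[:p] + v.alt_allele + out[p:]
    return out


# ---------------------------------------------------------------------------
# Consequences

def _gene_local_index(f: GeneFeature, position: int, L: int) -> int:
    """0-based offset of a genome position within the feature's coding-strand
    sequence (circular)."""
    if f.strand == "+":
        return (position - f.start) % L
    return (f.stop - position) % L


def annotate_consequences(
    variants: list[VariantRecord],
    ann: MitogenomeAnnotation,
    g: CircularSequence,
    code: GeneticCode = VERTEBRATE_MITO,
) -> list[ConsequenceRecord]:
    """Codon-level effect of each variant.

    PCG substitutions: the affected codon is recomputed on the coding strand
    and compared under the genetic code.  PCG indels: frameshift unless the
    length is a codon multiple (then "inframe").  tRNA/rRNA variants are
    "rna"; control region and intergenic variants are "noncoding".  Variants
    covered by overlapping genes yield one record per covering feature.
    """
    L = ann.genome_length
    out = []
    for v in variants:
        if not (1 <= v.ref_position <= L):
            raise ValueError(f"variant position {v.ref_position} outside [1, {L}]")
        anchor = v.ref_position if v.type != "insertion" else max(v.ref_position, 1)
        covering = ann.covering(anchor)
        if not covering:
            out.append(
                ConsequenceRecord(v, "intergenic", None, MISSING, MISSING, "noncoding")
            )
            continue
        for f in covering:
            if f.feature_class in (TRNA, RRNA):
                out.append(ConsequenceRecord(v, f.name, None, MISSING, MISSING, "rna"))
            elif f.feature_class == CONTROL_REGION:
                out.append(
                    ConsequenceRecord(v, f.name, None, MISSING, MISSING, "noncoding")
                )
            elif v.type == "substitution":
                out.append(_substitution_consequence(v, f, g, code, L))
            else:
                indel_len = len(v.ref_allele if v.type == "deletion" else v.alt_allele)
                effect = "frameshift" if indel_len % 3 else "inframe"
                off = _gene_local_index(f, anchor, L)
                out.append(
                    ConsequenceRecord(v, f.name, off // 3 + 1, MISSING, MISSING, effect)
                )
    return out


def _substitution_consequence(
    v: VariantRecord,
    f: GeneFeature,
    g: CircularSequence,
    code: GeneticCode,
    L: int,
) -> ConsequenceRecord:
    coding = extract_feature_sequence(g, f)
    # coding-strand offsets of the substituted bases
    offsets = [
        _gene_local_index(f, (v.ref_position - 1 + k) % L + 1, L)
        for k in range(len(v.ref_allele))
    ]
    alt_bases = v.alt_allele if f.strand == "+" else reverse_complement(v.alt_allele)
    if f.strand == "-":
        offsets = offsets[::-1]
    mutated = list(coding)
    for off, base in zip(offsets, alt_bases):
        if off < len(mutated):
            mutated[off] = base
    mutated_seq = "".join(mutated)
    first_codon = min(offsets) // 3
    last_codon = max(o for o in offsets if o < len(coding)) // 3
    ref_aa = alt_aa = ""
    codon_index = first_codon + 1
    for ci in range(first_codon, last_codon + 1):
        ref_codon = coding[3 * ci : 3 * ci + 3]
        alt_codon = mutated_seq[3 * ci : 3 * ci + 3]
        if len(ref_codon) < 3:
            break  # substitution falls in an incomplete terminal codon
        r = code.aa(ref_codon) or "X"
        a = code.aa(alt_codon) or "X"
        if r != a and not ref_aa:
            codon_index = ci + 1
            ref_aa, alt_aa = r, a
    if not ref_aa:  # no codon changed its residue
        ref_codon = coding[3 * first_codon : 3 * first_codon + 3]
        if len(ref_codon) == 3:
            ref_aa = alt_aa = code.aa(ref_codon) or "X"
            effect = "synonymous"
        else:
            ref_aa = alt_aa = MISSING
            effect = "synonymous"
    else:
        effect = "missense"
    return ConsequenceRecord(v, f.name, codon_index, ref_aa, alt_aa, effect)


def diff_summary(
    variants: list[VariantRecord],
    consequences: list[ConsequenceRecord] | None = None,
    ann: MitogenomeAnnotation | None = None,
) -> DiffSummary:
    """Counts by variant type, by feature class, and amino-acid-changing
    positions (missense, frameshift, or in-frame indel consequences)."""
    by_class: dict[str, int] = {}
    for v in variants:
        cls = "intergenic"
        if ann is not None and v.feature_name != "intergenic":
            try:
                cls = ann.get(v.feature_name).feature_class
            except KeyError:
                cls = "intergenic"
        by_class[cls] = by_class.get(cls, 0) + 1
    aa_changing: set[int] = set()
    for c in consequences or []:
        if c.effect in ("missense", "frameshift", "inframe"):
            aa_changing.add(c.variant.ref_position)
    return DiffSummary(
        n_total=len(variants),
        n_substitutions=sum(1 for v in variants if v.type == "substitution"),
        n_insertions=sum(1 for v in variants if v.type == "insertion"),
        n_deletions=sum(1 for v in variants if v.type == "deletion"),
        by_feature_class=by_class,
        n_aa_changing=len(aa_changing),
    )
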