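"""Rotation, global alignment, variant calling and consequence annotation."""

import numpy as np
import pytest

from mitoprofile.compare import (
    Scoring,
    VariantRecord,
    annotate_consequences,
    apply_variants,
    call_variants,
    diff_summary,
    global_align,
    rotate,
    rotate_to_anchor,
)
from mitoprofile.core import (
    CONTROL_REGION,
    PCG,
    TRNA,
    CircularSequence,
    GeneFeature,
    MitogenomeAnnotation,
    reverse_complement,
)
from mitoprofile.synth import MutationPlan, generate_genome, mutate_genome, random_layout


class TestRotation:
    def test_anchor_rotation(self):
        g = CircularSequence("toy", "CCAATT")
        rotated, _, offset = rotate_to_anchor(g, "AA")
        assert rotated.residues == "AATTCC"
        assert offset == 2

    def test_already_anchored_identity(self):
        g = CircularSequence("toy", "AATTCC")
        rotated, _, _ = rotate_to_anchor(g, "AATT")
        assert rotated.residues == g.residues

    def test_ambiguous_anchor_rejected(self):
        g = CircularSequence("toy", "AATTAATT")
        with pytest.raises(ValueError, match="exactly once"):
            rotate_to_anchor(g, "AATT")

    def test_absent_anchor_rejected(self):
        g = CircularSequence("toy", "CCCCGGGG")
        with pytest.raises(ValueError, match="0 forward"):
            rotate_to_anchor(g, "ATAT")

    def test_wrapping_anchor_found(self):
        g = CircularSequence("toy", "CGGGTTA")  # anchor ACG spans the origin
        rotated, _, offset = rotate_to_anchor(g, "ACG")
        assert rotated.residues == "ACGGGTT"
        assert offset == 6

    def test_random_rotation_restored(self):
        rng = np.random.default_rng(5)
        g, _ = generate_genome(random_layout(rng), at_target=0.6, seed=17)
        anchor = g.residues[:40]
        shifted = rotate(g, 731 % g.length)
        restored, _, _ = rotate_to_anchor(shifted, anchor)
        assert restored.residues == g.residues

    def test_annotation_shifts_with_sequence(self):
        g = CircularSequence("toy", "CCAATGTT")
        ann = MitogenomeAnnotation(
            features=[GeneFeature("t", TRNA, 3, 6, "+")], genome_length=8
        )
        rotated, ann2, _ = rotate_to_anchor(g, "AATG", ann)
        f = ann2.get("t")
        assert (f.start, f.stop) == (1, 4)
        assert rotated.residues[f.start - 1 : f.stop] == "AATG"


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 4.0
        assert aln.aligned_ref == aln.aligned_query == "ACGT"

    def test_single_substitution_column(self):
        aln = global_align("ACGT", "AGGT")
        assert aln.aligned_ref == "ACGT"
        assert aln.aligned_query == "AGGT"

    def test_gap_removal_recovers_inputs(self):
        aln = global_align("ACGTACGTAC", "ACGTCGTAC")
        assert aln.ref == "ACGTACGTAC"
        assert aln.query == "ACGTCGTAC"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_score_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 160
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = list(a)
        for p in sorted(rng.choice(n - 20, size=4, replace=False) + 10):
            b[p] = "ACGT"[int(rng.integers(4))]
        del b[40:43]
        b = "".join(b)
        aln = global_align(a, b)
        assert aln.score == pytest.approx(_affine_oracle_score(a, b))

    def test_determinism(self):
        a = "ACGTACGTACGTAAATTTCCCGGG"
        b = "ACGTACGAACGTAAATTTCCGGG"
        r1 = global_align(a, b)
        r2 = global_align(a, b)
        assert (r1.aligned_ref, r1.aligned_query, r1.score) == (
            r2.aligned_ref,
            r2.aligned_query,
            r2.score,
        )


def _affine_oracle_score(a, b, scoring=Scoring()):
    """Textbook Gotoh affine DP, quadratic space, score only.  Independent of
    the aligner used by the package."""
    match, mismatch = scoring.match, scoring.mismatch
    o, e = scoring.gap_open, scoring.gap_extend
    neg = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)  # best ending in aligned pair
    E = np.full((n + 1, m + 1), neg)  # best ending in gap in a (ins in b)
    F = np.full((n + 1, m + 1), neg)  # best ending in gap in b (del from a)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = max(M[0, j - 1] + o, E[0, j - 1] + e)
    for i in range(1, n + 1):
        F[i, 0] = max(M[i - 1, 0] + o, F[i - 1, 0] + e)
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1]) + s
            E[i, j] = max(M[i, j - 1] + o, E[i, j - 1] + e, F[i, j - 1] + o)
            F[i, j] = max(M[i - 1, j] + o, F[i - 1, j] + e, E[i - 1, j] + o)
    return max(M[n, m], E[n, m], F[n, m])


class TestCallVariants:
    def _ann(self, L=300):
        return MitogenomeAnnotation(
            features=[GeneFeature("nad1", PCG, 50, 250, "+")], genome_length=L
        )

    def test_single_mismatch_in_feature(self):
        rng = np.random.default_rng(9)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        qry = list(ref)
        qry[99] = "A" if ref[99] != "A" else "C"
        aln = global_align(ref, "".join(qry))
        variants = call_variants(aln, self._ann())
        assert len(variants) == 1
        v = variants[0]
        assert (v.ref_position, v.type, v.feature_name) == (100, "substitution", "nad1")

    def test_adjacent_gap_columns_merge_into_one_deletion(self):
        rng = np.random.default_rng(10)
        ref = "".join(rng.choice(list("ACGT"), size=300))
        qry = ref[:150] + ref[153:]
        aln = global_align(ref, qry)
        variants = call_variants(aln, self._ann())
        assert len(variants) == 1
        v = variants[0]
        assert v.type == "deletion"
        assert len(v.ref_allele) == 3

    def test_identical_sequences_no_variants(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert call_variants(aln) == []

    def test_deletion_left_aligned(self):
        # deleting any one A of the homopolymer run is reported at its start
        ref = "CCGTAAAAGTCC"
        qry = "CCGTAAAGTCC"
        aln = global_align(ref, qry)
        (v,) = call_variants(aln)
        assert (v.type, v.ref_position, v.ref_allele) == ("deletion", 5, "A")

    def test_roundtrip_application(self):
        ref = "ACGTACGTACGTACGTACGT"
        qry = "ACGTACCTACGTACGT"
        aln = global_align(ref, qry)
        variants = call_variants(aln)
        assert apply_variants(ref, variants) == qry


class TestConsequences:
    def _pcg_genome(self, cds, strand="+", offset=10):
        pad = "GCGCGCGCGC"
        if strand == "+":
            residues = pad + cds + pad
        else:
            residues = pad + reverse_complement(cds) + pad
        g = CircularSequence("toy", residues)
        ann = MitogenomeAnnotation(
            features=[GeneFeature("gene1", PCG, 11, 10 + len(cds), strand)],
            genome_length=len(residues),
        )
        return g, ann

    def test_thr_to_ile_missense_at_known_codon(self):
        # codon 12 is ACT (Thr); C->T makes ATT (Ile)
        cds = "ATG" + "GCA" * 10 + "ACT" + "GCA" * 5 + "TAA"
        g, ann = self._pcg_genome(cds)
        pos = 10 + 33 + 2  # genome position of the C in codon 12
        v = VariantRecord(pos, "substitution", "C", "T", "gene1")
        (c,) = annotate_consequences([v], ann, g)
        assert (c.effect, c.codon_index, c.ref_aa, c.alt_aa) == ("missense", 12, "T", "I")

    def test_synonymous_atg_to_ata(self):
        cds = "ATG" + "GCA" * 5 + "TAA"
        g, ann = self._pcg_genome(cds)
        v = VariantRecord(13, "substitution", "G", "A", "gene1")  # ATG -> ATA
        (c,) = annotate_consequences([v], ann, g)
        assert c.effect == "synonymous"
        assert c.ref_aa == c.alt_aa == "M"

    def test_minus_strand_substitution_uses_coding_strand(self):
        cds = "ATG" + "GCA" * 10 + "ACT" + "GCA" * 5 + "TAA"
        g, ann = self._pcg_genome(cds, strand="-")
        # coding offset of codon 12's middle base is 34; genome position maps
        # through the reverse complement
        f = ann.get("gene1")
        genome_pos = f.stop - 34
        ref_base = g.residues[genome_pos - 1]
        assert ref_base == "G"  # complement of coding C
        v = VariantRecord(genome_pos, "substitution", "G", "A", "gene1")
        (c,) = annotate_consequences([v], ann, g)
        assert (c.effect, c.codon_index, c.ref_aa, c.alt_aa) == ("missense", 12, "T", "I")

    def test_single_base_deletion_is_frameshift(self):
        cds = "ATG" + "GCA" * 5 + "TAA"
        g, ann = self._pcg_genome(cds)
        v = VariantRecord(15, "deletion", g.residues[14], ".", "gene1")
        (c,) = annotate_consequences([v], ann, g)
        assert c.effect == "frameshift"

    def test_codon_multiple_deletion_is_inframe(self):
        cds = "ATG" + "GCA" * 5 + "TAA"
        g, ann = self._pcg_genome(cds)
        v = VariantRecord(14, "deletion", g.residues[13:16], ".", "gene1")
        (c,) = annotate_consequences([v], ann, g)
        assert c.effect == "inframe"

    def test_rna_and_noncoding_effects(self):
        residues = "A" * 40
        g = CircularSequence("toy", residues)
        ann = MitogenomeAnnotation(
            features=[
                GeneFeature("trnX", TRNA, 1, 10, "+"),
                GeneFeature("control_region", CONTROL_REGION, 21, 30, "+"),
            ],
            genome_length=40,
        )
        vs = [
            VariantRecord(5, "substitution", "A", "G", "trnX"),
            VariantRecord(25, "substitution", "A", "G", "control_region"),
            VariantRecord(35, "substitution", "A", "G", "intergenic"),
        ]
        effects = [c.effect for c in annotate_consequences(vs, ann, g)]
        assert effects == ["rna", "noncoding", "noncoding"]

    def test_overlapping_genes_get_one_record_each(self):
        residues = "GC" + "ATGGCAGCATAA" + "GC"
        g = CircularSequence("toy", residues)
        ann = MitogenomeAnnotation(
            features=[
                GeneFeature("a", PCG, 3, 14, "+"),
                GeneFeature("b", PCG, 9, 14, "+"),
            ],
            genome_length=len(residues),
        )
        v = VariantRecord(10, "substitution", g.residues[9], "T", "a")
        records = annotate_consequences([v], ann, g)
        assert {r.gene for r in records} == {"a", "b"}

    def test_position_out_of_range_rejected(self):
        g = CircularSequence("toy", "ACGTACGT")
        ann = MitogenomeAnnotation(features=[], genome_length=8)
        with pytest.raises(ValueError, match="outside"):
            annotate_consequences(
                [VariantRecord(99, "substitution", "A", "G")], ann, g
            )


class TestDiffSummary:
    def test_empty(self):
        s = diff_summary([], [])
        assert (s.n_total, s.n_aa_changing) == (0, 0)

    def test_synthetic_pair_counts(self):
        rng = np.random.default_rng(31)
        g, ann = generate_genome(random_layout(rng, allow_overlap=False), 0.6, seed=23)
        plan = MutationPlan(
            n_substitutions=6, n_insertions=2, n_deletions=3, seed=11,
            min_spacing=30, margin=60, max_indel_length=4,
        )
        mut, truth = mutate_genome(g, ann, plan)
        aln = global_align(g.residues, mut.residues)
        variants = call_variants(aln, ann)
        cons = annotate_consequences(variants, ann, g)
        s = diff_summary(variants, cons, ann)
        assert (s.n_total, s.n_substitutions, s.n_insertions, s.n_deletions) == (11, 6, 2, 3)
        assert sum(s.by_feature_class.values()) == 11


class TestVariantRecordValidation:
    def test_insertion_requires_missing_ref(self):
        with pytest.raises(ValueError):
            VariantRecord(5, "insertion", "A", "AC")

    def test_deletion_requires_missing_alt(self):
        with pytest.raises(ValueError):
            VariantRecord(5, "deletion", "A", "C")

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord(5, "inversion", "A", "T")
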