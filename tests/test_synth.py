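"""Synthetic genome generator: layout realization, composition control,
codon constraints, and mutation truth sets."""

import numpy as np
import pytest

from mitoprofile.codons import VERTEBRATE_MITO, classify_terminal_codons, translate_cds
from mitoprofile.compare import apply_variants
from mitoprofile.composition import skew_profile
from mitoprofile.core import PCG, extract_feature_sequence, feature_length
from mitoprofile.synth import (
    LayoutEntry,
    LayoutSpec,
    MutationPlan,
    default_layout,
    generate_genome,
    mutate_genome,
    random_layout,
)


class TestDefaultLayout:
    def test_totals(self):
        lay = default_layout()
        assert lay.total_length == 16541
        assert lay.control_region_length == 1094
        pcg = [e for e in lay.entries if e.feature_class == PCG]
        assert len(pcg) == 13
        assert sum(e.length for e in pcg) == 11292

    def test_gap_column_contains_the_printed_overlaps(self):
        gaps = {e.name: e.gap_after for e in default_layout().entries}
        assert gaps["atp8"] == -22
        assert gaps["trnV(gta)"] == -2
        assert gaps["trnI(atc)"] == -3
        assert gaps["nad4l"] == -4

    def test_pcg_lengths_are_codon_multiples(self):
        for e in default_layout().entries:
            if e.feature_class == PCG:
                assert e.length % 3 == 0, e.name

    def test_annotation_realizes_gaps_exactly(self):
        lay = default_layout()
        ann = lay.to_annotation()
        feats = list(ann)
        for entry, (up, down) in zip(lay.entries, zip(feats, feats[1:])):
            assert down.start - up.stop - 1 == entry.gap_after, entry.name


class TestLayoutValidation:
    def test_overlap_longer_than_feature_rejected(self):
        entries = (
            LayoutEntry("a", "tRNA", 60, "+", -70),
            LayoutEntry("b", "tRNA", 65, "+", 5),
        )
        with pytest.raises(ValueError, match="overlap"):
            LayoutSpec(entries=entries, control_region_length=200, control_region_head=10)

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            LayoutSpec(
                entries=(LayoutEntry("a", "tRNA", 0, "+", 0),),
                control_region_length=200,
            )


class TestGenerateGenome:
    def test_determinism(self):
        lay = default_layout()
        g1, _ = generate_genome(lay, 0.614, seed=5)
        g2, _ = generate_genome(lay, 0.614, seed=5)
        assert g1.residues == g2.residues

    def test_different_seeds_differ(self):
        lay = default_layout()
        g1, _ = generate_genome(lay, 0.614, seed=5)
        g2, _ = generate_genome(lay, 0.614, seed=6)
        assert g1.residues != g2.residues

    def test_default_genome_shape(self, default_genome):
        g, ann = default_genome
        assert g.length == 16541
        assert len(ann) == 38  # 37 genes + control region

    def test_pcg_codon_constraints(self, default_genome):
        """Every PCG starts with a canonical ATN codon, ends with a stop, and
        translates without internal stops."""
        g, ann = default_genome
        for rec in classify_terminal_codons(ann, g):
            assert rec.start_class == "canonical-ATN", rec
            assert rec.stop_class == "complete", rec
        for f in ann.by_class(PCG):
            tr = translate_cds(extract_feature_sequence(g, f))
            assert tr.internal_stops == (), f.name

    def test_at_target_on_toy_layout(self):
        lay = LayoutSpec(
            entries=(
                LayoutEntry("pcg0", PCG, 300, "+", 10),
                LayoutEntry("trna0", "tRNA", 70, "+", 5),
            ),
            control_region_length=300,
            control_region_head=50,
        )
        g, _ = generate_genome(lay, at_target=0.5, seed=3)
        assert abs(skew_profile(g.residues).at_content - 0.5) < 0.02

    @pytest.mark.parametrize("at_target", [0.45, 0.614, 0.75])
    def test_at_target_on_default_layout(self, at_target):
        g, _ = generate_genome(default_layout(), at_target=at_target, seed=8)
        assert abs(skew_profile(g.residues).at_content - at_target) < 0.005

    def test_bad_at_target_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(default_layout(), at_target=1.2, seed=0)

    def test_random_layouts_conserve_and_satisfy_constraints(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            lay = random_layout(rng)
            g, ann = generate_genome(lay, 0.6, seed=int(rng.integers(2**31)))
            assert g.length == lay.total_length
            for f in ann.by_class(PCG):
                tr = translate_cds(extract_feature_sequence(g, f))
                assert tr.internal_stops == ()


class TestMutateGenome:
    def test_zero_plan_is_identity(self, default_genome):
        g, ann = default_genome
        plan = MutationPlan(0, 0, 0, seed=1)
        mut, truth = mutate_genome(g, ann, plan)
        assert mut.residues == g.residues
        assert truth == []

    def test_truth_count_matches_plan(self, default_genome):
        g, ann = default_genome
        plan = MutationPlan(30, 4, 9, seed=7)
        mut, truth = mutate_genome(g, ann, plan)
        assert len(truth) == 43
        types = [v.type for v in truth]
        assert types.count("substitution") == 30
        assert types.count("insertion") == 4
        assert types.count("deletion") == 9

    def test_truth_applies_to_reference(self, default_genome):
        g, ann = default_genome
        plan = MutationPlan(10, 2, 3, seed=13)
        mut, truth = mutate_genome(g, ann, plan)
        assert apply_variants(g.residues, truth) == mut.residues

    def test_determinism(self, default_genome):
        g, ann = default_genome
        plan = MutationPlan(5, 1, 2, seed=21)
        m1, t1 = mutate_genome(g, ann, plan)
        m2, t2 = mutate_genome(g, ann, plan)
        assert m1.residues == m2.residues
        assert t1 == t2

    def test_events_respect_spacing(self, default_genome):
        g, ann = default_genome
        plan = MutationPlan(20, 5, 5, seed=2, min_spacing=50, max_indel_length=6)
        _, truth = mutate_genome(g, ann, plan)
        positions = sorted(v.ref_position for v in truth)
        # left-normalization can pull an indel a few bases leftward, but
        # events stay well separated
        assert min(b - a for a, b in zip(positions, positions[1:])) >= 30

    def test_infeasible_plan_rejected(self, default_genome):
        g, ann = default_genome
        with pytest.raises(ValueError, match="infeasible"):
            mutate_genome(g, ann, MutationPlan(400, 0, 0, seed=1, min_spacing=50))
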