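"""Synthetic annotated mitogenomes with controlled composition and exact
mutation truth sets.

The generator realizes a layout (feature lengths, strands, signed
inter-feature gaps, and an origin-spanning control region) as a concrete
circular sequence:

* background regions (tRNA, rRNA, control region, spacers) are drawn with an
  exact base-count quota matching the requested A+T fraction;
* every protein-coding gene gets a canonical ATN start, a stop codon, and a
  stop-free interior sampled codon-wise from sense codons of the vertebrate
  mitochondrial code, with the per-base composition compensated so that
  excluding stop codons does not bias the realized A+T away from target;
* where gene overlaps pin conflicting start/stop bases (e.g. a downstream
  start codon inside an upstream gene's stop), alternative ATN starts and
  alternative stop codons are tried for a consistent joint assignment, and a
  warning is logged if none exists.

Mutated copies implant substitutions, insertions and deletions at
well-separated positions and return a truth set in reference coordinates,
left-normalized with the same routine the variant caller uses so truth and
calls share one canonical representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .codons import VERTEBRATE_MITO, GeneticCode
from .compare import (
    MISSING,
    VariantRecord,
    _left_align_deletion,
    _left_align_insertion,
    apply_variants,
)
from .core import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    CircularSequence,
    GeneFeature,
    MitogenomeAnnotation,
    feature_length,
)
from .layouts import CONTROL_REGION_ROW, GENE_ROWS, GENOME_LENGTH

__all__ = [
    "LayoutEntry",
    "LayoutSpec",
    "MutationPlan",
    "default_layout",
    "random_layout",
    "generate_genome",
    "mutate_genome",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_START_CANDIDATES = ("ATG", "ATA", "ATT", "ATC")
_STOP_CANDIDATES = ("TAA", "TAG", "AGA", "AGG")


@dataclass(frozen=True)
class LayoutEntry:
    """One gene in a layout: its class, length, strand, and the signed gap to
    the next feature (the last entry's gap leads to the control region)."""

    name: str
    feature_class: str
    length: int
    strand: str
    gap_after: int


@dataclass(frozen=True)
class LayoutSpec:
    """Ordered gene entries plus an origin-spanning control region.

    ``control_region_head`` is the number of control-region bases lying
    before the first gene, so the first gene starts at head + 1 and the
    control region wraps through the origin whenever head >= 1.  The total
    genome length is the sum of entry lengths, signed gaps, and the control
    region length.
    """

    entries: tuple[LayoutEntry, ...]
    control_region_length: int
    control_region_head: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("layout needs at least one gene entry")
        if self.control_region_length < 1:
            raise ValueError("control region length must be positive")
        if not (0 <= self.control_region_head < self.control_region_length):
            raise ValueError("control_region_head must lie within the control region")
        for e in self.entries:
            if e.length < 1:
                raise ValueError(f"entry {e.name!r} has non-positive length")
        for a, b in zip(self.entries, self.entries[1:]):
            if a.gap_after < 0 and -a.gap_after >= min(a.length, b.length):
                raise ValueError(
                    f"overlap between {a.name!r} and {b.name!r} is longer than "
                    "either feature"
                )
        if self.total_length < 1:
            raise ValueError("layout implies a non-positive genome length")

    @property
    def total_length(self) -> int:
        return (
            sum(e.length for e in self.entries)
            + sum(e.gap_after for e in self.entries)
            + self.control_region_length
        )

    def to_annotation(self) -> MitogenomeAnnotation:
        """Concrete 1-based coordinates realizing the layout's gaps exactly."""
        L = self.total_length
        features = []
        pos = self.control_region_head + 1  # first gene start
        for e in self.entries:
            start = pos
            stop = start + e.length - 1
            if stop > L:
                raise ValueError(f"entry {e.name!r} runs past the genome end")
            features.append(GeneFeature(e.name, e.feature_class, start, stop, e.strand))
            pos = stop + e.gap_after + 1
        cr_start = pos
        cr_stop = self.control_region_head
        if cr_stop == 0:  # non-wrapping control region closing the circle
            cr_stop = L
        expected_start = L - (self.control_region_length - self.control_region_head) + 1
        if cr_start != expected_start:
            raise ValueError(
                f"layout arithmetic is inconsistent: control region starts at "
                f"{cr_start}, expected {expected_start}"
            )
        features.append(
            GeneFeature("control_region", CONTROL_REGION, cr_start, cr_stop, "+")
        )
        return MitogenomeAnnotation(features=features, genome_length=L)


def default_layout() -> LayoutSpec:
    """The canonical 37-gene layout: 13 PCGs (11,292 bp), 22 tRNAs, 2 rRNAs,
    and a 1094 bp origin-spanning control region; total 16,541 bp."""
    entries = []
    rows = list(GENE_ROWS)
    cr_start = CONTROL_REGION_ROW[2]
    for i, (name, cls, start, stop, strand) in enumerate(rows):
        next_start = rows[i + 1][2] if i + 1 < len(rows) else cr_start
        entries.append(
            LayoutEntry(
                name=name,
                feature_class=cls,
                length=stop - start + 1,
                strand=strand,
                gap_after=next_start - stop - 1,
            )
        )
    cr_len = (GENOME_LENGTH - cr_start + 1) + CONTROL_REGION_ROW[3]
    return LayoutSpec(
        entries=tuple(entries),
        control_region_length=cr_len,
        control_region_head=CONTROL_REGION_ROW[3],
    )


def random_layout(
    rng: np.random.Generator,
    n_pcg: int = 3,
    n_trna: int = 6,
    n_rrna: int = 1,
    allow_overlap: bool = True,
) -> LayoutSpec:
    """A small random but valid layout for property testing."""
    entries: list[LayoutEntry] = []
    kinds = (
        [(PCG, i) for i in range(n_pcg)]
        + [(TRNA, i) for i in range(n_trna)]
        + [(RRNA, i) for i in range(n_rrna)]
    )
    order = rng.permutation(len(kinds))
    for idx in order:
        cls, i = kinds[idx]
        if cls == PCG:
            length = 3 * int(rng.integers(30, 120))
            strand = "+" if rng.random() < 0.85 else "-"
            name = f"pcg{i}"
        elif cls == TRNA:
            length = int(rng.integers(59, 76))
            strand = "+" if rng.random() < 0.7 else "-"
            name = f"trna{i}"
        else:
            length = int(rng.integers(150, 500))
            strand = "+"
            name = f"rrna{i}"
        entries.append(LayoutEntry(name, cls, length, strand, gap_after=0))
    # assign gaps; occasional small overlaps between non-PCG neighbours
    for i in range(len(entries)):
        nxt = entries[i + 1] if i + 1 < len(entries) else None
        if (
            allow_overlap
            and nxt is not None
            and rng.random() < 0.15
            and entries[i].feature_class != PCG
            and nxt.feature_class != PCG
        ):
            gap = -int(rng.integers(1, 6))
        else:
            gap = int(rng.integers(0, 40))
        entries[i] = replace(entries[i], gap_after=gap)
    cr_len = int(rng.integers(200, 600))
    head = int(rng.integers(1, cr_len))
    return LayoutSpec(
        entries=tuple(entries),
        control_region_length=cr_len,
        control_region_head=head,
    )


# ---------------------------------------------------------------------------
# Genome generation

def _genome_index(f: GeneFeature, coding_offset: int, L: int) -> int:
    """0-based genome index of a coding-strand offset within a feature."""
    if f.strand == "+":
        return (f.start - 1 + coding_offset) % L
    return (f.stop - 1 - coding_offset) % L


def _codon_positions_and_bases(
    f: GeneFeature, codon_idx: int, codon: str, L: int
) -> list[tuple[int, str]]:
    out = []
    for j, base in enumerate(codon):
        gpos = _genome_index(f, 3 * codon_idx + j, L)
        out.append((gpos, base if f.strand == "+" else _COMPLEMENT[base]))
    return out


def _sense_codon_distribution(
    at_target: float, code: GeneticCode
) -> tuple[list[str], np.ndarray]:
    """Sense codons with probabilities whose conditional per-base A+T equals
    the target (compensating for the exclusion of AT-rich stop codons)."""

    sense = code.sense_codons()

    def conditional_at(q: float) -> float:
        p = {"A": q / 2, "T": q / 2, "G": (1 - q) / 2, "C": (1 - q) / 2}
        probs = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in sense])
        probs /= probs.sum()
        at_per_codon = np.array([sum(b in "AT" for b in c) for c in sense])
        return float((probs * at_per_codon).sum()) / 3.0

    lo, hi = 0.02, 0.98
    for _ in range(60):  # bisection; conditional_at is monotone in q
        mid = (lo + hi) / 2
        if conditional_at(mid) < at_target:
            lo = mid
        else:
            hi = mid
    q = (lo + hi) / 2
    p = {"A": q / 2, "T": q / 2, "G": (1 - q) / 2, "C": (1 - q) / 2}
    probs = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in sense])
    probs /= probs.sum()
    return sense, probs


class _CodonSampler:
    """Batched deterministic sampling of sense codons."""

    def __init__(self, rng: np.random.Generator, codons: list[str], probs: np.ndarray):
        self.rng = rng
        self.codons = codons
        self.probs = probs
        self._batch: list[int] = []

    def draw(self) -> str:
        if not self._batch:
            self._batch = list(self.rng.choice(len(self.codons), size=2048, p=self.probs))
        return self.codons[self._batch.pop()]


def generate_genome(
    layout: LayoutSpec,
    at_target: float = 0.614,
    seed: int = 0,
    code: GeneticCode = VERTEBRATE_MITO,
) -> tuple[CircularSequence, MitogenomeAnnotation]:
    """Deterministically realize a layout as an annotated circular genome.

    Every PCG begins with a canonical ATN codon (ATG where overlaps permit)
    and ends with a stop codon, with no internal stops; the realized
    whole-genome A+T fraction lands within 0.5 percentage points of
    ``at_target`` (base quotas are exact up to what overlap pinning allows).
    """
    if not (0 < at_target < 1):
        raise ValueError("at_target must lie in (0, 1)")
    ann = layout.to_annotation()
    L = ann.genome_length
    rng = np.random.default_rng(seed)

    # 1. background with exact base quotas
    n_at = round(L * at_target)
    n_a = n_at // 2
    n_t = n_at - n_a
    n_gc = L - n_at
    n_g = n_gc // 2
    n_c = n_gc - n_g
    pool = np.array(["A"] * n_a + ["T"] * n_t + ["G"] * n_g + ["C"] * n_c)
    seq = list(rng.permutation(pool))

    pcgs = ann.by_class(PCG)
    pins: dict[int, str] = {}

    def pin_codon(f: GeneFeature, codon_idx: int, candidates: tuple[str, ...], role: str) -> None:
        for cand in candidates:
            placed = _codon_positions_and_bases(f, codon_idx, cand, L)
            if all(pins.get(p, b) == b for p, b in placed):
                for p, b in placed:
                    pins[p] = b
                    seq[p] = b
                return
        log.warning(
            "could not satisfy %s codon of %s against overlapping pins", role, f.name
        )

    # 2. pin start and stop codons (genome order)
    for f in pcgs:
        n_codons = feature_length(f, L) // 3
        pin_codon(f, 0, _START_CANDIDATES, "start")
        pin_codon(f, n_codons - 1, _STOP_CANDIDATES, "stop")

    # 3. stop-free interiors, codon-wise
    sense, probs = _sense_codon_distribution(at_target, code)
    sampler = _CodonSampler(rng, sense, probs)
    consistent_cache: dict[tuple, list[str]] = {}

    def write_interior_codon(f: GeneFeature, ci: int) -> None:
        for _ in range(100):
            codon = sampler.draw()
            placed = _codon_positions_and_bases(f, ci, codon, L)
            if all(pins.get(p, b) == b for p, b in placed):
                for p, b in placed:
                    seq[p] = b
                return
        # pinned bases make random draws unlikely: enumerate consistent codons
        key = tuple(
            (j, pins[p])
            for j, (p, _) in enumerate(_codon_positions_and_bases(f, ci, "AAA", L))
            if p in pins
        )
        options = consistent_cache.get((f.strand, key))
        if options is None:
            options = []
            for cand in sense:
                placed = _codon_positions_and_bases(f, ci, cand, L)
                if all(pins.get(p, b) == b for p, b in placed):
                    options.append(cand)
            consistent_cache[(f.strand, key)] = options
        if not options:
            log.warning("no sense codon fits pins at %s codon %d", f.name, ci + 1)
            return
        codon = options[int(rng.integers(len(options)))]
        for p, b in _codon_positions_and_bases(f, ci, codon, L):
            seq[p] = b

    for f in pcgs:
        n_codons = feature_length(f, L) // 3
        for ci in range(1, n_codons - 1):
            write_interior_codon(f, ci)

    # 4. repair: overlapping genes may write stops into each other's frame
    def read_codon(f: GeneFeature, ci: int) -> str:
        bases = []
        for j in range(3):
            p = _genome_index(f, 3 * ci + j, L)
            b = seq[p]
            bases.append(b if f.strand == "+" else _COMPLEMENT[b])
        return "".join(bases)

    for _ in range(60):
        dirty = False
        for f in pcgs:
            n_codons = feature_length(f, L) // 3
            for ci in range(1, n_codons - 1):
                if read_codon(f, ci) in code.stop_codons:
                    write_interior_codon(f, ci)
                    dirty = True
        if not dirty:
            break
    else:
        log.warning("internal-stop repair did not converge; some stops may remain")

    # 5. touch up background bases so the realized A+T hits the quota
    pcg_cover = set()
    for f in pcgs:
        for k in range(feature_length(f, L)):
            pcg_cover.add(_genome_index(f, k, L))
    adjustable = [i for i in range(L) if i not in pcg_cover and i not in pins]
    current_at = sum(1 for b in seq if b in "AT")
    delta = n_at - current_at  # positive: need more A/T
    order = rng.permutation(len(adjustable))
    flip_to = ["A", "T"] if delta > 0 else ["G", "C"]
    source = "GC" if delta > 0 else "AT"
    k = 0
    for oi in order:
        if delta == 0:
            break
        i = adjustable[oi]
        if seq[i] in source:
            seq[i] = flip_to[k % 2]
            k += 1
            delta += -1 if delta > 0 else 1
    if delta != 0:
        log.warning("A+T quota missed by %d bases (insufficient adjustable sites)", delta)

    g = CircularSequence(
        identifier=f"synthetic_mitogenome_seed{seed}", residues="".join(seq)
    )
    return g, ann


# ---------------------------------------------------------------------------
# Mutation with truth set

@dataclass(frozen=True)
class MutationPlan:
    """Counts and geometry of implanted events.

    ``min_spacing`` separates event start positions (plus the maximum indel
    length) so events never interact; ``margin`` keeps events away from the
    sequence origin so a linear global alignment of the rotated circle stays
    anchored at both ends.
    """

    n_substitutions: int
    n_insertions: int
    n_deletions: int
    seed: int
    max_indel_length: int = 6
    min_spacing: int = 50
    margin: int = 100

    @property
    def n_events(self) -> int:
        return self.n_substitutions + self.n_insertions + self.n_deletions


def mutate_genome(
    g: CircularSequence,
    ann: MitogenomeAnnotation,
    plan: MutationPlan,
) -> tuple[CircularSequence, list[VariantRecord]]:
    """Implant the planned events and return (mutated genome, truth records).

    Truth records use reference coordinates with "." marking the absent side
    of an indel, and are left-normalized exactly as the variant caller
    normalizes its calls.
    """
    L = g.length
    ref = g.residues
    rng = np.random.default_rng(plan.seed)
    n = plan.n_events
    if n == 0:
        return CircularSequence(g.identifier + "_mut", ref), []

    lo = plan.margin + 1
    hi = L - plan.margin - plan.max_indel_length
    spacing = plan.min_spacing + plan.max_indel_length
    slack = (hi - lo) - (n - 1) * spacing
    if slack < 0:
        raise ValueError(
            f"plan infeasible: {n} events with spacing {spacing} do not fit in "
            f"[{lo}, {hi}]"
        )
    # sorted draws plus an arithmetic spacing ramp: consecutive positions are
    # guaranteed >= spacing apart, no rejection needed
    draw = np.sort(rng.integers(0, slack + 1, size=n))
    positions = [int(lo + d + i * spacing) for i, d in enumerate(draw)]

    types = (
        ["substitution"] * plan.n_substitutions
        + ["insertion"] * plan.n_insertions
        + ["deletion"] * plan.n_deletions
    )
    types = [types[i] for i in rng.permutation(n)]

    bases = "ACGT"
    truth: list[VariantRecord] = []
    for pos, vtype in zip(positions, types):
        if vtype == "substitution":
            ref_base = ref[pos - 1]
            alt = bases[int(rng.integers(4))]
            while alt == ref_base:
                alt = bases[int(rng.integers(4))]
            rec = VariantRecord(pos, "substitution", ref_base, alt)
        elif vtype == "deletion":
            length = int(rng.integers(1, plan.max_indel_length + 1))
            p = _left_align_deletion(ref, pos, length)
            rec = VariantRecord(p, "deletion", ref[p - 1 : p - 1 + length], MISSING)
        else:
            length = int(rng.integers(1, plan.max_indel_length + 1))
            ins = "".join(bases[int(b)] for b in rng.integers(0, 4, size=length))
            p, ins = _left_align_insertion(ref, pos, ins)
            rec = VariantRecord(p, "insertion", MISSING, ins)
        anchor = rec.ref_position if rec.type != "insertion" else max(rec.ref_position, 1)
        hits = ann.covering(anchor)
        truth.append(
            replace(rec, feature_name=hits[0].name if hits else "intergenic")
        )

    mutated = apply_variants(ref, truth)
    return (
        CircularSequence(g.identifier + "_mut", mutated),
        sorted(truth, key=lambda v: v.ref_position),
    )
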