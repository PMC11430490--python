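# Methods

## Coordinate model

All coordinates are 1-based and fully inclusive, the convention of published
mitogenome feature tables, so printed table rows can be used directly as
input. A circular genome of length L joins position L to position 1; a
feature with `stop < start` is a single record wrapping through the origin
(the control region in the canonical layout: start 15,584, stop 136, length
`(L − start + 1) + stop = 1094`). Wrapping extraction concatenates the
suffix from `start` with the prefix to `stop`; minus-strand features return
the reverse complement of that span (coding orientation).

The signed intergenic gap between consecutive features is
`downstream.start − upstream.stop − 1`, with L added when the pair closes
the circle through the origin; negative gaps are overlaps. Reported both
ways the literature uses them: signed in tables (−22), by magnitude in prose
("a 22 bp overlap"). With the closing pair included, the conservation
identity `Σ feature lengths + Σ signed gaps = L` holds for every valid
annotation; it is property-tested on the canonical layout and on random
layouts, and the generator realizes layouts through the same arithmetic.
Features contained inside another feature are still paired by genome order
of starts, with a warning, so degenerate inputs cannot crash the table.

## Composition statistics

`AT-skew = (A − T)/(A + T)`, `GC-skew = (G − C)/(G + C)`,
`A+T = (A + T)/(A + C + G + T)`. The GC-skew is the standard G-versus-C
asymmetry statistic of the mitogenomics literature; published primate PCG
values (≈ −0.35 with G ≈ 12.5 % and C ≈ 26.1 %) are consistent only with
this form. Ambiguous bases (N) are tallied separately and excluded from all
denominators. The PCG aggregate concatenates the 13 genes in genome order in
coding orientation (the minus-strand nad6 contributes its reverse
complement), and overlapping bases count once per gene they belong to, so
the aggregate equals the sum of per-gene profiles — an invariant the tests
assert. Values are kept at full precision internally; report writers round
percentages to 2 decimals and skews to 5.

## Genetic code and codon statistics

NCBI translation table 2 (vertebrate mitochondrial): TGA→Trp, ATA→Met,
AGA/AGG→stop. Translation reads frame 0 and reports one letter per complete
codon, the 0–2 base remainder, and any internal stop positions. Start codons
are classified canonical for any ATN (ATG/ATA/ATT/ATC — all observed as
mitochondrial initiators), alternative for TTG/GTG, invalid otherwise. Stops
are complete when the final full codon is in the stop set, incomplete for a
trailing T or TA (completed to TAA by mRNA polyadenylation — required for
real mitogenomes, where several PCGs end this way), invalid otherwise.

`RSCU(c) = n_c · k / Σ_family n` with k the synonymous family size; a family
with zero total gets RSCU 0 throughout, so family sums equal k whenever the
family is observed (property-tested on random counts). Stop codons are
excluded from RSCU and from amino-acid frequencies, the standard practice
for mitochondrial codon-usage figures. Codons containing N are skipped and
counted as ambiguous.

## Control region analysis

Positions in all control-region reports are local to the wrap-extracted
sequence (1..length). Motif counting defaults to overlapping occurrences
(every start position); a greedy non-overlapping mode is a flag, since
published motif counts rarely state their convention. Tandem-repeat
detection is exact-match only: for each unit size u it finds maximal
periodic runs (`seq[i] == seq[i+u]`), reports each run once at its leftmost
start with its complete-copy count, and discards non-primitive units (so a
5-base homopolymer is one array of unit "A" × 5, never also "AA"). The naive
O(n · max_unit) scan is fully adequate at control-region scale (~1.1 kb) and
keeps the brute-force test oracle trivial; no mismatch tolerance is
attempted.

## Pairwise comparison

Two circular genomes must share an origin before a linear global alignment
is meaningful, so the query can first be rotated onto a unique anchor
(forward-strand hits take precedence; a unique reverse-strand hit flips the
molecule first). Alignment is optimal global affine-gap (Needleman–Wunsch/
Gotoh) via Biopython's PairwiseAligner, defaults match +1, mismatch −1, gap
open −4, gap extend −1, where a gap of length k costs
`open + (k − 1)·extend`; all scores are configurable. The first optimal
alignment enumerated is taken, which is deterministic for fixed inputs; an
independent textbook quadratic DP in the test suite confirms score
optimality.

Variants are read per alignment column: substitutions per column, runs of
adjacent gap columns merged into single indels. Indels are left-aligned
against the reference (shifting while the preceding base equals the last
indel base), giving one canonical representation; the synthetic truth
generator normalizes with the same routine, so recovery comparisons are
representation-independent. Insertions anchor after their reference
position; "." marks the absent side of an indel.

Consequences: PCG substitutions are re-evaluated on the coding strand — the
affected codon(s) recomputed, synonymous vs missense decided under table 2,
with the first changed codon's index and residues reported. PCG indels are
frameshift when their length is not a codon multiple and "inframe"
otherwise (an extra effect value beyond the classic triple, since an
in-frame indel changes the protein without shifting the frame). tRNA/rRNA
variants get effect "rna" — structural RNAs are never translated — and
control-region or intergenic variants "noncoding". A variant inside
overlapping genes (atp8/atp6, nad4l/nad4) yields one consequence record per
covering gene.

## Synthetic genome generator

The generator's default layout is the canonical 37-gene complement with the
published coordinates: 16,541 bp, 13 PCGs totalling 11,292 bp (all lengths
codon multiples), tRNAs 59–75 bp, rRNAs 949/1565 bp, the four overlaps
(−2, −3, −22, −4), the 68 bp longest spacer, and a 1094 bp control region
of which 136 bp precede the first gene — so generated annotations are
coordinate-identical to the reference table. Default A+T is 0.614, the
whole-genome value reported for this genome.

Realization: background bases are drawn by shuffling an exact count quota
for the target A+T (balanced A/T and G/C). Each PCG gets a pinned ATG start
and TAA stop; where overlaps make pins collide (the nad4l stop shares bases
with the nad4 start), alternative ATN starts and alternative stops are tried
for a consistent joint assignment — nad4 then starts with ATA, itself a
canonical mitochondrial initiator — and only if none exists is a warning
logged. Interiors are sampled codon-wise from sense codons with the per-base
composition solved (by bisection) so that the sense-conditional A+T equals
the target: excluding the AT-rich stop codons would otherwise depress PCG
A+T by about one percentage point. A repair pass rescans all PCG frames
(overlapping genes can write stops into each other) until stop-free, and a
final pass flips unconstrained background bases to land the genome-wide
count on the quota exactly. tRNA/rRNA features are plain background — no
cloverleaf or secondary-structure realism, which is out of scope — and the
control region is background too, so motif/repeat tests construct their own
sequences.

Mutated copies place events at positions drawn with a guaranteed minimum
spacing (sorted uniform draws plus a spacing ramp), at least 100 bp from the
origin so the global alignment stays anchored at both ends, and left-
normalize indel truth records with the caller's own routine. With the
default spacing (50 bp + max indel 6 bp) events never interact, which is
what makes exact precision = recall = 1.0 the correct expectation rather
than an optimistic one.

What passing tests therefore show: the statistics, coordinate arithmetic and
variant machinery are exact on genomes whose structure matches real
mitogenomes but whose sequence is memoryless. What they do not show:
performance on real data's repeat structure (control-region tandem arrays
can make indel placement ambiguous), heteroplasmy, sequencing error, or
biased mutation spectra — none of which the generator emulates.

## Problem sizes and numerical choices

The test suite runs the full 16.5 kb generate–mutate–align–call pipeline at
the published scale (43 events: 30 substitutions, 4 insertions, 9
deletions) once, and the 100-seed round-trip property on compact random
layouts (~1.5–2.5 kb), which exercises the identical code paths; a full
16.5 kb affine alignment takes a few seconds, so the property suite uses the
smaller genomes to keep the default run fast. Skew denominators of zero
(no A/T or no G/C) yield skew 0 rather than an error; empty or all-N regions
are errors. Floating-point comparisons in reports happen only after
rounding; internal values are exact integer counts wherever possible.

## Known limitations

- Reproducing the published cross-accession numbers (43 differences / 23
  amino-acid changes between two deposited genomes, their per-accession
  composition tables) requires fetching those GenBank records; the recipe is
  in the README, and the machinery is validated on synthetic truth instead.
- The alignment's tie-breaking among co-optimal paths is the aligner's
  canonical first path, not a documented diagonal-first rule; calls are
  deterministic, and left-alignment removes representation ambiguity for
  isolated indels, but co-optimal placements in long repeats may differ from
  other tools' output.
- Consequence annotation evaluates one variant at a time against the
  reference gene model; compound effects of multiple nearby variants on the
  same codon, and downstream effects of frameshifts, are not computed.
- GenBank reading is a thin convenience mapping CDS/tRNA/rRNA/D-loop onto
  the package's types; join() locations (other than origin wrap expressed as
  stop < start) and multi-record files are not supported.
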