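"""Vertebrate mitochondrial genetic code, translation, RSCU and amino-acid
frequency statistics.

The vertebrate mitochondrial code (NCBI translation table 2) differs from the
standard code in four assignments: TGA encodes Trp, ATA encodes Met, and AGA /
AGG are stop codons.  Mitochondrial protein genes may also terminate on an
incomplete stop codon -- a trailing T or TA completed to TAA by
polyadenylation of the mRNA -- so a 1-2 base remainder after the last full
codon is classified, not treated as an error.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .core import (
    PCG,
    CircularSequence,
    MitogenomeAnnotation,
    extract_feature_sequence,
)

__all__ = [
    "GeneticCode",
    "VERTEBRATE_MITO",
    "Translation",
    "TerminalCodons",
    "CodonUsageTable",
    "translate_cds",
    "classify_terminal_codons",
    "count_codons",
    "rscu",
    "aa_frequencies",
    "codon_usage_table",
]

_ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]


@dataclass(frozen=True)
class GeneticCode:
    """A codon table: codon->amino acid ('*' for stop) plus start/stop sets."""

    code_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi_id(cls, code_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(
            code_id=code_id,
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
            stop_codons=frozenset(table.stop_codons),
        )

    def aa(self, codon: str) -> str | None:
        """Amino acid for a codon, ``'*'`` for stops, None if ambiguous (N)."""
        return self.codon_to_aa.get(codon)

    def sense_codons(self) -> list[str]:
        return [c for c in _ALL_CODONS if self.codon_to_aa[c] != "*"]

    def family(self, amino_acid: str) -> list[str]:
        """Synonymous codon family for one amino acid."""
        return [c for c in _ALL_CODONS if self.codon_to_aa[c] == amino_acid]


#: NCBI translation table 2.
VERTEBRATE_MITO = GeneticCode.from_ncbi_id(2)


@dataclass(frozen=True)
class Translation:
    """Translation of a CDS read in frame 0: one letter per complete codon
    ('*' for stops), the 0-2 base incomplete-stop remainder, and the 1-based
    indices of internal stop codons."""

    protein: str
    remainder: str
    internal_stops: tuple[int, ...]


def translate_cds(seq: str, code: GeneticCode = VERTEBRATE_MITO) -> Translation:
    if len(seq) < 3:
        raise ValueError(f"CDS of length {len(seq)} is shorter than one codon")
    n_codons = len(seq) // 3
    letters = []
    internal = []
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        aa = code.aa(codon)
        if aa is None:  # codon containing N
            aa = "X"
        if aa == "*" and i < n_codons - 1:
            internal.append(i + 1)
        letters.append(aa)
    return Translation(
        protein="".join(letters),
        remainder=seq[3 * n_codons :],
        internal_stops=tuple(internal),
    )


@dataclass(frozen=True)
class TerminalCodons:
    """Start/stop codon classification for one protein-coding gene."""

    name: str
    start_codon: str
    start_class: str  # canonical-ATN | alternative | invalid
    stop_codon: str  # last full codon, or the 1-2 base remainder
    stop_class: str  # complete | incomplete | invalid


_ALTERNATIVE_STARTS = {"TTG", "GTG"}


def _classify_start(codon: str, code: GeneticCode) -> str:
    if len(codon) == 3 and codon[0] == "A" and codon[1] == "T":
        return "canonical-ATN"
    if codon in _ALTERNATIVE_STARTS:
        return "alternative"
    return "invalid"


def classify_terminal_codons(
    ann: MitogenomeAnnotation,
    g: CircularSequence,
    code: GeneticCode = VERTEBRATE_MITO,
) -> list[TerminalCodons]:
    """Start and stop codon classes for every PCG, in genome order.

    Stops: complete when the length is a codon multiple and the final codon
    is in the code's stop set; incomplete when a trailing T or TA remainder
    is present (polyadenylation-completed); otherwise invalid.
    """
    out = []
    for f in ann.by_class(PCG):
        seq = extract_feature_sequence(g, f)
        if len(seq) < 6:
            raise ValueError(f"PCG {f.name!r} is shorter than 6 bp")
        start_codon = seq[:3]
        remainder_len = len(seq) % 3
        if remainder_len == 0:
            stop_codon = seq[-3:]
            stop_class = "complete" if stop_codon in code.stop_codons else "invalid"
        else:
            stop_codon = seq[-remainder_len:]
            stop_class = "incomplete" if stop_codon in {"T", "TA"} else "invalid"
        out.append(
            TerminalCodons(
                name=f.name,
                start_codon=start_codon,
                start_class=_classify_start(start_codon, code),
                stop_codon=stop_codon,
                stop_class=stop_class,
            )
        )
    return out


def count_codons(
    seq: str, code: GeneticCode = VERTEBRATE_MITO
) -> tuple[Counter, int]:
    """Codon counts over complete codons of one CDS (frame 0).

    Returns (counts over all 64 codons, number of skipped ambiguous codons).
    Codons containing N are skipped and tallied as ambiguous.
    """
    counts: Counter = Counter()
    ambiguous = 0
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if code.aa(codon) is None:
            ambiguous += 1
        else:
            counts[codon] += 1
    return counts, ambiguous


def rscu(
    counts: dict[str, int], code: GeneticCode = VERTEBRATE_MITO
) -> dict[str, float]:
    """Relative synonymous codon usage over sense codons.

    RSCU(c) = count(c) * k / sum of family counts, with k the synonymous
    family size; a family with zero total gets RSCU 0 throughout.  Stop
    codons are excluded.
    """
    for codon, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for codon {codon}")
    values: dict[str, float] = {}
    amino_acids = sorted(set(code.codon_to_aa.values()) - {"*"})
    for aa in amino_acids:
        family = code.family(aa)
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            values[c] = counts.get(c, 0) * k / total if total else 0.0
    return values


def aa_frequencies(
    ann: MitogenomeAnnotation,
    g: CircularSequence,
    code: GeneticCode = VERTEBRATE_MITO,
) -> dict[str, float]:
    """Amino-acid composition (percent) over translated residues of all PCGs.

    Stop codons and incomplete-stop remainders are excluded; residues from
    ambiguous codons count as 'X'.
    """
    tally: Counter = Counter()
    for f in ann.by_class(PCG):
        tr = translate_cds(extract_feature_sequence(g, f), code)
        for aa in tr.protein:
            if aa != "*":
                tally[aa] += 1
    total = sum(tally.values())
    if total == 0:
        return {}
    return {aa: 100.0 * n / total for aa, n in sorted(tally.items())}


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts, RSCU values, and amino-acid percentages for the PCG
    complement of one genome."""

    counts: dict[str, int]
    rscu: dict[str, float]
    aa_freq: dict[str, float]
    n_ambiguous_codons: int = 0


def codon_usage_table(
    ann: MitogenomeAnnotation,
    g: CircularSequence,
    code: GeneticCode = VERTEBRATE_MITO,
) -> CodonUsageTable:
    """Codon usage over all PCGs in coding orientation (stop codons excluded
    from RSCU and amino-acid frequencies)."""
    counts: Counter = Counter()
    ambiguous = 0
    for f in ann.by_class(PCG):
        c, amb = count_codons(extract_feature_sequence(g, f), code)
        counts.update(c)
        ambiguous += amb
    sense = {c: n for c, n in counts.items() if code.aa(c) != "*"}
    return CodonUsageTable(
        counts=dict(counts),
        rscu=rscu(sense, code),
        aa_freq=aa_frequencies(ann, g, code),
        n_ambiguous_codons=ambiguous,
    )
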