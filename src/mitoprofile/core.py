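"""Domain types and I/O for circular annotated mitochondrial genomes.

Coordinates are 1-based and fully inclusive throughout the package, matching
the convention of published mitogenome feature tables.  A feature with
``stop < start`` wraps through the sequence origin (position ``L`` joins
position 1); the canonical example is the control region of a vertebrate
mitogenome, which spans the origin of the deposited sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PCG",
    "TRNA",
    "RRNA",
    "CONTROL_REGION",
    "FEATURE_CLASSES",
    "CircularSequence",
    "GeneFeature",
    "MitogenomeAnnotation",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "feature_length",
    "extract_feature_sequence",
    "reverse_complement",
]

#: Feature class labels used across the package.
PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"
FEATURE_CLASSES = frozenset({PCG, TRNA, RRNA, CONTROL_REGION})

_VALID_RESIDUES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A circular DNA molecule: an identifier plus uppercase residues.

    Residues are restricted to ``A C G T N``; lowercase input is upcased at
    construction, anything else is rejected with the offending position.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        if not residues:
            raise ValueError("sequence must contain at least one residue")
        for i, ch in enumerate(residues):
            if ch not in _VALID_RESIDUES:
                raise ValueError(
                    f"illegal residue {ch!r} at position {i + 1} "
                    f"in sequence {self.identifier!r}"
                )
        object.__setattr__(self, "residues", residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Residue at a 1-based circular position (any integer accepted)."""
        return self.residues[(position - 1) % self.length]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a circular genome.

    ``stop < start`` denotes a feature wrapping through the origin; it is a
    single record, not two segments.
    """

    name: str
    feature_class: str
    start: int
    stop: int
    strand: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"unknown feature class {self.feature_class!r} for {self.name!r};"
                f" expected one of {sorted(FEATURE_CLASSES)}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.stop < 1:
            raise ValueError(f"coordinates must be >= 1 for {self.name!r}")

    @property
    def wraps(self) -> bool:
        return self.stop < self.start


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circular genome of length ``genome_length``.

    Non-wrapping: ``stop - start + 1``.  Wrapping (``stop < start``):
    ``(L - start + 1) + stop``.
    """
    if f.wraps:
        return (genome_length - f.start + 1) + f.stop
    return f.stop - f.start + 1


def extract_feature_sequence(g: CircularSequence, f: GeneFeature) -> str:
    """Feature sequence in coding orientation.

    Plus strand returns the heavy-strand span; minus strand returns its
    reverse complement.  Wrapping features concatenate the suffix starting at
    ``start`` with the prefix ending at ``stop``.
    """
    if f.wraps:
        span = g.residues[f.start - 1 :] + g.residues[: f.stop]
    else:
        span = g.residues[f.start - 1 : f.stop]
    if f.strand == "-":
        return reverse_complement(span)
    return span


@dataclass
class MitogenomeAnnotation:
    """Ordered collection of features on one circular genome.

    Features are kept sorted by the start of their non-wrapping span (genome
    order); names must be unique and coordinates must lie in
    ``[1, genome_length]``.
    """

    features: list[GeneFeature]
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        for f in self.features:
            if f.start > self.genome_length or f.stop > self.genome_length:
                raise ValueError(
                    f"feature {f.name!r} ({f.start}..{f.stop}) lies outside "
                    f"[1, {self.genome_length}]"
                )
        self.features = sorted(self.features, key=lambda f: f.start)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def covering(self, position: int) -> list[GeneFeature]:
        """All features whose circular span covers a 1-based position."""
        hits = []
        for f in self.features:
            if f.wraps:
                if position >= f.start or position <= f.stop:
                    hits.append(f)
            elif f.start <= position <= f.stop:
                hits.append(f)
        return hits


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> CircularSequence:
    """Read a single-record FASTA file as a circular genome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one FASTA record in {path}, found {len(records)}"
        )
    rec = records[0]
    return CircularSequence(identifier=rec.id, residues=str(rec.seq))


def write_fasta(g: CircularSequence, path: str | Path, width: int = 70) -> None:
    """Write a genome as single-record FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        fh.write(f">{g.identifier}\n")
        for i in range(0, g.length, width):
            fh.write(g.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature table TSV
#
# Dialect: header `name  class  start  stop  strand` (tab-separated);
# thousands separators such as "10,032" are tolerated on read, never written.

_TABLE_COLUMNS = ["name", "class", "start", "stop", "strand"]
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}  # accept unicode minus


def _parse_coord(text: str, column: str, line_no: int) -> int:
    cleaned = text.replace(",", "").strip()
    if not re.fullmatch(r"\d+", cleaned):
        raise ValueError(f"line {line_no}: bad {column} value {text!r}")
    return int(cleaned)


def read_feature_table(path: str | Path, genome_length: int) -> MitogenomeAnnotation:
    """Read the minimal feature-table TSV into an annotation.

    Numbers may carry thousands separators ("10,032"); the strand column
    accepts ``+``/``-`` and the typographic minus sign.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        header = fh.readline()
        cols = [c.strip() for c in header.rstrip("\n").split("\t")]
        if cols != _TABLE_COLUMNS:
            raise ValueError(
                f"bad feature table header {cols!r}; expected {_TABLE_COLUMNS}"
            )
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) != 5:
                raise ValueError(f"line {line_no}: expected 5 columns, got {len(parts)}")
            name, cls, start_s, stop_s, strand_s = parts
            strand = _STRAND_ALIASES.get(strand_s)
            if strand is None:
                raise ValueError(f"line {line_no}: bad strand {strand_s!r}")
            start = _parse_coord(start_s, "start", line_no)
            stop = _parse_coord(stop_s, "stop", line_no)
            if not (1 <= start <= genome_length and 1 <= stop <= genome_length):
                raise ValueError(
                    f"line {line_no}: coordinates {start}..{stop} outside "
                    f"[1, {genome_length}]"
                )
            features.append(GeneFeature(name, cls, start, stop, strand))
    return MitogenomeAnnotation(features=features, genome_length=genome_length)


def write_feature_table(ann: MitogenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for f in ann:
            fh.write(f"{f.name}\t{f.feature_class}\t{f.start}\t{f.stop}\t{f.strand}\n")


# ---------------------------------------------------------------------------
# GenBank convenience reader

_GENBANK_CLASS = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA, "D-loop": CONTROL_REGION}


def read_genbank(path: str | Path) -> tuple[CircularSequence, MitogenomeAnnotation]:
    """Thin GenBank flat-file reader mapping CDS/tRNA/rRNA/D-loop features
    onto the package's domain types.  Feature names come from the ``gene``
    qualifier, falling back to ``product``; unnamed D-loops become
    ``control_region``."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one GenBank record in {path}, found {len(records)}"
        )
    rec = records[0]
    g = CircularSequence(identifier=rec.id, residues=str(rec.seq))
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in rec.features:
        cls = _GENBANK_CLASS.get(feat.type)
        if cls is None:
            continue
        quals = feat.qualifiers
        name = quals.get("gene", quals.get("product", [None]))[0]
        if name is None:
            name = CONTROL_REGION if cls == CONTROL_REGION else feat.type
        if name in seen:  # disambiguate duplicated gene names
            i = 2
            while f"{name}_{i}" in seen:
                i += 1
            name = f"{name}_{i}"
        seen.add(name)
        start = int(feat.location.start) + 1  # GenBank parser is 0-based
        stop = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GeneFeature(name, cls, start, stop, strand))
    return g, MitogenomeAnnotation(features=features, genome_length=g.length)
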