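"""Control-region (D-loop) analysis: motif occurrence counting and exact
tandem-repeat detection.

The control region is the major non-coding region of the mitogenome and here
spans the sequence origin; all positions reported are local to the extracted
control-region sequence (1..CR length).  Tandem-repeat detection is exact
match only -- a naive O(n * max_unit) scan is fully adequate for ~1.1 kb
regions and keeps the brute-force oracle trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    CONTROL_REGION,
    CircularSequence,
    MitogenomeAnnotation,
    extract_feature_sequence,
    feature_length,
)
from .composition import CompositionProfile, skew_profile

__all__ = [
    "MotifHit",
    "TandemRepeat",
    "ControlRegionReport",
    "count_motif",
    "find_exact_tandem_repeats",
    "control_region_report",
    "DEFAULT_MOTIFS",
]

#: Motifs scanned by default in control-region reports.
DEFAULT_MOTIFS = ("TATAA", "AATAAT")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    position: int  # 1-based offset within the scanned sequence
    overlapping: bool


@dataclass(frozen=True)
class TandemRepeat:
    """A maximal exact array of >= 2 adjacent copies of a primitive unit."""

    unit: str
    unit_length: int
    copies: int
    start: int  # 1-based
    total_span: int

    def __post_init__(self) -> None:
        assert self.total_span == self.unit_length * self.copies


def count_motif(
    seq: str, motif: str, overlapping: bool = True
) -> tuple[int, list[MotifHit]]:
    """Count motif occurrences and return their positions.

    Overlapping mode counts every start position; non-overlapping scans
    left-to-right greedily.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    bad = set(motif) - set("ACGT")
    if bad:
        raise ValueError(f"motif contains non-ACGT characters: {sorted(bad)}")
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(MotifHit(motif=motif, position=i + 1, overlapping=overlapping))
        i = seq.find(motif, i + 1 if overlapping else i + len(motif))
    return len(hits), hits


def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_exact_tandem_repeats(
    seq: str, min_unit: int = 1, max_unit: int = 6, min_copies: int = 2
) -> list[TandemRepeat]:
    """Maximal exact tandem arrays with primitive units, sorted by start.

    An array is reported once, at its leftmost start, with the number of
    complete copies it contains; arrays extendable by a full period on the
    left are part of a longer run and are not re-reported.
    """
    n = len(seq)
    if not (1 <= min_unit <= max_unit <= max(1, n // 2)):
        raise ValueError(
            f"require 1 <= min_unit <= max_unit <= len(seq)/2, "
            f"got {min_unit}..{max_unit} for length {n}"
        )
    found = []
    for u in range(min_unit, max_unit + 1):
        # match[i] = True when seq[i] == seq[i+u]; runs of matches are
        # periodic stretches with period u.
        i = 0
        while i + u < n:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            j = i  # extend the periodic run
            while j + u < n and seq[j] == seq[j + u]:
                j += 1
            run_len = (j - i) + u  # bases in the periodic stretch
            copies = run_len // u
            unit = seq[i : i + u]
            if copies >= min_copies and _is_primitive(unit):
                found.append(
                    TandemRepeat(
                        unit=unit,
                        unit_length=u,
                        copies=copies,
                        start=i + 1,
                        total_span=u * copies,
                    )
                )
            i = j + 1
    return sorted(found, key=lambda r: (r.start, r.unit_length))


@dataclass(frozen=True)
class ControlRegionReport:
    length: int
    profile: CompositionProfile
    motif_counts: dict[str, int]
    motif_hits: dict[str, tuple[MotifHit, ...]]
    tandem_repeats: tuple[TandemRepeat, ...]


def control_region_report(
    g: CircularSequence,
    ann: MitogenomeAnnotation,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    overlapping: bool = True,
    min_unit: int = 1,
    max_unit: int = 6,
    min_copies: int = 2,
) -> ControlRegionReport:
    """Length, composition, motif counts and tandem repeats of the control
    region, extracted with wrap-around; positions are CR-local (1..length)."""
    crs = ann.by_class(CONTROL_REGION)
    if not crs:
        raise ValueError("annotation has no control_region feature")
    cr = crs[0]
    seq = extract_feature_sequence(g, cr)
    counts: dict[str, int] = {}
    hits: dict[str, tuple[MotifHit, ...]] = {}
    for m in motifs:
        n, h = count_motif(seq, m, overlapping=overlapping)
        counts[m] = n
        hits[m] = tuple(h)
    repeats = tuple(
        find_exact_tandem_repeats(seq, min_unit, max_unit, min_copies)
    )
    return ControlRegionReport(
        length=feature_length(cr, ann.genome_length),
        profile=skew_profile(seq, "control_region"),
        motif_counts=counts,
        motif_hits=hits,
        tandem_repeats=repeats,
    )
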