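"""Base composition, A+T content, and strand-asymmetry skew statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C); both lie in [-1, 1]
and negate under complementation.  A+T content is (A + T)/(A + C + G + T).
Ambiguous bases (N) are tallied separately and excluded from every
denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .core import (
    CONTROL_REGION,
    PCG,
    RRNA,
    CircularSequence,
    GeneFeature,
    MitogenomeAnnotation,
    extract_feature_sequence,
)

__all__ = [
    "CompositionProfile",
    "base_counts",
    "skew_profile",
    "region_profiles",
    "sliding_window_skew",
]

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CompositionProfile:
    """Composition statistics for one named region (full precision; rounding
    happens only in report writers)."""

    region_name: str
    a: int
    c: int
    g: int
    t: int
    n_ambiguous: int
    at_content: float
    at_skew: float
    gc_skew: float

    @property
    def counts(self) -> dict[str, int]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}

    @property
    def total_unambiguous(self) -> int:
        return self.a + self.c + self.g + self.t


def base_counts(seq: str) -> dict[str, int]:
    """Exact counts of A/C/G/T with N tallied under ``"N"``."""
    counts = {b: seq.count(b) for b in _BASES}
    counts["N"] = seq.count("N")
    if sum(counts.values()) != len(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return counts


def skew_profile(seq: str, region_name: str = "region") -> CompositionProfile:
    """Composition profile of one sequence; errors on empty or all-N input."""
    counts = base_counts(seq)
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    total = a + c + g + t
    if total == 0:
        raise ValueError(f"region {region_name!r} has no unambiguous bases")
    at = a + t
    gc = g + c
    return CompositionProfile(
        region_name=region_name,
        a=a,
        c=c,
        g=g,
        t=t,
        n_ambiguous=counts["N"],
        at_content=at / total,
        at_skew=(a - t) / at if at else 0.0,
        gc_skew=(g - c) / gc if gc else 0.0,
    )


def region_profiles(
    g: CircularSequence, ann: MitogenomeAnnotation
) -> list[CompositionProfile]:
    """Profiles for the whole genome, the PCG concatenation (genome order,
    coding orientation), each rRNA, the control region, and every feature.

    Minus-strand protein-coding genes contribute their coding-strand
    (reverse-complemented) sequence to the PCG aggregate; overlapping bases
    are counted once per gene, matching gene-wise totals.
    """
    profiles = [skew_profile(g.residues, "whole_genome")]

    pcgs = ann.by_class(PCG)
    if pcgs:
        concat = "".join(extract_feature_sequence(g, f) for f in pcgs)
        profiles.append(skew_profile(concat, "PCGs"))
    else:
        log.warning("no PCG features annotated; skipping PCG aggregate")

    rrnas = ann.by_class(RRNA)
    if not rrnas:
        log.warning("no rRNA features annotated; skipping rRNA profiles")

    crs = ann.by_class(CONTROL_REGION)
    if crs:
        for f in crs:
            profiles.append(
                skew_profile(extract_feature_sequence(g, f), "control_region")
            )
    else:
        log.warning("no control region annotated; skipping its profile")

    for f in ann:
        if f.feature_class == CONTROL_REGION:
            continue
        profiles.append(skew_profile(extract_feature_sequence(g, f), f.name))
    return profiles


def sliding_window_skew(
    g: CircularSequence, window: int, step: int
) -> pd.DataFrame:
    """Per-window skew table over circular windows.

    Windows start at 1, 1+step, ...; each spans ``window`` bp with wrap-around.
    Returns ``ceil(L/step)`` rows of (center, at_skew, gc_skew); centers are
    1-based circular positions.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    L = g.length
    if window > L:
        raise ValueError(f"window {window} exceeds genome length {L}")
    doubled = g.residues + g.residues
    rows = []
    for i in range(math.ceil(L / step)):
        start = i * step  # 0-based
        chunk = doubled[start : start + window]
        prof = skew_profile(chunk, f"window_{i}")
        center = (start + (window - 1) // 2) % L + 1
        rows.append((center, prof.at_skew, prof.gc_skew))
    return pd.DataFrame(rows, columns=["center", "at_skew", "gc_skew"])
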