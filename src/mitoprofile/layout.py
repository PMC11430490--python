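"""Gene inventory, intergenic spacer and overlap accounting.

A mitogenome annotation closes into a cycle: walking the features in genome
order and summing every feature length and every signed inter-feature gap
(overlaps negative) must give back the genome length exactly.  All spacer
arithmetic here is circular so that invariant holds by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    GeneFeature,
    MitogenomeAnnotation,
    feature_length,
)

__all__ = [
    "SpacerRecord",
    "SpacerTable",
    "InventorySummary",
    "intergenic_gap",
    "spacer_overlap_table",
    "summarize_inventory",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpacerRecord:
    """Signed gap between two consecutive features; negative = overlap."""

    upstream_name: str
    downstream_name: str
    gap: int


@dataclass(frozen=True)
class SpacerTable:
    """All consecutive-pair spacer records plus headline numbers."""

    records: tuple[SpacerRecord, ...]
    longest_gap: int
    longest_gap_pair: tuple[str, str]
    n_spacers: int  # positive gaps
    n_overlaps: int  # negative gaps

    def gap(self, upstream_name: str) -> int:
        for r in self.records:
            if r.upstream_name == upstream_name:
                return r.gap
        raise KeyError(upstream_name)


@dataclass(frozen=True)
class InventorySummary:
    n_total: int
    n_pcg: int
    n_trna: int
    n_rrna: int
    has_control_region: bool
    pcg_total_bp: int
    pcg_fraction: float  # percent of genome, rounded to 2 decimals
    trna_min_bp: int | None
    trna_max_bp: int | None
    class_lengths: dict[str, list[int]] = field(default_factory=dict)


def intergenic_gap(upstream: GeneFeature, downstream: GeneFeature, genome_length: int) -> int:
    """Signed bp between consecutive features: ``downstream.start - upstream.stop - 1``,
    adding the genome length when the pair spans the origin.  Negative values
    are overlaps."""
    gap = downstream.start - upstream.stop - 1
    # A closing pair (last feature back to first) produces a large negative
    # raw value; true overlaps are short.  Wrapped upstream features already
    # carry a small linear stop, so no correction applies to them.
    if gap <= -genome_length // 2:
        gap += genome_length
    return gap


def spacer_overlap_table(ann: MitogenomeAnnotation) -> SpacerTable:
    """Gap/overlap for every consecutive pair in genome order, including the
    closing wrap-around pair."""
    feats = list(ann)
    if len(feats) < 2:
        raise ValueError("spacer table needs an annotation with >= 2 features")
    records = []
    for up, down in zip(feats, feats[1:] + feats[:1]):
        g = intergenic_gap(up, down, ann.genome_length)
        up_len = feature_length(up, ann.genome_length)
        down_len = feature_length(down, ann.genome_length)
        if g <= -min(up_len, down_len):
            log.warning(
                "feature %s appears contained within %s (gap %d)", down.name, up.name, g
            )
        records.append(SpacerRecord(up.name, down.name, g))
    positive = [r for r in records if r.gap > 0]
    longest = max(records, key=lambda r: r.gap)
    return SpacerTable(
        records=tuple(records),
        longest_gap=longest.gap,
        longest_gap_pair=(longest.upstream_name, longest.downstream_name),
        n_spacers=len(positive),
        n_overlaps=sum(1 for r in records if r.gap < 0),
    )


def summarize_inventory(ann: MitogenomeAnnotation) -> InventorySummary:
    """Counts and size summaries by feature class.

    ``pcg_fraction`` is 100 x total PCG bp / genome length, rounded to two
    decimals.  ``n_total`` counts genes plus the control region when one is
    annotated.
    """
    L = ann.genome_length
    class_lengths: dict[str, list[int]] = {}
    for f in ann:
        class_lengths.setdefault(f.feature_class, []).append(feature_length(f, L))
    pcg_lengths = class_lengths.get(PCG, [])
    trna_lengths = class_lengths.get(TRNA, [])
    rrna_lengths = class_lengths.get(RRNA, [])
    has_cr = bool(class_lengths.get(CONTROL_REGION))
    pcg_total = sum(pcg_lengths)
    return InventorySummary(
        n_total=len(pcg_lengths) + len(trna_lengths) + len(rrna_lengths) + int(has_cr),
        n_pcg=len(pcg_lengths),
        n_trna=len(trna_lengths),
        n_rrna=len(rrna_lengths),
        has_control_region=has_cr,
        pcg_total_bp=pcg_total,
        pcg_fraction=round(100.0 * pcg_total / L, 2),
        trna_min_bp=min(trna_lengths) if trna_lengths else None,
        trna_max_bp=max(trna_lengths) if trna_lengths else None,
        class_lengths=class_lengths,
    )
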