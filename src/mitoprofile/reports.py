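"""TSV and JSON report emission.

Internals carry full precision; rounding happens only here (two decimals for
percentages, five for skew values).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .codons import VERTEBRATE_MITO, CodonUsageTable, GeneticCode
from .compare import ConsequenceRecord, DiffSummary, VariantRecord
from .composition import CompositionProfile
from .dloop import ControlRegionReport
from .layout import InventorySummary, SpacerTable

__all__ = [
    "write_spacer_table",
    "write_inventory",
    "write_composition",
    "write_rscu",
    "write_aa_frequencies",
    "write_control_region",
    "write_variants_tsv",
    "write_variants_vcf",
    "write_consequences",
    "write_summary_json",
]


def _round(x: float, nd: int) -> float:
    return round(float(x), nd)


def write_spacer_table(table: SpacerTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("upstream\tdownstream\tgap_bp\n")
        for r in table.records:
            fh.write(f"{r.upstream_name}\t{r.downstream_name}\t{r.gap}\n")


def write_inventory(inv: InventorySummary, path: str | Path) -> None:
    payload = dataclasses.asdict(inv)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_composition(profiles: list[CompositionProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "region\tA\tC\tG\tT\tN\tlength\tat_percent\tat_skew\tgc_skew\n"
        )
        for p in profiles:
            fh.write(
                f"{p.region_name}\t{p.a}\t{p.c}\t{p.g}\t{p.t}\t{p.n_ambiguous}"
                f"\t{p.total_unambiguous + p.n_ambiguous}"
                f"\t{_round(100 * p.at_content, 2)}"
                f"\t{_round(p.at_skew, 5)}\t{_round(p.gc_skew, 5)}\n"
            )


def write_rscu(
    table: CodonUsageTable, path: str | Path, code: GeneticCode = VERTEBRATE_MITO
) -> None:
    """RSCU table ordered by amino acid, then codon."""
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\trscu\n")
        amino_acids = sorted(set(code.codon_to_aa.values()) - {"*"})
        for aa in amino_acids:
            for codon in code.family(aa):
                fh.write(
                    f"{codon}\t{aa}\t{table.counts.get(codon, 0)}"
                    f"\t{_round(table.rscu.get(codon, 0.0), 5)}\n"
                )


def write_aa_frequencies(table: CodonUsageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({aa: _round(v, 2) for aa, v in table.aa_freq.items()}, fh, indent=2)
        fh.write("\n")


def write_control_region(report: ControlRegionReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        p = report.profile
        fh.write(f"# control region: {report.length} bp")
        fh.write(
            f", AT {_round(100 * p.at_content, 2)}%"
            f", AT-skew {_round(p.at_skew, 5)}, GC-skew {_round(p.gc_skew, 5)}\n"
        )
        fh.write("record\tvalue\tdetail\n")
        for motif, count in report.motif_counts.items():
            hits = ",".join(str(h.position) for h in report.motif_hits[motif])
            fh.write(f"motif:{motif}\t{count}\t{hits}\n")
        for tr in report.tandem_repeats:
            fh.write(
                f"tandem_repeat:{tr.unit}\t{tr.copies}\t"
                f"start={tr.start};span={tr.total_span}\n"
            )


def write_variants_tsv(variants: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_position\ttype\tref_allele\talt_allele\tfeature\n")
        for v in variants:
            fh.write(
                f"{v.ref_position}\t{v.type}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t{v.feature_name}\n"
            )


def write_variants_vcf(
    variants: list[VariantRecord],
    path: str | Path,
    chrom: str,
    ref_seq: str,
    consequences: list[ConsequenceRecord] | None = None,
) -> None:
    """Minimal VCF: indels are anchored on the preceding reference base, as
    the format requires; FEATURE and AA INFO tags carry the annotation."""
    aa_by_pos: dict[int, str] = {}
    for c in consequences or []:
        if c.effect in ("missense", "synonymous"):
            aa_by_pos.setdefault(
                c.variant.ref_position, f"{c.ref_aa}{c.codon_index}{c.alt_aa}"
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(ref_seq)}>\n")
        fh.write('##INFO=<ID=FEATURE,Number=1,Type=String,Description="Covering feature">\n')
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Amino acid change">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            if v.type == "substitution":
                pos, ref, alt = v.ref_position, v.ref_allele, v.alt_allele
            elif v.type == "deletion":
                pos = max(v.ref_position - 1, 1)
                anchor = ref_seq[pos - 1]
                ref, alt = anchor + v.ref_allele, anchor
            else:
                pos = max(v.ref_position, 1)
                anchor = ref_seq[pos - 1]
                ref, alt = anchor, anchor + v.alt_allele
            info = f"FEATURE={v.feature_name}"
            if v.ref_position in aa_by_pos:
                info += f";AA={aa_by_pos[v.ref_position]}"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def write_consequences(consequences: list[ConsequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ref_position\ttype\tgene\tcodon_index\tref_aa\talt_aa\teffect\n"
        )
        for c in consequences:
            fh.write(
                f"{c.variant.ref_position}\t{c.variant.type}\t{c.gene}"
                f"\t{c.codon_index if c.codon_index is not None else '.'}"
                f"\t{c.ref_aa}\t{c.alt_aa}\t{c.effect}\n"
            )


def write_summary_json(summary: DiffSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(summary), fh, indent=2)
        fh.write("\n")
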