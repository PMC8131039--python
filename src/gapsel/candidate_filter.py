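"""Candidate-gene exclusion rules over QTL intervals and variant annotations.

A gene survives iff it
  R1: overlaps at least one QTL interval (>=1 bp, half-open arithmetic);
  R2: carries at least one impactful variant (one disrupting an upstream
      cis-element or a coding functional domain);
  R3: has detectable expression;
  R4: is not a case where every impactful variant is promoter-only while
      the gene is absent from the DEG set.
Rules are conjunctive, so application order cannot change the surviving
set; the audit records the first rule that removed each excluded gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io_tables import GenomicInterval, VariantRecord

#: default upstream promoter window (bp) ahead of the coding start
DEFAULT_PROMOTER_WINDOW = 2000

RULE_LABELS = {
    "R1": "outside all QTL intervals",
    "R2": "no cis-element- or domain-disrupting variant",
    "R3": "expression not detectable",
    "R4": "impactful variants promoter-only and not a DEG",
}


@dataclass
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    expressed: bool
    is_deg: bool
    variants: list[VariantRecord] = field(default_factory=list)

    def impactful_variants(self) -> list[VariantRecord]:
        return [
            v for v in self.variants
            if v.disrupts_cis_element or v.disrupts_domain
        ]


@dataclass
class FilterAudit:
    survivors: list[str]
    removed_by: dict[str, str]  # gene_id -> first failing rule id

    def rule_counts(self) -> dict[str, int]:
        counts = {rule: 0 for rule in RULE_LABELS}
        for rule in self.removed_by.values():
            counts[rule] += 1
        return counts


def first_failing_rule(gene: GeneRecord,
                       qtls: Sequence[GenomicInterval]) -> Optional[str]:
    """Return the first exclusion rule the gene fails, or None if it survives."""
    if not any(gene.interval.overlaps(q) for q in qtls):
        return "R1"
    impactful = gene.impactful_variants()
    if not impactful:
        return "R2"
    if not gene.expressed:
        return "R3"
    if all(v.region == "promoter" for v in impactful) and not gene.is_deg:
        return "R4"
    return None


def filter_candidates(genes: Sequence[GeneRecord],
                      qtls: Sequence[GenomicInterval]) -> FilterAudit:
    """Apply the exclusion rules, returning survivors and a per-gene audit."""
    survivors: list[str] = []
    removed_by: dict[str, str] = {}
    for gene in genes:
        rule = first_failing_rule(gene, qtls)
        if rule is None:
            survivors.append(gene.gene_id)
        else:
            removed_by[gene.gene_id] = rule
    return FilterAudit(survivors=survivors, removed_by=removed_by)


def build_gene_records(gene_intervals: Sequence[GenomicInterval],
                       variants: Sequence[VariantRecord],
                       expression: dict[str, float],
                       deg_ids: Sequence[str],
                       promoter_window: int = DEFAULT_PROMOTER_WINDOW,
                       expression_floor: float = 0.0) -> list[GeneRecord]:
    """Assemble GeneRecords from parsed inputs.

    Variants are attached to a gene when they fall inside its span extended
    upstream by ``promoter_window`` (genes are taken as plus-strand, so
    upstream means lower coordinates).  Expression is "detectable" when the
    gene's value exceeds ``expression_floor``.
    """
    deg_set = set(deg_ids)
    records: list[GeneRecord] = []
    for iv in gene_intervals:
        window_start = max(0, iv.start - promoter_window)
        attached = [
            v for v in variants
            if v.chrom == iv.chrom and window_start <= v.pos < iv.end
        ]
        records.append(
            GeneRecord(
                gene_id=iv.label,
                interval=iv,
                expressed=expression.get(iv.label, 0.0) > expression_floor,
                is_deg=iv.label in deg_set,
                variants=attached,
            )
        )
    return records
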