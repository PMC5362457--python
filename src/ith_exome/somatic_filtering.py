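"""Somatic variant filtering: SNV cut-offs, indel rules, polymorphism and exon masks.

The SNV cascade applies, per tumor region, the seven published cut-offs:
(1) mapping quality >= 20, (2) tumor VAF >= 5%, (3) depth >= 10 in both the
tumor and the non-tumor sample, (4) >= 2 tumor variant reads, (5) <= 1 normal
variant read, (6) no candidate indel within 5 bp, and (7) no more than 2 SNVs
in any 10-bp window.  Indels use a separate 4-rule filter (depth >= 20 both
samples, VAF >= 10%, >= 5 variant reads, zero normal variant reads).  Known
polymorphisms and sites outside the exon/splice-site annotation are excluded
afterwards.

Decisions accumulate ALL failed rules (no short-circuiting), so a rejected
record's ``reasons`` list is an exhaustive audit.  The window rule removes
every SNV of an offending window — the unique order-independent choice — and
all rules are evaluated per tumor region independently; clonality is decided
later by cross-region interrogation, not here.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .core_model import FilterConfig, MutationRecord

SNV_REASONS = ("MAPQ", "VAF", "DEPTH", "TUMOR_VAR", "NORMAL_VAR", "NEAR_INDEL", "WINDOW")
INDEL_REASONS = ("INDEL_DEPTH", "INDEL_VAF", "INDEL_VAR", "INDEL_NORMAL")
MASK_REASONS = ("POLYMORPHISM", "NON_EXONIC")
ALL_REASONS = SNV_REASONS + INDEL_REASONS + MASK_REASONS


@dataclass(frozen=True)
class FilterDecision:
    """Pass/reject verdict for one record in one tumor region.

    Invariant: ``passed`` iff ``reasons`` is empty.
    """

    record: MutationRecord
    region: str
    reasons: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.reasons

    def with_reason(self, reason: str) -> "FilterDecision":
        if reason in self.reasons:
            return self
        return replace(self, reasons=self.reasons + (reason,))


@dataclass(frozen=True)
class Neighborhood:
    """Positional context of one region's candidate list: indel anchors and
    window-rule flags, both keyed by chromosome."""

    indel_positions: Mapping[str, tuple[int, ...]]
    window_flagged: frozenset[tuple[str, int]]

    @classmethod
    def from_records(
        cls, records: Sequence[MutationRecord], config: FilterConfig | None = None
    ) -> "Neighborhood":
        config = config or FilterConfig()
        indels: dict[str, list[int]] = {}
        snvs: dict[str, list[int]] = {}
        for rec in records:
            # the indel's leftmost affected base anchors the exclusion zone
            bucket = indels if rec.is_indel else snvs
            bucket.setdefault(rec.site.chrom, []).append(rec.site.pos)
        flagged = set()
        for chrom, positions in snvs.items():
            for pos in apply_window_rule(
                sorted(positions), config.snv_window_bp, config.snv_window_max
            ):
                flagged.add((chrom, pos))
        return cls(
            indel_positions={c: tuple(sorted(p)) for c, p in indels.items()},
            window_flagged=frozenset(flagged),
        )

    def has_indel_within(self, chrom: str, pos: int, dist_bp: int) -> bool:
        positions = self.indel_positions.get(chrom, ())
        i = bisect_left(positions, pos - dist_bp)
        return i < len(positions) and positions[i] <= pos + dist_bp


def apply_window_rule(
    positions: Sequence[int], window_bp: int = 10, max_snvs: int = 2
) -> set[int]:
    """Flag every SNV that shares some ``window_bp``-long window with > ``max_snvs``
    candidates (itself included).

    ``positions`` must be sorted within one chromosome/sample.  A window is any
    run p..p+window_bp-1 (1-based inclusive); any window holding >= max_snvs+1
    candidates can be shifted to start on its leftmost contained candidate, so
    scanning candidate-anchored windows is exhaustive.
    """
    positions = list(positions)
    if positions != sorted(positions):
        raise ValueError("positions must be sorted")
    flagged: set[int] = set()
    for i, pos in enumerate(positions):
        j = bisect_right(positions, pos + window_bp - 1)
        if j - i > max_snvs:
            flagged.update(positions[i:j])
    return flagged


def filter_snv(
    record: MutationRecord,
    tumor_region: str,
    config: FilterConfig | None = None,
    neighborhood: Neighborhood | None = None,
) -> FilterDecision:
    """Evaluate the seven SNV cut-offs for one record in one tumor region.

    All thresholds are inclusive exactly as published (>= / <=); every failed
    rule lands in ``reasons``.
    """
    config = config or FilterConfig()
    if "normal" not in record.evidence:
        raise ValueError(
            f"{record.site.chrom}:{record.site.pos}: somatic status undecidable "
            "without non-tumor evidence"
        )
    if tumor_region not in record.evidence:
        raise ValueError(f"no {tumor_region} evidence at {record.site.chrom}:{record.site.pos}")
    tumor = record.evidence[tumor_region]
    normal = record.evidence["normal"]
    reasons = []
    if tumor.mapping_quality < config.snv_min_mapq:
        reasons.append("MAPQ")
    if tumor.vaf < config.snv_min_tumor_vaf:
        reasons.append("VAF")
    if tumor.depth < config.snv_min_depth or normal.depth < config.snv_min_depth:
        reasons.append("DEPTH")
    if tumor.var_reads < config.snv_min_tumor_var_reads:
        reasons.append("TUMOR_VAR")
    if normal.var_reads > config.snv_max_normal_var_reads:
        reasons.append("NORMAL_VAR")
    if neighborhood is not None:
        if neighborhood.has_indel_within(
            record.site.chrom, record.site.pos, config.snv_indel_exclusion_bp
        ):
            reasons.append("NEAR_INDEL")
        if (record.site.chrom, record.site.pos) in neighborhood.window_flagged:
            reasons.append("WINDOW")
    return FilterDecision(record=record, region=tumor_region, reasons=tuple(reasons))


def filter_indel(
    record: MutationRecord,
    tumor_region: str,
    config: FilterConfig | None = None,
) -> FilterDecision:
    """Evaluate the 4-rule indel filter (all rules inclusive)."""
    config = config or FilterConfig()
    if not record.is_indel:
        raise ValueError("filter_indel requires an indel-consequence record")
    if "normal" not in record.evidence:
        raise ValueError(
            f"{record.site.chrom}:{record.site.pos}: somatic status undecidable "
            "without non-tumor evidence"
        )
    tumor = record.evidence[tumor_region]
    normal = record.evidence["normal"]
    reasons = []
    if tumor.depth < config.indel_min_depth or normal.depth < config.indel_min_depth:
        reasons.append("INDEL_DEPTH")
    if tumor.vaf < config.indel_min_vaf:
        reasons.append("INDEL_VAF")
    if tumor.var_reads < config.indel_min_var_reads:
        reasons.append("INDEL_VAR")
    if normal.var_reads > config.indel_max_normal_var_reads:
        reasons.append("INDEL_NORMAL")
    return FilterDecision(record=record, region=tumor_region, reasons=tuple(reasons))


def exclude_polymorphisms(
    decisions: Iterable[FilterDecision],
    polymorphism_sites: set[tuple[str, int, str, str]],
) -> list[FilterDecision]:
    """Add POLYMORPHISM to every decision whose (chrom, pos, ref, alt) is listed."""
    out = []
    for dec in decisions:
        if dec.record.site.key in polymorphism_sites:
            dec = dec.with_reason("POLYMORPHISM")
        out.append(dec)
    return out


def restrict_to_exonic(
    decisions: Iterable[FilterDecision],
    annotation: Sequence[tuple[str, int, int]],
) -> list[FilterDecision]:
    """Add NON_EXONIC to sites outside every exon/splice-site interval.

    ``annotation`` holds 1-based inclusive (chrom, start, end) intervals.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in annotation:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    out = []
    for dec in decisions:
        tree = trees.get(dec.record.site.chrom)
        if tree is None or not tree[dec.record.site.pos]:
            dec = dec.with_reason("NON_EXONIC")
        out.append(dec)
    return out


def filter_region(
    records: Sequence[MutationRecord],
    tumor_region: str,
    config: FilterConfig | None = None,
    polymorphism_sites: set[tuple] | None = None,
    exon_intervals: Sequence[tuple[str, int, int]] | None = None,
) -> list[FilterDecision]:
    """Run the full cascade for one tumor region of one patient's candidate table."""
    config = config or FilterConfig()
    neighborhood = Neighborhood.from_records(records, config)
    decisions = [
        filter_indel(rec, tumor_region, config)
        if rec.is_indel
        else filter_snv(rec, tumor_region, config, neighborhood)
        for rec in records
    ]
    if polymorphism_sites:
        decisions = exclude_polymorphisms(decisions, polymorphism_sites)
    if exon_intervals is not None:
        decisions = restrict_to_exonic(decisions, exon_intervals)
    return decisions


def decisions_table(decisions: Sequence[FilterDecision]):
    """Decisions as a tidy DataFrame (one row per record x region)."""
    import pandas as pd

    rows = []
    for dec in decisions:
        rows.append(
            {
                "patient": dec.record.patient or "",
                "chrom": dec.record.site.chrom,
                "pos": dec.record.site.pos,
                "ref": dec.record.site.ref,
                "alt": dec.record.site.alt,
                "gene": dec.record.gene,
                "region": dec.region,
                "passed": dec.passed,
                "reasons": ",".join(dec.reasons),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient", "chrom", "pos", "ref", "alt", "gene", "region", "passed", "reasons"],
    )
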