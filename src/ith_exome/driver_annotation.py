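"""Driver-gene matching and three-tier relevance classification.

Non-synonymous mutations are matched against a curated driver knowledge base
(recurrently mutated iCCA genes, genes mutated in >= 3% of biliary tract
cancers, and cancer gene census members).  Matched mutations are tiered:

* high_confidence — the exact amino-acid change is a known mutation, or its
  SIFT score is < 0.05 (strict), or it was promoted by manual review;
* putative — the amino-acid position lies within 5 residues of a known
  mutation in the same gene (inclusive);
* unknown — the gene matches but neither criterion applies;
* non_driver — the gene is not in the knowledge base.

Proximity is measured in amino-acid residues: the sources annotate every
affected mutation at residue level, so the residue metric is the one their
"within 5 of a known mutation" statements are actually about.

The packaged fixtures under ``data/driver_kb/`` are synthetic stand-ins for
the non-redistributable COSMIC/SIFT extracts, curated so that the published
20-mutation driver table re-derives its printed tiers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import GenomicSite, MutationRecord

log = logging.getLogger(__name__)

TIERS = ("high_confidence", "putative", "unknown", "non_driver")
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}

PROVENANCE_TAGS = ("recurrent_iCCA_study", "cosmic_ge3pct_biliary", "cancer_gene_census")

_AA_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)(.*)$")


def parse_aa_change(aa_change: str | None) -> tuple[str, int, str] | None:
    """Parse a protein change like ``Gly12Asp`` or ``Thr524HisfsTer52`` into
    (reference residue, 1-based position, remainder); None if unparseable."""
    if not aa_change or aa_change.upper() == "NA":
        return None
    m = _AA_RE.match(aa_change)
    if not m:
        return None
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass
class DriverKnowledgeBase:
    """Gene list with provenance, known amino-acid-level mutations, SIFT scores."""

    genes: dict[str, frozenset[str]]                 # symbol -> provenance tags
    known_mutations: set[tuple[str, str]]            # (gene, aa_change)
    known_positions: dict[str, tuple[int, ...]]      # gene -> sorted residue positions
    sift_scores: dict[tuple[str, str], float]        # (gene, aa_change) -> [0, 1]

    def __post_init__(self) -> None:
        for gene in self.genes:
            if gene != gene.upper():
                raise ValueError(f"gene symbols must be uppercase: {gene!r}")
        for (_, _), score in self.sift_scores.items():
            if not 0 <= score <= 1:
                raise ValueError("SIFT scores must lie in [0, 1]")
        for gene, positions in self.known_positions.items():
            if any(p < 1 for p in positions):
                raise ValueError(f"aa_position must be >= 1 ({gene})")

    def source_counts(self) -> dict[str, int]:
        counts = {tag: 0 for tag in PROVENANCE_TAGS}
        for tags in self.genes.values():
            for tag in tags:
                counts[tag] = counts.get(tag, 0) + 1
        return counts


def _read_fixture(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def compile_driver_list(
    gene_list: str | Path,
    known_mutations: str | Path | None = None,
    sift_scores: str | Path | None = None,
) -> DriverKnowledgeBase:
    """Build the knowledge base from fixture TSVs (union, provenance retained).

    ``gene_list`` needs columns gene/source; ``known_mutations`` gene/aa_change
    (the residue position is parsed from the change); ``sift_scores``
    gene/aa_change/score.  Malformed rows are hard errors naming the line.
    """
    genes: dict[str, set[str]] = {}
    df = _read_fixture(Path(gene_list), ["gene", "source"])
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = row.gene.strip().upper()
        if not gene:
            raise ValueError(f"{gene_list}: row {i}: empty gene symbol")
        genes.setdefault(gene, set()).add(row.source.strip())

    known: set[tuple[str, str]] = set()
    positions: dict[str, set[int]] = {}
    if known_mutations is not None:
        df = _read_fixture(Path(known_mutations), ["gene", "aa_change"])
        for i, row in enumerate(df.itertuples(index=False), start=2):
            gene = row.gene.strip().upper()
            parsed = parse_aa_change(row.aa_change)
            if parsed is None:
                raise ValueError(
                    f"{known_mutations}: row {i}: unparseable aa_change {row.aa_change!r}"
                )
            known.add((gene, row.aa_change))
            positions.setdefault(gene, set()).add(parsed[1])

    sift: dict[tuple[str, str], float] = {}
    if sift_scores is not None:
        df = _read_fixture(Path(sift_scores), ["gene", "aa_change", "score"])
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                sift[(row.gene.strip().upper(), row.aa_change)] = float(row.score)
            except ValueError as exc:
                raise ValueError(f"{sift_scores}: row {i}: bad score {row.score!r}") from exc

    return DriverKnowledgeBase(
        genes={g: frozenset(tags) for g, tags in genes.items()},
        known_mutations=known,
        known_positions={g: tuple(sorted(p)) for g, p in positions.items()},
        sift_scores=sift,
    )


def _kb_path(name: str) -> Path:
    return Path(str(resources.files("ith_exome").joinpath("data", "driver_kb", name)))


def load_default_kb() -> DriverKnowledgeBase:
    """The packaged (synthetic stand-in) iCCA driver knowledge base."""
    return compile_driver_list(
        _kb_path("driver_genes.tsv"),
        _kb_path("known_mutations.tsv"),
        _kb_path("sift_scores.tsv"),
    )


@dataclass(frozen=True)
class DriverCall:
    record: MutationRecord
    tier: str
    reason: str
    parse_warning: bool = False

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def is_potential_driver(self) -> bool:
        return self.tier != "non_driver"


def categorize(record: MutationRecord, kb: DriverKnowledgeBase) -> DriverCall:
    """Tier one non-synonymous mutation: high_confidence > putative > unknown.

    The SIFT cut-off is strict (< 0.05); proximity is inclusive (<= 5 residues
    to any known mutation of the same gene).  Records in a matched gene whose
    protein change cannot be parsed can only reach a tier through an exact
    known-mutation string match (or later manual promotion).
    """
    if not record.is_nonsynonymous:
        raise ValueError("categorize applies to non-synonymous mutations only")
    gene = record.gene.upper()
    if gene not in kb.genes:
        return DriverCall(record, "non_driver", "no_gene_match")
    aa = record.aa_change
    if aa and (gene, aa) in kb.known_mutations:
        return DriverCall(record, "high_confidence", "known_mutation")
    sift = kb.sift_scores.get((gene, aa)) if aa else None
    if sift is not None and sift < 0.05:
        return DriverCall(record, "high_confidence", "sift_lt_0.05")
    parsed = parse_aa_change(aa)
    if parsed is None:
        if aa:
            log.warning("unparseable aa_change %r in driver gene %s", aa, gene)
        return DriverCall(record, "unknown", "gene_match_only", parse_warning=bool(aa))
    position = parsed[1]
    if any(abs(position - p) <= 5 for p in kb.known_positions.get(gene, ())):
        return DriverCall(record, "putative", "proximity_le_5")
    return DriverCall(record, "unknown", "gene_match_only")


def flag_manual_review(
    calls: Sequence[DriverCall],
    promotions: str | Path | Iterable[tuple[str, str, str]] | None = None,
) -> list[DriverCall]:
    """Promote listed (gene, aa_change) mutations to high_confidence/manual_review.

    ``promotions`` is a TSV (gene, aa_change, justification) or an iterable of
    such triples; promotions referencing mutations absent from the cohort are
    warnings, not errors.
    """
    if promotions is None:
        promotions = _kb_path("promotions.tsv")
    if isinstance(promotions, (str, Path)):
        df = _read_fixture(Path(promotions), ["gene", "aa_change", "justification"])
        entries = [(r.gene.upper(), r.aa_change, r.justification) for r in df.itertuples(index=False)]
    else:
        entries = [(g.upper(), a, j) for g, a, j in promotions]

    index = {(c.record.gene.upper(), c.record.aa_change): i for i, c in enumerate(calls)}
    out = list(calls)
    for gene, aa_change, justification in entries:
        i = index.get((gene, aa_change))
        if i is None:
            log.warning("promotion for absent mutation %s %s ignored", gene, aa_change)
            continue
        log.info("manual-review promotion: %s %s (%s)", gene, aa_change, justification)
        out[i] = DriverCall(out[i].record, "high_confidence", "manual_review")
    return out


@dataclass
class DriverSummary:
    table: pd.DataFrame
    n_total: int
    per_patient: dict[str, int]
    mean_per_patient: float
    range_per_patient: tuple[int, int]
    n_private: int
    private_fraction: float


def summarize_drivers(calls: Sequence[DriverCall]) -> DriverSummary:
    """Potential-driver table (tiers high/putative/unknown) with per-patient totals."""
    drivers = [c for c in calls if c.is_potential_driver]
    rows = [
        {
            "patient": c.record.patient or "",
            "clonality": c.record.clonality,
            "gene": c.record.gene,
            "category": c.record.consequence,
            "aa_change": c.record.aa_change or "NA",
            "relevance": c.tier,
            "reason": c.reason,
        }
        for c in drivers
    ]
    table = pd.DataFrame(
        rows,
        columns=["patient", "clonality", "gene", "category", "aa_change", "relevance", "reason"],
    )
    if len(table):
        table = table.sort_values(
            by=["patient", "relevance"],
            key=lambda col: col.map(_TIER_RANK) if col.name == "relevance" else col,
            kind="stable",
        ).reset_index(drop=True)
    per_patient = table.groupby("patient").size().to_dict() if len(table) else {}
    counts = list(per_patient.values())
    n_private = int(sum(table["clonality"].str.startswith("private"))) if len(table) else 0
    return DriverSummary(
        table=table,
        n_total=len(table),
        per_patient=per_patient,
        mean_per_patient=sum(counts) / len(counts) if counts else float("nan"),
        range_per_patient=(min(counts), max(counts)) if counts else (0, 0),
        n_private=n_private,
        private_fraction=n_private / len(table) if len(table) else float("nan"),
    )


# ---------------------------------------------------------------------------
# packaged cohort fixture
# ---------------------------------------------------------------------------


def load_driver_mutation_fixture() -> list[MutationRecord]:
    """The packaged 20-row iCCA potential-driver cohort (synthetic site stubs).

    Genomic sites and read evidence are placeholders; the scientifically
    meaningful columns are patient, clonality, gene, consequence and aa_change.
    """
    path = Path(str(resources.files("ith_exome").joinpath("data", "icca_driver_mutations.tsv")))
    df = _read_fixture(path, ["patient", "clonality", "gene", "consequence", "aa_change"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        records.append(
            MutationRecord(
                site=GenomicSite("chrF", i * 1000, "A", "C"),
                gene=row.gene,
                consequence=row.consequence,
                aa_change=None if row.aa_change in ("", "NA") else row.aa_change,
                clonality=row.clonality,
                patient=row.patient,
            )
        )
    return records
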