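"""Shared domain types, coordinate conventions, and tabular/genomic I/O.

Every stage of the multiregion exome pipeline speaks the types defined here:
a somatic candidate is a :class:`MutationRecord` carrying per-region
:class:`SiteEvidence` for the non-tumor, central-tumor and peripheral-tumor
samples of one patient; copy-number output is a list of :class:`CnvSegment`.

Coordinate convention: all public coordinates are 1-based inclusive (the VCF
convention, since variants are VCF-facing).  BED and bedGraph exports are
0-based half-open; the conversion happens only at the BED boundary and
round-trips exactly.

Variant allele fractions are always recomputed from read counts; a VAF column
in an input file is never trusted.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__version__ = "0.1.0"

REGIONS = ("normal", "central", "peripheral")
TUMOR_REGIONS = ("central", "peripheral")

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift", "inframe_indel", "silent"}
)
INDEL_CONSEQUENCES = frozenset({"frameshift", "inframe_indel"})
NONSYNONYMOUS = frozenset(CONSEQUENCES - {"silent"})

_BASES = frozenset("ACGT")

CLONALITY_LABELS = ("common", "private_central", "private_peripheral", "unresolved")


class VariantTableError(ValueError):
    """Raised on malformed or invariant-violating variant table content."""


class SegmentError(ValueError):
    """Raised on invalid copy-number segment sets (e.g. overlaps)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicSite:
    """A single variant locus: 1-based position plus ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantTableError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantTableError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise VariantTableError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _BASES:
                raise VariantTableError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} has non-ACGT bases"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class SiteEvidence:
    """Per-sample sequencing evidence at one genomic site.

    ``vaf`` is derived from the counts (0 when depth is 0), never stored.
    """

    depth: int
    var_reads: int
    mapping_quality: float = 60.0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.var_reads < 0:
            raise VariantTableError("depth and var_reads must be non-negative")
        if self.var_reads > self.depth:
            raise VariantTableError(
                f"var_reads ({self.var_reads}) exceeds depth ({self.depth})"
            )

    @property
    def vaf(self) -> float:
        return self.var_reads / self.depth if self.depth > 0 else 0.0


@dataclass
class MutationRecord:
    """A candidate somatic mutation with annotation and per-region evidence."""

    site: GenomicSite
    gene: str
    consequence: str
    evidence: dict[str, SiteEvidence] = field(default_factory=dict)
    aa_change: str | None = None
    trinucleotide_context: str | None = None
    clonality: str = "unresolved"
    patient: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise VariantTableError(
                f"unknown consequence {self.consequence!r}; expected one of {sorted(CONSEQUENCES)}"
            )
        if self.clonality not in CLONALITY_LABELS:
            raise VariantTableError(f"unknown clonality label {self.clonality!r}")
        for region in self.evidence:
            if region not in REGIONS:
                raise VariantTableError(f"unknown evidence region {region!r}")
        ctx = self.trinucleotide_context
        if ctx is not None:
            if len(ctx) != 3 or not set(ctx) <= _BASES:
                raise VariantTableError(f"bad trinucleotide context {ctx!r}")
            if self.site.is_snv and ctx[1] != self.site.ref:
                raise VariantTableError(
                    f"context {ctx} middle base does not match ref {self.site.ref} "
                    f"at {self.site.chrom}:{self.site.pos}"
                )

    @property
    def is_indel(self) -> bool:
        return self.consequence in INDEL_CONSEQUENCES or not self.site.is_snv

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence in NONSYNONYMOUS

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.site.key


@dataclass(frozen=True)
class SampleTrio:
    """A patient's three-sample design with per-region tumor purity."""

    patient_id: str
    purity_central: float
    purity_peripheral: float

    def __post_init__(self) -> None:
        for p in (self.purity_central, self.purity_peripheral):
            if not 0 < p <= 1:
                raise ValueError(f"tumor purity must be in (0, 1], got {p}")

    def purity(self, region: str) -> float:
        if region == "central":
            return self.purity_central
        if region == "peripheral":
            return self.purity_peripheral
        raise KeyError(region)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic SNV cut-offs and the 4-rule indel filter.

    Defaults are the published values: mapping quality >= 20, tumor VAF >= 5%,
    depth >= 10 in tumor and non-tumor, >= 2 tumor variant reads, <= 1 normal
    variant read, no indel within 5 bp, at most 2 SNVs per 10-bp window; for
    indels depth >= 20 in both samples, VAF >= 10%, >= 5 variant reads and no
    variant read in the non-tumor sample.
    """

    snv_min_mapq: float = 20.0
    snv_min_tumor_vaf: float = 0.05
    snv_min_depth: int = 10
    snv_min_tumor_var_reads: int = 2
    snv_max_normal_var_reads: int = 1
    snv_indel_exclusion_bp: int = 5
    snv_window_bp: int = 10
    snv_window_max: int = 2
    indel_min_depth: int = 20
    indel_min_vaf: float = 0.10
    indel_min_var_reads: int = 5
    indel_max_normal_var_reads: int = 0

    def __post_init__(self) -> None:
        for name, value in self.to_dict().items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.snv_window_max < 1:
            raise ValueError("snv_window_max must be >= 1")

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class CnvInterpretation:
    """One way of reading a segment's deviation as a copy state at a cell fraction."""

    copy_number: int
    clonal_fraction: float
    expected_deviation_pct: float
    label: str  # clonal_tumor | subclonal_tumor | non_tumor | nearest_state


@dataclass(frozen=True)
class CnvSegment:
    """A contiguous run of bins with concordant coverage deviation.

    Coordinates are 1-based inclusive; ``call`` is one of het_dup, hom_dup,
    het_del, hom_del, ambiguous, none.
    """

    chrom: str
    start: int
    end: int
    mean_deviation_pct: float
    call: str
    interpretations: tuple[CnvInterpretation, ...] = ()
    n_bins: int = 0
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SegmentError(f"bad segment coordinates {self.chrom}:{self.start}-{self.end}")
        if not math.isfinite(self.mean_deviation_pct):
            raise SegmentError("segment deviation must be finite")
        if self.call != "none" and not self.interpretations:
            raise SegmentError("called segments must carry at least one interpretation")


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_line(cfg_hash: str | None = None) -> str:
    tag = f"ith-exome {__version__}"
    if cfg_hash:
        tag += f" config={cfg_hash}"
    return tag


# ---------------------------------------------------------------------------
# variant table I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    ["patient", "chrom", "pos", "ref", "alt", "gene", "consequence", "aa_change", "context"]
    + [f"{r}_{f}" for r in REGIONS for f in ("depth", "var_reads", "mapq")]
)


def _record_sort_key(rec: MutationRecord):
    return (rec.patient or "", rec.site.chrom, rec.site.pos, rec.site.alt)


def _check_duplicates(records: Sequence[MutationRecord], path) -> None:
    seen: set[tuple] = set()
    for rec in records:
        k = (rec.patient, rec.site.chrom, rec.site.pos, rec.site.alt)
        if k in seen:
            raise VariantTableError(
                f"{path}: duplicate variant {rec.site.chrom}:{rec.site.pos}>{rec.site.alt} "
                f"for patient {rec.patient}"
            )
        seen.add(k)


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[MutationRecord]:
    """Read candidate mutations from a TSV or minimal-VCF file.

    Records come back sorted by (patient, chrom, pos, alt); malformed rows raise
    :class:`VariantTableError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf_min":
        return _read_vcf_min(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _read_tsv(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            evidence = {
                region: SiteEvidence(
                    depth=int(row[f"{region}_depth"]),
                    var_reads=int(row[f"{region}_var_reads"]),
                    mapping_quality=float(row[f"{region}_mapq"]),
                )
                for region in REGIONS
                if row[f"{region}_depth"] != ""
            }
            rec = MutationRecord(
                site=GenomicSite(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                gene=row["gene"],
                consequence=row["consequence"],
                evidence=evidence,
                aa_change=_opt(row["aa_change"]),
                trinucleotide_context=_opt(row["context"]),
                patient=_opt(row["patient"]),
            )
        except (VariantTableError, ValueError) as exc:
            raise VariantTableError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
    records.sort(key=_record_sort_key)
    _check_duplicates(records, path)
    return records


def write_variant_table(
    records: Iterable[MutationRecord],
    path: str | Path,
    dialect: str = "tsv",
    cfg_hash: str | None = None,
) -> Path:
    """Write mutation records as TSV or minimal VCF, with a provenance header."""
    path = Path(path)
    records = sorted(records, key=_record_sort_key)
    if dialect == "tsv":
        rows = []
        for rec in records:
            row = {
                "patient": rec.patient or "",
                "chrom": rec.site.chrom,
                "pos": rec.site.pos,
                "ref": rec.site.ref,
                "alt": rec.site.alt,
                "gene": rec.gene,
                "consequence": rec.consequence,
                "aa_change": rec.aa_change or "",
                "context": rec.trinucleotide_context or "",
            }
            for region in REGIONS:
                ev = rec.evidence.get(region)
                row[f"{region}_depth"] = ev.depth if ev else ""
                row[f"{region}_var_reads"] = ev.var_reads if ev else ""
                row[f"{region}_mapq"] = f"{ev.mapping_quality:g}" if ev else ""
            rows.append(row)
        with open(path, "w") as fh:
            fh.write(f"# {provenance_line(cfg_hash)}\n")
            pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(fh, sep="\t", index=False)
        return path
    if dialect == "vcf_min":
        return _write_vcf_min(records, path, cfg_hash)
    raise ValueError(f"unknown dialect {dialect!r}")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source={source}
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence label">
##INFO=<ID=AA,Number=1,Type=String,Description="Amino acid change">
##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context on the plus strand">
##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=VD,Number=1,Type=Integer,Description="Variant-supporting read count">
##FORMAT=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
"""


def _write_vcf_min(records: Sequence[MutationRecord], path: Path, cfg_hash: str | None) -> Path:
    chroms = sorted({r.site.chrom for r in records})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(source=provenance_line(cfg_hash)))
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(r.upper() for r in REGIONS) + "\n")
        for rec in records:
            info = [f"GENE={rec.gene}", f"CSQ={rec.consequence}"]
            if rec.aa_change:
                info.append(f"AA={rec.aa_change}")
            if rec.trinucleotide_context:
                info.append(f"CTX={rec.trinucleotide_context}")
            if rec.patient:
                info.append(f"PATIENT={rec.patient}")
            samples = []
            for region in REGIONS:
                ev = rec.evidence.get(region)
                samples.append(f"{ev.depth}:{ev.var_reads}:{ev.mapping_quality:g}"
                               if ev else ".:.:.")
            fh.write("\t".join([
                rec.site.chrom, str(rec.site.pos), ".", rec.site.ref, rec.site.alt,
                ".", ".", ";".join(info), "DP:VD:MQ", *samples,
            ]) + "\n")
    return path


def _read_vcf_min(path: Path) -> list[MutationRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_order = [s.lower() for s in vcf.samples]
    unknown = set(sample_order) - set(REGIONS)
    if unknown:
        raise VariantTableError(f"{path}: unexpected sample name(s) {sorted(unknown)}")
    records = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise VariantTableError(
                f"{path}: {variant.CHROM}:{variant.POS}: minimal VCF dialect requires a single ALT"
            )
        for key in ("GENE", "CSQ"):
            if variant.INFO.get(key) is None:
                raise VariantTableError(
                    f"{path}: {variant.CHROM}:{variant.POS}: missing required INFO field {key}"
                )
        dp = variant.format("DP")
        vd = variant.format("VD")
        mq = variant.format("MQ")
        if dp is None or vd is None or mq is None:
            raise VariantTableError(
                f"{path}: {variant.CHROM}:{variant.POS}: missing required FORMAT field "
                "(DP, VD and MQ are required)"
            )
        evidence = {}
        for i, region in enumerate(sample_order):
            if dp[i][0] < 0:  # cyvcf2 encodes '.' as a negative sentinel
                continue
            evidence[region] = SiteEvidence(
                depth=int(dp[i][0]), var_reads=int(vd[i][0]), mapping_quality=float(mq[i][0])
            )
        try:
            rec = MutationRecord(
                site=GenomicSite(variant.CHROM, variant.POS, variant.REF, variant.ALT[0]),
                gene=str(variant.INFO["GENE"]),
                consequence=str(variant.INFO["CSQ"]),
                evidence=evidence,
                aa_change=variant.INFO.get("AA"),
                trinucleotide_context=variant.INFO.get("CTX"),
                patient=variant.INFO.get("PATIENT"),
            )
        except VariantTableError as exc:
            raise VariantTableError(f"{path}: {variant.CHROM}:{variant.POS}: {exc}") from exc
        records.append(rec)
    records.sort(key=_record_sort_key)
    _check_duplicates(records, path)
    return records


# ---------------------------------------------------------------------------
# segment I/O (BED6 + bedGraph, 0-based half-open on disk)
# ---------------------------------------------------------------------------


def write_segments(
    segments: Sequence[CnvSegment],
    out_prefix: str | Path,
    cfg_hash: str | None = None,
) -> tuple[Path, Path]:
    """Write segments as ``<prefix>.bed`` (calls) and ``<prefix>.bedGraph`` (deviation).

    Internal 1-based inclusive coordinates become 0-based half-open on disk.
    Overlapping segments on one chromosome are a hard error.
    """
    out_prefix = Path(out_prefix)
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start, s.end))
    prev: CnvSegment | None = None
    for seg in ordered:
        if prev is not None and seg.chrom == prev.chrom and seg.start <= prev.end:
            raise SegmentError(
                f"overlapping segments {prev.chrom}:{prev.start}-{prev.end} and "
                f"{seg.chrom}:{seg.start}-{seg.end}"
            )
        prev = seg
    bed_path = out_prefix.with_suffix(".bed")
    bg_path = out_prefix.with_suffix(".bedGraph")
    header = f"# {provenance_line(cfg_hash)}\n"
    with open(bed_path, "w") as fh:
        fh.write(header)
        for seg in ordered:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.call}\t0\t.\n")
    with open(bg_path, "w") as fh:
        fh.write(header)
        fh.write("track type=bedGraph\n")
        for seg in ordered:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.mean_deviation_pct:.6g}\n")
    return bed_path, bg_path


def read_segments(out_prefix: str | Path) -> list[CnvSegment]:
    """Read back a ``write_segments`` pair (coordinates converted to 1-based inclusive)."""
    out_prefix = Path(out_prefix)
    bed = pd.read_csv(
        out_prefix.with_suffix(".bed"), sep="\t", comment="#", header=None,
        names=["chrom", "start0", "end", "call", "score", "strand"],
    )
    bg_rows = []
    with open(out_prefix.with_suffix(".bedGraph")) as fh:
        for line in fh:
            if line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            bg_rows.append(((chrom, int(s), int(e)), float(v)))
    deviation = dict(bg_rows)
    segments = []
    for row in bed.itertuples(index=False):
        dev = deviation.get((row.chrom, row.start0, row.end), 0.0)
        interp = ()
        if row.call != "none":
            interp = (CnvInterpretation(2, 1.0, dev, "nearest_state"),)
        segments.append(
            CnvSegment(
                chrom=row.chrom, start=int(row.start0) + 1, end=int(row.end),
                mean_deviation_pct=dev, call=row.call, interpretations=interp,
            )
        )
    return segments
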