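"""Trunk/private clonality classification and intratumoral-heterogeneity summaries.

A mutation passing the somatic filter in both tumor regions is common (trunk)
without further interrogation.  A mutation passing in only one region is
cross-interrogated in the other region's raw evidence: presence there (>= 2
variant reads at depth >= 10 by default) also makes it common; absence with
adequate coverage makes it a private candidate, which an orthogonal
allele-fraction assay then confirms (>= 5% AF excess over the non-tumor sample
in the harboring region only), refutes (excess in both regions -> relabeled
common), or leaves untested.  Absence that cannot be asserted for lack of
coverage yields the label ``unresolved``.

The module also provides the mutation-spectrum machinery: strand-collapsed
six-class substitution typing, CpG-fraction bookkeeping over trinucleotide
contexts, and per-sample/per-patient ITH summary statistics.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import MutationRecord, SiteEvidence, TUMOR_REGIONS
from .somatic_filtering import FilterDecision
from .synthetic_cohort import SUBSTITUTION_CLASSES

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONFIRMATIONS = ("not_required", "confirmed", "refuted", "unsupported", "untested")


@dataclass(frozen=True)
class PresenceRule:
    """Cross-interrogation thresholds: when does the other region 'have' the variant.

    Defaults (>= 2 variant reads AND depth >= 10) mirror the somatic-evidence
    minimum of the filter itself and guard against single-read sequencing error.
    """

    min_var_reads: int = 2
    min_depth: int = 10


@dataclass(frozen=True)
class CrossResult:
    status: str  # present | absent
    low_coverage: bool


def cross_interrogate(
    evidence: SiteEvidence | None, rule: PresenceRule | None = None
) -> CrossResult:
    """Decide presence/absence of a variant in the other tumor region's reads."""
    rule = rule or PresenceRule()
    if evidence is None or evidence.depth == 0:
        return CrossResult("absent", low_coverage=True)
    present = evidence.var_reads >= rule.min_var_reads and evidence.depth >= rule.min_depth
    return CrossResult(
        "present" if present else "absent",
        low_coverage=evidence.depth < rule.min_depth,
    )


def confirm_private(
    af_harboring: float,
    af_other: float,
    af_normal: float,
    min_diff: float = 0.05,
) -> str:
    """Score a private candidate against orthogonal AF measurements.

    confirmed: only the harboring region exceeds the non-tumor AF by >= min_diff;
    refuted: both regions exceed it (the variant is really common);
    unsupported: not even the harboring region exceeds it (assay-negative).
    """
    eps = 1e-12  # the >= comparison must not fail on float rounding at 5%
    harb = af_harboring - af_normal >= min_diff - eps
    other = af_other - af_normal >= min_diff - eps
    if harb and other:
        return "refuted"
    if harb:
        return "confirmed"
    return "unsupported"


@dataclass(frozen=True)
class ClonalityCall:
    record: MutationRecord
    label: str  # common | private_central | private_peripheral | unresolved
    passed_regions: tuple[str, ...]
    cross_evidence: SiteEvidence | None = None
    confirmation: str = "not_required"

    def __post_init__(self) -> None:
        if self.confirmation not in CONFIRMATIONS:
            raise ValueError(f"unknown confirmation status {self.confirmation!r}")
        if self.label.startswith("private") and self.confirmation not in (
            "confirmed", "untested",
        ):
            raise ValueError("private labels require a confirmed or untested assay status")

    @property
    def harboring_region(self) -> str | None:
        if self.label == "private_central":
            return "central"
        if self.label == "private_peripheral":
            return "peripheral"
        return None


def classify_patient(
    decisions_central: Sequence[FilterDecision],
    decisions_peripheral: Sequence[FilterDecision],
    orthogonal_af: Mapping[tuple, Mapping[str, float]] | None = None,
    rule: PresenceRule | None = None,
    min_diff: float = 0.05,
) -> list[ClonalityCall]:
    """Assign exactly one clonality label to every mutation passing in >= 1 region."""
    rule = rule or PresenceRule()
    passed = {
        "central": {d.record.key: d for d in decisions_central if d.passed},
        "peripheral": {d.record.key: d for d in decisions_peripheral if d.passed},
    }
    calls: list[ClonalityCall] = []
    for key in sorted(set(passed["central"]) | set(passed["peripheral"])):
        in_c, in_p = key in passed["central"], key in passed["peripheral"]
        record = (passed["central"].get(key) or passed["peripheral"][key]).record
        if in_c and in_p:
            calls.append(ClonalityCall(record, "common", ("central", "peripheral")))
            continue
        region = "central" if in_c else "peripheral"
        other = "peripheral" if in_c else "central"
        other_ev = record.evidence.get(other)
        cross = cross_interrogate(other_ev, rule)
        if cross.status == "present":
            calls.append(
                ClonalityCall(record, "common", (region,), other_ev, "not_required")
            )
            continue
        if cross.low_coverage:
            # absence cannot be asserted without coverage
            calls.append(
                ClonalityCall(record, "unresolved", (region,), other_ev, "untested")
            )
            continue
        af = (orthogonal_af or {}).get(key)
        if af is None:
            calls.append(
                ClonalityCall(record, f"private_{region}", (region,), other_ev, "untested")
            )
            continue
        verdict = confirm_private(af[region], af[other], af["normal"], min_diff)
        if verdict == "confirmed":
            label, conf = f"private_{region}", "confirmed"
        elif verdict == "refuted":
            label, conf = "common", "refuted"
        else:  # assay-negative candidate: treated as an artefact
            label, conf = "unresolved", "unsupported"
        calls.append(ClonalityCall(record, label, (region,), other_ev, conf))
    return calls


# ---------------------------------------------------------------------------
# mutation spectra
# ---------------------------------------------------------------------------


def substitution_class(ref: str, alt: str) -> str:
    """Strand-collapsed paired substitution class of a single-base change.

    The 12 ordered base pairs map two-to-one onto the six classes written in
    pyrimidine-first paired notation (e.g. G>A and C>T are both "C>T/G>A").
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"not a single-nucleotide substitution: {ref}>{alt}")
    if ref in "AG":  # collapse onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    for cls in SUBSTITUTION_CLASSES:
        if cls.startswith(f"{ref}>{alt}"):
            return cls
    raise AssertionError("unreachable")


def is_cpg(record: MutationRecord) -> bool | None:
    """CpG status of a C>T/G>A event; None when no context is available.

    A mutated C is CpG when G follows it; a mutated G (plus strand) is CpG when
    C precedes it.
    """
    ctx = record.trinucleotide_context
    if ctx is None:
        return None
    if record.site.ref == "C":
        return ctx[2] == "G"
    if record.site.ref == "G":
        return ctx[0] == "C"
    raise ValueError("CpG status is defined for C>T/G>A events only")


@dataclass(frozen=True)
class CpgResult:
    fraction: float
    n_cpg: int
    n_evaluated: int
    n_missing_context: int


def cpg_fraction(records: Iterable[MutationRecord]) -> CpgResult:
    """Fraction of C>T/G>A events at CpG sites among records with context.

    Records lacking a trinucleotide context are excluded from numerator and
    denominator and reported in ``n_missing_context``.
    """
    n_cpg = n_eval = n_missing = 0
    for rec in records:
        if not rec.site.is_snv:
            continue
        if substitution_class(rec.site.ref, rec.site.alt) != "C>T/G>A":
            continue
        status = is_cpg(rec)
        if status is None:
            n_missing += 1
            continue
        n_eval += 1
        n_cpg += int(status)
    frac = n_cpg / n_eval if n_eval else float("nan")
    return CpgResult(frac, n_cpg, n_eval, n_missing)


def spectrum_counts(records: Iterable[MutationRecord]) -> pd.Series:
    """SNV counts per paired substitution class (indels are skipped)."""
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for rec in records:
        if rec.site.is_snv:
            counts[substitution_class(rec.site.ref, rec.site.alt)] += 1
    return pd.Series(counts, name="count")


# ---------------------------------------------------------------------------
# ITH summary
# ---------------------------------------------------------------------------


@dataclass
class IthSummary:
    """Per-sample counts/VAF medians plus per-patient spectrum and CpG tables."""

    per_sample: pd.DataFrame
    spectrum: pd.DataFrame           # patient x clonality x class counts (long form)
    cpg: pd.DataFrame                # per patient CpG bookkeeping
    functional_categories: pd.DataFrame


def _median(values: list[float]) -> float:
    return statistics.median(values) if values else float("nan")


def _record_vaf(call: ClonalityCall) -> float:
    """VAF convention: harboring region for private calls, mean of both tumor
    regions for common ones (the published convention is unstated)."""
    rec = call.record
    if call.harboring_region:
        return rec.evidence[call.harboring_region].vaf
    vafs = [rec.evidence[r].vaf for r in TUMOR_REGIONS if r in rec.evidence]
    return sum(vafs) / len(vafs)


def summarize_ith(calls_by_patient: Mapping[str, Sequence[ClonalityCall]]) -> IthSummary:
    """Counts, private fractions and median VAFs per sample; spectra per patient.

    Counts and fractions cover non-synonymous mutations (the published
    convention); the spectrum and functional-category tables cover all calls.
    """
    sample_rows = []
    spectrum_rows = []
    cpg_rows = []
    cat_rows = []
    for patient, calls in calls_by_patient.items():
        nonsyn = [c for c in calls if c.record.is_nonsynonymous]
        common = [c for c in nonsyn if c.label == "common"]
        for region in TUMOR_REGIONS:
            private = [c for c in nonsyn if c.label == f"private_{region}"]
            unresolved = [c for c in nonsyn if c.label == "unresolved"]
            n_common, n_private = len(common), len(private)
            denom = n_common + n_private
            sample_vafs = [c.record.evidence[region].vaf for c in common] + [
                _record_vaf(c) for c in private
            ]
            sample_rows.append(
                {
                    "patient": patient,
                    "region": region,
                    "n_common": n_common,
                    "n_private": n_private,
                    "n_unresolved": len(unresolved),
                    "private_fraction": n_private / denom if denom else float("nan"),
                    "median_vaf_common": _median([_record_vaf(c) for c in common]),
                    "median_vaf_private": _median([_record_vaf(c) for c in private]),
                    "median_vaf_sample": _median(sample_vafs),
                }
            )
        for group, members in (
            ("common", [c for c in calls if c.label == "common"]),
            ("private", [c for c in calls if c.label.startswith("private")]),
        ):
            counts = spectrum_counts(c.record for c in members)
            for cls, n in counts.items():
                spectrum_rows.append(
                    {"patient": patient, "clonality": group, "class": cls, "count": int(n)}
                )
        cp = cpg_fraction(c.record for c in calls)
        cpg_rows.append(
            {
                "patient": patient,
                "cpg_fraction": cp.fraction,
                "n_cpg": cp.n_cpg,
                "n_evaluated": cp.n_evaluated,
                "n_missing_context": cp.n_missing_context,
            }
        )
        for call in calls:
            cat_rows.append(
                {"patient": patient, "consequence": call.record.consequence, "label": call.label}
            )
    categories = (
        pd.DataFrame(cat_rows)
        .groupby(["patient", "consequence", "label"])
        .size()
        .rename("count")
        .reset_index()
        if cat_rows
        else pd.DataFrame(columns=["patient", "consequence", "label", "count"])
    )
    return IthSummary(
        per_sample=pd.DataFrame(sample_rows),
        spectrum=pd.DataFrame(spectrum_rows),
        cpg=pd.DataFrame(cpg_rows),
        functional_categories=categories,
    )
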