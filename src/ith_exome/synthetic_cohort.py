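"""Synthetic multiregion tumor/normal cohorts with known ground truth.

The generator emulates the study design every downstream stage expects: for
each patient a non-tumor, a central-tumor and a peripheral-tumor exome, with

* planted clonal ("common") and region-restricted ("private") somatic
  mutations whose variant allele fractions follow purity dilution,
* a C>T/G>A-dominated substitution spectrum with CpG enrichment, plus an
  optional hypermutator mode that makes one region's private mutations
  C>A/G>T-dominated (the mismatch-repair-deficient phenotype),
* per-bin exome coverage with a capture-bias field shared by all samples,
  planted heterozygous/homozygous duplications and deletions scaled by tumor
  purity, and a reference panel of >= 10 normal coverage profiles,
* noisy orthogonal allele-fraction re-measurements for the >=5%-over-normal
  confirmation step, and
* germline heterozygous polymorphisms listed in a polymorphism-exclusion file.

Ground truth is serialized alongside every cohort so any downstream stage can
be scored without re-running the generator.  Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_model import (
    GenomicSite,
    MutationRecord,
    SampleTrio,
    SiteEvidence,
    write_variant_table,
)

READ_LENGTH_BP = 100  # converts per-base depth into per-bin read counts

SUBSTITUTION_CLASSES = (
    "C>T/G>A", "C>A/G>T", "C>G/G>C", "T>C/A>G", "T>A/A>T", "T>G/A>C",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeModel:
    """A small synthetic exome: named chromosomes tiled into constant-width bins.

    Coordinates are 1-based inclusive.  The model stands in for a reference
    genome; trinucleotide contexts are assigned at planting time rather than
    read from sequence, because context (not sequence) is what downstream
    statistics consume.
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 60_000_000), ("chr2", 60_000_000), ("chr3", 60_000_000),
    )
    bin_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.bin_bp < 1:
            raise ValueError("bin_bp must be positive")
        for name, length in self.chromosomes:
            if length < self.bin_bp:
                raise ValueError(f"chromosome {name} shorter than one bin")

    @property
    def exome_bins(self) -> list[tuple[str, int, int]]:
        """Sorted, non-overlapping (chrom, start, end) tiles, 1-based inclusive."""
        bins = []
        for name, length in self.chromosomes:
            for start in range(1, length + 1, self.bin_bp):
                bins.append((name, start, min(start + self.bin_bp - 1, length)))
        return bins

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass(frozen=True)
class SpectrumParams:
    """Substitution-class weights, CpG enrichment, and the hypermutator switch."""

    substitution_weights: tuple[float, ...] = (0.48, 0.12, 0.08, 0.18, 0.07, 0.07)
    cpg_enrichment: float = 0.45
    hypermutator_mode: bool = False

    def __post_init__(self) -> None:
        if len(self.substitution_weights) != len(SUBSTITUTION_CLASSES):
            raise ValueError("need one weight per paired substitution class")
        if abs(sum(self.substitution_weights) - 1.0) > 1e-9:
            raise ValueError("substitution weights must sum to 1")
        if not 0 <= self.cpg_enrichment <= 1:
            raise ValueError("cpg_enrichment must be in [0, 1]")

    @classmethod
    def hypermutator(cls) -> "SpectrumParams":
        """C>A/G>T-dominated spectrum of a mismatch-repair-deficient region."""
        return cls(
            substitution_weights=(0.20, 0.45, 0.07, 0.12, 0.08, 0.08),
            cpg_enrichment=0.45,
            hypermutator_mode=True,
        )

    def weight_of(self, cls_label: str) -> float:
        return self.substitution_weights[SUBSTITUTION_CLASSES.index(cls_label)]


@dataclass(frozen=True)
class NoiseParams:
    """Sequencing-noise knobs shared by the variant and coverage simulators.

    ``mean_depth`` is the per-base target coverage (default 109, a realistic
    exome mean); per-bin read counts scale it by bin width / read length.
    ``depth_dispersion`` d gives negative-binomial variance m + d*m^2; d = 0
    means deterministic depth (the noise-free limit).  ``sequencing_error_rate``
    feeds Poisson-distributed spurious variant reads; ``pyro_sd`` is the SD of
    the orthogonal allele-fraction re-measurement.
    """

    mean_depth: float = 109.0
    depth_dispersion: float = 4e-4
    sequencing_error_rate: float = 1e-3
    pyro_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("mean_depth", "depth_dispersion", "sequencing_error_rate", "pyro_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortParams:
    """Study-scale knobs: 4 trios, panel of 10, count ranges of the iCCA cohort.

    Defaults mirror the observed magnitudes: ~24-41 common non-synonymous and
    ~9-14 silent mutations per patient, 0-14 private mutations per sample with
    the hypermutator burden concentrated in one peripheral sample, tumor
    purities averaging ~0.47 with the peripheral sample slightly purer.
    """

    n_reference: int = 10
    common_nonsyn: tuple[int, ...] = (41, 35, 33, 24)
    common_silent: tuple[int, ...] = (13, 12, 14, 12)
    private_counts: tuple[tuple[int, int], ...] = ((2, 1), (1, 2), (3, 0), (2, 14))
    purities: tuple[tuple[float, float], ...] = (
        (0.40, 0.50), (0.45, 0.55), (0.35, 0.45), (0.40, 0.70),
    )
    indels_per_patient: int = 2
    n_polymorphisms: int = 5
    hypermutator_patient: int | None = 3  # 0-based index; None disables
    spectrum: SpectrumParams = SpectrumParams()

    def __post_init__(self) -> None:
        n = len(self.common_nonsyn)
        if not (len(self.common_silent) == len(self.private_counts) == len(self.purities) == n):
            raise ValueError("per-patient parameter tuples must have equal length")
        if self.n_reference < 10:
            raise ValueError("reference panel must contain at least 10 samples")

    @property
    def n_patients(self) -> int:
        return len(self.common_nonsyn)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthMutation:
    site: GenomicSite
    gene: str
    consequence: str
    clonality: str  # common | private_central | private_peripheral
    cancer_cell_fraction: float
    trinucleotide_context: str | None

    def __post_init__(self) -> None:
        if not 0 < self.cancer_cell_fraction <= 1:
            raise ValueError("cancer_cell_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TruthCnv:
    chrom: str
    start: int
    end: int
    copy_number: int
    region: str  # both | central_only | peripheral_only

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 2, 3, 4):
            raise ValueError("copy_number must be in {0,...,4}")
        if self.region not in ("both", "central_only", "peripheral_only"):
            raise ValueError(f"bad CNV region {self.region!r}")


@dataclass
class PatientTruth:
    trio: SampleTrio
    mutations: list[TruthMutation]
    cnvs: list[TruthCnv]


@dataclass
class TruthSet:
    patients: list[PatientTruth]
    spectrum: SpectrumParams

    def to_json(self) -> str:
        payload = {
            "spectrum": asdict(self.spectrum),
            "patients": [
                {
                    "patient_id": pt.trio.patient_id,
                    "purity_central": pt.trio.purity_central,
                    "purity_peripheral": pt.trio.purity_peripheral,
                    "mutations": [
                        {
                            "chrom": m.site.chrom, "pos": m.site.pos,
                            "ref": m.site.ref, "alt": m.site.alt,
                            "gene": m.gene, "consequence": m.consequence,
                            "clonality": m.clonality,
                            "cancer_cell_fraction": m.cancer_cell_fraction,
                            "context": m.trinucleotide_context,
                        }
                        for m in pt.mutations
                    ],
                    "cnvs": [asdict(c) for c in pt.cnvs],
                }
                for pt in self.patients
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        payload = json.loads(text)
        patients = []
        for p in payload["patients"]:
            trio = SampleTrio(p["patient_id"], p["purity_central"], p["purity_peripheral"])
            muts = [
                TruthMutation(
                    GenomicSite(m["chrom"], m["pos"], m["ref"], m["alt"]),
                    m["gene"], m["consequence"], m["clonality"],
                    m["cancer_cell_fraction"], m["context"],
                )
                for m in p["mutations"]
            ]
            cnvs = [TruthCnv(**c) for c in p["cnvs"]]
            patients.append(PatientTruth(trio, muts, cnvs))
        return cls(patients, SpectrumParams(
            tuple(payload["spectrum"]["substitution_weights"]),
            payload["spectrum"]["cpg_enrichment"],
            payload["spectrum"]["hypermutator_mode"],
        ))


@dataclass
class CoverageProfile:
    """Per-bin read counts for one sample on the shared exome tiling."""

    sample_id: str
    bins: list[tuple[str, int, int]]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bins):
            raise ValueError("counts and bins must align")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class PatientData:
    trio: SampleTrio
    records: list[MutationRecord]
    coverage: dict[str, CoverageProfile]  # region -> profile
    # (chrom,pos,ref,alt) -> {"central": af, "peripheral": af, "normal": af}
    orthogonal_af: dict[tuple, dict[str, float]]


@dataclass
class Cohort:
    genome: GenomeModel
    noise: NoiseParams
    params: CohortParams
    seed: int
    truth: TruthSet
    patients: list[PatientData]
    reference_panel: list[CoverageProfile]
    polymorphism_sites: set[tuple]  # (chrom,pos,ref,alt)
    exon_intervals: list[tuple[str, int, int]]


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def expected_vaf(purity: float, ccf: float, local_cn: int = 2, multiplicity: int = 1) -> float:
    """Expected variant allele fraction under purity dilution.

    purity * ccf * multiplicity / (purity * local_cn + (1 - purity) * 2):
    the variant allele sits on ``multiplicity`` of ``local_cn`` tumor copies in
    a fraction ``purity * ccf`` of cells, while admixed normal cells contribute
    two reference copies.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if not 0 < ccf <= 1:
        raise ValueError("ccf must be in (0, 1]")
    if local_cn < 1:
        raise ValueError("local_cn must be >= 1")
    if multiplicity < 1 or multiplicity > local_cn:
        raise ValueError("multiplicity must be in [1, local_cn]")
    return purity * ccf * multiplicity / (purity * local_cn + (1 - purity) * 2)


def simulate_orthogonal_af(true_af: float, pyro_sd: float, rng: np.random.Generator) -> float:
    """One orthogonal AF re-measurement: Gaussian noise truncated to [0, 1]."""
    if not 0 <= true_af <= 1:
        raise ValueError("true_af must be in [0, 1]")
    if pyro_sd == 0:
        return true_af
    return float(np.clip(true_af + rng.normal(0.0, pyro_sd), 0.0, 1.0))


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------


def _draw_counts(mean, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with var = m + d*m^2; deterministic when d = 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=mean.shape).astype(float)


def _draw_site_depth(noise: NoiseParams, rng: np.random.Generator) -> int:
    if noise.depth_dispersion == 0:
        return int(round(noise.mean_depth))
    return int(_draw_counts(np.array(noise.mean_depth), noise.depth_dispersion, rng))


def _draw_evidence(
    noise: NoiseParams, rng: np.random.Generator, evaf: float, mapq: float = 60.0
) -> SiteEvidence:
    depth = _draw_site_depth(noise, rng)
    var = int(rng.binomial(depth, evaf)) if evaf > 0 else 0
    if noise.sequencing_error_rate > 0:
        # spurious support for this particular alt allele: 1/3 of base errors
        var += int(rng.poisson(depth * noise.sequencing_error_rate / 3))
    return SiteEvidence(depth=depth, var_reads=min(var, depth), mapping_quality=mapq)


def sample_substitution(
    spectrum: SpectrumParams, rng: np.random.Generator
) -> tuple[str, str, str]:
    """Draw one substitution: (ref, alt, trinucleotide context).

    The paired class is drawn from ``substitution_weights``; the strand
    orientation is a fair coin.  For C>T/G>A events the context is a CpG with
    probability ``cpg_enrichment`` (G 3' of a mutated C, or C 5' of a mutated
    G on the plus strand) and explicitly non-CpG otherwise.
    """
    cls = SUBSTITUTION_CLASSES[
        rng.choice(len(SUBSTITUTION_CLASSES), p=spectrum.substitution_weights)
    ]
    pyr_ref, pyr_alt = cls.split("/")[0].split(">")
    if rng.random() < 0.5:
        ref, alt = pyr_ref, pyr_alt
    else:
        ref, alt = _COMPLEMENT[pyr_ref], _COMPLEMENT[pyr_alt]
    bases = "ACGT"
    left = bases[rng.integers(4)]
    right = bases[rng.integers(4)]
    if cls == "C>T/G>A":
        cpg = rng.random() < spectrum.cpg_enrichment
        if ref == "C":
            right = "G" if cpg else "ACT"[rng.integers(3)]
        else:  # mutated G: CpG means C immediately 5'
            left = "C" if cpg else "AGT"[rng.integers(3)]
    return ref, alt, left + ref + right


# ---------------------------------------------------------------------------
# site placement
# ---------------------------------------------------------------------------


class _SitePlacer:
    """Draws well-separated positions so planted sites never trip the
    proximity rules (10-bp window, 5-bp indel exclusion) by construction."""

    MIN_SEPARATION_BP = 25

    def __init__(self, genome: GenomeModel, rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self._used: dict[str, list[int]] = {name: [] for name, _ in genome.chromosomes}
        self._lengths = np.array([length for _, length in genome.chromosomes], dtype=float)
        self._names = [name for name, _ in genome.chromosomes]

    def place(self) -> tuple[str, int]:
        for _ in range(10_000):
            ci = int(self.rng.choice(len(self._names), p=self._lengths / self._lengths.sum()))
            chrom = self._names[ci]
            pos = int(self.rng.integers(2, int(self._lengths[ci]) - 1))
            used = self._used[chrom]
            i = bisect_left(used, pos)
            near = [used[j] for j in (i - 1, i) if 0 <= j < len(used)]
            if all(abs(pos - p) >= self.MIN_SEPARATION_BP for p in near):
                insort(used, pos)
                return chrom, pos
        raise RuntimeError(
            "could not place a further mutation: requested count exceeds available exome sites"
        )


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------


def _bin_copy_numbers(
    genome: GenomeModel, cnvs: Sequence[TruthCnv], region: str
) -> np.ndarray:
    bins = genome.exome_bins
    cn = np.full(len(bins), 2.0)
    wanted = {"both", f"{region}_only"}
    for cnv in cnvs:
        if cnv.region not in wanted:
            continue
        for i, (chrom, start, end) in enumerate(bins):
            if chrom == cnv.chrom and start >= cnv.start and end <= cnv.end:
                cn[i] = cnv.copy_number
    return cn


def simulate_coverage(
    sample_id: str,
    genome: GenomeModel,
    bias: np.ndarray,
    noise: NoiseParams,
    rng: np.random.Generator,
    purity: float = 1.0,
    cnvs: Sequence[TruthCnv] = (),
    region: str = "central",
) -> CoverageProfile:
    """Per-bin read counts for one sample.

    The multiplicative ``bias`` field (capture/library bias) is shared across
    all samples of a cohort.  A bin carrying tumor copy number ``cn`` scales
    the diploid expectation by ``purity * cn/2 + (1 - purity)``.
    """
    bins = genome.exome_bins
    base = noise.mean_depth * genome.bin_bp / READ_LENGTH_BP
    cn = _bin_copy_numbers(genome, cnvs, region) if len(cnvs) else np.full(len(bins), 2.0)
    scale = purity * cn / 2.0 + (1.0 - purity)
    mean = base * bias * scale
    counts = _draw_counts(mean, noise.depth_dispersion, rng)
    return CoverageProfile(sample_id=sample_id, bins=bins, counts=counts)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    genome: GenomeModel | None = None,
    params: CohortParams | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a full multiregion cohort with serialized ground truth.

    Every planted mutation appears in its patient's candidate table (its
    evidence may be sub-threshold under noise); germline polymorphisms are
    planted as decoy candidates and listed in the polymorphism-exclusion set.
    """
    genome = genome or GenomeModel()
    params = params or CohortParams()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    n_sites = params.n_patients * (
        max(params.common_nonsyn) + max(params.common_silent) + 20 + params.indels_per_patient
    ) + params.n_polymorphisms
    if n_sites * _SitePlacer.MIN_SEPARATION_BP > genome.total_bp:
        raise ValueError("requested mutation count exceeds available exome sites")

    placer = _SitePlacer(genome, rng)
    bias = rng.lognormal(mean=0.0, sigma=0.3, size=len(genome.exome_bins))
    bias /= bias.mean()

    # cohort-wide germline polymorphism decoys
    polymorphisms: list[GenomicSite] = []
    for _ in range(params.n_polymorphisms):
        chrom, pos = placer.place()
        ref, alt, _ctx = sample_substitution(params.spectrum, rng)
        polymorphisms.append(GenomicSite(chrom, pos, ref, alt))

    gene_counter = 0
    truth_patients: list[PatientTruth] = []
    patients: list[PatientData] = []

    for pi in range(params.n_patients):
        patient_id = f"P{pi + 1}"
        trio = SampleTrio(patient_id, *params.purities[pi])
        hyper = params.hypermutator_patient == pi
        hyper_spectrum = SpectrumParams.hypermutator()

        planted: list[TruthMutation] = []

        def plant(n: int, clonality: str, consequence_pool, spectrum: SpectrumParams):
            nonlocal gene_counter
            for _ in range(n):
                chrom, pos = placer.place()
                ref, alt, ctx = sample_substitution(spectrum, rng)
                gene_counter += 1
                csq = consequence_pool[rng.integers(len(consequence_pool))]
                planted.append(
                    TruthMutation(
                        GenomicSite(chrom, pos, ref, alt),
                        f"MUT{gene_counter:04d}", csq, clonality, 1.0, ctx,
                    )
                )

        nonsyn_pool = ("missense",) * 17 + ("nonsense",) * 2 + ("splice_site",)
        plant(params.common_nonsyn[pi], "common", nonsyn_pool, params.spectrum)
        plant(params.common_silent[pi], "common", ("silent",), params.spectrum)
        n_c, n_p = params.private_counts[pi]
        plant(n_c, "private_central", nonsyn_pool, params.spectrum)
        plant(n_p, "private_peripheral", nonsyn_pool,
              hyper_spectrum if hyper else params.spectrum)
        # indels as filter-test fixtures (no published indel spectrum)
        for _ in range(params.indels_per_patient):
            chrom, pos = placer.place()
            gene_counter += 1
            ref = "ACGT"[rng.integers(4)]
            ins = "ACGT"[rng.integers(4)]
            planted.append(
                TruthMutation(
                    GenomicSite(chrom, pos, ref, ref + ins),
                    f"MUT{gene_counter:04d}", "frameshift", "common", 1.0, None,
                )
            )

        records: list[MutationRecord] = []
        orthogonal: dict[tuple, dict[str, float]] = {}
        for m in planted:
            evidence: dict[str, SiteEvidence] = {}
            true_af: dict[str, float] = {"normal": 0.0}
            for region in ("central", "peripheral"):
                present = m.clonality in ("common", f"private_{region}")
                evaf = (
                    expected_vaf(trio.purity(region), m.cancer_cell_fraction)
                    if present else 0.0
                )
                true_af[region] = evaf
                evidence[region] = _draw_evidence(noise, rng, evaf)
            evidence["normal"] = _draw_evidence(noise, rng, 0.0)
            records.append(
                MutationRecord(
                    site=m.site, gene=m.gene, consequence=m.consequence,
                    evidence=evidence, trinucleotide_context=m.trinucleotide_context,
                    patient=patient_id,
                )
            )
            orthogonal[m.site.key] = {
                r: simulate_orthogonal_af(true_af[r], noise.pyro_sd, rng)
                for r in ("normal", "central", "peripheral")
            }
        # germline decoys: heterozygous in every sample, purity-independent
        for site in polymorphisms:
            evidence = {r: _draw_evidence(noise, rng, 0.5) for r in REGION_ORDER}
            gene_counter += 1
            records.append(
                MutationRecord(
                    site=site, gene=f"MUT{gene_counter:04d}", consequence="missense",
                    evidence=evidence, patient=patient_id,
                )
            )

        # copy-number truth: shared dup + del for everyone, plus one
        # peripheral-only duplication for the hypermutator patient
        cnvs = [
            TruthCnv("chr1", 10_000_001, 25_000_000, 3, "both"),
            TruthCnv("chr2", 30_000_001, 45_000_000, 1, "both"),
        ]
        if hyper:
            cnvs.append(TruthCnv("chr3", 1, 50_000_000, 3, "peripheral_only"))

        coverage = {
            "normal": simulate_coverage(
                f"{patient_id}_normal", genome, bias, noise, rng, purity=1.0
            ),
        }
        for region in ("central", "peripheral"):
            coverage[region] = simulate_coverage(
                f"{patient_id}_{region}", genome, bias, noise, rng,
                purity=trio.purity(region), cnvs=cnvs, region=region,
            )

        truth_patients.append(PatientTruth(trio, planted, cnvs))
        patients.append(PatientData(trio, records, coverage, orthogonal))

    panel = [
        simulate_coverage(f"REF{j + 1:02d}", genome, bias, noise, rng, purity=1.0)
        for j in range(params.n_reference)
    ]

    return Cohort(
        genome=genome,
        noise=noise,
        params=params,
        seed=seed,
        truth=TruthSet(truth_patients, params.spectrum),
        patients=patients,
        reference_panel=panel,
        polymorphism_sites={s.key for s in polymorphisms},
        exon_intervals=list(genome.exome_bins),
    )


REGION_ORDER = ("normal", "central", "peripheral")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str | Path, cfg_hash: str | None = None) -> Path:
    """Write variant tables, coverage tables, panel, truth and fixtures to disk.

    Output is deterministic given the cohort object, so identical seeds give
    byte-identical directories.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def write_coverage(profile: CoverageProfile, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tcount\n")
            for (chrom, start, end), c in zip(profile.bins, profile.counts):
                fh.write(f"{chrom}\t{start}\t{end}\t{c:.6g}\n")

    manifest: dict[str, object] = {"seed": cohort.seed, "patients": [], "reference_panel": []}
    for pdata in cohort.patients:
        pid = pdata.trio.patient_id
        write_variant_table(pdata.records, outdir / f"{pid}.variants.tsv", "tsv", cfg_hash)
        write_variant_table(pdata.records, outdir / f"{pid}.variants.vcf", "vcf_min", cfg_hash)
        for region, prof in pdata.coverage.items():
            write_coverage(prof, outdir / f"{pid}_{region}.coverage.tsv")
        with open(outdir / f"{pid}.orthogonal_af.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tnormal_af\tcentral_af\tperipheral_af\n")
            for key in sorted(pdata.orthogonal_af):
                af = pdata.orthogonal_af[key]
                fh.write(
                    f"{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t"
                    f"{af['normal']:.6f}\t{af['central']:.6f}\t{af['peripheral']:.6f}\n"
                )
        manifest["patients"].append(pid)
    for prof in cohort.reference_panel:
        write_coverage(prof, outdir / f"{prof.sample_id}.coverage.tsv")
        manifest["reference_panel"].append(prof.sample_id)

    (outdir / "truth.json").write_text(cohort.truth.to_json())
    with open(outdir / "polymorphisms.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(cohort.polymorphism_sites):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    with open(outdir / "exons.bed", "w") as fh:
        for chrom, start, end in cohort.exon_intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def read_coverage_table(path: str | Path, sample_id: str | None = None) -> CoverageProfile:
    """Read a per-bin coverage TSV written by :func:`write_cohort`."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    bins = [(str(c), int(s), int(e)) for c, s, e in zip(df["chrom"], df["start"], df["end"])]
    return CoverageProfile(
        sample_id=sample_id or path.stem.replace(".coverage", ""),
        bins=bins,
        counts=df["count"].to_numpy(dtype=float),
    )
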