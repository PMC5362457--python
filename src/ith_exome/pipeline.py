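"""End-to-end orchestration: simulate -> filter -> classify -> drivers -> cnv -> report.

A run is fully determined by a :class:`RunConfig` (seed included): rerunning
with the same config reproduces byte-identical tabular outputs.  Every stage
writes its artifacts under the run directory, and the final
:class:`CohortReport` is reconciled against those files — no stage-internal
state reaches the report without passing through an artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import cnv_depth_model as cnv
from . import driver_annotation as drv
from .core_model import FilterConfig, config_hash, write_segments
from .heterogeneity_analysis import PresenceRule, classify_patient, summarize_ith
from .somatic_filtering import decisions_table, filter_region
from .synthetic_cohort import (
    Cohort,
    CohortParams,
    GenomeModel,
    NoiseParams,
    simulate_cohort,
    write_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run: seed, scale, thresholds and paths, serializable to YAML."""

    seed: int = 1
    outdir: str = "ith_run"
    filter: FilterConfig = field(default_factory=FilterConfig)
    presence: PresenceRule = field(default_factory=PresenceRule)
    cnv_call: cnv.CnvCallConfig = field(default_factory=cnv.CnvCallConfig)
    genome: GenomeModel = field(default_factory=GenomeModel)
    cohort: CohortParams = field(default_factory=CohortParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @property
    def hash(self) -> str:
        # hash the scientific configuration only: where outputs land (and
        # whether plots are drawn) must not change the provenance of results
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("make_plots", None)
        return config_hash(d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("seed", "outdir", "make_plots"):
            if key in raw:
                kwargs[key] = raw[key]
        if "filter" in raw:
            kwargs["filter"] = FilterConfig(**raw["filter"])
        if "presence" in raw:
            kwargs["presence"] = PresenceRule(**raw["presence"])
        if "cnv_call" in raw:
            kwargs["cnv_call"] = cnv.CnvCallConfig(**raw["cnv_call"])
        if "genome" in raw:
            g = raw["genome"]
            kwargs["genome"] = GenomeModel(
                tuple((str(n), int(l)) for n, l in g["chromosomes"]), int(g["bin_bp"])
            )
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "spectrum" in c:
                from .synthetic_cohort import SpectrumParams

                s = c["spectrum"]
                c["spectrum"] = SpectrumParams(
                    tuple(s["substitution_weights"]), s["cpg_enrichment"], s["hypermutator_mode"]
                )
            for key in ("common_nonsyn", "common_silent"):
                if key in c:
                    c[key] = tuple(c[key])
            for key in ("private_counts", "purities"):
                if key in c:
                    c[key] = tuple(tuple(x) for x in c[key])
            kwargs["cohort"] = CohortParams(**c)
        if "noise" in raw:
            kwargs["noise"] = NoiseParams(**raw["noise"])
        return cls(**kwargs)


@dataclass
class CohortReport:
    """Totals of one run; every number is recomputed from an artifact file."""

    config_hash: str
    n_candidates: int
    n_passed_by_region: dict[str, int]
    clonality_counts: dict[str, int]
    per_sample: list[dict]
    driver_totals: dict
    cnv_ith_intervals: int
    clinical: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def descriptive_stats(clinical: pd.DataFrame, columns: list[str] | None = None) -> dict:
    """Arithmetic mean (half-up, one decimal) and min-max range per numeric column."""
    columns = columns or ["age", "diameter_cm", "distance_cm"]
    out = {}
    for col in columns:
        try:
            # exact decimal arithmetic so e.g. a true mean of 7.05 rounds
            # half-up to 7.1 rather than through a binary-float 7.049...
            values = [Decimal(str(v)) for v in clinical[col]]
        except Exception as exc:
            raise ValueError(f"non-numeric cell in column {col!r}") from exc
        mean = float(
            (sum(values) / len(values)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        )
        out[col] = {"mean": mean, "min": float(min(values)), "max": float(max(values))}
    return out


def load_clinical_fixture() -> pd.DataFrame:
    path = Path(str(resources.files("ith_exome").joinpath("data", "clinical_cohort.tsv")))
    return pd.read_csv(path, sep="\t", comment="#")


def _write_df(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ith-exome config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> CohortReport:
    """Execute every stage on a freshly simulated cohort and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash
    config.to_yaml(outdir / "config.yaml")
    log.info("run %s: thresholds %s", cfg_hash, config.filter.to_dict())

    # --- simulate ---------------------------------------------------------
    try:
        cohort = simulate_cohort(config.genome, config.cohort, config.noise, config.seed)
        write_cohort(cohort, outdir / "cohort", cfg_hash)
    except (ValueError, RuntimeError) as exc:
        raise StageError("simulate", str(exc)) from exc

    # --- filter -----------------------------------------------------------
    decisions = {}
    try:
        frames = []
        for pdata in cohort.patients:
            for region in ("central", "peripheral"):
                decs = filter_region(
                    pdata.records, region, config.filter,
                    cohort.polymorphism_sites, cohort.exon_intervals,
                )
                decisions[(pdata.trio.patient_id, region)] = decs
                frames.append(decisions_table(decs))
        (outdir / "filter").mkdir(exist_ok=True)
        _write_df(pd.concat(frames, ignore_index=True), outdir / "filter" / "decisions.tsv", cfg_hash)
    except ValueError as exc:
        raise StageError("filter", str(exc)) from exc

    # --- classify ---------------------------------------------------------
    try:
        calls_by_patient = {}
        for pdata in cohort.patients:
            pid = pdata.trio.patient_id
            calls_by_patient[pid] = classify_patient(
                decisions[(pid, "central")],
                decisions[(pid, "peripheral")],
                pdata.orthogonal_af,
                config.presence,
            )
        summary = summarize_ith(calls_by_patient)
        (outdir / "classify").mkdir(exist_ok=True)
        clonality_rows = [
            {
                "patient": pid,
                "chrom": c.record.site.chrom,
                "pos": c.record.site.pos,
                "ref": c.record.site.ref,
                "alt": c.record.site.alt,
                "gene": c.record.gene,
                "consequence": c.record.consequence,
                "label": c.label,
                "confirmation": c.confirmation,
            }
            for pid, calls in calls_by_patient.items()
            for c in calls
        ]
        clonality_df = pd.DataFrame(clonality_rows)
        _write_df(clonality_df, outdir / "classify" / "clonality.tsv", cfg_hash)
        _write_df(summary.per_sample, outdir / "classify" / "ith_summary.tsv", cfg_hash)
        _write_df(summary.spectrum, outdir / "classify" / "spectrum.tsv", cfg_hash)
        _write_df(summary.cpg, outdir / "classify" / "cpg.tsv", cfg_hash)
    except ValueError as exc:
        raise StageError("classify", str(exc)) from exc

    # --- drivers ----------------------------------------------------------
    try:
        kb = drv.load_default_kb()
        driver_calls = []
        for pid, calls in calls_by_patient.items():
            for call in calls:
                if not call.record.is_nonsynonymous:
                    continue
                rec = call.record
                rec.clonality = call.label
                driver_calls.append(drv.categorize(rec, kb))
        driver_calls = drv.flag_manual_review(driver_calls)
        driver_summary = drv.summarize_drivers(driver_calls)
        (outdir / "drivers").mkdir(exist_ok=True)
        _write_df(driver_summary.table, outdir / "drivers" / "driver_calls.tsv", cfg_hash)
    except ValueError as exc:
        raise StageError("drivers", str(exc)) from exc

    # --- cnv --------------------------------------------------------------
    try:
        model = cnv.build_reference_model(cohort.reference_panel)
        (outdir / "cnv").mkdir(exist_ok=True)
        ith_frames = []
        for pdata in cohort.patients:
            pid = pdata.trio.patient_id
            segments = {}
            profiles = {}
            for region in ("normal", "central", "peripheral"):
                prof = cnv.deviation_profile(pdata.coverage[region], model)
                profiles[region] = prof
                content = 1.0 if region == "normal" else pdata.trio.purity(region)
                segs = cnv.call_regions(prof, model, content, config.cnv_call)
                segments[region] = segs
                write_segments(segs, outdir / "cnv" / f"{pid}_{region}", cfg_hash)
            ith = cnv.compare_regions(
                segments["central"], segments["peripheral"], model.bins
            )
            ith.insert(0, "patient", pid)
            ith_frames.append(ith)
            if config.make_plots:
                cnv.plot_patient_overlay(
                    profiles, outdir / "cnv" / f"{pid}_overlay.png", title=pid
                )
        non_empty = [f for f in ith_frames if len(f)]
        ith_report = (
            pd.concat(non_empty, ignore_index=True) if non_empty else ith_frames[0]
        )
        _write_df(ith_report, outdir / "cnv" / "ith_report.tsv", cfg_hash)
    except ValueError as exc:
        raise StageError("cnv", str(exc)) from exc

    # --- report (recomputed from artifacts) -------------------------------
    decisions_df = pd.read_csv(outdir / "filter" / "decisions.tsv", sep="\t", comment="#")
    clonality_df = pd.read_csv(outdir / "classify" / "clonality.tsv", sep="\t", comment="#")
    per_sample_df = pd.read_csv(outdir / "classify" / "ith_summary.tsv", sep="\t", comment="#")
    drivers_df = pd.read_csv(outdir / "drivers" / "driver_calls.tsv", sep="\t", comment="#")
    ith_df = pd.read_csv(outdir / "cnv" / "ith_report.tsv", sep="\t", comment="#")
    report = CohortReport(
        config_hash=cfg_hash,
        n_candidates=int(len(decisions_df) / 2),
        n_passed_by_region={
            region: int((decisions_df[decisions_df["region"] == region]["passed"]).sum())
            for region in ("central", "peripheral")
        },
        clonality_counts=clonality_df["label"].value_counts().to_dict(),
        per_sample=per_sample_df.to_dict(orient="records"),
        driver_totals={
            "n_potential_drivers": int(len(drivers_df)),
            "per_patient": drivers_df.groupby("patient").size().to_dict()
            if len(drivers_df) else {},
        },
        cnv_ith_intervals=int(len(ith_df)),
        clinical=descriptive_stats(load_clinical_fixture()),
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
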