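"""Read-depth CNV calling against a panel-of-normals coverage model.

The method: (1) scale every reference profile to a common total read count and
learn a per-bin expected coverage mean and SD — the panel absorbs capture,
GC, library and inter-sample biases; (2) express a test sample's normalized
coverage as percent deviation from the expected mean; (3) call maximal runs of
bins deviating by at least 2 SD whose mean deviation is concordant with a
biologically possible copy state.  In pure material a heterozygous duplication
sits at +50% and a heterozygous deletion at -50%; in a tumor of purity t the
expectation scales linearly, 100 * t * (cn - 2) / 2, so at 60% tumor content a
heterozygous duplication appears as +30% while an observed +20% is ambiguous
between a subclonal tumor duplication and a duplication of the admixed
non-tumor tissue.  Germline calling is the same procedure at tumor content 1.

A 5-Mb tumbling-window median smoother is provided for presentation only;
calling always operates on the unsmoothed per-bin deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import CnvInterpretation, CnvSegment
from .synthetic_cohort import CoverageProfile

log = logging.getLogger(__name__)

COPY_STATES = {0: "hom_del", 1: "het_del", 3: "het_dup", 4: "hom_dup"}
_STATE_GRID = (0, 1, 2, 3, 4)


def expected_deviation(copy_number: int, tumor_content: float) -> float:
    """Percent coverage deviation of a clonal copy state at a given tumor content.

    100 * tumor_content * (copy_number - 2) / 2: +50% for a heterozygous
    duplication in pure material, +30% at 60% tumor content, 0% for diploid.
    Linear in tumor content and odd around copy number 2.
    """
    if copy_number not in _STATE_GRID:
        raise ValueError(f"copy_number must be in {_STATE_GRID}, got {copy_number}")
    if not 0 < tumor_content <= 1:
        raise ValueError(f"tumor_content must be in (0, 1], got {tumor_content}")
    return 100.0 * tumor_content * (copy_number - 2) / 2.0


@dataclass
class ReferenceCoverageModel:
    """Per-bin expected normalized coverage (mean, SD) from >= 10 reference samples."""

    bins: list[tuple[str, int, int]]
    expected_mean: np.ndarray
    expected_sd: np.ndarray
    mask: np.ndarray  # True = usable bin
    n_reference: int

    def __post_init__(self) -> None:
        if self.n_reference < 10:
            raise ValueError("reference panel must contain at least 10 samples")
        if (self.expected_sd[self.mask] <= 0).any():
            raise ValueError("usable bins must have positive expected SD")


def _normalize(profile: CoverageProfile) -> np.ndarray:
    """Scale counts so a sample's mean usable bin is ~1 (total-count correction)."""
    total = profile.total
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id} has zero total coverage")
    return profile.counts / total * len(profile.counts)


def build_reference_model(panel: Sequence[CoverageProfile]) -> ReferenceCoverageModel:
    """Learn per-bin expected coverage from a reference panel.

    Hard errors: fewer than 10 samples, or tiling mismatch across the panel.
    Bins with degenerate panel statistics (zero SD, e.g. an identical-profile
    panel, or near-zero mean coverage) are masked with a warning.
    """
    if len(panel) < 10:
        raise ValueError(
            f"reference panel must contain at least 10 samples, got {len(panel)}"
        )
    bins = panel[0].bins
    for profile in panel[1:]:
        if profile.bins != bins:
            raise ValueError(
                f"coverage tiling of {profile.sample_id} does not match the panel"
            )
    matrix = np.vstack([_normalize(p) for p in panel])
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    floor = 0.05 * np.median(mean[mean > 0]) if (mean > 0).any() else 0.0
    mask = (mean > floor) & (sd > 0)
    n_degenerate = int(((sd <= 0) & (mean > floor)).sum())
    if n_degenerate:
        log.warning(
            "degenerate panel: %d bins have zero inter-sample SD and were masked",
            n_degenerate,
        )
    return ReferenceCoverageModel(
        bins=list(bins), expected_mean=mean, expected_sd=sd,
        mask=mask, n_reference=len(panel),
    )


@dataclass
class DeviationProfile:
    """Per-bin percent deviation from expected coverage, with panel z-scores."""

    sample_id: str
    bins: list[tuple[str, int, int]]
    deviation_pct: np.ndarray  # NaN on masked bins
    z: np.ndarray              # NaN on masked bins


def deviation_profile(
    sample: CoverageProfile, model: ReferenceCoverageModel
) -> DeviationProfile:
    """Percent deviation 100*(normalized/expected - 1) per bin; masked bins are NaN.

    After total-count scaling the profile is recentred so the genome-wide
    MEDIAN ratio to the expected coverage is 1.  Total count alone is
    confounded by the aberrant fraction itself (a tumor gaining 50 Mb drags
    every diploid bin below the panel mean); the median ratio is robust as
    long as most of the exome is copy-neutral.  Both steps leave the profile
    invariant to uniform scaling of the sample's counts.
    """
    if sample.bins != model.bins:
        raise ValueError(f"sample {sample.sample_id} is not on the model tiling")
    norm = _normalize(sample)
    m = model.mask
    median_ratio = float(np.median(norm[m] / model.expected_mean[m]))
    if median_ratio <= 0:
        raise ValueError(f"sample {sample.sample_id} has degenerate coverage")
    norm = norm / median_ratio
    # second pass: the median itself is pulled by the aberrant fraction (a
    # third of the genome gained shifts it ~0.7 noise-SD); re-estimate the
    # scale from bins that look copy-neutral after the first pass
    z0 = np.abs(norm[m] - model.expected_mean[m]) / model.expected_sd[m]
    neutral = z0 < 3.0
    if neutral.sum() >= 30:
        refined = float(np.mean(norm[m][neutral] / model.expected_mean[m][neutral]))
        if refined > 0:
            norm = norm / refined
    dev = np.full(len(norm), np.nan)
    z = np.full(len(norm), np.nan)
    dev[m] = 100.0 * (norm[m] / model.expected_mean[m] - 1.0)
    z[m] = (norm[m] - model.expected_mean[m]) / model.expected_sd[m]
    return DeviationProfile(sample.sample_id, list(model.bins), dev, z)


@dataclass(frozen=True)
class CnvCallConfig:
    min_sd: float = 2.0
    min_bins: int = 5
    concordance_tol_pct: float | None = None  # None: max(10, min_sd * 100 * SD/mean)

    def __post_init__(self) -> None:
        if self.min_sd <= 0 or self.min_bins < 1:
            raise ValueError("min_sd must be > 0 and min_bins >= 1")


def _segment_tolerance(
    model: ReferenceCoverageModel, idx: np.ndarray, config: CnvCallConfig
) -> float:
    if config.concordance_tol_pct is not None:
        return config.concordance_tol_pct
    rel_sd = np.median(model.expected_sd[idx] / model.expected_mean[idx])
    return max(10.0, config.min_sd * 100.0 * float(rel_sd))


def _interpret(mean_dev: float, tumor_content: float, tol: float):
    """Enumerate copy states compatible with a segment's mean deviation."""
    interpretations: list[CnvInterpretation] = []
    clonal_matches: list[int] = []
    for cn in _STATE_GRID:
        if cn == 2:
            continue
        exp_clonal = expected_deviation(cn, tumor_content)
        if abs(mean_dev - exp_clonal) < tol:
            clonal_matches.append(cn)
            interpretations.append(
                CnvInterpretation(cn, tumor_content, exp_clonal, "clonal_tumor")
            )
        # cell fraction at which this state would produce the observed deviation
        f_implied = mean_dev / (100.0 * (cn - 2) / 2.0)
        if 0 < f_implied <= 1 and f_implied < tumor_content and cn not in clonal_matches:
            interpretations.append(
                CnvInterpretation(cn, round(f_implied, 4), mean_dev, "subclonal_tumor")
            )
            if f_implied <= (1.0 - tumor_content) + 1e-9:
                interpretations.append(
                    CnvInterpretation(cn, round(f_implied, 4), mean_dev, "non_tumor")
                )
    if not interpretations:
        # out-of-grid amplitude: report the nearest grid state at clipped fraction
        nearest = min(
            (cn for cn in _STATE_GRID if cn != 2),
            key=lambda cn: abs(mean_dev - expected_deviation(cn, tumor_content)),
        )
        interpretations.append(
            CnvInterpretation(
                nearest, tumor_content, expected_deviation(nearest, tumor_content),
                "nearest_state",
            )
        )
        clonal_matches = []
    # a unique clonal fit wins; subclonal/non-tumor alternatives stay listed as
    # interpretations but only demote the call when no clonal state fits
    call = COPY_STATES[clonal_matches[0]] if len(clonal_matches) == 1 else "ambiguous"
    return call, tuple(interpretations)


def interpret_deviation(
    mean_dev: float, tumor_content: float, tol: float = 10.0
) -> tuple[str, tuple[CnvInterpretation, ...]]:
    """Classify a single observed percent deviation (the worked-example entry point)."""
    if not 0 < tumor_content <= 1:
        raise ValueError("tumor_content must be in (0, 1]")
    return _interpret(mean_dev, tumor_content, tol)


def call_regions(
    profile: DeviationProfile,
    model: ReferenceCoverageModel,
    tumor_content: float | None,
    config: CnvCallConfig | None = None,
) -> list[CnvSegment]:
    """Call CNV segments: maximal same-sign runs of >= min_bins bins at >= min_sd SD.

    ``tumor_content`` must be supplied for tumor samples (use 1.0 for germline
    calling); each segment's call is the copy state whose clonal expectation
    matches the segment mean deviation within the concordance tolerance, or
    ``ambiguous`` with all feasible interpretations listed.
    """
    if tumor_content is None:
        raise ValueError("tumor_content must be set for CNV calling (1.0 for germline)")
    if not 0 < tumor_content <= 1:
        raise ValueError("tumor_content must be in (0, 1]")
    config = config or CnvCallConfig()
    z = profile.z
    candidate = np.isfinite(z) & (np.abs(z) >= config.min_sd)
    segments: list[CnvSegment] = []
    i, n = 0, len(z)
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        sign = np.sign(z[i])
        chrom = profile.bins[i][0]
        j = i
        while (
            j + 1 < n
            and candidate[j + 1]
            and np.sign(z[j + 1]) == sign
            and profile.bins[j + 1][0] == chrom
        ):
            j += 1
        if j - i + 1 >= config.min_bins:
            idx = np.arange(i, j + 1)
            mean_dev = float(np.nanmean(profile.deviation_pct[idx]))
            tol = _segment_tolerance(model, idx, config)
            call, interpretations = _interpret(mean_dev, tumor_content, tol)
            segments.append(
                CnvSegment(
                    chrom=chrom,
                    start=profile.bins[i][1],
                    end=profile.bins[j][2],
                    mean_deviation_pct=mean_dev,
                    call=call,
                    interpretations=interpretations,
                    n_bins=int(j - i + 1),
                    sample_id=profile.sample_id,
                )
            )
        i = j + 1
    return segments


def smooth_median(
    profile: DeviationProfile, window_mb: float = 5.0
) -> pd.DataFrame:
    """Median deviation over non-overlapping (tumbling) windows, per chromosome.

    Presentation-only smoothing: each window's value is the median of its
    non-masked bin deviations (NaN when a window holds no data).
    """
    window_bp = int(window_mb * 1_000_000)
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for idx, (chrom, _, _) in enumerate(profile.bins):
        by_chrom.setdefault(chrom, []).append(idx)
    for chrom, indices in by_chrom.items():
        last_end = max(profile.bins[i][2] for i in indices)
        for wstart in range(1, last_end + 1, window_bp):
            wend = min(wstart + window_bp - 1, last_end)
            values = [
                profile.deviation_pct[i]
                for i in indices
                if wstart <= profile.bins[i][1] <= wend
                and math.isfinite(profile.deviation_pct[i])
            ]
            rows.append(
                {
                    "chrom": chrom,
                    "start": wstart,
                    "end": wend,
                    "median_deviation_pct": float(np.median(values)) if values else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "median_deviation_pct"])


def compare_regions(
    central_segments: Sequence[CnvSegment],
    peripheral_segments: Sequence[CnvSegment],
    bins: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Flag intervals where the two tumor regions' copy-number calls disagree.

    Both segment sets must be called against the same model/tiling.  Each
    discordant interval reports both calls and deviations; disagreement
    involving an ambiguous call is flagged ``discordant_with_ambiguity``.
    """

    def per_bin(segments: Sequence[CnvSegment]):
        calls = ["none"] * len(bins)
        devs = [float("nan")] * len(bins)
        for seg in segments:
            for i, (chrom, start, end) in enumerate(bins):
                if chrom == seg.chrom and start >= seg.start and end <= seg.end:
                    calls[i] = seg.call
                    devs[i] = seg.mean_deviation_pct
        return calls, devs

    for seg in list(central_segments) + list(peripheral_segments):
        covered = any(
            b[0] == seg.chrom and b[1] >= seg.start and b[2] <= seg.end for b in bins
        )
        if not covered:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} does not match the shared tiling"
            )

    c_calls, c_devs = per_bin(central_segments)
    p_calls, p_devs = per_bin(peripheral_segments)
    rows = []
    i, n = 0, len(bins)
    while i < n:
        if c_calls[i] == p_calls[i]:
            i += 1
            continue
        chrom = bins[i][0]
        j = i
        while (
            j + 1 < n
            and bins[j + 1][0] == chrom
            and c_calls[j + 1] != p_calls[j + 1]
            and (c_calls[j + 1], p_calls[j + 1]) == (c_calls[i], p_calls[i])
        ):
            j += 1
        flag = (
            "discordant_with_ambiguity"
            if "ambiguous" in (c_calls[i], p_calls[i])
            else "discordant"
        )
        rows.append(
            {
                "chrom": chrom,
                "start": bins[i][1],
                "end": bins[j][2],
                "central_call": c_calls[i],
                "peripheral_call": p_calls[i],
                "central_deviation_pct": c_devs[i],
                "peripheral_deviation_pct": p_devs[i],
                "flag": flag,
            }
        )
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "central_call", "peripheral_call",
            "central_deviation_pct", "peripheral_deviation_pct", "flag",
        ],
    )


def plot_patient_overlay(
    profiles: Mapping[str, DeviationProfile],
    out_path,
    window_mb: float = 5.0,
    title: str | None = None,
) -> None:
    """Three-sample (normal/central/peripheral) smoothed-deviation overlay plot
    with +/-50% guide lines, one panel per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"normal": "black", "central": "red", "peripheral": "blue"}
    chroms = list(dict.fromkeys(c for c, _, _ in next(iter(profiles.values())).bins))
    fig, axes = plt.subplots(1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True)
    if len(chroms) == 1:
        axes = [axes]
    for region, profile in profiles.items():
        smoothed = smooth_median(profile, window_mb)
        for ax, chrom in zip(axes, chroms):
            sub = smoothed[smoothed["chrom"] == chrom]
            ax.step(
                sub["start"] / 1e6, sub["median_deviation_pct"], where="post",
                color=colors.get(region, "grey"), label=region, lw=1,
            )
    for ax, chrom in zip(axes, chroms):
        ax.axhline(50, ls=":", c="grey")
        ax.axhline(-50, ls=":", c="grey")
        ax.set_xlabel(f"{chrom} (Mb)")
    axes[0].set_ylabel("deviation from expected coverage (%)")
    axes[0].legend(loc="upper right", fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
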