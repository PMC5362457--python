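"""Panel model building, deviation closed forms, segment calling, smoothing,
and center-vs-periphery comparison."""

import numpy as np
import pandas as pd
import pytest

from ith_exome.cnv_depth_model import (
    CnvCallConfig,
    build_reference_model,
    call_regions,
    compare_regions,
    deviation_profile,
    expected_deviation,
    interpret_deviation,
    smooth_median,
)
from ith_exome.synthetic_cohort import (
    CoverageProfile,
    GenomeModel,
    NoiseParams,
    TruthCnv,
    simulate_coverage,
)

GENOME = GenomeModel(chromosomes=(("chr1", 30_000_000),), bin_bp=100_000)
NOISELESS = NoiseParams(depth_dispersion=0.0, sequencing_error_rate=0.0)


def make_panel(rng, n=10, genome=GENOME, noise=None, bias=None):
    noise = noise or NoiseParams()
    if bias is None:
        bias = rng.lognormal(0, 0.3, size=len(genome.exome_bins))
    return bias, [
        simulate_coverage(f"R{i}", genome, bias, noise, rng) for i in range(n)
    ]


class TestExpectedDeviation:
    @pytest.mark.parametrize(
        "cn,tc,want",
        [(3, 1.0, 50.0), (1, 1.0, -50.0), (3, 0.6, 30.0), (2, 0.37, 0.0), (4, 0.5, 50.0)],
    )
    def test_closed_form(self, cn, tc, want):
        assert expected_deviation(cn, tc) == pytest.approx(want)

    def test_linear_in_tumor_content_and_odd_around_diploid(self):
        for tc in (0.2, 0.5, 1.0):
            assert expected_deviation(3, tc) == -expected_deviation(1, tc)
            assert expected_deviation(4, tc) == 2 * expected_deviation(3, tc)

    @pytest.mark.parametrize("cn,tc", [(5, 0.5), (-1, 0.5), (3, 0.0), (3, 1.5)])
    def test_out_of_range_inputs_rejected(self, cn, tc):
        with pytest.raises(ValueError):
            expected_deviation(cn, tc)


class TestReferenceModel:
    def test_panel_of_9_is_hard_error(self, rng):
        _, panel = make_panel(rng, n=9)
        with pytest.raises(ValueError, match="at least 10"):
            build_reference_model(panel)

    def test_tiling_mismatch_is_hard_error(self, rng):
        _, panel = make_panel(rng)
        other = GenomeModel(chromosomes=(("chr1", 20_000_000),), bin_bp=100_000)
        panel[3] = simulate_coverage("odd", other, np.ones(len(other.exome_bins)),
                                     NoiseParams(), rng)
        with pytest.raises(ValueError, match="tiling"):
            build_reference_model(panel)

    def test_identical_profiles_masked_as_degenerate(self, rng):
        bias = np.ones(len(GENOME.exome_bins))
        profile = simulate_coverage("r", GENOME, bias, NOISELESS, rng)
        panel = [CoverageProfile(f"R{i}", profile.bins, profile.counts.copy())
                 for i in range(10)]
        model = build_reference_model(panel)
        assert not model.mask.any()

    def test_expected_mean_proportional_to_bias(self, rng):
        bias = rng.lognormal(0, 0.3, size=len(GENOME.exome_bins))
        panel = [simulate_coverage(f"R{i}", GENOME, bias, NoiseParams(), rng)
                 for i in range(12)]
        model = build_reference_model(panel)
        ratio = model.expected_mean / bias
        assert np.nanstd(ratio) / np.nanmean(ratio) < 0.02


class TestDeviationProfile:
    def test_diploid_noise_free_deviations_are_zero(self, rng):
        bias, panel = make_panel(rng, noise=NoiseParams())
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NOISELESS, rng)
        prof = deviation_profile(sample, model)
        # the panel still has sampling noise; the noise-free sample should sit
        # within a fraction of a percent of the panel mean everywhere
        assert np.nanmax(np.abs(prof.deviation_pct)) < 5.0
        assert abs(np.nanmedian(prof.deviation_pct)) < 0.5

    def test_bin_at_1p5x_expected_reads_plus_50pct(self, rng):
        bias = np.ones(len(GENOME.exome_bins))
        base = simulate_coverage("r", GENOME, bias, NOISELESS, rng)
        panel = []
        for i in range(10):
            counts = base.counts.copy()
            # break exact degeneracy with a tiny alternating perturbation
            counts[i % len(counts)] *= 1.001
            panel.append(CoverageProfile(f"R{i}", base.bins, counts))
        model = build_reference_model(panel)
        counts = base.counts.copy()
        counts[7] *= 1.5
        prof = deviation_profile(CoverageProfile("s", base.bins, counts), model)
        assert prof.deviation_pct[7] == pytest.approx(50.0, abs=1.0)

    def test_invariant_to_uniform_scaling(self, rng):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NoiseParams(), rng)
        scaled = CoverageProfile("s2", sample.bins, sample.counts * 3.7)
        np.testing.assert_allclose(
            deviation_profile(sample, model).deviation_pct,
            deviation_profile(scaled, model).deviation_pct,
        )


class TestInterpretDeviation:
    def test_plus30_at_60pct_content_is_het_dup(self):
        call, interp = interpret_deviation(30.0, 0.6)
        assert call == "het_dup"
        clonal = [i for i in interp if i.label == "clonal_tumor"]
        assert [i.copy_number for i in clonal] == [3]

    def test_plus20_at_60pct_content_is_ambiguous_with_both_readings(self):
        call, interp = interpret_deviation(20.0, 0.6)
        assert call == "ambiguous"
        labels = {(i.copy_number, i.label) for i in interp}
        # a subclonal duplication in the tumor or a duplication of the
        # admixed non-tumor tissue, both at cell fraction 0.4
        assert (3, "subclonal_tumor") in labels
        assert (3, "non_tumor") in labels

    def test_germline_minus50_is_het_del(self):
        call, _ = interpret_deviation(-50.0, 1.0)
        assert call == "het_del"


class TestCallRegions:
    def test_planted_het_dup_recovered_at_60pct_purity(self, rng):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        cnv = TruthCnv("chr1", 10_000_001, 20_000_000, 3, "both")
        sample = simulate_coverage("t", GENOME, bias, NoiseParams(), rng,
                                   purity=0.6, cnvs=[cnv])
        segs = call_regions(deviation_profile(sample, model), model, 0.6)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.call == "het_dup"
        assert seg.mean_deviation_pct == pytest.approx(30.0, abs=3.0)
        assert abs(seg.start - cnv.start) <= GENOME.bin_bp
        assert abs(seg.end - cnv.end) <= GENOME.bin_bp

    def test_diploid_noise_free_sample_yields_zero_segments(self, rng):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NOISELESS, rng)
        assert call_regions(deviation_profile(sample, model), model, 1.0) == []

    def test_tumor_content_required(self, rng):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NoiseParams(), rng)
        with pytest.raises(ValueError, match="tumor_content"):
            call_regions(deviation_profile(sample, model), model, None)

    def test_run_length_requirement_suppresses_isolated_outliers(self, rng):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NoiseParams(), rng)
        sample.counts[50] *= 1.6  # one spiked bin only
        segs = call_regions(deviation_profile(sample, model), model, 1.0)
        assert segs == []

    def test_germline_false_positive_rate_under_2sd_threshold(self, rng):
        """Per-bin |z| >= 2 exceedance for a panel-like sample is near the
        Gaussian expectation; the 5-bin run requirement kills segments."""
        bias, panel = make_panel(rng, n=30)
        model = build_reference_model(panel[:10])
        exceed = total = 0
        n_segments = 0
        for sample in panel[10:]:
            prof = deviation_profile(sample, model)
            z = prof.z[np.isfinite(prof.z)]
            exceed += (np.abs(z) >= 2).sum()
            total += z.size
            n_segments += len(call_regions(prof, model, 1.0))
        rate = exceed / total
        assert 0.005 < rate < 0.15  # loose band around the ~5% Gaussian tail
        assert n_segments == 0


class TestSmoothing:
    def test_constant_profile_stays_constant(self, rng):
        bias = np.ones(len(GENOME.exome_bins))
        panel = [simulate_coverage(f"R{i}", GENOME, bias, NoiseParams(), rng)
                 for i in range(10)]
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NOISELESS, rng)
        prof = deviation_profile(sample, model)
        prof.deviation_pct[:] = 7.0
        smoothed = smooth_median(prof)
        assert (smoothed["median_deviation_pct"] == 7.0).all()

    def test_median_removes_single_bin_spike(self, rng):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NOISELESS, rng)
        prof = deviation_profile(sample, model)
        prof.deviation_pct[:] = 0.0
        prof.deviation_pct[10] = 80.0
        smoothed = smooth_median(prof)
        assert np.nanmax(np.abs(smoothed["median_deviation_pct"])) < 1e-9

    def test_matches_brute_force_window_medians(self, rng):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        sample = simulate_coverage("s", GENOME, bias, NoiseParams(), rng)
        prof = deviation_profile(sample, model)
        smoothed = smooth_median(prof, window_mb=5)
        for row in smoothed.itertuples(index=False):
            values = [
                d for (c, s, e), d in zip(prof.bins, prof.deviation_pct)
                if c == row.chrom and row.start <= s <= row.end and np.isfinite(d)
            ]
            if values:
                assert row.median_deviation_pct == pytest.approx(np.median(values))
            else:
                assert np.isnan(row.median_deviation_pct)


class TestCompareRegions:
    def _segments_for(self, rng, cnvs_by_region, purity=0.6):
        bias, panel = make_panel(rng)
        model = build_reference_model(panel)
        segs = {}
        for region, cnvs in cnvs_by_region.items():
            sample = simulate_coverage(f"{region}", GENOME, bias, NoiseParams(), rng,
                                       purity=purity, cnvs=cnvs, region=region)
            segs[region] = call_regions(deviation_profile(sample, model), model, purity)
        return model, segs

    def test_identical_calls_give_empty_report(self, rng):
        shared = [TruthCnv("chr1", 10_000_001, 20_000_000, 3, "both")]
        model, segs = self._segments_for(
            rng, {"central": shared, "peripheral": shared}
        )
        report = compare_regions(segs["central"], segs["peripheral"], model.bins)
        # at most a single edge bin of breakpoint wobble may differ
        assert report.empty or (report["end"] - report["start"] <= GENOME.bin_bp).all()

    def test_peripheral_only_dup_flagged_with_90pct_overlap(self, rng):
        # the event must stay a minority of the genome: depth-only
        # normalization takes the majority copy state as its baseline
        planted = TruthCnv("chr1", 5_000_001, 13_000_000, 3, "peripheral_only")
        model, segs = self._segments_for(
            rng, {"central": [], "peripheral": [planted]}
        )
        report = compare_regions(segs["central"], segs["peripheral"], model.bins)
        flagged = report[report["peripheral_call"] == "het_dup"]
        overlap = 0
        for row in flagged.itertuples(index=False):
            overlap += max(
                0, min(row.end, planted.end) - max(row.start, planted.start) + 1
            )
        assert overlap >= 0.9 * (planted.end - planted.start + 1)

    def test_ambiguity_in_one_region_flagged_distinctly(self):
        from ith_exome.core_model import CnvInterpretation, CnvSegment

        interp = (CnvInterpretation(3, 0.4, 20.0, "subclonal_tumor"),)
        central = [CnvSegment("chr1", 1, 1_000_000, 30.0, "het_dup",
                              (CnvInterpretation(3, 0.6, 30.0, "clonal_tumor"),))]
        peripheral = [CnvSegment("chr1", 1, 1_000_000, 20.0, "ambiguous", interp)]
        bins = [("chr1", s, s + 99_999) for s in range(1, 1_000_000, 100_000)]
        report = compare_regions(central, peripheral, bins)
        assert (report["flag"] == "discordant_with_ambiguity").all()
        assert len(report) == 1
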