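"""Filter cascade: published boundary values, brute-force oracle equivalence,
window-rule enumeration, and threshold monotonicity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ith_exome.core_model import FilterConfig, GenomicSite, SiteEvidence
from ith_exome.somatic_filtering import (
    Neighborhood,
    apply_window_rule,
    exclude_polymorphisms,
    filter_indel,
    filter_region,
    filter_snv,
    restrict_to_exonic,
)

from conftest import make_record

CFG = FilterConfig()


def brute_force_snv_reasons(tumor, normal, indel_dists, window_counts, cfg=CFG):
    """Independent re-statement of the seven SNV cut-offs, rule by rule.

    ``indel_dists``: distances to candidate indels on the chromosome;
    ``window_counts``: for every 10-bp window containing the site, how many
    candidate SNVs it holds (site included).
    """
    reasons = []
    if tumor.mapping_quality < cfg.snv_min_mapq:
        reasons.append("MAPQ")
    if (tumor.var_reads / tumor.depth if tumor.depth else 0.0) < cfg.snv_min_tumor_vaf:
        reasons.append("VAF")
    if tumor.depth < cfg.snv_min_depth or normal.depth < cfg.snv_min_depth:
        reasons.append("DEPTH")
    if tumor.var_reads < cfg.snv_min_tumor_var_reads:
        reasons.append("TUMOR_VAR")
    if normal.var_reads > cfg.snv_max_normal_var_reads:
        reasons.append("NORMAL_VAR")
    if any(d <= cfg.snv_indel_exclusion_bp for d in indel_dists):
        reasons.append("NEAR_INDEL")
    if any(c > cfg.snv_window_max for c in window_counts):
        reasons.append("WINDOW")
    return reasons


class TestSnvCutoffs:
    def test_boundary_values_all_inclusive_pass(self):
        # exactly at every published threshold: vaf 5%, mapq 20, depths 10,
        # 2 tumor / 1 normal variant reads
        rec = make_record(
            normal=(10, 1, 20.0), central=(100, 5, 20.0), peripheral=None
        )
        decision = filter_snv(rec, "central", CFG)
        assert decision.passed and decision.reasons == ()

    @pytest.mark.parametrize(
        "normal,central,reason",
        [
            ((50, 1, 60.0), (100, 4, 60.0), "VAF"),          # 4% is below >=5%
            ((50, 1, 60.0), (100, 30, 19.9), "MAPQ"),
            ((9, 0, 60.0), (100, 30, 60.0), "DEPTH"),        # normal side too
            ((50, 1, 60.0), (9, 3, 60.0), "DEPTH"),
            ((50, 1, 60.0), (80, 1, 60.0), "TUMOR_VAR"),
            ((50, 2, 60.0), (100, 30, 60.0), "NORMAL_VAR"),
        ],
    )
    def test_single_rule_failures(self, normal, central, reason):
        rec = make_record(normal=normal, central=central, peripheral=None)
        assert reason in filter_snv(rec, "central", CFG).reasons

    def test_all_reasons_accumulate_without_short_circuit(self):
        rec = make_record(normal=(5, 3, 60.0), central=(8, 0, 10.0), peripheral=None)
        reasons = set(filter_snv(rec, "central", CFG).reasons)
        assert {"MAPQ", "VAF", "DEPTH", "TUMOR_VAR", "NORMAL_VAR"} <= reasons

    def test_missing_normal_evidence_is_hard_error(self):
        rec = make_record(normal=None)
        with pytest.raises(ValueError, match="undecidable"):
            filter_snv(rec, "central", CFG)

    @pytest.mark.parametrize("distance,flagged", [(5, True), (6, False)])
    def test_indel_exclusion_zone_is_5bp_inclusive(self, distance, flagged):
        snv = make_record(pos=1000)
        indel = make_record(pos=1000 + distance, ref="A", alt="AT",
                            consequence="frameshift")
        hood = Neighborhood.from_records([snv, indel], CFG)
        reasons = filter_snv(snv, "central", CFG, hood).reasons
        assert ("NEAR_INDEL" in reasons) is flagged


class TestWindowRule:
    @pytest.mark.parametrize(
        "positions,flagged",
        [
            ([100, 105, 109], {100, 105, 109}),  # window 100-109 holds 3
            ([100, 105, 110], set()),            # no 10-bp window holds 3
            ([42], set()),
            ([100, 101, 102, 200, 201], {100, 101, 102}),
        ],
    )
    def test_known_configurations(self, positions, flagged):
        assert apply_window_rule(positions) == flagged

    @given(st.lists(st.integers(1, 120), min_size=0, max_size=25, unique=True))
    @settings(max_examples=200, derandomize=True)
    def test_matches_exhaustive_window_enumeration(self, positions):
        positions = sorted(positions)
        expected = set()
        if positions:
            for start in range(min(positions), max(positions) + 1):
                inside = [p for p in positions if start <= p <= start + 9]
                if len(inside) > 2:
                    expected.update(inside)
        assert apply_window_rule(positions) == expected


class TestIndelFilter:
    def test_boundary_of_all_four_rules_passes(self):
        rec = make_record(ref="A", alt="AT", consequence="frameshift",
                          normal=(20, 0, 60.0), central=(20, 5, 60.0),
                          peripheral=None)
        assert filter_indel(rec, "central", CFG).passed

    @pytest.mark.parametrize(
        "normal,central,reason",
        [
            ((20, 1, 60.0), (20, 5, 60.0), "INDEL_NORMAL"),  # "no read" is strict
            ((20, 0, 60.0), (19, 5, 60.0), "INDEL_DEPTH"),
            ((19, 0, 60.0), (20, 5, 60.0), "INDEL_DEPTH"),
            ((20, 0, 60.0), (60, 5, 60.0), "INDEL_VAF"),     # 5/60 < 10%
            ((20, 0, 60.0), (50, 4, 60.0), "INDEL_VAR"),
        ],
    )
    def test_single_rule_failures(self, normal, central, reason):
        rec = make_record(ref="A", alt="AT", consequence="frameshift",
                          normal=normal, central=central, peripheral=None)
        assert reason in filter_indel(rec, "central", CFG).reasons


class TestMasks:
    def test_polymorphism_exclusion_is_exact_allele_match(self):
        rec = make_record(pos=777, ref="C", alt="T")
        dec = filter_snv(rec, "central", CFG)
        same = exclude_polymorphisms([dec], {("chr1", 777, "C", "T")})[0]
        assert "POLYMORPHISM" in same.reasons and not same.passed
        other_alt = exclude_polymorphisms([dec], {("chr1", 777, "C", "G")})[0]
        assert "POLYMORPHISM" not in other_alt.reasons
        assert exclude_polymorphisms([dec], set())[0] == dec

    def test_exonic_restriction_interval_stabbing(self):
        exons = [("chr1", 500, 1500)]
        inside = filter_snv(make_record(pos=1500), "central", CFG)
        outside = filter_snv(make_record(pos=1501), "central", CFG)
        updated = restrict_to_exonic([inside, outside], exons)
        assert "NON_EXONIC" not in updated[0].reasons
        assert "NON_EXONIC" in updated[1].reasons

    def test_empty_annotation_rejects_everything(self):
        dec = filter_snv(make_record(), "central", CFG)
        assert "NON_EXONIC" in restrict_to_exonic([dec], [])[0].reasons


class TestOracleEquivalence:
    def test_cascade_matches_brute_force_on_random_draws(self):
        """1,000 random evidence/neighborhood draws: exhaustive reason-set match."""
        rng = np.random.default_rng(2024)
        for trial in range(1000):
            pos = 5000
            tumor = SiteEvidence(
                depth=int(rng.integers(0, 60)),
                var_reads=0,
                mapping_quality=float(rng.integers(0, 45)),
            )
            tumor = dataclasses.replace(
                tumor, var_reads=int(rng.integers(0, tumor.depth + 1))
            )
            nd = int(rng.integers(0, 60))
            normal = SiteEvidence(nd, int(rng.integers(0, min(nd, 4) + 1)), 60.0)
            rec = make_record(
                pos=pos,
                normal=(normal.depth, normal.var_reads, normal.mapping_quality),
                central=(tumor.depth, tumor.var_reads, tumor.mapping_quality),
                peripheral=None,
            )
            neighbors = [rec]
            offsets = rng.choice(np.arange(1, 15), size=rng.integers(0, 4), replace=False)
            indel_dists = []
            for off in offsets:
                off = int(off) * (1 if rng.random() < 0.5 else -1)
                if rng.random() < 0.4:
                    neighbors.append(
                        make_record(pos=pos + off, ref="A", alt="AT",
                                    consequence="frameshift")
                    )
                    indel_dists.append(abs(off))
                else:
                    neighbors.append(make_record(pos=pos + off, ref="G", alt="A"))
            snv_positions = sorted(r.site.pos for r in neighbors if not r.is_indel)
            window_counts = [
                sum(1 for p in snv_positions if start <= p <= start + 9)
                for start in range(pos - 9, pos + 1)
            ]
            hood = Neighborhood.from_records(neighbors, CFG)
            got = set(filter_snv(rec, "central", CFG, hood).reasons)
            want = set(brute_force_snv_reasons(tumor, normal, indel_dists, window_counts))
            assert got == want, f"trial {trial}: {got} != {want}"

    @pytest.mark.parametrize(
        "field",
        ["snv_min_mapq", "snv_min_tumor_vaf", "snv_min_depth", "snv_min_tumor_var_reads"],
    )
    def test_raising_a_minimum_never_rescues_a_reject(self, field):
        rng = np.random.default_rng(7)
        stricter = FilterConfig(**{field: getattr(CFG, field) + 1})
        for _ in range(200):
            d = int(rng.integers(1, 40))
            rec = make_record(
                normal=(int(rng.integers(5, 40)), int(rng.integers(0, 3)), 60.0),
                central=(d, int(rng.integers(0, d + 1)), float(rng.integers(10, 40))),
                peripheral=None,
            )
            if not filter_snv(rec, "central", CFG).passed:
                assert not filter_snv(rec, "central", stricter).passed


class TestEndToEndIdentity:
    def test_noise_free_pass_set_equals_planted_set(self, small_genome):
        """With zero noise and default thresholds the filter recovers exactly
        the planted somatic mutations present in each region."""
        from ith_exome.synthetic_cohort import CohortParams, NoiseParams, simulate_cohort

        params = CohortParams(
            common_nonsyn=(12, 10), common_silent=(4, 4),
            private_counts=((2, 1), (0, 3)), purities=((1.0, 1.0), (1.0, 1.0)),
            indels_per_patient=2, n_polymorphisms=4, hypermutator_patient=None,
        )
        noiseless = NoiseParams(depth_dispersion=0.0, sequencing_error_rate=0.0, pyro_sd=0.0)
        cohort = simulate_cohort(small_genome, params, noiseless, seed=11)
        for pdata, ptruth in zip(cohort.patients, cohort.truth.patients):
            for region in ("central", "peripheral"):
                decisions = filter_region(
                    pdata.records, region, None,
                    cohort.polymorphism_sites, cohort.exon_intervals,
                )
                passed = {d.record.site.key for d in decisions if d.passed}
                planted = {
                    m.site.key
                    for m in ptruth.mutations
                    if m.clonality in ("common", f"private_{region}")
                }
                assert passed == planted
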