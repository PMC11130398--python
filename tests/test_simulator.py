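"""The synthetic locus and its generators: determinism, planted truth,
noise properties, end-to-end recovery."""

import numpy as np
import pytest
from scipy import stats

from lilrcnv.caller import HaplotypeCNType, LatticeMixtureCaller, default_hap_freqs
from lilrcnv.depth import sample_cn
from lilrcnv.errors import LilrError
from lilrcnv.hybrid import build_hybrid
from lilrcnv.regions import GenomicInterval
from lilrcnv.simulate import (
    SimulationConfig,
    build_toy_locus,
    draw_diplotypes,
    events_for,
    make_haplotype,
    simulate_cohort,
    simulate_depth,
    simulate_long_reads,
)
from lilrcnv.sv import call_deletions

H = HaplotypeCNType


class TestBuildToyLocus:
    def test_same_seed_byte_identical(self):
        a = build_toy_locus(SimulationConfig(seed=42))
        b = build_toy_locus(SimulationConfig(seed=42))
        assert a.reference == b.reference
        assert a.regions.body == b.regions.body
        assert [g.exons for g in a.genes] == [g.exons for g in b.genes]

    def test_different_seed_different_sequence(self):
        a = build_toy_locus(SimulationConfig(seed=1))
        b = build_toy_locus(SimulationConfig(seed=2))
        assert a.reference != b.reference

    def test_homology_tract_appears_exactly_twice(self, locus):
        tract = locus.reference[locus.a6_tract.start : locus.a6_tract.end]
        assert locus.reference.count(tract) == 2

    def test_deletion_length_is_config_default(self, locus):
        assert locus.del_end - locus.del_start == 33692

    def test_breakpoints_are_intronic(self, locus):
        b5_i12 = locus.b5.introns()[11]
        b3_i11 = locus.b3.introns()[10]
        assert b5_i12.start <= locus.del_start < b5_i12.end
        assert b3_i11.start <= locus.del_end < b3_i11.end

    def test_regions_validate_and_cores_sit_inside_units(self, locus):
        core_b3 = locus.regions.core_b3[0]
        core_a6 = locus.regions.core_a6[0]
        assert locus.b3_unit.contains(core_b3)
        assert locus.a6_unit.contains(core_a6)
        # cores avoid the ambiguous homology tract
        assert not core_b3.overlaps(locus.b3_tract)
        assert not core_a6.overlaps(locus.a6_tract)

    def test_oversized_tract_rejected(self):
        with pytest.raises(LilrError):
            SimulationConfig(seed=1, homology_tract=9000)
        with pytest.raises(LilrError):
            SimulationConfig(seed=1, identity_tract=5000)


class TestMakeHaplotype:
    def test_no_events_identity(self, locus):
        hap = make_haplotype(locus, [])
        assert hap.sequence == locus.reference
        assert hap.segments == [(0, len(locus.reference), 0)]

    def test_hybrid_deletion_shortens_by_33692(self, locus):
        hap = make_haplotype(locus, ["hybrid_del"])
        assert len(locus.reference) - len(hap) == 33692
        # junction is seamless through the identity tract
        assert hap.sequence == locus.reference[: locus.del_start] + locus.reference[locus.del_end :]

    def test_duplication_triples_a6_unit(self, locus):
        hap = make_haplotype(locus, [("dupA6", 2)])
        unit = locus.reference[locus.a6_unit.start : locus.a6_unit.end]
        assert hap.sequence.count(unit) == 3
        assert len(hap) == len(locus.reference) + 2 * locus.cfg.unit_length

    def test_dela6_removes_unit(self, locus):
        hap = make_haplotype(locus, ["delA6"])
        assert len(locus.reference) - len(hap) == locus.cfg.unit_length

    @pytest.mark.parametrize(
        "events", [["hybrid_del", "delA6"], ["delA6", ("dupA6", 1)], ["hybrid_del", ("dupA6", 2)]]
    )
    def test_conflicting_events_rejected(self, locus, events):
        with pytest.raises(LilrError):
            make_haplotype(locus, events)

    def test_events_for_covers_constructible_haplotypes(self):
        assert events_for(H(1, 1)) == []
        assert events_for(H(0, 0)) == ["hybrid_del"]
        assert events_for(H(1, 0)) == ["delA6"]
        assert events_for(H(1, 3)) == [("dupA6", 2)]
        with pytest.raises(LilrError):
            events_for(H(2, 1))


class TestSimulateDepth:
    def test_reference_diploid_expected_values(self, locus):
        p30, p0 = simulate_depth(locus, (H(1, 1), H(1, 1)), exact=True)
        ncn, pt, qc = sample_cn(p30, p0, locus.regions)
        assert (ncn.cn_b3core, ncn.cn_a6core, ncn.cn_sum) == (2.0, 2.0, 4.0)
        assert qc.passed

    def test_hybrid_carrier_called_one_one(self, locus):
        """Het hybrid carrier shows (1, 1, 2) -- the single-copy signature."""
        rng = np.random.default_rng(5)
        p30, p0 = simulate_depth(locus, (H(0, 0), H(1, 1)), rng)
        ncn, _, _ = sample_cn(p30, p0, locus.regions)
        X = np.array([[b, a, b + a] for b in range(3) for a in range(4)] * 2, float)
        model = LatticeMixtureCaller().fit(X)
        g = model.predict(ncn.as_array()[None, :])[0]
        assert tuple(g) == (1, 1)

    def test_bin_counts_are_poisson_dispersed(self, locus):
        rng = np.random.default_rng(7)
        p30, _ = simulate_depth(locus, (H(1, 1), H(1, 1)), rng)
        ctrl = p30.restrict(locus.regions.control)
        counts = np.array([c for _, c in ctrl.bins])
        # Poisson: variance equals mean (within sampling error at 500 bins)
        assert abs(counts.var() / counts.mean() - 1) < 0.15

    def test_ambiguous_tract_reads_only_in_mapq0_view(self, locus, rng):
        p30, p0 = simulate_depth(locus, (H(1, 1), H(1, 1)), rng)
        tract = [locus.a6_tract, locus.b3_tract]
        assert p30.restrict(tract).total_bases() == 0
        assert p0.restrict(tract).total_bases() > 0

    def test_tract_split_preserves_total(self, locus):
        _, p0 = simulate_depth(locus, (H(1, 1), H(1, 1)), exact=True)
        per_copy = locus.cfg.mean_depth / 2
        expected = 2 * 2 * per_copy * locus.cfg.homology_tract
        got = p0.restrict([locus.a6_tract, locus.b3_tract]).total_bases()
        assert got == pytest.approx(expected)


class TestSimulateLongReads:
    def test_cigars_consume_read_lengths(self, locus, rng):
        records, reads = simulate_long_reads(locus, (H(0, 0), H(1, 1)), rng)
        for rec in records:
            assert rec.query_length == len(reads[rec.read_id])

    def test_reference_haplotypes_yield_no_candidates(self, locus, rng):
        records, _ = simulate_long_reads(locus, (H(1, 1), H(1, 1)), rng)
        assert call_deletions(records) == []

    def test_het_hybrid_supported_by_at_least_five_reads(self, locus):
        rng = np.random.default_rng(3)
        records, _ = simulate_long_reads(locus, (H(0, 0), H(1, 1)), rng)
        calls = call_deletions(records)
        assert len(calls) == 1 and calls[0].support >= 5

    def test_substitution_errors_do_not_move_breakpoints(self, locus):
        locus.cfg.error_rate = 0.01
        try:
            rng = np.random.default_rng(9)
            records, _ = simulate_long_reads(locus, (H(0, 0), H(1, 1)), rng)
            calls = call_deletions(records)
            assert len(calls) == 1
            assert (calls[0].interval.start, calls[0].interval.end) == (
                locus.del_start,
                locus.del_end,
            )
        finally:
            locus.cfg.error_rate = 0.0


class TestCohort:
    def test_fixed_haplotype_gives_fixed_genotype(self, locus, rng):
        truths, table = simulate_cohort(locus, {H(1, 1): 1.0}, 5, rng, exact=True)
        assert all(t.h1 == t.h2 == H(1, 1) for t in truths)
        assert np.allclose(table["cn_sum"], 4.0)

    def test_truth_row_count(self, locus, rng):
        truths, table = simulate_cohort(locus, default_hap_freqs(), 8, rng, exact=True)
        assert len(truths) == len(table) == 8

    def test_hardy_weinberg_draw_proportions(self, rng):
        freqs = {H(1, 1): 0.6, H(1, 2): 0.3, H(1, 0): 0.1}
        diplos = draw_diplotypes(freqs, 1000, rng)
        haps = [h for pair in diplos for h in pair]
        observed = np.array([haps.count(h) for h in freqs])
        expected = np.array([f * 2000 for f in freqs.values()])
        chi2 = ((observed - expected) ** 2 / expected).sum()
        # 2 degrees of freedom; not extreme at the 1e-3 level
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_seeded_cohort_reproducible(self, locus):
        t1, d1 = simulate_cohort(locus, default_hap_freqs(), 6, np.random.default_rng(13))
        t2, d2 = simulate_cohort(locus, default_hap_freqs(), 6, np.random.default_rng(13))
        assert [(t.h1, t.h2) for t in t1] == [(t.h1, t.h2) for t in t2]
        assert d1.equals(d2)


class TestEndToEndHybridRecovery:
    def test_long_read_deletion_feeds_hybrid_module(self, locus):
        """Planted deletion -> exact call -> correct fused gene model."""
        rng = np.random.default_rng(3)
        records, _ = simulate_long_reads(locus, (H(0, 0), H(1, 1)), rng)
        call = call_deletions(records, reference=locus.genome())[0]
        assert (call.interval.start, call.interval.end) == (locus.del_start, locus.del_end)
        model = build_hybrid(call, locus.genes)
        assert model.retained_5p_exons == list(range(1, 13))
        assert model.retained_3p_exons == [12, 13]
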