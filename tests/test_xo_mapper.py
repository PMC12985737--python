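"""Genotype calling, haplotype segmentation and breakpoint localization."""

import numpy as np
import pytest
from scipy import stats

from xomap import synthetic
from xomap.xo_mapper import (
    AlleleDepthTable,
    CallStatus,
    GenotypeTrack,
    Genotype,
    Marker,
    Orientation,
    SnpMap,
    call_crossover,
    call_site_genotypes,
    filter_snp_candidates,
    map_population,
    read_crossover_bed,
    read_depth_tables,
    read_snp_map_tsv,
    read_snp_map_vcf,
    write_crossover_bed,
    write_depth_tables,
    write_snp_map_tsv,
    write_snp_map_vcf,
)


def _map_at(positions, start=1, end=None):
    end = end or positions[-1]
    markers = tuple(
        Marker(p, "A", "G", f"m{k}") for k, p in enumerate(positions, start=1)
    )
    return SnpMap("iv", "chrT", start, end, markers)


def _track(positions, genotypes):
    calls = np.array([Genotype[g] for g in genotypes], dtype=np.int8)
    return GenotypeTrack(
        recombinant_id="t",
        positions=np.array(positions, dtype=np.int64),
        calls=calls,
        col_fraction=np.full(len(positions), np.nan),
        marker_ids=[f"m{k}" for k in range(1, len(positions) + 1)],
    )


class TestSiteGenotyping:
    def test_threshold_bands(self):
        snps = _map_at([100, 200, 300, 400])
        depths = AlleleDepthTable(
            "r1",
            snps.marker_ids,
            np.array([0, 740, 10, 1]),
            np.array([1500, 760, 5, 2]),
        )
        track = call_site_genotypes(depths, snps)
        assert track.calls[0] == Genotype.HOM_LER  # 0 / 1500
        assert track.calls[1] == Genotype.HET  # 740 / 760
        assert track.calls[2] == Genotype.MISSING  # depth 15 < min_depth
        assert track.calls[3] == Genotype.MISSING

    def test_ambiguous_fraction_is_missing(self):
        snps = _map_at([100, 200])
        depths = AlleleDepthTable(
            "r1", snps.marker_ids, np.array([300, 1300]), np.array([1000, 200])
        )
        track = call_site_genotypes(depths, snps)
        assert track.calls[0] == Genotype.MISSING  # 0.23: between hom and het bands
        assert track.calls[1] == Genotype.HOM_COL

    def test_incoherent_thresholds_rejected(self):
        snps = _map_at([100, 200])
        depths = AlleleDepthTable(
            "r1", snps.marker_ids, np.array([1, 1]), np.array([1, 1])
        )
        with pytest.raises(ValueError):
            call_site_genotypes(depths, snps, het_band=(0.1, 0.9), hom_max=0.15)

    def test_miscall_probability_negligible_at_study_depth(self):
        """Binomial tails outside the calling bands at 1500x, 0.2% error."""
        n, e = 1500, 0.002
        # heterozygous site: observed Col fraction Binomial(n, 0.5)
        het_miss = stats.binom.cdf(int(0.30 * n) - 1, n, 0.5) + stats.binom.sf(
            int(0.70 * n), n, 0.5
        )
        # homozygous Ler site: observed Col fraction Binomial(n, e)
        hom_miss = stats.binom.sf(int(0.15 * n), n, e)
        assert het_miss < 1e-6
        assert hom_miss < 1e-6


class TestCrossoverCalling:
    def test_single_boundary_localized_between_flanking_markers(self):
        track = _track([100, 200, 300, 400], ["HOM_LER"] * 2 + ["HET"] * 2)
        call = call_crossover(track)
        assert call.status is CallStatus.OK
        assert (call.left_pos, call.right_pos) == (200, 300)
        assert call.midpoint == 250
        assert call.orientation is Orientation.LER_TO_HET

    def test_reciprocal_orientation(self):
        track = _track([100, 200, 300, 400], ["HET"] * 2 + ["HOM_LER"] * 2)
        assert call_crossover(track).orientation is Orientation.HET_TO_LER

    def test_uniform_track_has_no_transition(self):
        track = _track([100, 200, 300, 400], ["HET"] * 4)
        assert call_crossover(track).status is CallStatus.NO_TRANSITION

    def test_double_boundary_rejected(self):
        track = _track(
            [100, 200, 300, 400, 500, 600],
            ["HOM_LER", "HOM_LER", "HET", "HET", "HOM_LER", "HOM_LER"],
        )
        assert call_crossover(track).status is CallStatus.MULTIPLE_TRANSITIONS

    def test_col_homozygosity_is_qc_failure(self):
        track = _track([100, 200, 300], ["HOM_LER", "HOM_COL", "HET"])
        assert call_crossover(track).status is CallStatus.UNEXPECTED_GENOTYPE

    def test_min_flank_guards_single_marker_blocks(self):
        track = _track([100, 200, 300, 400], ["HOM_LER"] + ["HET"] * 3)
        assert call_crossover(track, min_flank=2).status is CallStatus.NO_TRANSITION
        assert call_crossover(track, min_flank=1).status is CallStatus.OK

    def test_missing_markers_are_skipped(self):
        track = _track(
            [100, 200, 300, 400, 500],
            ["HOM_LER", "HOM_LER", "MISSING", "HET", "HET"],
        )
        call = call_crossover(track)
        assert call.status is CallStatus.OK
        assert (call.left_pos, call.right_pos) == (200, 400)

    def test_too_few_informative_markers_is_an_error(self):
        track = _track([100, 200, 300], ["MISSING", "MISSING", "HET"])
        with pytest.raises(ValueError):
            call_crossover(track)


class TestRecoveryProperties:
    def test_noise_free_recovery_is_exact(self, snp_map, mixture_model):
        """Without read error the called gap is the true inter-marker gap."""
        truth = synthetic.simulate_recombinants(100, mixture_model, rng_seed=11)
        tables = synthetic.simulate_allele_depths(
            truth, snp_map, mean_depth=2000, error_rate=0.0, rng_seed=12
        )
        calls, tally = map_population(tables, snp_map)
        by_id = {t.recombinant_id: t for t in truth.recombinants}
        pos = snp_map.positions
        assert tally[CallStatus.OK] == 100
        for c in calls:
            bp = by_id[c.recombinant_id].breakpoints[0]
            assert c.left_pos <= bp < c.right_pos
            gap = np.searchsorted(pos, bp, side="right")
            assert (c.left_pos, c.right_pos) == (pos[gap - 1], pos[gap])

    def test_masking_one_marker_only_widens_to_adjacent_gaps(self):
        positions = [100, 200, 300, 400, 500, 600]
        genotypes = ["HOM_LER"] * 3 + ["HET"] * 3
        base = call_crossover(_track(positions, genotypes))
        assert (base.left_pos, base.right_pos) == (300, 400)
        # union of the base gap with its two neighbouring inter-marker gaps
        lo, hi = 200, 500
        for masked in range(1, 5):  # keep >= min_flank markers on both ends
            g = list(genotypes)
            g[masked] = "MISSING"
            call = call_crossover(_track(positions, g))
            assert call.status is CallStatus.OK
            assert lo <= call.left_pos and call.right_pos <= hi

    def test_orientation_follows_seed_colour_geometry(self, snp_map, mixture_model):
        truth = synthetic.simulate_recombinants(60, mixture_model, rng_seed=21)
        tables = synthetic.simulate_allele_depths(
            truth, snp_map, mean_depth=1500, error_rate=0.002, rng_seed=22
        )
        calls, _ = map_population(tables, snp_map)
        by_id = {t.recombinant_id: t for t in truth.recombinants}
        checked = 0
        for c in calls:
            if c.status is CallStatus.OK:
                assert c.orientation is by_id[c.recombinant_id].orientation
                checked += 1
        assert checked > 0


class TestPopulationMapping:
    def test_empty_population(self, snp_map):
        calls, tally = map_population([], snp_map)
        assert calls == [] and sum(tally.values()) == 0

    def test_double_crossover_simulants_never_called_ok(self, snp_map, mixture_model):
        truth = synthetic.simulate_recombinants(
            200, mixture_model, rng_seed=31, double_co_fraction=0.05
        )
        tables = synthetic.simulate_allele_depths(
            truth, snp_map, mean_depth=1500, error_rate=0.002, rng_seed=32
        )
        calls, tally = map_population(tables, snp_map)
        pos = snp_map.positions
        by_id = {t.recombinant_id: t for t in truth.recombinants}
        n_detectable_doubles = 0
        for c in calls:
            bps = by_id[c.recombinant_id].breakpoints
            if len(bps) == 2:
                gaps = np.searchsorted(pos, np.array(bps), side="right")
                if gaps[0] != gaps[1] and bps[1] < pos[-1]:
                    n_detectable_doubles += 1
                    assert c.status is CallStatus.MULTIPLE_TRANSITIONS
        assert n_detectable_doubles > 0
        assert tally[CallStatus.MULTIPLE_TRANSITIONS] >= n_detectable_doubles


class TestMarkerFiltering:
    def test_perfect_candidates_all_retained(self, snp_map):
        candidates, _ = synthetic.simulate_marker_support(
            snp_map, bad_fraction=0.0, n_obs=200, rng_seed=41, good_support=1.0
        )
        out = filter_snp_candidates(candidates, min_support=0.9)
        assert len(out) == len(snp_map)

    def test_discordant_site_dropped(self, snp_map):
        candidates, _ = synthetic.simulate_marker_support(
            snp_map, bad_fraction=0.0, n_obs=200, rng_seed=42, good_support=1.0
        )
        bad = candidates[10]
        candidates[10] = type(bad)(
            bad.position, bad.col_allele, bad.ler_allele, bad.id, 200, 100
        )
        out = filter_snp_candidates(candidates, min_support=0.9)
        assert len(out) == len(snp_map) - 1
        assert bad.id not in out.marker_ids

    def test_known_bad_subset_exactly_removed(self, snp_map):
        candidates, bad_ids = synthetic.simulate_marker_support(
            snp_map, bad_fraction=0.05, n_obs=200, rng_seed=43
        )
        out = filter_snp_candidates(candidates, min_support=0.9)
        assert set(snp_map.marker_ids) - set(out.marker_ids) == bad_ids

    def test_empty_result_warns(self, snp_map):
        candidates, _ = synthetic.simulate_marker_support(
            snp_map, bad_fraction=1.0, n_obs=200, rng_seed=44, bad_support=0.1
        )
        with pytest.warns(UserWarning):
            filter_snp_candidates(candidates, min_support=0.9)


class TestIO:
    def test_snp_map_tsv_roundtrip_is_bit_exact(self, snp_map, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_snp_map_tsv(snp_map, p1)
        again = read_snp_map_tsv(p1)
        assert again == snp_map
        write_snp_map_tsv(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_snp_map_vcf_roundtrip_is_bit_exact(self, snp_map, tmp_path):
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_snp_map_vcf(snp_map, p1)
        again = read_snp_map_vcf(p1)
        assert again.markers == snp_map.markers
        assert (again.start, again.end) == (snp_map.start, snp_map.end)
        write_snp_map_vcf(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_depth_table_roundtrip(self, snp_map, mixture_model, tmp_path):
        truth = synthetic.simulate_recombinants(5, mixture_model, rng_seed=51)
        tables = synthetic.simulate_allele_depths(
            truth, snp_map, mean_depth=100, error_rate=0.01, rng_seed=52
        )
        path = tmp_path / "depths.tsv"
        write_depth_tables(tables, path)
        again = read_depth_tables(path, snp_map)
        assert [t.recombinant_id for t in again] == [t.recombinant_id for t in tables]
        for a, b in zip(tables, again):
            np.testing.assert_array_equal(a.depth_col, b.depth_col)
            np.testing.assert_array_equal(a.depth_ler, b.depth_ler)

    def test_crossover_bed_roundtrip(self, snp_map, mixture_model, tmp_path):
        truth = synthetic.simulate_recombinants(20, mixture_model, rng_seed=53)
        tables = synthetic.simulate_allele_depths(
            truth, snp_map, mean_depth=1500, error_rate=0.002, rng_seed=54
        )
        calls, _ = map_population(tables, snp_map)
        path = tmp_path / "xo.bed"
        write_crossover_bed(calls, path)
        again = read_crossover_bed(path)
        assert [(c.recombinant_id, c.status, c.midpoint) for c in again] == [
            (c.recombinant_id, c.status, c.midpoint) for c in calls
        ]
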