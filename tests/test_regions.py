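"""Region discovery: binning, Poisson calling, merging, profiles, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enhdyn.regions import (
    BinnedTrack,
    CandidateRegion,
    GeneAnnotator,
    PeakCallParams,
    bin_tag_counts,
    call_significant_bins,
    compute_gc_cpg,
    discover_regions,
    locate_center_and_profile,
    merge_into_regions,
    orient_and_filter,
    poisson_bin_pvalue,
)
from enhdyn.simulate import (
    SimulationConfig,
    TagTrack,
    generate_genome,
    generate_tag_tracks,
    plant_truth,
)


def _track(positions, strands, feature="H3K4me1"):
    return TagTrack(
        feature,
        pd.DataFrame({"chrom": "chr1", "pos": positions, "strand": strands}),
    )


class TestBinning:
    def test_chip_shift_rules(self):
        params = PeakCallParams()
        lengths = {"chr1": 2000}
        # plus-strand read at 100 shifts to 175 -> bin 0
        b = bin_tag_counts(_track([100], ["+"]), lengths, params, is_chip=True)
        assert b.counts["chr1"][0] == 1
        # minus-strand read at 210 shifts to 135 -> bin 0
        b = bin_tag_counts(_track([210], ["-"]), lengths, params, is_chip=True)
        assert b.counts["chr1"][0] == 1 and b.counts["chr1"][1] == 0

    def test_out_of_range_after_shift_clamped(self):
        params = PeakCallParams()
        b = bin_tag_counts(_track([10], ["-"]), {"chr1": 1000}, params, is_chip=True)
        assert b.counts["chr1"][0] == 1
        assert b.total == 1

    def test_uniform_reads_match_direct_histogram(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 1_000_000, size=100_000)
        strands = np.where(rng.random(100_000) < 0.5, "+", "-")
        params = PeakCallParams()
        b = bin_tag_counts(_track(pos, strands, "TSS"), {"chr1": 1_000_000}, params, is_chip=False)
        oracle, _ = np.histogram(pos, bins=np.arange(0, 1_000_001, 200))
        np.testing.assert_array_equal(b.counts["chr1"], oracle)
        assert abs(b.counts["chr1"].mean() - 20) < 0.5

    def test_tss_binned_per_strand(self):
        params = PeakCallParams()
        b = bin_tag_counts(
            _track([50, 60, 70], ["+", "-", "-"], "TSS"), {"chr1": 1000}, params, is_chip=False
        )
        assert b.stranded
        assert b.strand_counts["chr1"]["+"][0] == 1
        assert b.strand_counts["chr1"]["-"][0] == 2


class TestPoissonPvalue:
    def test_zero_count_has_full_mass(self):
        assert poisson_bin_pvalue(0, 2.0) == 1.0

    def test_closed_form_count_one(self):
        assert poisson_bin_pvalue(1, 2.0) == pytest.approx(1 - np.exp(-2), rel=1e-12)

    def test_matches_brute_force_tail_sum(self):
        # P(X >= 12 | lam=0.8) via explicit pmf summation
        from math import exp, factorial

        lam, c = 0.8, 12
        tail = sum(exp(-lam) * lam**k / factorial(k) for k in range(c, 60))
        assert poisson_bin_pvalue(c, lam) == pytest.approx(tail, rel=1e-9)
        assert poisson_bin_pvalue(c, lam) < 1e-6

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_bin_pvalue(3, 0.0)


class TestSignificantBins:
    def test_all_zero_track_yields_empty_set(self):
        b = BinnedTrack("H3K4me1", {"chr1": np.zeros(100, dtype=int)}, total=0)
        sig = call_significant_bins(b, PeakCallParams())
        assert len(sig["chr1"]) == 0

    def test_null_poisson_calibration(self):
        # 1e6 null bins at lam=1: expect ~1 significant bin at p=1e-6
        rng = np.random.default_rng(42)
        counts = rng.poisson(1.0, size=1_000_000)
        b = BinnedTrack("x", {"chr1": counts}, total=int(counts.sum()))
        sig = call_significant_bins(b, PeakCallParams())
        assert len(sig["chr1"]) <= 5

    def test_planted_region_at_20x_background_fully_significant(self):
        cfg = SimulationConfig(seed=2, background_rate=1.0, enrichment_rate=20.0)
        genome = generate_genome(cfg)
        truth = plant_truth(cfg, genome)
        tracks = generate_tag_tracks(cfg, truth)
        params = PeakCallParams()
        b = bin_tag_counts(tracks["H3K4me1"], cfg.chrom_lengths, params, is_chip=True)
        sig = {c: set(v) for c, v in call_significant_bins(b, params).items()}
        enh = truth.regions.query("state == 'enhancer'")
        half = cfg.region_width_bins // 2
        hits = total = 0
        for r in enh.itertuples():
            c = r.center // 200
            bins_sig = [k in sig[r.chrom] for k in range(c - half, c + half + 1)]
            hits += sum(bins_sig)
            total += len(bins_sig)
            # every planted region is detected through at least one bin
            assert any(bins_sig)
        # at 20x background nearly every planted bin clears p <= 1e-6
        assert hits / total > 0.95


class TestMerge:
    def _sig(self, bins):
        return {"f": {"chr1": np.array(sorted(bins), dtype=np.int64)}}

    def test_gap_below_500_merges(self):
        # bins [1000,1200) and [1600,1800): indices 5 and 8, gap 400
        regions = merge_into_regions(self._sig([5, 8]), PeakCallParams())
        assert len(regions) == 1

    def test_gap_exactly_500_stays_split(self):
        # merge_gap=500 with 250-bp bins cannot arise; use explicit params
        params = PeakCallParams(bin_size=250, step=250)
        # indices 0 and 3: gap = 2*250 = 500 -> strict "less than" keeps two
        regions = merge_into_regions(
            {"f": {"chr1": np.array([0, 3])}}, params
        )
        assert len(regions) == 2

    def test_matches_naive_quadratic_merge_oracle(self):
        rng = np.random.default_rng(7)
        params = PeakCallParams()
        for _ in range(20):
            bins = np.unique(rng.integers(0, 400, size=60))
            regions = merge_into_regions(self._sig(bins), params)
            # oracle: O(n^2) transitive closure on "gap < 500"
            groups = [[b] for b in bins]
            changed = True
            while changed:
                changed = False
                for i in range(len(groups)):
                    for j in range(i + 1, len(groups)):
                        if any(
                            (abs(x - y) - 1) * 200 < 500
                            for x in groups[i]
                            for y in groups[j]
                        ):
                            groups[i] += groups.pop(j)
                            changed = True
                            break
                    if changed:
                        break
            assert len(regions) == len(groups)
            got = sorted(tuple(sorted(r.bins)) for r in regions)
            want = sorted(tuple(sorted(g)) for g in groups)
            assert got == want

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(3)
        bins = np.unique(rng.integers(0, 500, size=80))
        params = PeakCallParams()
        once = merge_into_regions(self._sig(bins), params)
        # feeding the merged runs back in changes nothing
        again = merge_into_regions(
            {"f": {"chr1": np.concatenate([r.bins for r in once])}}, params
        )
        assert [list(r.bins) for r in once] == [list(r.bins) for r in again]

    def test_union_across_features_sets_flags(self):
        sig = {
            "H3K4me1": {"chr1": np.array([10])},
            "TSS": {"chr1": np.array([11])},
        }
        (region,) = merge_into_regions(sig, PeakCallParams())
        assert region.sig_features == {"H3K4me1": True, "TSS": True}


def _binned_with_counts(counts):
    arr = np.asarray(counts, dtype=np.int64)
    return {"f": BinnedTrack("f", {"chr1": arr}, total=int(arr.sum()))}


class TestCenterAndProfile:
    def test_single_bin_is_its_own_center(self):
        counts = np.zeros(100, dtype=int)
        counts[40] = 9
        region = CandidateRegion("chr1", np.array([40]), {"f": True})
        locate_center_and_profile(region, _binned_with_counts(counts), PeakCallParams())
        assert region.center_bin == 40

    def test_equal_weights_center_on_midpoint(self):
        counts = np.zeros(100, dtype=int)
        counts[10] = counts[12] = 5
        region = CandidateRegion("chr1", np.array([10, 12]), {"f": True})
        locate_center_and_profile(region, _binned_with_counts(counts), PeakCallParams())
        assert region.center_bin == 11

    def test_round_half_up_on_weighted_mean(self):
        # weights (1, 3) at indices 10, 12 -> mean 11.5 -> center 12
        counts = np.zeros(100, dtype=int)
        counts[10], counts[12] = 1, 3
        region = CandidateRegion("chr1", np.array([10, 12]), {"f": True})
        locate_center_and_profile(region, _binned_with_counts(counts), PeakCallParams())
        assert region.center_bin == 12

    def test_window_near_edge_dropped(self):
        counts = np.zeros(15, dtype=int)
        counts[2] = 9
        region = CandidateRegion("chr1", np.array([2]), {"f": True})
        out = locate_center_and_profile(region, _binned_with_counts(counts), PeakCallParams())
        assert out is None

    def test_profile_is_ppm_normalized(self):
        counts = np.zeros(100, dtype=int)
        counts[50] = 10
        counts[0] = 90  # elsewhere, contributes to the total only
        region = CandidateRegion("chr1", np.array([50]), {"f": True})
        profile = locate_center_and_profile(
            region, _binned_with_counts(counts), PeakCallParams()
        )
        assert profile.shape == (21, 1)
        assert profile[10, 0] == pytest.approx(10 * 1e6 / 100)


class TestOrientAndFilter:
    def _tss_binned(self, plus, minus, n=100):
        p = np.zeros(n, dtype=int)
        m = np.zeros(n, dtype=int)
        p[50], m[50] = plus, minus
        return BinnedTrack(
            "TSS",
            {"chr1": p + m},
            total=plus + minus,
            stranded=True,
            strand_counts={"chr1": {"+": p, "-": m}},
        )

    def _region(self, sig):
        r = CandidateRegion("chr1", np.array([50]), sig)
        r.center_bin = 50
        r.start, r.end = 40 * 200, 61 * 200
        return r

    def test_minus_majority_flips_orientation_and_profile(self):
        region = self._region({"H3K4me1": True, "TSS": True})
        profile = np.arange(21, dtype=float)[:, None]
        kept, profs = orient_and_filter(
            [region], [profile], self._tss_binned(2, 10), PeakCallParams()
        )
        assert kept[0].strand == "-"
        np.testing.assert_array_equal(profs[0][:, 0], np.arange(20, -1, -1))

    def test_tie_defaults_to_plus(self):
        region = self._region({"H3K4me1": True, "TSS": True})
        kept, _ = orient_and_filter(
            [region], [np.zeros((21, 1))], self._tss_binned(3, 3), PeakCallParams()
        )
        assert kept[0].strand == "+"

    def test_tss_only_region_excluded(self):
        region = self._region({"H3K4me1": False, "TSS": True})
        kept, _ = orient_and_filter(
            [region], [np.zeros((21, 1))], self._tss_binned(5, 0), PeakCallParams()
        )
        assert kept == []

    def test_histone_only_region_retained(self):
        region = self._region({"H3K4me1": True, "TSS": False})
        kept, _ = orient_and_filter(
            [region], [np.zeros((21, 1))], self._tss_binned(0, 0), PeakCallParams()
        )
        assert len(kept) == 1


class TestAnnotation:
    @pytest.fixture()
    def annotator(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [10_000, 50_000, 20_100],
                "end": [20_000, 60_000, 25_000],
                "strand": ["+", "-", "+"],
                "tss": [10_000, 59_999, 20_100],
            }
        )
        features = pd.DataFrame(
            [
                ("gA", "chr1", "exon", 10_000, 12_000, "+"),
                ("gA", "chr1", "exon", 15_000, 20_000, "+"),
                ("gA", "chr1", "five_prime_utr", 10_000, 10_200, "+"),
                ("gA", "chr1", "three_prime_utr", 19_500, 20_000, "+"),
                ("gB", "chr1", "exon", 50_000, 60_000, "-"),
                ("gB", "chr1", "five_prime_utr", 59_000, 59_400, "-"),
                ("gB", "chr1", "three_prime_utr", 50_000, 50_400, "-"),
            ],
            columns=["gene_id", "chrom", "feature", "start", "end", "strand"],
        )
        return GeneAnnotator(genes, features)

    def test_exon_beats_intron(self, annotator):
        # window spans the exon/intron boundary of gA
        assert annotator.annotate("chr1", 11_900, 12_300) == "exon"

    def test_intron_when_only_intron(self, annotator):
        assert annotator.annotate("chr1", 13_000, 13_400) == "intron"

    def test_intergenic_when_nothing_overlaps(self, annotator):
        assert annotator.annotate("chr1", 30_000, 34_200) == "intergenic"

    def test_tss_beats_three_prime_utr_of_other_gene(self, annotator):
        # window overlaps gA's 3'UTR and sits within 500 bp of gC's TSS
        assert annotator.annotate("chr1", 19_700, 20_000) == "TSS"

    def test_five_prime_utr_beats_exon(self, annotator):
        # inside gB's 5'UTR (which is also exonic), beyond its TSS window
        assert annotator.annotate("chr1", 59_100, 59_300) == "five_prime_utr"


class TestGcCpg:
    def test_at_only_sequence_scores_zero(self):
        df = compute_gc_cpg("AT" * 100, 200)
        assert df.loc[0, "gc"] == 0.0
        assert df.loc[0, "cpg_score"] == 0.0

    def test_gc_only_sequence(self):
        seq = "GC" * 100  # GCGC... has CpG at every odd offset
        df = compute_gc_cpg(seq, 200)
        assert df.loc[0, "gc"] == 1.0
        # oracle: direct dinucleotide scan
        obs = sum(1 for i in range(199) if seq[i : i + 2] == "CG")
        exp = seq.count("C") * seq.count("G") / 200
        assert df.loc[0, "cpg_score"] == pytest.approx(obs / exp)

    @given(st.text(alphabet="ACGTN", min_size=200, max_size=200))
    @settings(max_examples=25, deadline=None)
    def test_matches_single_pass_counter_oracle(self, seq):
        df = compute_gc_cpg(seq, 200)
        g, c = seq.count("G"), seq.count("C")
        obs = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        assert df.loc[0, "gc"] == pytest.approx((g + c) / 200)
        exp = c * g / 200
        want = obs / exp if exp > 0 else 0.0
        assert df.loc[0, "cpg_score"] == pytest.approx(want)


class TestDiscoveryProperties:
    def test_all_windows_are_21_bins_wide(self, small_config, small_sim):
        table, profiles = discover_regions(small_sim.tracks, small_config.chrom_lengths)
        assert (table["end"] - table["start"] == 4200).all()
        assert profiles.shape[1:] == (21, 4)

    def test_region_count_monotone_in_threshold(self, small_config, small_sim):
        strict = PeakCallParams(p_threshold=1e-9)
        loose = PeakCallParams(p_threshold=1e-4)
        t_strict, _ = discover_regions(small_sim.tracks, small_config.chrom_lengths, strict)
        t_loose, _ = discover_regions(small_sim.tracks, small_config.chrom_lengths, loose)
        assert len(t_strict) <= len(t_loose)

    def test_planted_regions_recovered(self, small_config, small_sim):
        from conftest import match_truth_states

        table, _ = discover_regions(small_sim.tracks, small_config.chrom_lengths)
        states = match_truth_states(table, small_sim.truth.regions)
        # every detected region corresponds to a planted one and vice versa
        assert states.notna().mean() > 0.99
        assert len(table) >= 0.98 * len(small_sim.truth.regions)
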