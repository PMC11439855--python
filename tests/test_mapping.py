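"""Tests of pooled-AF computation, filtering, binning and region detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palemapper import simulate
from palemapper.formats import GenomeMap, VariantRecord
from palemapper.mapping import (
    BinSummary,
    CandidateRegion,
    ExcludedVariant,
    FilterConfig,
    PoolAF,
    RegionConfig,
    bin_variants,
    compute_pool_af,
    compute_pool_afs,
    detect_candidate_regions,
    filter_segregating,
    map_pipeline,
)


def rec(pos, ad_mut, ad_wt, chrom="chr7H"):
    return VariantRecord(chrom, pos, "G", "A", ad_mut, ad_wt)


def af(pos, af_mut, af_wt, chrom="chr7H", depth=100):
    alt_m = round(af_mut * depth)
    alt_w = round(af_wt * depth)
    return PoolAF(
        variant=rec(pos, (depth - alt_m, alt_m), (depth - alt_w, alt_w), chrom),
        af_mut=af_mut,
        af_wt=af_wt,
        depth_mut=depth,
        depth_wt=depth,
    )


class TestComputePoolAF:
    def test_causal_locus_pattern(self):
        # mutant pool fixed (AF 1), wt pool heterozygote mixture (AF 1/3)
        out = compute_pool_af(rec(1, (0, 40), (20, 10)), FilterConfig())
        assert out.af_mut == 1.0
        assert out.af_wt == pytest.approx(1 / 3)

    def test_simple_fractions(self):
        out = compute_pool_af(rec(1, (10, 10), (30, 10)), FilterConfig())
        assert (out.af_mut, out.af_wt) == (0.5, 0.25)

    @pytest.mark.parametrize(
        "ad_mut, ad_wt, reason",
        [
            ((3, 2), (30, 10), "low depth mut_pool"),
            ((30, 10), (3, 2), "low depth wt_pool"),
        ],
    )
    def test_low_depth_excluded_with_reason(self, ad_mut, ad_wt, reason):
        out = compute_pool_af(rec(1, ad_mut, ad_wt), FilterConfig(min_depth=10))
        assert isinstance(out, ExcludedVariant)
        assert out.reason == reason


class TestFilterSegregating:
    @pytest.mark.parametrize(
        "af_mut, af_wt, kept",
        [
            (1.0, 0.33, True),  # causal-region pattern
            (0.6, 0.05, False),  # af_wt below lower bound
            (0.5, 0.95, False),  # af_wt above upper bound
            (0.1, 0.5, False),  # strict: af_mut == min_af_both fails
            (0.5, 0.9, False),  # strict: af_wt == max_af_wt fails
            (0.11, 0.89, True),
        ],
    )
    def test_rule(self, af_mut, af_wt, kept):
        out = filter_segregating([af(1, af_mut, af_wt)], FilterConfig())
        assert (len(out) == 1) is kept

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            max_size=50,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_subset_order_and_idempotence(self, pairs):
        afs = [af(i + 1, m, w) for i, (m, w) in enumerate(pairs)]
        cfg = FilterConfig()
        once = filter_segregating(afs, cfg)
        assert all(x in afs for x in once)
        positions = [x.variant.pos for x in once]
        assert positions == sorted(positions)  # order preserved
        assert filter_segregating(once, cfg) == once


class TestBinning:
    genome = GenomeMap({"chr7H": 10_000_000})

    def test_boundary_positions(self):
        bins = bin_variants(
            [af(2_000_000, 0.5, 0.5), af(2_000_001, 0.5, 0.5)], self.genome
        )
        occupied = {b.bin_start: b.n_variants for b in bins if b.n_variants}
        assert occupied == {0: 1, 2_000_000: 1}

    def test_mean_and_high_fraction(self):
        members = [af(10, 0.9, 0.3), af(20, 1.0, 0.3), af(30, 0.8, 0.3)]
        b = bin_variants(members, self.genome)[0]
        assert b.mean_af_mut == pytest.approx(0.9)
        assert b.frac_high_mut == pytest.approx(2 / 3)

    def test_empty_bins_emitted_with_nan(self):
        bins = bin_variants([], self.genome)
        assert len(bins) == 5
        assert all(b.n_variants == 0 and math.isnan(b.mean_af_mut) for b in bins)

    def test_position_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            bin_variants([af(10_000_001, 0.5, 0.5)], self.genome)

    def test_count_conservation_and_naive_oracle(self):
        rng = np.random.default_rng(42)
        genome = GenomeMap({"chrA": 9_000_000, "chrB": 4_000_000})
        afs = []
        for i in range(1000):
            chrom = "chrA" if rng.random() < 0.7 else "chrB"
            pos = int(rng.integers(1, genome[chrom] + 1))
            afs.append(af(pos, float(rng.random()), float(rng.random()), chrom))
        width = 2_000_000
        bins = bin_variants(afs, genome, width)
        assert sum(b.n_variants for b in bins) == len(afs)
        # oracle: naive per-variant double loop over all bins
        for b in bins:
            members = [
                x
                for x in afs
                if x.variant.chrom == b.chrom
                and b.bin_start < x.variant.pos <= b.bin_start + width
            ]
            assert b.n_variants == len(members)
            if members:
                assert b.mean_af_mut == pytest.approx(
                    np.mean([m.af_mut for m in members])
                )
                assert b.mean_af_wt == pytest.approx(
                    np.mean([m.af_wt for m in members])
                )


def make_bins(mut_means, wt_means, chrom="chr7H", n_variants=10, width=2_000_000):
    return [
        BinSummary(chrom, i * width, width, n_variants, m, w, 0.0)
        for i, (m, w) in enumerate(zip(mut_means, wt_means))
    ]


def brute_force_regions(bins, cfg):
    """Independent oracle: enumerate every contiguous bin run, keep the
    maximal all-qualifying runs meeting the length and peak rules."""

    def q(b):
        return (
            b.n_variants >= cfg.min_variants_per_bin
            and b.mean_af_mut > cfg.af_threshold
            and b.mean_af_wt < cfg.af_threshold
        )

    def adjacent(a, b):
        return a.chrom == b.chrom and b.bin_start == a.bin_start + a.bin_width

    n = len(bins)
    found = []
    chrom_order = {b.chrom: i for i, b in enumerate(bins)}
    for i in range(n):
        for j in range(i, n):
            run = bins[i : j + 1]
            if not all(q(b) for b in run):
                continue
            if any(not adjacent(run[k], run[k + 1]) for k in range(len(run) - 1)):
                continue
            left_ok = i == 0 or not (q(bins[i - 1]) and adjacent(bins[i - 1], bins[i]))
            right_ok = j == n - 1 or not (
                q(bins[j + 1]) and adjacent(bins[j], bins[j + 1])
            )
            if not (left_ok and right_ok):
                continue
            peak = max(b.mean_af_mut for b in run)
            if len(run) >= cfg.min_bins and peak >= cfg.high_threshold:
                found.append(
                    (
                        run[0].chrom,
                        run[0].bin_start + 1,
                        run[-1].bin_start + run[-1].bin_width,
                        len(run),
                        peak,
                        chrom_order[run[0].chrom],
                    )
                )
    found.sort(key=lambda t: (-t[4], -t[3], t[5]))
    return [(c, s, e, n_) for c, s, e, n_, _, _ in found]


class TestRegionDetection:
    def test_strict_thresholds_cut_run_edges(self):
        bins = make_bins(
            [0.50, 0.95, 1.00, 0.90, 0.45], [0.40, 0.33, 0.30, 0.35, 0.50]
        )
        regions = detect_candidate_regions(bins, RegionConfig())
        assert len(regions) == 1
        r = regions[0]
        # bins 2-4 (0-based 1..3): 0.50 fails strict >, 0.45 fails, wt 0.50 fails
        assert (r.start, r.end) == (2_000_001, 8_000_000)
        assert r.n_bins == 3 and r.peak_af_mut == 1.0

    def test_exact_threshold_yields_no_region(self):
        bins = make_bins([0.5] * 6, [0.4] * 6)
        assert detect_candidate_regions(bins, RegionConfig()) == []

    def test_underpopulated_bins_never_qualify(self):
        bins = make_bins([1.0] * 4, [0.3] * 4, n_variants=3)
        assert detect_candidate_regions(bins, RegionConfig()) == []

    def test_two_runs_ranked_by_peak(self):
        mut = [0.95, 1.00, 0.45, 0.45, 0.75, 0.80]
        wt = [0.30] * 6
        bins = make_bins(mut, wt)
        cfg = RegionConfig(high_threshold=0.7)
        regions = detect_candidate_regions(bins, cfg)
        assert [r.peak_af_mut for r in regions] == [1.0, 0.8]

    def test_boundaries_use_outermost_variants_when_available(self):
        bins = make_bins([0.95, 1.00], [0.3, 0.3])
        variants = [af(500_000, 1.0, 0.3), af(3_500_000, 1.0, 0.3)]
        regions = detect_candidate_regions(bins, RegionConfig(), afs=variants)
        assert (regions[0].start, regions[0].end) == (500_000, 3_500_000)

    @given(st.data())
    @settings(deadline=None, max_examples=100)
    def test_agrees_with_exhaustive_enumeration(self, data):
        n = data.draw(st.integers(1, 40))
        chroms = data.draw(
            st.lists(st.sampled_from(["c1", "c2", "c3"]), min_size=n, max_size=n)
        )
        mut = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        )
        wt = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)
        )
        nv = data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
        by_chrom: dict[str, list] = {}
        for c, m, w, v in zip(sorted(chroms), mut, wt, nv):
            start = len(by_chrom.setdefault(c, [])) * 2_000_000
            by_chrom[c].append(BinSummary(c, start, 2_000_000, v, m, w, 0.0))
        bins = [b for c in sorted(by_chrom) for b in by_chrom[c]]
        cfg = RegionConfig(min_variants_per_bin=5, high_threshold=0.9)
        got = [
            (r.chrom, r.start, r.end, r.n_bins)
            for r in detect_candidate_regions(bins, cfg)
        ]
        assert got == brute_force_regions(bins, cfg)


class TestPipeline:
    def test_zero_variants_gives_empty_report(self):
        genome = GenomeMap({"chr1H": 4_000_000})
        report = map_pipeline([], genome)
        assert report.n_input == 0 and report.regions == []
        assert all(b.n_variants == 0 for b in report.bins)

    def test_recovers_causal_locus_on_default_simulation(self):
        cfg = simulate.CrossSimConfig(seed=123)
        cohort = simulate.simulate_f2_population(cfg)
        records = simulate.pool_and_sequence(cohort, cfg)
        report = map_pipeline(records, cfg.genome)
        top = report.top_region
        assert top is not None
        assert top.chrom == cfg.causal_chrom
        assert cfg.causal_pos in top

    def test_round_trips_through_vcf(self, tmp_path, default_cross):
        from palemapper.formats import write_vcf_minimal

        cfg, _, records = default_cross
        path = tmp_path / "pools.vcf"
        write_vcf_minimal(records, path)
        from_disk = map_pipeline(path, cfg.genome)
        in_memory = map_pipeline(records, cfg.genome)
        assert from_disk.regions == in_memory.regions
        assert from_disk.n_after_filter == in_memory.n_after_filter
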