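import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cobarscaf as cs
from cobarscaf.io_formats import Contig, ContigSet, ReadAlignment
from cobarscaf.prep import (all_pairs_js, bin_spans, build_bin_index,
                            contig_js, estimate_depths, jaccard_bins,
                            minhash_sample, select_seeds)


def _aln(contig, pos, barcode="bc", read_id="r", unique=True):
    return ReadAlignment(read_id=read_id, barcode=barcode, contig_id=contig,
                         position=pos, strand="+", is_unique=unique)


class TestDepthsAndSeeds:
    def test_depth_arithmetic(self):
        contigs = ContigSet([Contig("c1", 1000), Contig("c2", 8000)])
        alns = [_aln("c1", i, read_id=f"r{i}") for i in range(10)]
        depths, mean = estimate_depths(alns, contigs, read_length=100,
                                       seed_min_length=500)
        assert depths["c1"] == pytest.approx(1.0)
        assert depths["c2"] == 0.0
        assert mean == pytest.approx(0.5)

    def test_no_long_contigs_raises(self):
        contigs = ContigSet([Contig("c1", 1000)])
        with pytest.raises(ValueError, match="seed_min_length"):
            estimate_depths([], contigs, 100, seed_min_length=5000)

    def test_length_threshold_and_depth_window(self):
        contigs = ContigSet([Contig("a", 3000), Contig("b", 8000),
                             Contig("c", 9000), Contig("d", 9000)])
        depths = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 3.0}
        seeds = select_seeds(contigs, depths, mean_depth=1.0,
                             seed_min_length=7000, depth_window=(0.5, 1.5))
        assert seeds == {"b", "c"}       # short and repeat-depth excluded
        assert contigs["b"].is_seed and not contigs["d"].is_seed

    def test_empty_seed_set_raises(self):
        contigs = ContigSet([Contig("a", 3000)])
        with pytest.raises(ValueError, match="no seed"):
            select_seeds(contigs, {"a": 1.0}, 1.0, 7000)

    def test_collapsed_repeats_excluded_by_depth_window(self):
        params = cs.SimParams(genome_length=1_000_000, n_repeat_contigs=5,
                              rng_seed=11)
        _, contigs, truth, alignments = cs.simulate_dataset(params)
        unique = [a for a in alignments if a.is_unique]
        depths, mean = estimate_depths(unique, contigs, params.read_length)
        repeats = [cid for cid, r in truth.records.items() if r.is_repeat]
        assert len(repeats) == 5
        long_repeats = [cid for cid in repeats
                        if contigs[cid].length >= 7000]
        excluded = [cid for cid in long_repeats
                    if not (0.5 * mean <= depths[cid] <= 1.5 * mean)]
        assert len(excluded) >= len(long_repeats) - 1


class TestBinning:
    def test_chop_from_both_ends_with_middle_remainder(self):
        assert bin_spans(12_000, 5000) == [(0, 5000), (5000, 7000),
                                           (7000, 12_000)]
        assert bin_spans(12_000, 5000, keep_middle=False) == [
            (0, 5000), (7000, 12_000)]

    def test_exact_multiple_has_no_remainder(self):
        assert bin_spans(10_000, 5000) == [(0, 5000), (5000, 10_000)]

    @given(st.integers(1, 100_000), st.integers(1, 9000))
    @settings(max_examples=200, deadline=None)
    def test_spans_tile_contig_without_overlap(self, length, bin_size):
        spans = bin_spans(length, bin_size, keep_middle=True)
        assert spans[0][0] == 0 and spans[-1][1] == length
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 == s1
        assert all(e > s for s, e in spans)

    def test_read_at_position_zero_lands_in_first_bin(self):
        contigs = ContigSet([Contig("c", 12_000)])
        index = build_bin_index([_aln("c", 0)], contigs, 5000)
        assert index.contig_bins("c")[0].barcodes == {"bc"}

    def test_union_of_bins_equals_contig_barcodes(self, small_sim):
        params, _, contigs, _, alignments = small_sim
        unique = [a for a in alignments if a.is_unique]
        index = build_bin_index(unique, contigs, 5000, keep_middle=True)
        per_contig = {}
        for a in unique:
            per_contig.setdefault(a.contig_id, set()).add(a.barcode)
        for cid, expect in per_contig.items():
            assert index.contig_barcodes(cid) == expect

    def test_non_unique_and_null_barcodes_excluded(self):
        contigs = ContigSet([Contig("c", 6000)])
        alns = [_aln("c", 0, barcode="good"),
                _aln("c", 1, barcode="0_0_0"),
                _aln("c", 2, barcode="multi", unique=False)]
        index = build_bin_index(alns, contigs, 5000)
        assert index.contig_barcodes("c") == {"good"}


class TestJaccard:
    def test_formula_forced_example(self):
        assert jaccard_bins({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_identity_and_empty_conventions(self):
        assert jaccard_bins({"A"}, {"A"}) == 1.0
        assert jaccard_bins(set(), set()) == 0.0

    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    @settings(max_examples=300, deadline=None)
    def test_matches_membership_count_oracle(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        inter = sum(1 for x in a if x in b)
        union = len(set(list(a) + list(b)))
        expect = inter / union if union else 0.0
        assert jaccard_bins(a, b) == pytest.approx(expect)
        assert jaccard_bins(a, b) == jaccard_bins(b, a)
        assert 0.0 <= jaccard_bins(a, b) <= 1.0


@pytest.fixture(scope="module")
def indexed_sim(small_sim):
    params, _, contigs, _, alignments = small_sim
    unique = [a for a in alignments if a.is_unique]
    return contigs, build_bin_index(unique, contigs, 5000)


class TestContigJS:
    def test_max_over_pairs_matches_double_loop_oracle(self, indexed_sim):
        contigs, index = indexed_sim
        ids = sorted(contigs.ids())[:20]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                edge = contig_js(a, b, index, min_union=10)
                best = 0.0
                for ba in index.contig_bins(a):
                    for bb in index.contig_bins(b):
                        if len(ba.barcodes | bb.barcodes) < 10:
                            continue
                        best = max(best,
                                   jaccard_bins(ba.barcodes, bb.barcodes))
                assert edge.js == pytest.approx(best)

    def test_batch_all_pairs_agrees_with_per_pair(self, indexed_sim):
        contigs, index = indexed_sim
        edges = {(e.contig_a, e.contig_b): e
                 for e in all_pairs_js(index, min_union=10)}
        ids = sorted(contigs.ids())[:20]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                single = contig_js(a, b, index, min_union=10)
                batch = edges.get((a, b)) or edges.get((b, a))
                if batch is None:
                    assert single.js == 0.0
                else:
                    assert batch.js == pytest.approx(single.js)
                    if single.js > 0:
                        assert batch.best_bin_pair == single.best_bin_pair

    def test_no_shared_barcodes_gives_zero(self):
        contigs = ContigSet([Contig("a", 5000), Contig("b", 5000)])
        alns = ([_aln("a", 0, barcode=f"x{i}") for i in range(12)]
                + [_aln("b", 0, barcode=f"y{i}") for i in range(12)])
        index = build_bin_index(alns, contigs, 5000)
        assert contig_js("a", "b", index).js == 0.0

    def test_absent_contig_raises(self, indexed_sim):
        _, index = indexed_sim
        with pytest.raises(KeyError):
            index.contig_bins("missing")


class TestMinHash:
    def test_ratio_one_keeps_everything(self):
        universe = {f"bc{i}" for i in range(100)}
        assert minhash_sample(universe, 1.0, 42) == universe

    def test_same_seed_same_subset(self):
        universe = [f"bc{i}" for i in range(500)]
        s1 = minhash_sample(universe, 0.3, 7)
        s2 = minhash_sample(universe, 0.3, 7)
        assert s1 == s2
        assert len(s1) == 150
        assert minhash_sample(universe, 0.3, 8) != s1

    def test_sampled_js_tracks_full_js(self):
        # estimator consistency needs bins with enough barcodes to
        # subsample, hence the denser fragment coverage here
        params = cs.SimParams(genome_length=500_000, fragment_coverage=40,
                              rng_seed=7)
        _, contigs, _, alignments = cs.simulate_dataset(params)
        unique = [a for a in alignments if a.is_unique]
        full = build_bin_index(unique, contigs, 5000)
        universe = {a.barcode for a in unique}
        kept = minhash_sample(universe, 0.5, params.rng_seed)
        sampled = build_bin_index(unique, contigs, 5000,
                                  barcode_whitelist=kept)
        full_edges = {(e.contig_a, e.contig_b): e.js
                      for e in all_pairs_js(full, 10)}
        sub_edges = {(e.contig_a, e.contig_b): e.js
                     for e in all_pairs_js(sampled, 5)}
        pairs = [k for k, js in full_edges.items() if js > 0.1]
        x = [full_edges[k] for k in pairs]
        y = [sub_edges.get(k, 0.0) for k in pairs]
        from scipy import stats
        rho = stats.spearmanr(x, y).statistic
        assert rho > 0.9

    def test_ratio_one_reproduces_exact_js(self, small_sim):
        params, _, contigs, _, alignments = small_sim
        unique = [a for a in alignments if a.is_unique]
        universe = {a.barcode for a in unique}
        kept = minhash_sample(universe, 1.0, 99)
        full = build_bin_index(unique, contigs, 5000)
        filt = build_bin_index(unique, contigs, 5000,
                               barcode_whitelist=kept)
        fe = [(e.contig_a, e.contig_b, e.js) for e in all_pairs_js(full)]
        se = [(e.contig_a, e.contig_b, e.js) for e in all_pairs_js(filt)]
        assert fe == se


def test_mean_js_non_increasing_with_bin_distance(small_sim):
    """Within long simulated contigs, mean JS decays with bin distance."""
    params, _, contigs, _, alignments = small_sim
    unique = [a for a in alignments if a.is_unique]
    index = build_bin_index(unique, contigs, 5000)
    by_gap: dict[int, list[float]] = {}
    for c in contigs:
        bins = [b for b in index.contig_bins(c.id)
                if b.end - b.start == 5000]
        for i in range(len(bins)):
            for j in range(i + 1, len(bins)):
                gap = round(abs(bins[j].center - bins[i].center) / 5000)
                by_gap.setdefault(gap, []).append(
                    jaccard_bins(bins[i].barcodes, bins[j].barcodes))
    gaps = sorted(g for g in by_gap if len(by_gap[g]) >= 30)[:5]
    means = [np.mean(by_gap[g]) for g in gaps]
    assert all(m0 >= m1 for m0, m1 in zip(means, means[1:]))
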