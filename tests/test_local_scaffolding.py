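import random

import networkx as nx
import pytest

import cobarscaf as cs
from cobarscaf.io_formats import (GAP_PAIRED_END, Contig, ContigSet,
                                  ReadAlignment, ScaffoldRecord)
from cobarscaf.local_scaffolding import (HEAD, TAIL, _canonical, _entry_end,
                                         _exit_end, build_pe_links,
                                         candidates_for_gap, fill_gap,
                                         insert_unscaffolded)
from cobarscaf.prep import build_bin_index


def _pair(n, c1, p1, s1, c2, p2, s2, unique=True):
    r1 = ReadAlignment(f"p{n}/1", "bc", c1, p1, s1,
                       mate_read_id=f"p{n}/2", is_unique=unique)
    r2 = ReadAlignment(f"p{n}/2", "bc", c2, p2, s2,
                       mate_read_id=f"p{n}/1", is_unique=unique)
    return [r1, r2]


@pytest.fixture
def two_contigs():
    return ContigSet([Contig("c1", 2000), Contig("c2", 2000)])


class TestPELinks:
    def test_concordant_pairs_aggregate(self, two_contigs):
        alns = []
        for n in range(5):
            # forward read near c1 tail, reverse read near c2 head
            alns += _pair(n, "c1", 1700, "+", "c2", 150, "-")
        links = build_pe_links(alns, two_contigs, pe_min_support=3,
                               max_end_distance=1000, read_length=100)
        key = _canonical(("c1", TAIL), ("c2", HEAD))
        assert links == {key: 5}

    def test_support_threshold(self, two_contigs):
        alns = []
        for n in range(2):
            alns += _pair(n, "c1", 1700, "+", "c2", 150, "-")
        assert build_pe_links(alns, two_contigs, pe_min_support=3) == {}

    def test_reads_far_from_ends_ignored(self, two_contigs):
        alns = []
        for n in range(5):
            alns += _pair(n, "c1", 200, "+", "c2", 150, "-")  # c1 read mid
        assert build_pe_links(alns, two_contigs, pe_min_support=3,
                              max_end_distance=500) == {}

    def test_simulated_adjacent_contigs_link_tail_to_head(self):
        """Truth-adjacent simulated contigs produce the orientation-
        consistent link."""
        params = cs.SimParams(genome_length=300_000, flip_prob=0.0,
                              rng_seed=5)
        _, contigs, truth, alignments = cs.simulate_dataset(params)
        links = build_pe_links(alignments, contigs, pe_min_support=3)
        recs = truth.ordered_non_chimeric()
        checked = 0
        for left, right in zip(recs, recs[1:]):
            key = _canonical((left.contig_id, TAIL),
                             (right.contig_id, HEAD))
            wrong = [k for k in links
                     if {k[0][0], k[1][0]} == {left.contig_id,
                                               right.contig_id}
                     and k != key]
            assert not wrong
            if key in links:
                checked += 1
        assert checked > 10


class TestCandidates:
    def test_empty_pool(self, small_sim):
        _, _, contigs, _, alignments = small_sim
        unique = [a for a in alignments if a.is_unique]
        index = build_bin_index(unique, contigs, 5000)
        ids = sorted(contigs.ids())
        assert candidates_for_gap(ids[0], ids[1], set(), index, 0.05) == set()

    def test_truth_neighbor_is_candidate(self, default_sim):
        _, _, contigs, truth, alignments = default_sim
        unique = [a for a in alignments if a.is_unique]
        index = build_bin_index(unique, contigs, 5000)
        recs = truth.ordered_non_chimeric()
        hits = total = 0
        for a, mid, b in zip(recs, recs[1:], recs[2:]):
            pool = {mid.contig_id}
            found = candidates_for_gap(a.contig_id, b.contig_id, pool,
                                       index, candidate_js_threshold=0.05)
            total += 1
            hits += mid.contig_id in found
            if total == 50:
                break
        assert hits / total >= 0.95


class TestFillGap:
    def _links(self, *specs):
        links = {}
        for a, ea, b, eb, sup in specs:
            links[_canonical((a, ea), (b, eb))] = sup
        return links

    def test_direct_link_confirms_gap_without_insertion(self):
        links = self._links(("L", TAIL, "R", HEAD, 4))
        fill = fill_gap(("L", "+"), ("R", "+"), set(), links)
        assert fill.status == "pe_confirmed"
        assert fill.inserted == [] and fill.support == 4

    def test_single_candidate_inserted_with_implied_orientation(self):
        links = self._links(("L", TAIL, "c", HEAD, 3),
                            ("c", TAIL, "R", HEAD, 5))
        fill = fill_gap(("L", "+"), ("R", "+"), {"c"}, links)
        assert fill.status == "filled"
        assert fill.inserted == [("c", "+")]
        assert fill.support == 8

    def test_reversed_candidate_orientation(self):
        links = self._links(("L", TAIL, "c", TAIL, 3),
                            ("c", HEAD, "R", HEAD, 3))
        fill = fill_gap(("L", "+"), ("R", "+"), {"c"}, links)
        assert fill.inserted == [("c", "-")]

    def test_no_path_leaves_gap_unfilled(self):
        links = self._links(("L", TAIL, "c", HEAD, 3))
        fill = fill_gap(("L", "+"), ("R", "+"), {"c"}, links)
        assert fill.status == "unfilled" and fill.inserted == []

    def test_shortest_path_matches_bfs_oracle_on_random_dags(self):
        rng = random.Random(11)
        for trial in range(100):
            n = rng.randint(1, 7)
            cands = {f"m{i}" for i in range(n)}
            nodes = ["L"] + sorted(cands) + ["R"]
            links = {}
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    if rng.random() < 0.4:
                        eu = TAIL if u == "L" else rng.choice([HEAD, TAIL])
                        ev = HEAD if v == "R" else rng.choice([HEAD, TAIL])
                        links[_canonical((u, eu), (v, ev))] = rng.randint(3, 9)
            fill = fill_gap(("L", "+"), ("R", "+"), cands, links,
                            max_path_nodes=7)
            # BFS oracle over the same (contig, orientation) state graph
            g = nx.DiGraph()
            states = [(c, o) for c in cands for o in "+-"]
            all_states = [("L", "+")] + states + [("R", "+")]
            for s in all_states:
                for t in all_states:
                    if s[0] == t[0]:
                        continue
                    key = _canonical((s[0], _exit_end(s[1])),
                                     (t[0], _entry_end(t[1])))
                    if key in links:
                        g.add_edge(s, t)
            try:
                oracle_len = nx.shortest_path_length(g, ("L", "+"),
                                                     ("R", "+")) - 1
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                oracle_len = None
            if oracle_len is None:
                assert fill.status == "unfilled"
            else:
                assert len(fill.inserted) == oracle_len


class TestInsertUnscaffolded:
    def test_infinite_support_threshold_is_identity(self, default_sim):
        _, _, contigs, _, alignments = default_sim
        unique = [a for a in alignments if a.is_unique]
        index = build_bin_index(unique, contigs, 5000)
        ids = sorted(contigs.ids())[:6]
        scaffolds = [ScaffoldRecord("s1", [(c, "+") for c in ids[:3]]),
                     ScaffoldRecord("s2", [(c, "+") for c in ids[3:]])]
        pool = set(contigs.ids()) - set(ids)
        links = build_pe_links(alignments, contigs,
                               pe_min_support=10**9)
        out, pool2, fills = insert_unscaffolded(
            scaffolds, pool, contigs, index, links, 0.05)
        assert [s.parts for s in out] == [s.parts for s in scaffolds]
        assert pool2 == pool
        assert all(f.status == "unfilled" for f in fills)

    def test_each_contig_inserted_at_most_once(self, default_run):
        contigs, truth, alignments, result = default_run
        placed = [cid for s in result.scaffolds for cid in s.contig_ids()]
        assert len(placed) == len(set(placed))

    def test_fills_never_touch_flanks(self, default_run):
        contigs, truth, alignments, result = default_run
        for s in result.scaffolds:
            for i, gap in enumerate(s.gaps):
                if gap.kind == GAP_PAIRED_END:
                    continue
        # flank order is asserted indirectly: every fill report references
        # flanks that are still adjacent up to the inserted run
        names = {s.name: s for s in result.scaffolds}
        for f in result.fills:
            if f.status != "filled":
                continue
            ids = names[f.scaffold].contig_ids()
            li, ri = ids.index(f.left), ids.index(f.right)
            assert ri - li == len(f.inserted) + 1
            assert ids[li + 1:ri] == [cid for cid, _ in f.inserted]
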