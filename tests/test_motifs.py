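"""Edge classification and CLGF census against brute-force enumeration."""

from itertools import combinations

import numpy as np
import pytest

from clgfnet.motifs import (classify_edges, count_clgf, group_motif_stats,
                            make_default_region_map, motif_instances)
from clgfnet.network import FeedbackEdge, FeedbackNetwork


def brute_force_clgf(net: FeedbackNetwork) -> int:
    """Independent oracle: exhaustive scan over all channel triples."""
    pos = {}
    for e in net.edges:
        if e.sign > 0:
            pos[frozenset(e.pair)] = e.scope
    count = 0
    for trio in combinations(net.channels, 3):
        for hub in trio:
            partners = [c for c in trio if c != hub]
            for b, c in (partners, partners[::-1]):
                if (pos.get(frozenset((hub, b))) == "global"
                        and pos.get(frozenset((hub, c))) == "local"):
                    count += 1
    return count


def random_network(rng, n_channels=30, n_edges=40):
    names = [f"ch{i:03d}" for i in range(n_channels)]
    rmap = make_default_region_map(names)
    edges, used = [], set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n_channels, 2)
        if i == j or (min(i, j), max(i, j)) in used:
            continue
        used.add((min(i, j), max(i, j)))
        edges.append(FeedbackEdge(names[i], names[j],
                                  +1 if rng.random() < 0.8 else -1))
    return classify_edges(FeedbackNetwork(names, edges), rmap), rmap


class TestRegionMap:
    def test_full_scale_layout(self):
        names = [f"ch{i:03d}" for i in range(102)]
        rmap = make_default_region_map(names)
        assert len(rmap) == 102
        assert len(set(rmap.values())) == 10
        sizes = sorted(np.unique(list(rmap.values()), return_counts=True)[1])
        assert set(sizes) <= {10, 11}

    def test_small_layouts_keep_pairable_regions(self):
        rmap = make_default_region_map([f"c{i}" for i in range(7)])
        from collections import Counter
        assert min(Counter(rmap.values()).values()) >= 2


class TestClassify:
    def test_same_region_is_local_cross_region_is_global(self):
        names = ["a1", "a2", "b1"]
        rmap = {"a1": "temporal-L", "a2": "temporal-L", "b1": "parietal-R"}
        net = FeedbackNetwork(names, [FeedbackEdge("a1", "a2", 1),
                                      FeedbackEdge("a1", "b1", 1)])
        out = classify_edges(net, rmap)
        scopes = {e.pair: e.scope for e in out.edges}
        assert scopes[("a1", "a2")] == "local"
        assert scopes[("a1", "b1")] == "global"

    def test_unmapped_channel_named(self):
        net = FeedbackNetwork(["x", "y"], [FeedbackEdge("x", "y", 1)])
        with pytest.raises(KeyError, match="y"):
            classify_edges(net, {"x": "temporal-L"})

    def test_label_counts_match_recount(self, rng):
        net, rmap = random_network(rng)
        recount = sum(1 for e in net.edges
                      if rmap[e.ch_a] == rmap[e.ch_b])
        assert sum(e.scope == "local" for e in net.edges) == recount


class TestCensus:
    def _star(self, n_global, n_local, sign=1):
        names = (["hub"] + [f"g{i}" for i in range(n_global)]
                 + [f"l{i}" for i in range(n_local)])
        edges = [FeedbackEdge("hub", f"g{i}", sign, scope="global")
                 for i in range(n_global)]
        edges += [FeedbackEdge("hub", f"l{i}", sign, scope="local")
                  for i in range(n_local)]
        return FeedbackNetwork(names, edges)

    def test_minimal_motif(self):
        assert count_clgf(self._star(1, 1)).n_clgf == 1

    def test_product_rule_two_global_three_local(self):
        net = self._star(2, 3)
        census = count_clgf(net)
        assert census.n_clgf == 6
        assert census.n_clgf == brute_force_clgf(net)
        assert census.n_clgf_hubs == 1

    def test_negative_edges_do_not_count(self):
        census = count_clgf(self._star(2, 3, sign=-1))
        assert census.n_clgf == 0
        assert census.n_neg_fb == 5

    def test_matches_brute_force_on_random_networks(self, rng):
        for _ in range(25):
            net, _ = random_network(rng)
            census = count_clgf(net)
            assert census.n_clgf == brute_force_clgf(net)
            assert (census.n_pos_fb_local + census.n_pos_fb_global
                    == census.n_pos_fb_total)
            assert census.n_clgf <= census.n_pos_fb_local * census.n_pos_fb_global

    def test_adding_local_edge_to_hub_raises_count_by_global_degree(self):
        net = self._star(3, 2)
        base = count_clgf(net).n_clgf
        net2 = FeedbackNetwork(net.channels + ["extra"],
                               net.edges + [FeedbackEdge("hub", "extra", 1,
                                                         scope="local")])
        assert count_clgf(net2).n_clgf == base + 3

    def test_relabelling_invariance(self, rng):
        net, _ = random_network(rng)
        mapping = {c: f"z{i:02d}" for i, c in
                   enumerate(rng.permutation(net.channels))}
        assert count_clgf(net.relabel(mapping)).n_clgf == count_clgf(net).n_clgf

    def test_instance_list_length_matches_count(self, rng):
        net, _ = random_network(rng, n_edges=60)
        assert len(motif_instances(net)) == count_clgf(net).n_clgf


class TestGroupMotifStats:
    def test_identical_groups_p_one(self):
        net = FeedbackNetwork(["a", "b", "c"],
                              [FeedbackEdge("a", "b", 1, scope="global")])
        c = [count_clgf(net)] * 3
        out = group_motif_stats(c, c)
        assert out["n_clgf"]["p"] == 1.0

    def test_empty_networks_flagged_degenerate(self):
        empty = [count_clgf(FeedbackNetwork(["a", "b"], []))] * 3
        out = group_motif_stats(empty, empty)
        assert out["n_clgf"]["degenerate"] is True
        assert out["n_clgf"]["t"] == 0.0
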