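import itertools

import numpy as np
import pytest

from lncforge.conservation import (
    GeneLocus,
    OrthologPair,
    SyntenyBlock,
    build_homology_graph,
    edge_weight,
    find_synteny_blocks,
    matched_lnc_pairs,
    mcl_cluster,
    positional_matches,
)
from lncforge.io_formats import HitRecord, TranscriptModel
from lncforge.synthetic_data import (
    HitNoise,
    SimulationConfig,
    make_ortholog_groups,
    simulate_hits,
    simulate_synteny,
)


def _hit(q, t, qcov=80.0, tcov=80.0, evalue=1e-20):
    return HitRecord(q, t, 90.0, qcov, tcov, evalue, 100.0)


class TestHomologyGraph:
    def test_coverage_below_cutoff_excluded(self):
        g = build_homology_graph([_hit("NMR|a", "HUM|b", qcov=49.0, tcov=49.0, evalue=1e-10)])
        assert g.number_of_edges() == 0

    def test_boundary_hit_retained_with_weight_five(self):
        g = build_homology_graph([_hit("NMR|a", "HUM|b", qcov=60.0, tcov=30.0, evalue=1e-5)])
        assert g.number_of_edges() == 1
        assert g["NMR|a"]["HUM|b"]["weight"] == pytest.approx(5.0)

    def test_zero_evalue_takes_weight_cap(self):
        assert edge_weight(0.0) == 200.0
        g = build_homology_graph([_hit("NMR|a", "HUM|b", evalue=0.0)])
        assert g["NMR|a"]["HUM|b"]["weight"] == 200.0

    def test_reciprocal_hits_merge_by_max_weight(self):
        g = build_homology_graph(
            [_hit("NMR|a", "HUM|b", evalue=1e-10), _hit("HUM|b", "NMR|a", evalue=1e-30)]
        )
        assert g.number_of_edges() == 1
        assert g["NMR|a"]["HUM|b"]["weight"] == pytest.approx(30.0)

    def test_min_coverage_rule_requires_both(self):
        hits = [_hit("NMR|a", "HUM|b", qcov=80.0, tcov=30.0)]
        assert build_homology_graph(hits, coverage_rule="max").number_of_edges() == 1
        assert build_homology_graph(hits, coverage_rule="min").number_of_edges() == 0

    def test_untagged_id_rejected(self):
        with pytest.raises(ValueError, match="species tag"):
            build_homology_graph([_hit("a", "HUM|b")])

    def test_species_attribute_set(self):
        g = build_homology_graph([_hit("NMR|a", "HUM|b")])
        assert g.nodes["NMR|a"]["species"] == "NMR"


class TestMcl:
    def test_two_cliques_give_two_groups(self):
        hits = [
            _hit(a, b)
            for a, b in itertools.combinations(["NMR|a", "HUM|b", "MUS|c"], 2)
        ] + [
            _hit(a, b)
            for a, b in itertools.combinations(["NMR|x", "HUM|y", "MUS|z"], 2)
        ]
        groups = mcl_cluster(build_homology_graph(hits))
        assert len(groups) == 2
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [3, 3]

    def test_single_edge_is_one_pair_group(self):
        groups = mcl_cluster(build_homology_graph([_hit("NMR|a", "HUM|b")]))
        assert len(groups) == 1
        assert {sid for _, sid in groups[0].members} == {"NMR|a", "HUM|b"}

    def test_inflation_at_most_one_rejected(self):
        g = build_homology_graph([_hit("NMR|a", "HUM|b")])
        with pytest.raises(ValueError):
            mcl_cluster(g, inflation=1.0)

    def test_groups_partition_non_singleton_nodes(self):
        cfg = SimulationConfig(seed=13, planted_ortholog_groups=(3, 4, 5))
        truth = make_ortholog_groups(cfg)
        groups = mcl_cluster(build_homology_graph(simulate_hits(cfg, truth)))
        seen: set[str] = set()
        for g in groups:
            ids = {sid for _, sid in g.members}
            assert not ids & seen  # disjoint
            seen |= ids

    def test_raising_inflation_never_decreases_cluster_count(self):
        cfg = SimulationConfig(
            seed=17,
            planted_ortholog_groups=(3, 3, 4, 5),
            hit_noise=HitNoise(decoy_rate=0.1, mode="low_weight"),
        )
        truth = make_ortholog_groups(cfg)
        graph = build_homology_graph(simulate_hits(cfg, truth))
        counts = [
            len(mcl_cluster(graph, inflation=inf)) for inf in (1.2, 1.5, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts)

    def test_planted_groups_recovered_with_decoy_edges(self):
        # Adjusted Rand >= 0.95 vs truth at 5% low-weight decoy edges
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed,
                planted_ortholog_groups=(3, 3, 4, 5),
                hit_noise=HitNoise(decoy_rate=0.05, mode="low_weight"),
            )
            truth = make_ortholog_groups(cfg)
            groups = mcl_cluster(build_homology_graph(simulate_hits(cfg, truth)))
            members = sorted({m for g in truth.ortholog_groups for m in g})
            true_label = {
                m: gi for gi, g in enumerate(truth.ortholog_groups) for m in g
            }
            pred_label = {
                sid: g.group_id for g in groups for _, sid in g.members
            }
            y_true = [true_label[m] for m in members]
            y_pred = [pred_label.get(m, -1 - i) for i, m in enumerate(members)]
            aris.append(adjusted_rand_score(y_true, y_pred))
        assert np.mean(aris) >= 0.95


def brute_force_longest_chain(pairs: list[OrthologPair], max_gap: int) -> int:
    """Oracle: enumerate all subsets, keep the largest valid monotone chain."""
    best = 1 if pairs else 0
    idx = sorted(range(len(pairs)), key=lambda i: (pairs[i].sp1.index, pairs[i].sp2.index))
    for r in range(2, len(pairs) + 1):
        for combo in itertools.combinations(idx, r):
            xs = [pairs[i].sp1.index for i in combo]
            ys = [pairs[i].sp2.index for i in combo]
            if any(b - a <= 0 or b - a > max_gap for a, b in zip(xs, xs[1:])):
                continue
            up = all(0 < b - a <= max_gap for a, b in zip(ys, ys[1:]))
            down = all(0 < a - b <= max_gap for a, b in zip(ys, ys[1:]))
            if up or down:
                best = max(best, r)
    return best


def _anchor(i: int, j: int, scaffold1="c1", scaffold2="c2") -> OrthologPair:
    return OrthologPair(
        sp1=GeneLocus(f"A{i}", scaffold1, 1000 * i, 1000 * i + 500, "+", i),
        sp2=GeneLocus(f"B{j}", scaffold2, 1000 * j, 1000 * j + 500, "+", j),
    )


class TestSynteny:
    def test_perfect_collinearity_one_block(self):
        anchors = [_anchor(i, i) for i in range(6)]
        (block,) = find_synteny_blocks(anchors)
        assert block.orientation == "collinear"
        assert len(block.anchors) == 6

    def test_below_min_block_size_no_block(self):
        anchors = [_anchor(i, i) for i in range(4)]
        assert find_synteny_blocks(anchors) == []

    def test_reversed_order_gives_inverted_block(self):
        anchors = [_anchor(i, 5 - i) for i in range(6)]
        (block,) = find_synteny_blocks(anchors)
        assert block.orientation == "inverted"
        assert len(block.anchors) == 6

    def test_gap_larger_than_max_breaks_chain(self):
        anchors = [_anchor(i, i) for i in range(5)] + [
            _anchor(i + 100, i + 100) for i in range(5)
        ]
        blocks = find_synteny_blocks(anchors, min_block_size=5, max_gap=25)
        assert [len(b.anchors) for b in blocks] == [5, 5]

    def test_duplicate_pair_deduplicated_with_warning(self):
        anchors = [_anchor(i, i) for i in range(5)]
        with pytest.warns(UserWarning, match="duplicate"):
            (block,) = find_synteny_blocks(anchors + [anchors[0]])
        assert len(block.anchors) == 5

    def test_dp_matches_brute_force_on_random_instances(self, rng):
        for trial in range(25):
            n = int(rng.integers(5, 12))
            xs = rng.permutation(30)[:n]
            ys = rng.permutation(30)[:n]
            pairs = [_anchor(int(x), int(y)) for x, y in zip(sorted(xs), ys)]
            max_gap = int(rng.integers(5, 30))
            blocks = find_synteny_blocks(pairs, min_block_size=1, max_gap=max_gap)
            dp_best = max((len(b.anchors) for b in blocks), default=0)
            assert dp_best == brute_force_longest_chain(pairs, max_gap)


def _lnc(tid, scaffold, start, end, strand) -> TranscriptModel:
    return TranscriptModel(tid, tid, scaffold, strand, ((start, end),))


class TestPositionalMatches:
    @pytest.fixture
    def block(self):
        anchors = [
            OrthologPair(
                sp1=GeneLocus(f"G1_{i}", "nmr1", 2_000_000 * (i + 1), 2_000_000 * (i + 1) + 20_000, "+", i),
                sp2=GeneLocus(f"G2_{i}", "hum1", 2_000_000 * (i + 1), 2_000_000 * (i + 1) + 20_000, "+", i),
            )
            for i in range(5)
        ]
        return SyntenyBlock(scaffold_pair=("nmr1", "hum1"), anchors=anchors, orientation="collinear")

    def test_same_side_same_orientation_matches(self, block):
        g1 = block.anchors[0].sp1
        g2 = block.anchors[0].sp2
        l1 = _lnc("L1", "nmr1", g1.start - 50_000, g1.start - 48_000, "+")
        l2 = _lnc("L2", "hum1", g2.start - 60_000, g2.start - 58_000, "+")
        matches = positional_matches([l1], [l2], [block])
        assert matched_lnc_pairs(matches) == {("L1", "L2")}
        assert matches[0].side == "upstream"
        assert matches[0].relative_orientation == "same"

    def test_outside_window_excluded(self, block):
        g1 = block.anchors[0].sp1
        g2 = block.anchors[0].sp2
        l1 = _lnc("L1", "nmr1", g1.start - 900_000, g1.start - 898_000, "+")  # > 815 kb
        l2 = _lnc("L2", "hum1", g2.start - 60_000, g2.start - 58_000, "+")
        assert positional_matches([l1], [l2], [block]) == []

    def test_opposite_sides_do_not_match(self, block):
        g1 = block.anchors[0].sp1
        g2 = block.anchors[0].sp2
        l1 = _lnc("L1", "nmr1", g1.start - 50_000, g1.start - 48_000, "+")
        l2 = _lnc("L2", "hum1", g2.end + 48_000, g2.end + 50_000, "+")
        assert positional_matches([l1], [l2], [block]) == []

    def test_orientation_mismatch_does_not_match(self, block):
        g1 = block.anchors[0].sp1
        g2 = block.anchors[0].sp2
        l1 = _lnc("L1", "nmr1", g1.start - 50_000, g1.start - 48_000, "+")
        l2 = _lnc("L2", "hum1", g2.start - 60_000, g2.start - 58_000, "-")
        assert positional_matches([l1], [l2], [block]) == []

    def test_upstream_follows_gene_strand(self):
        # minus-strand anchor: its 5' end is the right span edge
        pair = OrthologPair(
            sp1=GeneLocus("G1", "nmr1", 1_000_000, 1_020_000, "-", 0),
            sp2=GeneLocus("G2", "hum1", 1_000_000, 1_020_000, "-", 0),
        )
        block = SyntenyBlock(("nmr1", "hum1"), [pair], "collinear")
        l1 = _lnc("L1", "nmr1", 1_060_000, 1_062_000, "-")
        l2 = _lnc("L2", "hum1", 1_070_000, 1_072_000, "-")
        (match,) = positional_matches([l1], [l2], [block])
        assert match.side == "upstream"
        assert match.relative_orientation == "same"

    def test_unknown_strand_lnc_skipped_with_warning(self, block):
        g1 = block.anchors[0].sp1
        l1 = _lnc("L1", "nmr1", g1.start - 50_000, g1.start - 48_000, ".")
        with pytest.warns(UserWarning, match="unknown strand"):
            assert positional_matches([l1], [], [block]) == []

    def test_species_swap_symmetry(self):
        cfg = SimulationConfig(seed=23, synteny_layout=(6, 2, (False, True)))
        anchors, l1, l2, _ = simulate_synteny(cfg)
        blocks = find_synteny_blocks(anchors)
        forward = matched_lnc_pairs(positional_matches(l1, l2, blocks, 815_000, 894_000))
        swapped_blocks = [
            SyntenyBlock(
                scaffold_pair=(b.scaffold_pair[1], b.scaffold_pair[0]),
                anchors=[OrthologPair(sp1=a.sp2, sp2=a.sp1) for a in b.anchors],
                orientation=b.orientation,
            )
            for b in blocks
        ]
        backward = matched_lnc_pairs(
            positional_matches(l2, l1, swapped_blocks, 894_000, 815_000)
        )
        assert forward == {(a, b) for b, a in backward}

    def test_planted_pairs_recovered_exactly(self):
        for seed in (0, 1, 2):
            cfg = SimulationConfig(seed=seed, synteny_layout=(6, 2, (False, True)))
            anchors, l1, l2, truth = simulate_synteny(cfg)
            found = matched_lnc_pairs(
                positional_matches(l1, l2, find_synteny_blocks(anchors))
            )
            assert found == set(truth.syntenic_pairs)
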