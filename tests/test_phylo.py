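"""Cluster detection, representative values, and independent pairing."""

import numpy as np
import pytest

from karyodrive.core import KaryotypeRecord
from karyodrive.phylo import (build_pairs, cluster_value, find_system_clusters,
                              prune_to, read_tree, validate_pair_independence)


def make_record(key, frac, system):
    genus, species = key.split("_", 1)
    two_n = 20
    return KaryotypeRecord(order="O", family="F", genus=genus, species=species,
                           female_2n=two_n, male_2n=two_n, female_nf=30, male_nf=30,
                           female_frac_acro=frac, male_frac_acro=frac, system=system)


class TestReadTree:
    def test_two_tips(self):
        assert sorted(read_tree("(A,B);").tip_labels) == ["A", "B"]

    def test_polytomy_accepted(self):
        assert len(read_tree("((A,B,C),D);").tip_labels) == 4

    def test_duplicate_label_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_tree("(A,(A,B));")

    def test_parse_failure_raises(self):
        with pytest.raises(ValueError, match="parse"):
            read_tree("((A,B);")

    def test_mismatches_reported_as_warnings(self):
        tree = read_tree("(A,(B,C));", expected_species=["A", "B", "D"])
        assert any("C" in w for w in tree.warnings)
        assert any("D" in w for w in tree.warnings)

    def test_reference_tree_matches_table(self, reference_tree):
        assert reference_tree.warnings == []
        assert len(reference_tree.tip_labels) == 41


class TestClusters:
    def test_gazella_and_taterillus_units(self, reference_units):
        by_id = {u.id: u for u in reference_units}
        assert len(by_id["Gazella_XY1Y2"]) == 6
        assert len(by_id["Taterillus_XY1Y2"]) == 6

    def test_nine_xy1y2_units(self, reference_units):
        assert sum(u.system == "XY1Y2" for u in reference_units) == 9

    def test_mus_splits_into_opposite_singletons(self, reference_units):
        mus = sorted(u.id for u in reference_units if u.id.startswith("Mus_"))
        assert mus == ["Mus_X1X2Y", "Mus_XY1Y2"]

    def test_units_partition_the_analysis_tips(self, reference_units, reference_records):
        members = [m for u in reference_units for m in u.member_species]
        assert sorted(members) == sorted(r.key for r in reference_records)

    def test_two_tip_tree_opposite_systems(self):
        tree = read_tree("(A_a,B_b);")
        units = find_system_clusters(tree, {"A_a": "X1X2Y", "B_b": "XY1Y2"})
        assert sorted((u.id, len(u)) for u in units) == [("A_X1X2Y", 1), ("B_XY1Y2", 1)]

    def test_simple_tips_break_clades_but_form_no_units(self):
        tree = read_tree("((A_a,B_b),(C_c,D_d));")
        systems = {"A_a": "X1X2Y", "B_b": "simple", "C_c": "X1X2Y", "D_d": "X1X2Y"}
        units = find_system_clusters(tree, systems)
        assert sorted(u.id for u in units) == ["A_X1X2Y", "C+D_X1X2Y"]

    def test_missing_system_label_rejected(self):
        tree = read_tree("(A_a,B_b);")
        with pytest.raises(ValueError, match="B_b"):
            find_system_clusters(tree, {"A_a": "X1X2Y"})

    def test_every_unit_is_monophyletic(self, reference_tree, reference_units):
        # independent check: the MRCA of each unit's members spans exactly them
        leaves = reference_tree.leaf_by_label()
        for unit in reference_units:
            nodes = [leaves[m] for m in unit.member_species]
            mrca = nodes[0]
            paths = []
            for node in nodes:
                chain = []
                cur = node
                while cur is not None:
                    chain.append(id(cur))
                    cur = cur.parent_node
                paths.append(chain)
            common = set(paths[0]).intersection(*map(set, paths[1:])) if len(paths) > 1 else {id(nodes[0])}
            mrca_node = next(n for n in reference_tree.tree.preorder_node_iter()
                             if id(n) in common and all(id(c) not in common for c in n.child_nodes()))
            spanned = sorted(leaf.taxon.label for leaf in mrca_node.leaf_iter())
            assert spanned == sorted(unit.member_species)


class TestClusterValue:
    def test_gazella_mean(self, reference_units, reference_recmap):
        gazella = next(u for u in reference_units if u.id == "Gazella_XY1Y2")
        assert round(cluster_value(gazella, reference_recmap, "mean"), 3) == 0.138

    def test_singleton_both_modes(self, reference_units, reference_recmap):
        single = next(u for u in reference_units if len(u) == 1)
        expected = reference_recmap[single.member_species[0]].female_frac_acro
        rng = np.random.default_rng(0)
        assert cluster_value(single, reference_recmap, "mean") == expected
        assert cluster_value(single, reference_recmap, "random", rng) == expected

    def test_random_draw_is_a_member_fraction(self, reference_units, reference_recmap):
        gazella = next(u for u in reference_units if u.id == "Gazella_XY1Y2")
        member_fracs = {reference_recmap[m].female_frac_acro for m in gazella.member_species}
        rng = np.random.default_rng(42)
        for _ in range(20):
            assert cluster_value(gazella, reference_recmap, "random", rng) in member_fracs

    def test_random_mode_is_seed_reproducible(self, reference_units, reference_recmap):
        gazella = next(u for u in reference_units if u.id == "Gazella_XY1Y2")
        draws1 = [cluster_value(gazella, reference_recmap, "random", np.random.default_rng(9))
                  for _ in range(5)]
        draws2 = [cluster_value(gazella, reference_recmap, "random", np.random.default_rng(9))
                  for _ in range(5)]
        assert draws1 == draws2

    def test_random_mode_requires_rng(self, reference_units, reference_recmap):
        with pytest.raises(ValueError, match="Generator"):
            cluster_value(reference_units[0], reference_recmap, "random")


class TestPairs:
    def test_packaged_config_yields_nine_valid_pairs(self, reference_pairs):
        assert len(reference_pairs) == 9
        assert all(p.unit_x1x2y.system == "X1X2Y" and p.unit_xy1y2.system == "XY1Y2"
                   for p in reference_pairs)
        used = [u.id for p in reference_pairs for u in (p.unit_x1x2y, p.unit_xy1y2)]
        assert len(used) == len(set(used))

    def test_packaged_pairs_are_edge_disjoint(self, reference_tree, reference_pairs):
        report = validate_pair_independence(reference_tree, reference_pairs)
        assert report.ok
        assert report.shared_edges == ()

    def test_pair_referencing_one_system_twice_rejected(self, reference_tree, reference_units):
        config = [{"x1x2y": "Mus_X1X2Y", "xy1y2": "Mus_X1X2Y"}]
        with pytest.raises(ValueError, match="system"):
            build_pairs(reference_tree, reference_units, config)

    def test_unknown_unit_id_rejected(self, reference_tree, reference_units):
        with pytest.raises(ValueError, match="Nonexistent"):
            build_pairs(reference_tree, reference_units,
                        [{"x1x2y": "Nonexistent_X1X2Y", "xy1y2": "Mus_XY1Y2"}])

    def test_reused_unit_rejected(self, reference_tree, reference_units):
        config = [{"x1x2y": "Mus_X1X2Y", "xy1y2": "Mus_XY1Y2"},
                  {"x1x2y": "Mus_X1X2Y", "xy1y2": "Gazella_XY1Y2"}]
        with pytest.raises(ValueError, match="more than one"):
            build_pairs(reference_tree, reference_units, config)

    def test_automatic_pairing_on_cherry_tree(self):
        tree = read_tree("((X1_a,Y1_b),(X2_c,Y2_d));")
        units = find_system_clusters(tree, {"X1_a": "X1X2Y", "Y1_b": "XY1Y2",
                                            "X2_c": "X1X2Y", "Y2_d": "XY1Y2"})
        pairs = build_pairs(tree, units)
        got = sorted((p.unit_x1x2y.id, p.unit_xy1y2.id) for p in pairs)
        assert got == [("X1_X1X2Y", "Y1_XY1Y2"), ("X2_X1X2Y", "Y2_XY1Y2")]

    def test_single_system_units_give_no_pairs(self):
        tree = read_tree("(A_a,B_b);")
        units = find_system_clusters(tree, {"A_a": "X1X2Y", "B_b": "X1X2Y"})
        assert build_pairs(tree, units) == []

    def test_automatic_pairing_on_reference_data_is_independent(self, reference_tree,
                                                                reference_units):
        pairs = build_pairs(reference_tree, reference_units)
        n_x = sum(u.system == "X1X2Y" for u in reference_units)
        n_y = sum(u.system == "XY1Y2" for u in reference_units)
        assert 0 < len(pairs) <= min(n_x, n_y)
        assert len(pairs) == 9  # equality on the packaged data
        assert validate_pair_independence(reference_tree, pairs).ok
        used = [u.id for p in pairs for u in (p.unit_x1x2y, p.unit_xy1y2)]
        assert len(used) == len(set(used))


class TestIndependenceReport:
    def test_shared_root_edge_detected(self):
        # both pairs must cross the two root edges; simple tips keep the
        # same-system tips from merging into single units
        tree = read_tree("((X1_a,(S1_s,X2_b)),(Y1_c,(S2_t,Y2_d)));")
        units = find_system_clusters(tree, {"X1_a": "X1X2Y", "X2_b": "X1X2Y",
                                            "Y1_c": "XY1Y2", "Y2_d": "XY1Y2",
                                            "S1_s": "simple", "S2_t": "simple"})
        config = [{"x1x2y": "X1_X1X2Y", "xy1y2": "Y1_XY1Y2"},
                  {"x1x2y": "X2_X1X2Y", "xy1y2": "Y2_XY1Y2"}]
        pairs = build_pairs(tree, units, config)
        report = validate_pair_independence(tree, pairs)
        assert not report.ok
        assert len(report.shared_edges) >= 1

    def test_empty_pair_set_is_ok(self, reference_tree):
        assert validate_pair_independence(reference_tree, []).ok


class TestPrune:
    def test_prune_keeps_only_requested_tips(self):
        tree = read_tree("((A_a,B_b),(C_c,D_d));")
        pruned = prune_to(tree, ["A_a", "C_c", "D_d"])
        assert sorted(pruned.tip_labels) == ["A_a", "C_c", "D_d"]

    def test_prune_rejects_unknown_labels(self):
        tree = read_tree("(A_a,B_b);")
        with pytest.raises(ValueError, match="Z_z"):
            prune_to(tree, ["A_a", "Z_z"])
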