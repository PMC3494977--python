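"""Species-tree handling: same-system monophyletic cluster units and
phylogenetically independent cross-system pairs.

Species that share a multiple sex chromosome system are frequently
monophyletic (e.g. the six XY1Y2 gazelles), so treating each species as an
independent observation would count one fusion event many times.  The
comparative procedure therefore collapses each maximal monophyletic set of
tips sharing one system into a single *cluster unit*, represents the unit by
one acrocentric-fraction value (cluster mean, or a randomly drawn member),
and contrasts units across systems in pairs whose connecting tree paths are
edge-disjoint — each contrast then reflects an independent evolutionary
event.

Branch lengths are never required: the packaged tree is topological, and
distances default to node counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .core import KaryotypeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesTree", "ClusterUnit", "ContrastPair", "IndependenceReport",
    "read_tree", "find_system_clusters", "cluster_value",
    "build_pairs", "validate_pair_independence",
]


@dataclass
class SpeciesTree:
    """A rooted species tree with unique tip labels (polytomies allowed)."""

    tree: dendropy.Tree
    warnings: list[str] = field(default_factory=list)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def leaf_by_label(self) -> dict[str, dendropy.Node]:
        return {leaf.taxon.label: leaf for leaf in self.tree.leaf_node_iter()}


def read_tree(newick_text: str, expected_species: Sequence[str] | None = None) -> SpeciesTree:
    """Parse a Newick string into a rooted species tree.

    Tip labels must be unique.  If *expected_species* is given, tips missing
    from it and species missing from the tree are reported as warnings on the
    returned object.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text, schema="newick",
            preserve_underscores=True, rooting="force-rooted",
        )
    except Exception as exc:
        raise ValueError(f"Newick parse failure: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(not lab for lab in labels):
        raise ValueError("tree contains an unlabeled tip")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise ValueError(f"duplicate tip label(s): {', '.join(sorted(dupes))}")
    warnings: list[str] = []
    if expected_species is not None:
        expected = set(expected_species)
        extra = sorted(set(labels) - expected)
        missing = sorted(expected - set(labels))
        if extra:
            warnings.append("tree tips absent from the species table: " + ", ".join(extra))
        if missing:
            warnings.append("table species absent from the tree: " + ", ".join(missing))
        for msg in warnings:
            logger.warning(msg)
    return SpeciesTree(tree=tree, warnings=warnings)


def prune_to(tree: SpeciesTree, labels: Sequence[str]) -> SpeciesTree:
    """Restrict a tree to the given tip labels (e.g. the analysis species,
    dropping simple-system tips from a simulated clade)."""
    keep = set(labels)
    missing = keep - set(tree.tip_labels)
    if missing:
        raise ValueError("labels absent from the tree: " + ", ".join(sorted(missing)))
    pruned = tree.tree.extract_tree_with_taxa_labels(labels=keep)
    pruned.is_rooted = True
    return SpeciesTree(tree=pruned, warnings=list(tree.warnings))


@dataclass(frozen=True)
class ClusterUnit:
    """A maximal monophyletic set of tips sharing one sex-chromosome system."""

    id: str
    member_species: tuple[str, ...]
    system: str

    def __len__(self) -> int:
        return len(self.member_species)


def _unit_id(members: Sequence[str], system: str,
             genus_map: Mapping[str, str] | None) -> str:
    if genus_map is not None:
        genera = sorted({genus_map[m] for m in members})
    else:
        genera = sorted({m.split("_", 1)[0] for m in members})
    return "+".join(genera) + "_" + system


def find_system_clusters(tree: SpeciesTree, system_map: Mapping[str, str],
                         genus_map: Mapping[str, str] | None = None) -> list[ClusterUnit]:
    """Maximal monophyletic same-system tip sets, found bottom-up.

    Every tip must appear in *system_map*.  A node roots a cluster when all
    tips below it share one system and no larger clade containing it does.
    Tips labelled ``simple`` take part in the monophyly computation (they
    break up multiple-system clades) but form no units of their own.
    Unit ids join the members' genera (from *genus_map*, or the label prefix
    before the first underscore) with the shared system.
    """
    for label in tree.tip_labels:
        if label not in system_map:
            raise ValueError(f"tree tip {label!r} has no sex-chromosome system label")
    systems_below: dict[int, set[str]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            systems_below[id(node)] = {system_map[node.taxon.label]}
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= systems_below[id(child)]
            systems_below[id(node)] = acc
    units: list[ClusterUnit] = []
    for node in tree.tree.preorder_node_iter():
        pure = len(systems_below[id(node)]) == 1
        parent_pure = (node.parent_node is not None
                       and len(systems_below[id(node.parent_node)]) == 1)
        if pure and not parent_pure:
            system = next(iter(systems_below[id(node)]))
            if system == "simple":
                continue
            members = tuple(sorted(leaf.taxon.label for leaf in node.leaf_iter()))
            units.append(ClusterUnit(_unit_id(members, system, genus_map), members, system))
    units.sort(key=lambda u: u.id)
    return units


def cluster_value(unit: ClusterUnit, records: Mapping[str, KaryotypeRecord],
                  mode: str = "mean", rng: np.random.Generator | None = None,
                  sex: str = "female") -> float:
    """Representative acrocentric fraction of a cluster unit.

    ``mean`` averages the members; ``random`` draws one member uniformly
    (a seeded generator is required).
    """
    if len(unit) == 0:
        raise ValueError("cluster unit has no members")
    fractions = [records[m].frac_acro(sex) for m in sorted(unit.member_species)]
    if mode == "mean":
        return float(sum(fractions)) / len(fractions)
    if mode == "random":
        if rng is None:
            raise ValueError("random mode requires a seeded numpy Generator")
        return float(fractions[int(rng.integers(len(fractions)))])
    raise ValueError(f"mode must be 'mean' or 'random', got {mode!r}")


@dataclass(frozen=True)
class ContrastPair:
    """One X1X2Y cluster unit contrasted with one XY1Y2 cluster unit."""

    unit_x1x2y: ClusterUnit
    unit_xy1y2: ClusterUnit

    def difference(self, records: Mapping[str, KaryotypeRecord], mode: str = "mean",
                   rng: np.random.Generator | None = None, sex: str = "female") -> float:
        """X1X2Y representative minus XY1Y2 representative."""
        return (cluster_value(self.unit_x1x2y, records, mode, rng, sex)
                - cluster_value(self.unit_xy1y2, records, mode, rng, sex))


def _depths(tree: dendropy.Tree) -> dict[int, int]:
    depth: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1
    return depth


def _unit_root(tree: SpeciesTree, unit: ClusterUnit,
               leaves: Mapping[str, dendropy.Node],
               depth: Mapping[int, int]) -> dendropy.Node:
    """MRCA node of a unit's members (the leaf itself for singletons)."""
    nodes = [leaves[m] for m in unit.member_species]
    mrca = nodes[0]
    for other in nodes[1:]:
        a, b = mrca, other
        while id(a) != id(b):
            if depth[id(a)] >= depth[id(b)]:
                a = a.parent_node
            else:
                b = b.parent_node
        mrca = a
    return mrca


def _path_edges(node_a: dendropy.Node, node_b: dendropy.Node,
                depth: Mapping[int, int]) -> list[dendropy.Node]:
    """Edges on the tree path between two nodes, each edge named by its
    child node."""
    edges: list[dendropy.Node] = []
    a, b = node_a, node_b
    while id(a) != id(b):
        if depth[id(a)] >= depth[id(b)]:
            edges.append(a)
            a = a.parent_node
        else:
            edges.append(b)
            b = b.parent_node
    return edges


def _node_count_distance(node_a, node_b, depth) -> int:
    return len(_path_edges(node_a, node_b, depth))


def build_pairs(tree: SpeciesTree, units: Sequence[ClusterUnit],
                explicit_pairs: Sequence[Mapping[str, str]] | None = None) -> list[ContrastPair]:
    """Construct phylogenetically independent cross-system contrast pairs.

    With *explicit_pairs* (a list of ``{"x1x2y": id, "xy1y2": id}``), the
    configuration is validated — opposite systems, every unit used at most
    once — and returned in config order.

    Without it, pairing is automatic: walking the tree in post-order,
    whenever a subtree holds at least one unpaired unit of each system the
    closest cross-system pair (node-count patristic distance between the
    units' clade roots, ties broken lexicographically by unit id) is paired,
    and every unpaired unit inside the paired subtree is retired so that no
    later pair's path can reuse its edges.
    """
    by_id = {u.id: u for u in units}
    if len(by_id) != len(units):
        raise ValueError("duplicate cluster unit ids")
    if explicit_pairs is not None:
        pairs: list[ContrastPair] = []
        used: set[str] = set()
        for entry in explicit_pairs:
            for key, system in (("x1x2y", "X1X2Y"), ("xy1y2", "XY1Y2")):
                uid = entry.get(key)
                if uid is None:
                    raise ValueError(f"pair entry missing the {key!r} unit id: {entry}")
                if uid not in by_id:
                    raise ValueError(f"unknown cluster unit id {uid!r}")
                if by_id[uid].system != system:
                    raise ValueError(
                        f"unit {uid!r} has system {by_id[uid].system}, expected {system}")
                if uid in used:
                    raise ValueError(f"unit {uid!r} appears in more than one pair")
                used.add(uid)
            pairs.append(ContrastPair(by_id[entry["x1x2y"]], by_id[entry["xy1y2"]]))
        return pairs

    depth = _depths(tree.tree)
    leaves = tree.leaf_by_label()
    roots = {u.id: _unit_root(tree, u, leaves, depth) for u in units}
    # ancestor chain (inclusive) per unit root, for subtree membership tests
    ancestors: dict[str, set[int]] = {}
    for uid, node in roots.items():
        chain = set()
        cur = node
        while cur is not None:
            chain.add(id(cur))
            cur = cur.parent_node
        ancestors[uid] = chain

    unpaired = {u.id for u in units}
    pairs = []
    for node in tree.tree.postorder_node_iter():
        while True:
            inside = [uid for uid in sorted(unpaired) if id(node) in ancestors[uid]]
            xs = [uid for uid in inside if by_id[uid].system == "X1X2Y"]
            ys = [uid for uid in inside if by_id[uid].system == "XY1Y2"]
            if not xs or not ys:
                break
            best = min(
                ((_node_count_distance(roots[x], roots[y], depth), x, y)
                 for x in xs for y in ys),
                key=lambda t: (t[0], t[1], t[2]),
            )
            _, x_id, y_id = best
            pairs.append(ContrastPair(by_id[x_id], by_id[y_id]))
            # retire everything under the paired subtree (the pair's MRCA)
            mrca = _unit_root(
                tree,
                ClusterUnit("_tmp", by_id[x_id].member_species + by_id[y_id].member_species,
                            "X1X2Y"),
                leaves, depth)
            unpaired -= {uid for uid in unpaired if id(mrca) in ancestors[uid]}
    if not pairs:
        logger.warning("no cross-system pairs could be formed (all units share one system?)")
    return pairs


@dataclass(frozen=True)
class IndependenceReport:
    ok: bool
    shared_edges: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.ok


def validate_pair_independence(tree: SpeciesTree, pairs: Sequence[ContrastPair]) -> IndependenceReport:
    """Check that no tree edge lies on the connecting path of more than one
    pair (paths run between the two units' member-spanning clades)."""
    depth = _depths(tree.tree)
    leaves = tree.leaf_by_label()
    edge_users: dict[int, list[str]] = {}
    edge_name: dict[int, str] = {}
    for pair in pairs:
        ra = _unit_root(tree, pair.unit_x1x2y, leaves, depth)
        rb = _unit_root(tree, pair.unit_xy1y2, leaves, depth)
        pair_name = f"{pair.unit_x1x2y.id}|{pair.unit_xy1y2.id}"
        for child in _path_edges(ra, rb, depth):
            edge_users.setdefault(id(child), []).append(pair_name)
            if id(child) not in edge_name:
                below = sorted(leaf.taxon.label for leaf in child.leaf_iter())
                edge_name[id(child)] = f"edge_above({below[0]}{'+%d' % (len(below) - 1) if len(below) > 1 else ''})"
    shared = tuple(
        f"{edge_name[e]} used by {', '.join(users)}"
        for e, users in sorted(edge_users.items(), key=lambda kv: edge_name[kv[0]])
        if len(users) > 1
    )
    return IndependenceReport(ok=not shared, shared_edges=shared)
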