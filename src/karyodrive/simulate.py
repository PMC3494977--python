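"""Generative model of karyotype and neo-sex-chromosome evolution under
female meiotic drive.

The simulator produces the three analysis inputs — a karyotype table, a
species tree, and implicit system labels — with the statistical structure
the comparative pipeline assumes, so that every stage can be exercised and
calibrated without real data.

Model sketch.  A pure-birth (Yule) tree is simulated; each lineage carries a
karyotype state (A acrocentric autosome pairs, B biarmed autosome pairs) and
a drive coefficient d.  Eggs retain only one meiotic product, so biased
segregation of fusion heterozygotes maps a signed drive coefficient to a
fixation probability through the logistic function sigma(2d) = 1/(1+e^(-2d)):
d > 0 means female meiosis favours biarmed (fused) chromosomes, d = 0 is
neutral (probability 1/2).  Along a branch of length t, Poisson(rho*t)
rearrangement attempts occur; each proposes a centromeric fusion (two
acrocentric pairs -> one biarmed pair, requires A >= 2, fixes with
probability sigma(2d)) or a fission (the reverse, requires B >= 1, fixes
with probability sigma(-2d)), the proposal type drawn proportional to
availability (A(A-1) vs B).  Every fusion/fission conserves the total arm
count; only the chromosome number changes.  The drive coefficient is
inherited and occasionally redrawn from a two-component mixture {+d, -d},
which drives lineages toward the two ends of the acrocentric-fraction range
and reproduces the bimodality seen in real mammal compilations.

Sex-chromosome fusions arise at rate mu * A/(A+B) per unit branch length
(only acrocentrics can fuse, so acrocentric-rich karyotypes mutate more
often).  An arising fusion involves the X or the Y with equal probability;
an X-autosome fusion must pass female meiosis and fixes with probability
sigma(2d), whereas a Y-autosome fusion is male-limited, never sees female
drive, and fixes with probability 1/2.  The first fixed event sets the
lineage's system permanently — XY1Y2 for an X-fusion, X1X2Y for a Y-fusion —
and consumes one acrocentric autosome pair.

This machinery is a deliberately minimal operationalisation used for
pipeline testing; it makes no claim to quantitative realism about mammalian
population genetics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .core import KaryotypeRecord, write_karyotype_table
from .phylo import SpeciesTree, build_pairs, find_system_clusters
from .pipeline import paired_comparison

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams", "KaryotypeState", "simulate_yule_tree", "evolve_karyotypes",
    "assign_sex_systems", "tip_records", "emit_dataset", "generate_dataset",
    "type_i_error_experiment", "sign_recovery_experiment", "sign_recovery_grid",
]


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated clade.

    Defaults are sized to give mammal-like structure: a few dozen species,
    acrocentric fractions spanning [0, 1] with two modes under strong drive
    heterogeneity, and same-system clusters of realistic size.
    """

    n_tips: int = 48
    birth_rate: float = 1.0               # Yule speciation rate, per unit time
    ancestral_acro_pairs: int = 16        # A0: acrocentric-rich ancestral karyotype
    ancestral_biarm_pairs: int = 4        # B0
    rearrange_rate: float = 6.0           # rho: fusion/fission attempts per unit branch
    drive_bias: float = 3.0               # |d| of the two mixture components
    drive_pos_weight: float = 0.5         # P(component +d) at each redraw
    drive_switch_prob: float = 0.15       # per-branch probability of redrawing d
    sex_fusion_rate: float = 1.0          # mu: sex-autosome fusion attempts per unit branch
    seed: int = 0

    @classmethod
    def null_calibration(cls, **overrides) -> "SimParams":
        """Conditions for size (type-I error) calibration: no drive, so
        fusion/fission and X/Y fixation probabilities are all 1/2 and system
        type is independent of karyotype.  A larger clade gives enough
        cross-system cluster units for the paired test to resolve."""
        base = dict(n_tips=192, drive_bias=0.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def drive_regime(cls, **overrides) -> "SimParams":
        """Conditions with strong drive heterogeneity (mixture of strongly
        biarm-favoring and strongly acrocentric-favoring lineages)."""
        base = dict(n_tips=96, drive_bias=3.0)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.ancestral_acro_pairs < 0 or self.ancestral_biarm_pairs < 0:
            raise ValueError("ancestral pair counts must be non-negative")
        if self.ancestral_acro_pairs + self.ancestral_biarm_pairs < 2:
            raise ValueError("need at least two ancestral autosome pairs")
        if self.rearrange_rate < 0 or self.sex_fusion_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.drive_pos_weight <= 1.0):
            raise ValueError("drive_pos_weight must lie in [0, 1]")
        if not (0.0 <= self.drive_switch_prob <= 1.0):
            raise ValueError("drive_switch_prob must lie in [0, 1]")


@dataclass
class KaryotypeState:
    """Per-lineage autosome composition and sex-chromosome system."""

    A: int                      # acrocentric autosome pairs
    B: int                      # biarmed autosome pairs
    system: str = "simple"
    drive: float = 0.0          # lineage drive coefficient d

    @property
    def arm_pairs(self) -> int:
        """Autosomal arm count per haploid set — invariant under fusion/fission."""
        return self.A + 2 * self.B


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> SpeciesTree:
    """Pure-birth tree with *n_tips* labelled tips and exponential branch
    lengths; bit-reproducible for a fixed seed."""
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node
    root.edge.length = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    # let the pendant edges run to the next (discarded) speciation event
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length += wait
    for i, node in enumerate(sorted(active, key=lambda n: _leafsort_key(n)), start=1):
        taxon = taxon_namespace.new_taxon(label=f"G{i:03d}_sp{i:03d}")
        node.taxon = taxon
    return SpeciesTree(tree=tree)


def _leafsort_key(node: dendropy.Node):
    """Deterministic leaf order: position in a preorder traversal."""
    path = []
    cur = node
    while cur.parent_node is not None:
        path.append(cur.parent_node.child_nodes().index(cur))
        cur = cur.parent_node
    return tuple(reversed(path))


def evolve_karyotypes(tree: SpeciesTree, params: SimParams,
                      rng: np.random.Generator | None = None) -> dict[str, KaryotypeState]:
    """Evolve (A, B) and the drive coefficient along every branch.

    Returns the tip states; intermediate node states are cached on the tree
    nodes (attribute ``sim_state``) for the sex-system pass.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    root = tree.tree.seed_node
    d0 = params.drive_bias if rng.random() < params.drive_pos_weight else -params.drive_bias
    root.sim_state = KaryotypeState(params.ancestral_acro_pairs,
                                    params.ancestral_biarm_pairs, drive=d0)
    tips: dict[str, KaryotypeState] = {}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            state = node.sim_state
        else:
            parent_state: KaryotypeState = node.parent_node.sim_state
            d = parent_state.drive
            if rng.random() < params.drive_switch_prob:
                d = params.drive_bias if rng.random() < params.drive_pos_weight else -params.drive_bias
            A, B = parent_state.A, parent_state.B
            t = node.edge.length or 0.0
            n_attempts = int(rng.poisson(params.rearrange_rate * t))
            for _ in range(n_attempts):
                w_fusion = A * (A - 1)
                w_fission = B
                total = w_fusion + w_fission
                if total == 0:
                    continue
                if rng.random() < w_fusion / total:
                    if rng.random() < _sigmoid(2 * d):     # drive favours the biarmed product
                        A -= 2
                        B += 1
                else:
                    if rng.random() < _sigmoid(-2 * d):
                        B -= 1
                        A += 2
            state = KaryotypeState(A, B, drive=d)
            node.sim_state = state
        if node.is_leaf():
            tips[node.taxon.label] = state
    return tips


def assign_sex_systems(tree: SpeciesTree, states: Mapping[str, KaryotypeState],
                       params: SimParams,
                       rng: np.random.Generator | None = None) -> dict[str, str]:
    """Place sex-autosome fusion events on the tree and fix systems.

    Requires :func:`evolve_karyotypes` to have annotated the tree.  The
    fusion-attempt rate on a branch uses the branch-start karyotype (rate
    resolution is one branch).  System states are absorbing: the first fixed
    event decides the lineage and all its descendants.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    root = tree.tree.seed_node
    if not hasattr(root, "sim_state"):
        raise ValueError("tree has no simulated karyotype states; run evolve_karyotypes first")
    systems: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            node.sim_system = "simple"
        else:
            system = node.parent_node.sim_system
            if system == "simple":
                parent_state: KaryotypeState = node.parent_node.sim_state
                A, B = parent_state.A, parent_state.B
                t = node.edge.length or 0.0
                rate = params.sex_fusion_rate * (A / (A + B)) if (A + B) > 0 and A > 0 else 0.0
                for _ in range(int(rng.poisson(rate * t))):
                    d = node.sim_state.drive
                    if rng.random() < 0.5:
                        # X-autosome fusion: the fused biarmed neo-X must
                        # survive female meiosis
                        if rng.random() < _sigmoid(2 * d):
                            system = "XY1Y2"
                            break
                    else:
                        # Y-autosome fusion: male-limited, drive-free
                        if rng.random() < 0.5:
                            system = "X1X2Y"
                            break
            node.sim_system = system
        if node.is_leaf():
            label = node.taxon.label
            systems[label] = node.sim_system
            states[label].system = node.sim_system
    return systems


def tip_records(tree: SpeciesTree, states: Mapping[str, KaryotypeState]) -> list[KaryotypeRecord]:
    """Render simulated tip states as karyotype records in the table schema.

    Conventions: the sex pair is biarmed and contributes a constant to 2n
    and NF (female 2n = 2(A+B)+2, NF = 2(A+2B)+2); a fixed fusion system has
    consumed one acrocentric autosome pair; males carry one chromosome fewer
    (X1X2Y) or one more (XY1Y2) than females, with the male NF clamped into
    the arm-count bounds.  The printed fraction is exactly A/(A+B).
    """
    records = []
    for label in sorted(states):
        st = states[label]
        A, B = st.A, st.B
        if st.system in ("X1X2Y", "XY1Y2") and A >= 1 and A + B >= 2:
            A -= 1          # the fused autosome pair joined the sex pair
        genus, species = label.split("_", 1)
        f2n = 2 * (A + B) + 2
        fnf = 2 * (A + 2 * B) + 2
        frac = A / (A + B)
        if st.system == "X1X2Y":
            m2n = f2n - 1
        elif st.system == "XY1Y2":
            m2n = f2n + 1
        else:
            m2n = f2n
        mnf = min(max(fnf, m2n), 2 * m2n)
        records.append(KaryotypeRecord(
            order="Simulata", family="Simulatidae", genus=genus, species=species,
            female_2n=f2n, male_2n=m2n, female_nf=fnf, male_nf=mnf,
            female_frac_acro=frac, male_frac_acro=frac,
            system=st.system, source="simulated"))
    return records


def emit_dataset(tree: SpeciesTree, states: Mapping[str, KaryotypeState],
                 systems: Mapping[str, str], out_dir: str | Path,
                 params: SimParams | None = None) -> dict[str, Path]:
    """Write the simulated dataset: analysis TSV (multiple-system tips only),
    Newick tree, and a truth JSON with parameters and per-tip states."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = tip_records(tree, states)
    analysis = [r for r in records if r.system in ("X1X2Y", "XY1Y2")]
    table_path = out_dir / "karyotypes.tsv"
    write_karyotype_table(analysis, table_path)
    tree_path = out_dir / "tree.nwk"
    newick = tree.tree.as_string(schema="newick", suppress_rooting=True)
    tree_path.write_text(newick, encoding="utf-8")
    truth = {
        "params": asdict(params) if params is not None else None,
        "tips": {label: {"A": st.A, "B": st.B, "system": st.system, "drive": st.drive}
                 for label, st in sorted(states.items())},
        "system_counts": {s: sum(1 for v in systems.values() if v == s)
                          for s in ("simple", "X1X2Y", "XY1Y2")},
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    logger.info("simulated dataset written to %s (%d analysis species)", out_dir, len(analysis))
    return {"table": table_path, "tree": tree_path, "truth": truth_path}


def generate_dataset(params: SimParams, seed: int | None = None):
    """Simulate one full dataset in memory.

    Returns ``(tree, states, systems, records)`` where *records* contains
    only the multiple-system tips (the analysis table).
    """
    base = params.seed if seed is None else seed
    tree = simulate_yule_tree(params.n_tips, params.birth_rate, base)
    rng = np.random.default_rng(base + 10_007)
    states = evolve_karyotypes(tree, params, rng)
    systems = assign_sex_systems(tree, states, params, rng)
    records = [r for r in tip_records(tree, states) if r.system in ("X1X2Y", "XY1Y2")]
    return tree, states, systems, records


def _dataset_with_pairs(params: SimParams, seed: int, min_pairs: int,
                        max_attempts: int = 500):
    """Draw datasets until both systems are present and at least *min_pairs*
    independent pairs can be formed."""
    for attempt in range(max_attempts):
        tree, states, systems, records = generate_dataset(params, seed + 1_000_003 * attempt)
        present = {r.system for r in records}
        if present != {"X1X2Y", "XY1Y2"}:
            continue
        # simple-system tips stay in the tree: they separate same-system
        # clades exactly as unsampled lineages do in real data
        units = find_system_clusters(tree, systems)
        pairs = build_pairs(tree, units)
        if len(pairs) >= min_pairs:
            return tree, records, pairs
    raise RuntimeError(
        f"could not generate a dataset with >= {min_pairs} independent pairs "
        f"in {max_attempts} attempts; raise sex_fusion_rate or n_tips")


def type_i_error_experiment(null_params: SimParams, reps: int = 1000,
                            alpha: float = 0.05, seed: int = 0,
                            min_pairs: int = 7) -> dict:
    """Empirical size of the mean-mode paired exact test under the no-drive,
    no-association null.

    *null_params* must encode the null (drive_bias == 0, so fusion, fission
    and X/Y fixation probabilities are all 1/2 and system type is independent
    of karyotype).  Replicates are conditioned on producing at least
    *min_pairs* independent pairs, because with fewer than six informative
    pairs the exact test's smallest attainable p-value exceeds 0.05 and the
    test cannot reject at all.
    """
    null_params.validate()
    if null_params.drive_bias != 0.0:
        raise ValueError("null_params must set drive_bias = 0 (no drive, no association)")
    if reps < 2:
        raise ValueError("reps must be at least 2")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
    rejections = 0
    n_pairs_seen = []
    for rep_seed in rep_seeds:
        tree, records, pairs = _dataset_with_pairs(null_params, int(rep_seed), min_pairs)
        result = paired_comparison(records, tree, pairs, mode="mean")
        n_pairs_seen.append(len(pairs))
        if result.p_two_sided <= alpha:
            rejections += 1
    rate = rejections / reps
    mc_se = math.sqrt(max(rate * (1 - rate), alpha * (1 - alpha)) / reps)
    return {"rejection_rate": rate, "mc_se": mc_se, "reps": reps, "alpha": alpha,
            "mean_n_pairs": float(np.mean(n_pairs_seen))}


def sign_recovery_experiment(drive_params: SimParams, reps: int = 100,
                             seed: int = 0) -> float:
    """Fraction of replicates in which the X1X2Y group's mean acrocentric
    fraction exceeds the XY1Y2 group's (the predicted direction under
    drive heterogeneity)."""
    drive_params.validate()
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=reps)
    hits = 0
    for rep_seed in rep_seeds:
        for attempt in range(500):
            _, _, _, records = generate_dataset(drive_params, int(rep_seed) + 1_000_003 * attempt)
            if {r.system for r in records} == {"X1X2Y", "XY1Y2"}:
                break
        else:
            raise RuntimeError("could not generate a dataset with both systems present")
        mean_x = np.mean([r.female_frac_acro for r in records if r.system == "X1X2Y"])
        mean_y = np.mean([r.female_frac_acro for r in records if r.system == "XY1Y2"])
        if mean_x > mean_y:
            hits += 1
    return hits / reps


def sign_recovery_grid(base_params: SimParams, magnitudes: list[float],
                       reps: int = 100, seed: int = 0) -> list[float]:
    """Sign-recovery fraction over an increasing drive-strength grid, with
    common random numbers across grid points."""
    from dataclasses import replace
    return [sign_recovery_experiment(replace(base_params, drive_bias=float(m)), reps, seed)
            for m in magnitudes]
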