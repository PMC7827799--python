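"""Synthetic clade-labelled alignments with known ground truth.

Emulates the study design behind the pipeline: a family of homologs evolved
on a tree, stratified into taxonomic clades, with designated slowly-evolving
(conserved) sites and clade-restricted sequence motifs planted at known
positions.  Because every site's true relative rate and every planted motif
is recorded in a :class:`TruthTable`, each downstream stage can be tested
against known answers.

Simulations are gap-free (indels are out of scope; gap handling is exercised
with hand-made fixtures) and motif planting overwrites residues after
evolution, so planted windows match their pattern exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation_core import AA_INDEX, N_STATES, SubstitutionModel, default_model
from .io_formats import AMINO_ACIDS, Alignment, CladeTable, PhyloTree, tree_from_newick

#: mean of the exponential branch-length distribution (substitutions/site)
MEAN_BRANCH_LENGTH = 0.1

#: default clade composition: the study's taxonomic mix scaled to 60 taxa
DEFAULT_CLADE_PLAN = {
    "mammal": 11,
    "bird": 1,
    "reptile": 2,
    "amphibian": 3,
    "fish": 42,
    "invertebrate": 1,
}


@dataclass(frozen=True)
class MotifPlant:
    """A residue string to overwrite at fixed columns in chosen clades."""

    clades: frozenset[str]
    start: int  # 1-based first column
    residues: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("plant start must be >= 1")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"plant residues outside the amino-acid alphabet: {bad}")

    @property
    def positions(self) -> range:
        return range(self.start, self.start + len(self.residues))


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines a synthetic dataset, including the seed.

    ``site_blocks`` lists (n_sites, true_rate) blocks laid out left to right;
    alternatively ``alpha_true`` draws i.i.d. gamma(alpha, mean 1) site rates.
    The default is the two-rate design used throughout the test-bed: 10% of
    sites frozen at rate 0.1 against a background of 1.5.
    """

    n_taxa: int = 60
    site_blocks: tuple[tuple[int, float], ...] | None = ((30, 0.1), (270, 1.5))
    alpha_true: float | None = None
    n_sites: int | None = None  # required with alpha_true
    clade_plan: Mapping[str, int] | None = None
    motif_plants: tuple[MotifPlant, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if (self.site_blocks is None) == (self.alpha_true is None):
            raise ValueError("specify exactly one of site_blocks or alpha_true")
        if self.site_blocks is not None:
            if sum(n for n, _ in self.site_blocks) <= 0:
                raise ValueError("total number of sites must be positive")
            if any(r <= 0 for _, r in self.site_blocks):
                raise ValueError("all site rates must be positive")
        else:
            if self.alpha_true <= 0:
                raise ValueError("alpha_true must be positive")
            if not self.n_sites or self.n_sites <= 0:
                raise ValueError("n_sites must be positive with alpha_true")

    @property
    def total_sites(self) -> int:
        if self.site_blocks is not None:
            return sum(n for n, _ in self.site_blocks)
        return self.n_sites


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for one simulated dataset."""

    rates: np.ndarray  # per-site true relative rate
    plants: tuple[MotifPlant, ...] = ()

    def conserved_mask(self, threshold: float = 1.0) -> np.ndarray:
        return self.rates < threshold


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int, seed: int, mean_branch: float = MEAN_BRANCH_LENGTH
) -> PhyloTree:
    """Pure-birth (Yule) topology with i.i.d. exponential branch lengths.

    Grown by repeatedly splitting a uniformly chosen extant lineage, the
    standard constructive form of the Yule process.  Leaves are labelled
    ``t1..tN`` in the order the tree lists them; deterministic given ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    # nodes as nested lists; leaves are integer placeholders
    next_id = [0, 1]
    topo: list = [0, 1]
    leaves = [topo]  # parent lists holding splittable leaf slots
    slots = [(topo, 0), (topo, 1)]
    while len(slots) < n_taxa:
        parent, idx = slots.pop(rng.integers(len(slots)))
        a, b = len(next_id), len(next_id) + 1
        next_id.extend([a, b])
        child: list = [a, b]
        parent[idx] = child
        slots.append((child, 0))
        slots.append((child, 1))

    counter = [0]

    def to_newick(node) -> str:
        t = rng.exponential(mean_branch)
        if isinstance(node, list):
            inner = ",".join(to_newick(c) for c in node)
            return f"({inner}):{t:.10f}"
        counter[0] += 1
        return f"t{counter[0]}:{t:.10f}"

    left = to_newick(topo[0])
    right = to_newick(topo[1])
    return tree_from_newick(f"({left},{right});")


def assign_clades(
    tree: PhyloTree, clade_plan: Mapping[str, int] | None = None
) -> CladeTable:
    """Partition leaves into labelled clades by tree traversal order.

    Contiguous blocks of leaves in the tree's own leaf order approximate
    monophyletic groups on a pure-birth tree, mimicking real taxonomy.
    """
    plan = dict(clade_plan or DEFAULT_CLADE_PLAN)
    labels = tree.leaf_labels
    if sum(plan.values()) != len(labels):
        raise ValueError(
            f"clade plan covers {sum(plan.values())} taxa, tree has {len(labels)}"
        )
    mapping: dict[str, str] = {}
    pos = 0
    for clade, count in plan.items():
        for sid in labels[pos : pos + count]:
            mapping[sid] = clade
        pos += count
    return CladeTable(mapping)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _sample_states(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draw, one state per row of probabilities."""
    prob_rows = np.clip(prob_rows, 0.0, None)
    cdf = np.cumsum(prob_rows, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random(prob_rows.shape[0])
    return (cdf < u[:, None]).sum(axis=1).astype(np.int8)


def simulate_alignment(
    tree: PhyloTree,
    config: SimulationConfig,
    model: SubstitutionModel | None = None,
) -> tuple[Alignment, TruthTable]:
    """Evolve sites down the tree at their true rates; return data + truth.

    The root is drawn from the model's stationary frequencies pi and each
    site s evolves independently with transition matrices P(t * r_s) along
    every branch of length t.  Motif plants from the config are applied
    afterwards (overwrite semantics).  Deterministic given ``config.seed``.
    """
    model = model or default_model()
    rng = np.random.default_rng(config.seed)
    if config.site_blocks is not None:
        rates = np.concatenate(
            [np.full(n, r, dtype=float) for n, r in config.site_blocks]
        )
    else:
        rates = rng.gamma(config.alpha_true, 1.0 / config.alpha_true, config.n_sites)
        rates = np.maximum(rates, 1e-8)
    n_sites = len(rates)

    lam, U, Uinv = model._eig
    root_states = _sample_states(np.tile(model.pi, (n_sites, 1)), rng)
    states: dict[object, np.ndarray] = {tree.tree.seed_node: root_states}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            pass
        else:
            t = node.edge.length or 0.0
            parent_states = states[node.parent_node]
            # rows of P(t*r_s) for each site's parent state, all sites at once:
            # P = U diag(exp(lam t r)) Uinv  =>  row_a = (U[a] * e) @ Uinv
            e = np.exp(np.outer(rates * t, lam))  # (n_sites, 20)
            rows = (U[parent_states] * e) @ Uinv
            states[node] = _sample_states(rows, rng)
        if node.is_leaf():
            leaf_states[node.taxon.label] = states[node]
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records = tuple(
        (sid, aa[leaf_states[sid]].tobytes().decode()) for sid in tree.leaf_labels
    )
    alignment = Alignment(records)
    truth = TruthTable(rates=rates, plants=config.motif_plants)
    return alignment, truth


def plant_motif(
    alignment: Alignment, clade_table: CladeTable, plant: MotifPlant
) -> Alignment:
    """Overwrite the plant's residues in every sequence of the listed clades.

    Sequences outside the clades are untouched.  Overlapping plants applied
    in sequence follow last-writer-wins.
    """
    if plant.start + len(plant.residues) - 1 > alignment.n_cols:
        raise ValueError(
            f"plant at columns {plant.start}-{plant.start + len(plant.residues) - 1} "
            f"exceeds alignment width {alignment.n_cols}"
        )
    target = {
        sid for sid, lab in clade_table.mapping.items() if lab in plant.clades
    }
    lo = plant.start - 1
    hi = lo + len(plant.residues)
    records = tuple(
        (sid, seq[:lo] + plant.residues + seq[hi:]) if sid in target else (sid, seq)
        for sid, seq in alignment.records
    )
    return Alignment(records)


def simulate_dataset(
    config: SimulationConfig, model: SubstitutionModel | None = None
) -> tuple[Alignment, PhyloTree, CladeTable, TruthTable]:
    """One-call generator: tree, alignment, clade labels and truth."""
    tree = simulate_tree(config.n_taxa, config.seed)
    alignment, truth = simulate_alignment(tree, config, model=model)
    plan = config.clade_plan
    if plan is None and config.n_taxa != sum(DEFAULT_CLADE_PLAN.values()):
        # scale the default composition to the requested taxon count
        total = sum(DEFAULT_CLADE_PLAN.values())
        items = sorted(DEFAULT_CLADE_PLAN.items(), key=lambda kv: kv[1])
        if config.n_taxa < len(items):
            # too few taxa for the full composition: one clade per taxon
            plan = {c: 1 for c, _ in items[-config.n_taxa:]}
        else:
            plan = {}
            acc = 0
            for clade, count in items[:-1]:
                k = max(1, int(config.n_taxa * count / total))
                plan[clade] = k
                acc += k
            plan[items[-1][0]] = config.n_taxa - acc  # largest clade absorbs remainder
        plan = {c: n for c, n in plan.items() if n > 0}
    clades = assign_clades(tree, plan)
    for p in config.motif_plants:
        alignment = plant_motif(alignment, clades, p)
    return alignment, tree, clades, truth
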