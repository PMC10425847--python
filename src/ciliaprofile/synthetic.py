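"""Synthetic evolution of gene presence/absence on a species tree.

The generator emulates the data-generating process the pipeline is built
for: a rooted eukaryotic species tree with the major groups as clades and a
prokaryotic outgroup clade; cilia ancestrally present and lost independently
on a configurable number of branches (Dollo, no regain); functional gene
modules (core biogenesis, motility machinery, BBSome) whose members
disappear wherever the structure they build was lost; a large background of
conserved genes subject to sporadic per-branch loss; and detection noise —
false-negative ortholog calls mimicking sequence divergence plus rare false
positives.  It can also fabricate directional alignment-hit tables whose
BBH round-trip reproduces a given matrix exactly, so the orthology layer is
testable without running any alignment search.

All randomness flows from the single ``rng_seed``; identical configs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import GeneMap, HitRecord, SpeciesAnnotation
from .orthology import BBHParameters, ProfileMatrix

#: Study-shaped genome panel: 147 eukaryotes spread over eight major groups
#: plus 12 prokaryotic outgroups.
DEFAULT_N_SPECIES: dict[str, int] = {
    "opisthokonta": 40,
    "amoebozoa": 8,
    "archaeplastida": 25,
    "rhizaria": 4,
    "alveolata": 20,
    "stramenopila": 20,
    "discicristata": 15,
    "cryptophyta_haptophyta": 15,
    "prokaryote": 12,
}


@dataclass(frozen=True)
class ModuleSpec:
    """A functional gene module co-lost with a structure.

    ``lost_with`` is "cilia" (gene absent wherever cilia were lost) or
    "motility" (absent additionally wherever cilia became immotile).
    """

    name: str
    size: int
    lost_with: str = "cilia"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if self.lost_with not in ("cilia", "motility"):
            raise ValueError(f"unknown trait {self.lost_with!r}")


#: Default module structure: a large biogenesis core, a motility-specific
#: block and the small BBSome — 300 ciliary genes in total.
DEFAULT_MODULES: tuple[ModuleSpec, ...] = (
    ModuleSpec("biogenesis", 240, "cilia"),
    ModuleSpec("motility", 40, "motility"),
    ModuleSpec("bbsome", 20, "cilia"),
)


@dataclass
class SimulationConfig:
    """Everything the simulator needs; rng_seed is mandatory."""

    rng_seed: int
    n_species: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SPECIES))
    n_background_genes: int = 4700
    module_specs: Sequence[ModuleSpec] = DEFAULT_MODULES
    n_cilium_losses: int = 13
    n_motility_only_losses: int = 2
    background_loss_prob: float = 0.005
    false_negative_rate: float = 0.05
    false_positive_rate: float = 0.001
    #: optional per-species multiplier on the false-negative rate, to mimic
    #: fast-evolving lineages; default off
    fn_multiplier: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in (self.background_loss_prob, self.false_negative_rate,
                  self.false_positive_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    tree: dendropy.Tree
    ciliated: dict[str, bool]
    motile: dict[str, bool]
    planted_matrix: ProfileMatrix
    module_of: dict[str, str]  # gene -> module name ("background" otherwise)
    cilium_loss_edges: list[frozenset[str]]
    motility_loss_edges: list[frozenset[str]]

    def module_members(self, name: str) -> set[str]:
        return {g for g, m in self.module_of.items() if m == name}

    @property
    def ciliary_genes(self) -> set[str]:
        return {g for g, m in self.module_of.items() if m != "background"}


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _random_binary_subtree(labels: list[str], rng: np.random.Generator) -> str:
    """Random binary Newick subtree over the labels (sequential joins)."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def _simulate_tree(
    n_species: Mapping[str, int], rng: np.random.Generator
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Groups as clades with random binary within-group structure; the
    groups themselves join by random binary topology at the root."""
    group_of: dict[str, str] = {}
    clades = []
    for group in sorted(n_species):
        count = n_species[group]
        labels = [f"{group[:4]}{i:03d}" for i in range(count)]
        for lb in labels:
            group_of[lb] = group
        clades.append(_random_binary_subtree(labels, rng))
    newick = _random_binary_subtree(clades, rng) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree, group_of


def _leafsets(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[id(node)] = frozenset([node.taxon.label])
        else:
            out[id(node)] = frozenset().union(
                *(out[id(c)] for c in node.child_nodes())
            )
    return out


def _sample_loss_edges(
    candidates: list,
    leafset: dict[int, frozenset[str]],
    n_losses: int,
    rng: np.random.Generator,
    already_absent: frozenset[str] = frozenset(),
) -> list:
    """Choose loss edges uniformly such that each chosen edge stays a
    maximal all-absent clade: leafsets are disjoint and every ancestor of a
    chosen edge keeps at least one unaffected leaf."""
    absent: set[str] = set(already_absent)
    chosen: list = []
    for _ in range(n_losses):
        eligible = []
        for node in candidates:
            leaves = leafset[id(node)]
            if leaves & absent:
                continue
            ok = True
            anc = node.parent_node
            while anc is not None:
                if not (leafset[id(anc)] - absent - leaves):
                    ok = False
                    break
                anc = anc.parent_node
            if ok:
                eligible.append(node)
        if not eligible:
            raise ValueError(
                f"requested {n_losses} losses but only {len(chosen)} placeable"
            )
        node = eligible[int(rng.integers(len(eligible)))]
        chosen.append(node)
        absent |= leafset[id(node)]
    return chosen


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate(
    config: SimulationConfig,
) -> tuple[ProfileMatrix, SimulationTruth, list[SpeciesAnnotation]]:
    """Run the generative model; returns (observed matrix, truth, annotations).

    Trait-loss edges are drawn uniformly among edges strictly inside
    eukaryotic group clades (group roots excluded, so every group keeps at
    least one ciliated genome), without nesting.  Module genes track their
    trait exactly in the planted matrix; background genes evolve by
    independent per-branch Dollo loss; the observed matrix then flips 1->0
    at the false-negative rate and 0->1 at the false-positive rate.
    """
    rng = np.random.default_rng(config.rng_seed)
    tree, group_of = _simulate_tree(config.n_species, rng)
    leafset = _leafsets(tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]

    euk_leaves = [s for s in leaves if group_of[s] != "prokaryote"]

    # candidate loss edges: proper descendants of eukaryotic group roots
    group_roots = {}
    for node in tree.preorder_node_iter():
        groups = {group_of[s] for s in leafset[id(node)]}
        if len(groups) == 1:
            g = groups.pop()
            if g not in group_roots or len(leafset[id(group_roots[g])]) < len(leafset[id(node)]):
                group_roots[g] = node
    candidates = []
    for g, root in group_roots.items():
        if g == "prokaryote":
            continue
        for node in root.preorder_iter():
            if node is not root:
                candidates.append(node)

    cilium_nodes = _sample_loss_edges(
        candidates, leafset, config.n_cilium_losses, rng
    )
    cilium_loss_edges = [leafset[id(n)] for n in cilium_nodes]
    nonciliated = set().union(*cilium_loss_edges) if cilium_loss_edges else set()

    # motility-only losses on still-ciliated clades
    motile_candidates = [
        n for n in candidates if not (leafset[id(n)] & nonciliated)
    ]
    motility_nodes = _sample_loss_edges(
        motile_candidates, leafset, config.n_motility_only_losses, rng,
        already_absent=frozenset(nonciliated),
    )
    motility_loss_edges = [leafset[id(n)] for n in motility_nodes]
    nonmotile_extra = (
        set().union(*motility_loss_edges) if motility_loss_edges else set()
    )

    ciliated = {
        s: (group_of[s] != "prokaryote" and s not in nonciliated) for s in leaves
    }
    motile = {s: (ciliated[s] and s not in nonmotile_extra) for s in leaves}

    # gene universe
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    for spec in config.module_specs:
        for i in range(spec.size):
            gid = f"{spec.name.upper()}{i + 1:04d}"
            gene_ids.append(gid)
            module_of[gid] = spec.name
    for i in range(config.n_background_genes):
        gid = f"BG{i + 1:05d}"
        gene_ids.append(gid)
        module_of[gid] = "background"

    n_genes, n_sp = len(gene_ids), len(leaves)
    col_of = {s: j for j, s in enumerate(leaves)}
    planted = np.zeros((n_genes, n_sp), dtype=np.int8)

    # module genes follow their trait
    trait_of_spec = {"cilia": ciliated, "motility": motile}
    row = 0
    for spec in config.module_specs:
        states = np.array(
            [trait_of_spec[spec.lost_with][s] for s in leaves], dtype=np.int8
        )
        planted[row:row + spec.size, :] = states
        row += spec.size

    # background genes: Dollo loss along branches, vectorized over genes
    n_bg = config.n_background_genes
    if n_bg:
        presence = {id(tree.seed_node): np.ones(n_bg, dtype=bool)}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_mask = presence[id(node.parent_node)]
            loss = rng.random(n_bg) < config.background_loss_prob
            mask = parent_mask & ~loss
            presence[id(node)] = mask
            if node.is_leaf():
                planted[row:, col_of[node.taxon.label]] = mask

    # detection noise
    observed = planted.copy()
    fp = rng.random(observed.shape) < config.false_positive_rate
    fn_draw = rng.random(observed.shape)
    fn_rate = np.full(n_sp, config.false_negative_rate)
    for s, mult in config.fn_multiplier.items():
        fn_rate[col_of[s]] = min(1.0, config.false_negative_rate * mult)
    fn = fn_draw < fn_rate[np.newaxis, :]
    observed = np.where(observed == 1, (~fn).astype(np.int8), fp.astype(np.int8))

    matrix = ProfileMatrix(gene_ids=gene_ids, species_ids=leaves, values=observed)
    planted_matrix = ProfileMatrix(
        gene_ids=list(gene_ids), species_ids=list(leaves), values=planted
    )
    truth = SimulationTruth(
        tree=tree,
        ciliated=ciliated,
        motile=motile,
        planted_matrix=planted_matrix,
        module_of=module_of,
        cilium_loss_edges=cilium_loss_edges,
        motility_loss_edges=motility_loss_edges,
    )
    annotations = [
        SpeciesAnnotation(
            species_id=s,
            major_group=group_of[s],
            is_ciliated=ciliated[s],
            has_motile_cilia=motile[s],
        )
        for s in leaves
    ]
    return matrix, truth, annotations


def recovery_benchmark_config(rng_seed: int) -> SimulationConfig:
    """Standard planted-cluster recovery conditions: 120 genomes (112
    eukaryotes + 8 prokaryote outgroups), one 300-gene ciliary module among
    5,000 genes, 10 independent cilium losses, 5% false-negative rate."""
    return SimulationConfig(
        rng_seed=rng_seed,
        n_species={
            "opisthokonta": 30,
            "amoebozoa": 6,
            "archaeplastida": 20,
            "rhizaria": 4,
            "alveolata": 16,
            "stramenopila": 16,
            "discicristata": 10,
            "cryptophyta_haptophyta": 10,
            "prokaryote": 8,
        },
        n_background_genes=4700,
        module_specs=(ModuleSpec("ciliary", 300, "cilia"),),
        n_cilium_losses=10,
        n_motility_only_losses=0,
        false_negative_rate=0.05,
    )


def eukaryote_subtree(truth: SimulationTruth, annotations) -> dendropy.Tree:
    """The simulated tree restricted to eukaryotic leaves (the domain of the
    cilium trait)."""
    euk = [
        a.species_id for a in annotations if a.major_group != "prokaryote"
    ]
    return truth.tree.extract_tree_with_taxa_labels(euk)


# ---------------------------------------------------------------------------
# hit-table fabrication
# ---------------------------------------------------------------------------

def make_gene_map(gene_ids: Sequence[str]) -> GeneMap:
    """Two isoforms per gene (P1 representative, P2 alternate) plus a decoy
    human gene that absorbs non-reciprocal reverse hits."""
    protein_to_gene = {}
    representative = {}
    for g in gene_ids:
        protein_to_gene[f"{g}_P1"] = g
        protein_to_gene[f"{g}_P2"] = g
        representative[g] = f"{g}_P1"
    protein_to_gene["DECOY_P1"] = "DECOY"
    representative["DECOY"] = "DECOY_P1"
    return GeneMap(protein_to_gene=protein_to_gene, representative=representative)


def fabricate_hit_tables(
    matrix: ProfileMatrix,
    params: BBHParameters = BBHParameters(),
    rng_seed: int = 0,
    gmap: GeneMap | None = None,
) -> tuple[dict[str, list[HitRecord]], dict[str, list[HitRecord]], GeneMap]:
    """Fabricate directional hit tables whose BBH round-trip equals ``matrix``.

    Present cells get an admissible forward best hit whose reverse best hit
    lands on an isoform of the same gene.  Absent cells get, at random,
    either no hit at all, a forward hit above the E threshold, or an
    admissible decoy whose reverse best hit maps to a different gene — the
    three ways a reciprocal test fails in real data.
    """
    rng = np.random.default_rng(rng_seed)
    if gmap is None:
        gmap = make_gene_map(matrix.gene_ids)
    forward: dict[str, list[HitRecord]] = {s: [] for s in matrix.species_ids}
    reverse: dict[str, list[HitRecord]] = {s: [] for s in matrix.species_ids}

    for j, sp in enumerate(matrix.species_ids):
        for i, gene in enumerate(matrix.gene_ids):
            rep = gmap.representative_of(gene)
            subject = f"{sp}|{gene}_H"
            if matrix.values[i, j] == 1:
                e_fwd = 10.0 ** -rng.uniform(5, 50)
                score = float(rng.uniform(100, 500))
                forward[sp].append(
                    HitRecord(rep, subject, e_fwd, score, sp)
                )
                # reverse best lands on the alternate isoform of the gene
                reverse[sp].append(
                    HitRecord(subject, f"{gene}_P2", e_fwd, score, sp)
                )
                reverse[sp].append(
                    HitRecord(subject, "DECOY_P1", e_fwd * 10, score / 2, sp)
                )
            else:
                mode = rng.integers(3)
                if mode == 0:
                    continue  # no forward hit at all
                if mode == 1:  # hit above the E threshold: inadmissible
                    forward[sp].append(
                        HitRecord(
                            rep, subject,
                            float(rng.uniform(params.e_threshold * 2, 10)),
                            float(rng.uniform(20, 40)), sp,
                        )
                    )
                else:  # admissible decoy, reciprocal maps to another gene
                    decoy = f"{sp}|{gene}_D"
                    forward[sp].append(
                        HitRecord(rep, decoy, 0.01, float(rng.uniform(50, 80)), sp)
                    )
                    reverse[sp].append(
                        HitRecord(decoy, "DECOY_P1", 1e-10, 400.0, sp)
                    )
    return forward, reverse, gmap
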