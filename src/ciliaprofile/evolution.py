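"""Trait-loss inference on the species tree and footprint-based prediction.

Cilia are treated as a Dollo character: present in the last eukaryotic
common ancestor, gained once, and only ever lost.  Under that model the
minimal explanation of the observed leaf states marks one loss on every
edge whose whole subtree lacks the trait while a sister lineage retains it;
counting those edges gives the number of independent losses.

The same presence/absence footprints classify genomes by which functional
gene modules they kept, and predict whether an uncharacterized cluster gene
works in cilium biogenesis or motility: motility genes vanish wherever
motile cilia were lost (nematodes, ticks) while biogenesis genes persist in
any ciliated genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import SpeciesAnnotation
from .orthology import ProfileMatrix

#: Discretization thresholds for per-category retention (strict inequalities
#: as printed: high iff fraction > 2/3, mid iff > 1/3, low otherwise).
HIGH_THRESHOLD = 2 / 3
MID_THRESHOLD = 1 / 3


@dataclass
class LossReport:
    """Minimal independent-loss assignment under Dollo parsimony."""

    total_losses: int
    per_group_losses: dict[str, int]
    loss_edges: list[frozenset[str]]  # species below each loss edge

    def __post_init__(self) -> None:
        if self.per_group_losses and sum(self.per_group_losses.values()) != self.total_losses:
            raise ValueError("per-group losses do not sum to total")


@dataclass(frozen=True)
class FunctionPrediction:
    gene_id: str
    call: str  # biogenesis | motility | no_prediction
    conservation_fraction: float

    def __post_init__(self) -> None:
        if self.call not in ("biogenesis", "motility", "no_prediction"):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class LossPattern:
    species_id: str
    per_category_state: tuple[tuple[str, str], ...]  # (category, state) pairs

    def states(self) -> dict[str, str]:
        return dict(self.per_category_state)


# ---------------------------------------------------------------------------
# species tree construction
# ---------------------------------------------------------------------------

def tree_from_annotations(
    annotations: Sequence[SpeciesAnnotation], include_prokaryotes: bool = False
) -> dendropy.Tree:
    """Build a rank-level species tree: major groups as polytomous clades
    hanging off the root, flat within-group structure.

    A resolved Newick tree can be substituted anywhere a tree is accepted;
    this constructor only encodes group memberships.
    """
    by_group: dict[str, list[str]] = {}
    for a in annotations:
        if a.major_group == "prokaryote" and not include_prokaryotes:
            continue
        by_group.setdefault(a.major_group, []).append(a.species_id)
    parts = []
    for group in sorted(by_group):
        members = ",".join(by_group[group])
        parts.append(f"({members})" if len(by_group[group]) > 1 else members)
    newick = f"({','.join(parts)});"
    return dendropy.Tree.get(data=newick, schema="newick")


def read_species_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


# ---------------------------------------------------------------------------
# Dollo loss counting
# ---------------------------------------------------------------------------

def count_independent_losses(
    tree: dendropy.Tree,
    trait: Mapping[str, bool],
    annotations: Sequence[SpeciesAnnotation] | None = None,
) -> LossReport:
    """Count independent losses of a Dollo trait on a rooted species tree.

    A loss edge is an edge whose entire subtree lacks the trait while the
    parent clade still contains a carrier; the set of such edges is the
    unique minimal Dollo explanation.  If annotations are supplied each loss
    is attributed to the major group of the species below it (groups joined
    with ``+`` in the rare case a loss clade spans several).
    """
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [s for s in leaf_labels if s not in trait]
    if missing:
        raise ValueError(f"trait missing for leaves: {missing}")

    group_of = (
        {a.species_id: a.major_group for a in annotations} if annotations else None
    )

    # postorder: does the subtree contain any trait carrier?
    any_present: dict[int, bool] = {}
    leaves_below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            any_present[id(node)] = bool(trait[label])
            leaves_below[id(node)] = frozenset([label])
        else:
            any_present[id(node)] = any(
                any_present[id(c)] for c in node.child_nodes()
            )
            leaves_below[id(node)] = frozenset().union(
                *(leaves_below[id(c)] for c in node.child_nodes())
            )

    loss_edges: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if any_present[id(node)]:
            continue
        if parent is None or any_present[id(parent)]:
            loss_edges.append(leaves_below[id(node)])

    per_group: dict[str, int] = {}
    if group_of is not None:
        for edge in loss_edges:
            groups = sorted({group_of[s] for s in edge})
            key = "+".join(groups)
            per_group[key] = per_group.get(key, 0) + 1

    return LossReport(
        total_losses=len(loss_edges),
        per_group_losses=per_group,
        loss_edges=loss_edges,
    )


# ---------------------------------------------------------------------------
# loss-pattern classification
# ---------------------------------------------------------------------------

def discretize_fraction(
    fraction: float,
    high_threshold: float = HIGH_THRESHOLD,
    mid_threshold: float = MID_THRESHOLD,
) -> str:
    if fraction > high_threshold:
        return "high"
    if fraction > mid_threshold:
        return "mid"
    return "low"


def classify_loss_patterns(
    matrix: ProfileMatrix,
    gene_categories: Mapping[str, str],
    species_list: Sequence[str] | None = None,
    high_threshold: float = HIGH_THRESHOLD,
    mid_threshold: float = MID_THRESHOLD,
) -> tuple[list[LossPattern], int]:
    """Per-species retention state of each functional gene category.

    For every genome and category the fraction of that category's genes
    retained is discretized (high / mid / low); genomes sharing the same
    discretized vector exhibit the same loss pattern.  Returns the patterns
    and the number of distinct ones.
    """
    if species_list is None:
        species_list = matrix.species_ids
    categories = sorted(set(gene_categories.values()))
    members: dict[str, list[int]] = {c: [] for c in categories}
    for gene, cat in gene_categories.items():
        if gene in matrix.gene_ids:
            members[cat].append(matrix.gene_ids.index(gene))
    empty = [c for c, idx in members.items() if not idx]
    if empty:
        raise ValueError(f"categories with no genes in matrix: {empty}")

    patterns = []
    for sp in species_list:
        j = matrix.species_ids.index(sp)
        states = []
        for cat in categories:
            frac = float(matrix.values[members[cat], j].mean())
            states.append((cat, discretize_fraction(frac, high_threshold, mid_threshold)))
        patterns.append(LossPattern(species_id=sp, per_category_state=tuple(states)))
    distinct = len({p.per_category_state for p in patterns})
    return patterns, distinct


# ---------------------------------------------------------------------------
# function prediction from conservation footprints
# ---------------------------------------------------------------------------

def predict_gene_function(
    gene_id: str,
    profile_row: Sequence[int] | np.ndarray,
    annotations: Sequence[SpeciesAnnotation],
    conservation_threshold: float = 0.5,
    motile_presence_threshold: float = 0.5,
) -> FunctionPrediction:
    """Predict biogenesis vs motility function from the conservation footprint.

    No call is made for genes retained in fewer than half of the ciliated
    genomes.  Above that bar, a gene absent from every ciliated genome whose
    cilia are immotile (the nematode/tick class) yet present in at least
    half of the motile-ciliated genomes is called a motility gene; anything
    else conserved enough is called biogenesis.
    """
    row = np.asarray(profile_row)
    if row.shape != (len(annotations),):
        raise ValueError(
            f"profile row length {row.shape} does not match "
            f"{len(annotations)} annotations"
        )
    ciliated = [i for i, a in enumerate(annotations) if a.is_ciliated]
    if not ciliated:
        raise ValueError("no ciliated species among annotations")
    conservation = float(row[ciliated].mean())
    if conservation < conservation_threshold:
        return FunctionPrediction(gene_id, "no_prediction", conservation)

    nonmotile = [
        i for i, a in enumerate(annotations)
        if a.is_ciliated and not a.has_motile_cilia
    ]
    motile = [i for i, a in enumerate(annotations) if a.has_motile_cilia]
    absent_all_nonmotile = not nonmotile or not row[nonmotile].any()
    motile_fraction = float(row[motile].mean()) if motile else 0.0
    if absent_all_nonmotile and nonmotile and motile_fraction >= motile_presence_threshold:
        return FunctionPrediction(gene_id, "motility", conservation)
    return FunctionPrediction(gene_id, "biogenesis", conservation)


def universally_conserved_genes(
    matrix: ProfileMatrix, annotations: Sequence[SpeciesAnnotation]
) -> list[str]:
    """Genes present in every ciliated genome and absent from every
    nonciliated eukaryote (prokaryote outgroup columns are ignored)."""
    ann = {a.species_id: a for a in annotations}
    missing = [s for s in matrix.species_ids if s not in ann]
    if missing:
        raise ValueError(f"unannotated species in matrix: {missing}")
    ciliated = [
        j for j, s in enumerate(matrix.species_ids) if ann[s].is_ciliated
    ]
    nonciliated_euk = [
        j for j, s in enumerate(matrix.species_ids)
        if not ann[s].is_ciliated and ann[s].major_group != "prokaryote"
    ]
    out = []
    for i, gene in enumerate(matrix.gene_ids):
        row = matrix.values[i]
        if row[ciliated].all() and (not nonciliated_euk or not row[nonciliated_euk].any()):
            out.append(gene)
    return out
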