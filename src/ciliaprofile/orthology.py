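"""Bidirectional-best-hit (BBH) orthology calls and the binary profile matrix.

A gene is called present in a target genome when its representative human
protein finds an admissible best hit there (E-value at or below the
threshold, highest bit score) and that subject protein's best hit back
against the human proteome lands on any isoform of the same gene.  The
resulting gene x genome 0/1 matrix is the pipeline's central object.

The E-value threshold defaults to the deliberately permissive 0.1 that
catches highly divergent orthologs (e.g. centriolar proteins in fast
evolving nematodes) which stricter orthology pipelines tend to miss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneMap, HitRecord


@dataclass(frozen=True)
class BBHParameters:
    """Admissibility threshold and tie policy for best-hit selection.

    tie_break "score_evalue_id" resolves equal bit scores by lower E-value,
    then lexicographically smaller subject id; this is the only policy and
    exists to make the call deterministic under permuted input order.
    """

    e_threshold: float = 0.1
    tie_break: str = "score_evalue_id"

    def __post_init__(self) -> None:
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if self.tie_break != "score_evalue_id":
            raise ValueError(f"unknown tie_break policy {self.tie_break!r}")


@dataclass
class ProfileMatrix:
    """Dense binary gene x species presence/absence matrix."""

    gene_ids: list[str]
    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.species_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.species_ids)} species"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix values must be strictly binary")
        self.values = self.values.astype(np.int8)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_species(self, keep: Sequence[str]) -> "ProfileMatrix":
        idx = [self.species_ids.index(s) for s in keep]
        return ProfileMatrix(
            gene_ids=list(self.gene_ids),
            species_ids=list(keep),
            values=self.values[:, idx].copy(),
        )

    def subset_genes(self, keep: Sequence[str]) -> "ProfileMatrix":
        idx = [self.gene_ids.index(g) for g in keep]
        return ProfileMatrix(
            gene_ids=list(keep),
            species_ids=list(self.species_ids),
            values=self.values[idx, :].copy(),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProfileMatrix)
            and self.gene_ids == other.gene_ids
            and self.species_ids == other.species_ids
            and np.array_equal(self.values, other.values)
        )


def best_hit(
    hits: Iterable[HitRecord], params: BBHParameters = BBHParameters()
) -> str | None:
    """Return the subject id of the admissible best hit, or None.

    All hits must share one query protein and one subject species.  The best
    hit is the admissible record (e_value <= e_threshold) with maximal bit
    score; ties break by lower e_value, then lexicographically smaller
    subject id, so the result is invariant to input order.
    """
    hits = list(hits)
    if not hits:
        return None
    queries = {h.query_protein_id for h in hits}
    species = {h.species_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"mixed query proteins in best_hit input: {sorted(queries)}")
    if len(species) > 1:
        raise ValueError(f"mixed species in best_hit input: {sorted(species)}")
    admissible = [h for h in hits if h.e_value <= params.e_threshold]
    if not admissible:
        return None
    best = min(admissible, key=lambda h: (-h.bit_score, h.e_value, h.subject_protein_id))
    return best.subject_protein_id


def _group_by_query(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    grouped: dict[str, list[HitRecord]] = {}
    for h in hits:
        grouped.setdefault(h.query_protein_id, []).append(h)
    return grouped


def bbh_present(
    gene_id: str,
    species_id: str,
    forward: Iterable[HitRecord],
    reverse: Iterable[HitRecord],
    gmap: GeneMap,
    params: BBHParameters = BBHParameters(),
) -> int:
    """1 iff the gene's representative protein and its best hit in the
    species are each other's best hits at the gene level.

    ``forward`` holds human->species hits for the representative protein;
    ``reverse`` holds species->human hits for candidate subjects.  The
    reverse best hit may be any isoform of the gene: matching happens on
    GeneID, not protein id.
    """
    rep = gmap.representative_of(gene_id)  # KeyError if gene unknown
    fwd_hits = [h for h in forward if h.query_protein_id == rep]
    fwd_best = best_hit(fwd_hits, params) if fwd_hits else None
    if fwd_best is None:
        return 0
    rev_hits = [h for h in reverse if h.query_protein_id == fwd_best]
    rev_best = best_hit(rev_hits, params) if rev_hits else None
    if rev_best is None:
        return 0
    return int(gmap.gene_of(rev_best) == gene_id)


def build_matrix(
    genes: Sequence[str],
    species: Sequence[str],
    forward_tables: Mapping[str, Iterable[HitRecord]],
    reverse_tables: Mapping[str, Iterable[HitRecord]],
    gmap: GeneMap,
    params: BBHParameters = BBHParameters(),
) -> ProfileMatrix:
    """Assemble the gene x species presence matrix from directional hit tables.

    One forward (human -> species) and one reverse (species -> human) table
    is required per species.  The result is deterministic and independent of
    row order inside the tables.
    """
    missing = [s for s in species if s not in forward_tables or s not in reverse_tables]
    if missing:
        raise ValueError(f"missing hit tables for species: {missing}")

    values = np.zeros((len(genes), len(species)), dtype=np.int8)
    for j, sp in enumerate(species):
        fwd_by_query = _group_by_query(forward_tables[sp])
        rev_by_query = _group_by_query(reverse_tables[sp])
        for i, gene in enumerate(genes):
            rep = gmap.representative_of(gene)
            fwd_best = best_hit(fwd_by_query.get(rep, []), params)
            if fwd_best is None:
                continue
            rev_best = best_hit(rev_by_query.get(fwd_best, []), params)
            if rev_best is not None and gmap.gene_of(rev_best) == gene:
                values[i, j] = 1
    return ProfileMatrix(gene_ids=list(genes), species_ids=list(species), values=values)
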