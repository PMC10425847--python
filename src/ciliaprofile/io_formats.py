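"""Readers and writers for the external formats the profiling pipeline touches.

Formats handled here:

* 12-column tabular alignment hits (the classic ``-outfmt 6`` dialect:
  query, subject, %identity, length, mismatches, gaps, qstart, qend,
  sstart, send, evalue, bitscore),
* TSV binary presence/absence profile matrices,
* the CDT/GTR/ATR trio consumed by TreeView-style dendrogram browsers,
* CSV species-annotation and gene-annotation tables,
* flat TOML run configuration.

Everything downstream (orthology, clustering, loss inference) works on the
in-memory types defined here and in :mod:`ciliaprofile.orthology`.
"""

from __future__ import annotations

import csv
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ciliaprofile")

MAJOR_GROUPS = (
    "opisthokonta",
    "amoebozoa",
    "archaeplastida",
    "rhizaria",
    "alveolata",
    "stramenopila",
    "discicristata",
    "cryptophyta_haptophyta",
    "prokaryote",
)

#: Number of columns in the tabular alignment-hit dialect.
HIT_TABLE_COLUMNS = 12


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a basic handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class HitRecord:
    """One directional alignment best-hit candidate.

    Columns 3-10 of the tabular dialect (identity, alignment length, etc.)
    are retained only as an opaque payload; the orthology logic uses the
    E-value and the bit score.
    """

    query_protein_id: str
    subject_protein_id: str
    e_value: float
    bit_score: float
    species_id: str
    payload: tuple = ()

    def __post_init__(self) -> None:
        if not self.query_protein_id or not self.subject_protein_id:
            raise ValueError("protein ids must be nonempty")
        if self.e_value < 0:
            raise ValueError(f"negative e_value {self.e_value!r}")
        if self.bit_score < 0:
            raise ValueError(f"negative bit_score {self.bit_score!r}")


@dataclass
class GeneMap:
    """Protein-to-gene mapping with one representative protein per gene.

    Orthology calls are made at the gene level: the forward search uses the
    representative protein (typically the longest isoform) and a reverse hit
    landing on *any* isoform of the same gene counts as reciprocal.
    """

    protein_to_gene: dict[str, str]
    representative: dict[str, str]

    def __post_init__(self) -> None:
        for gene, prot in self.representative.items():
            mapped = self.protein_to_gene.get(prot)
            if mapped != gene:
                raise ValueError(
                    f"representative protein {prot!r} of gene {gene!r} maps to "
                    f"{mapped!r}"
                )

    def gene_of(self, protein_id: str) -> str | None:
        return self.protein_to_gene.get(protein_id)

    def representative_of(self, gene_id: str) -> str:
        try:
            return self.representative[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in GeneMap") from None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.representative)


@dataclass(frozen=True)
class SpeciesAnnotation:
    """Per-genome flags driving leaf ordering, loss counting and prediction."""

    species_id: str
    major_group: str
    is_ciliated: bool
    has_motile_cilia: bool
    reduced_complement: bool = False
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.major_group not in MAJOR_GROUPS:
            raise ValueError(f"unknown major group {self.major_group!r}")
        if self.major_group == "prokaryote" and self.is_ciliated:
            raise ValueError(f"prokaryote {self.species_id} flagged as ciliated")
        if self.has_motile_cilia and not self.is_ciliated:
            raise ValueError(
                f"{self.species_id}: motile cilia imply ciliated status"
            )


# ---------------------------------------------------------------------------
# tabular alignment hits
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path, species_id: str | None = None) -> list[HitRecord]:
    """Parse a 12-column tabular alignment file into :class:`HitRecord` rows.

    Parameters
    ----------
    path
        Tab-separated file; lines starting with ``#`` are skipped.
    species_id
        Species the subject proteome belongs to.  Defaults to the first
        dot-separated token of the file name (``hsap_vs_crei.fwd.tsv`` ->
        ``hsap_vs_crei``).

    Raises
    ------
    FormatError
        On a line with fewer than 12 columns or unparseable numeric fields,
        naming the offending line number.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.name.split(".")[0]
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < HIT_TABLE_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {HIT_TABLE_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            if len(fields) > HIT_TABLE_COLUMNS:
                logger.warning(
                    "%s:%d: %d extra columns ignored",
                    path, lineno, len(fields) - HIT_TABLE_COLUMNS,
                )
            try:
                e_value = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            try:
                records.append(
                    HitRecord(
                        query_protein_id=fields[0],
                        subject_protein_id=fields[1],
                        e_value=e_value,
                        bit_score=bit_score,
                        species_id=species_id,
                        payload=tuple(fields[2:10]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> None:
    """Write hit records back out in the 12-column tabular dialect."""
    with open(path, "w") as fh:
        for rec in records:
            payload = list(rec.payload) if len(rec.payload) == 8 else ["0"] * 8
            fh.write(
                "\t".join(
                    [rec.query_protein_id, rec.subject_protein_id, *payload,
                     repr(rec.e_value), repr(rec.bit_score)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# profile matrix TSV
# ---------------------------------------------------------------------------

def read_profile_matrix(path: str | Path):
    """Read a gene x species binary matrix from TSV.

    First column holds gene ids, the header row species ids, cells are 0/1.
    Returns a :class:`ciliaprofile.orthology.ProfileMatrix`.
    """
    from .orthology import ProfileMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"{path}: duplicate gene ids {dupes}")
    species_ids = [str(s) for s in df.columns]
    values = df.to_numpy()
    flat = values.ravel()
    bad = ~np.isin(flat, ["0", "1"])
    if bad.any():
        idx = int(np.argmax(bad))
        raise FormatError(
            f"{path}: non-binary cell value {flat[idx]!r} "
            f"(gene {gene_ids[idx // len(species_ids)]!r})"
        )
    return ProfileMatrix(
        gene_ids=gene_ids,
        species_ids=species_ids,
        values=values.astype(np.int8),
    )


def write_profile_matrix(matrix, path: str | Path) -> None:
    """Write a :class:`ProfileMatrix` as TSV (round-trips bit-exactly)."""
    df = pd.DataFrame(
        matrix.values, index=matrix.gene_ids, columns=matrix.species_ids
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# species / gene annotation CSV
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "true": True, "yes": True,
         "0": False, "false": False, "no": False, "": False}


def read_species_annotations(path: str | Path) -> list[SpeciesAnnotation]:
    """Read a CSV with columns species_id, major_group, is_ciliated,
    has_motile_cilia, reduced_complement[, display_name]."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SpeciesAnnotation(
                    species_id=row["species_id"],
                    major_group=row["major_group"],
                    is_ciliated=_BOOL[row["is_ciliated"].strip().lower()],
                    has_motile_cilia=_BOOL[row["has_motile_cilia"].strip().lower()],
                    reduced_complement=_BOOL[
                        row.get("reduced_complement", "0").strip().lower()
                    ],
                    display_name=row.get("display_name", ""),
                )
            )
    return out


def write_species_annotations(
    annotations: Iterable[SpeciesAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["species_id", "major_group", "is_ciliated", "has_motile_cilia",
             "reduced_complement", "display_name"]
        )
        for a in annotations:
            writer.writerow(
                [a.species_id, a.major_group, int(a.is_ciliated),
                 int(a.has_motile_cilia), int(a.reduced_complement),
                 a.display_name]
            )


# ---------------------------------------------------------------------------
# TreeView bundle (CDT / GTR / ATR)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{float(x):.6g}"


def _treeview_tree_lines(dendrogram, prefix: str) -> list[str]:
    """Merge list -> GTR/ATR lines with NODE{k}X ids and correlation-style
    heights (1 - h/hmax, so tighter merges score closer to 1)."""
    n = len(dendrogram.leaf_ids)
    hmax = max((h for _, _, h in dendrogram.merges), default=1.0) or 1.0

    def node_name(idx: int) -> str:
        if idx < n:
            return f"{prefix}{idx}X"
        return f"NODE{idx - n + 1}X"

    lines = []
    for k, (left, right, height) in enumerate(dendrogram.merges):
        lines.append(
            "\t".join(
                [f"NODE{k + 1}X", node_name(left), node_name(right),
                 _fmt(1.0 - height / hmax)]
            )
        )
    return lines


def write_treeview_bundle(
    matrix, gene_dendrogram, species_dendrogram, path_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Emit CDT (ordered matrix), GTR (gene tree) and ATR (array tree) files.

    Leaf order in the CDT equals the dendrogram leaf order on both axes.
    Returns the three paths written.
    """
    if list(gene_dendrogram.leaf_ids) != list(matrix.gene_ids):
        raise ValueError("gene dendrogram leaves do not match matrix rows")
    if list(species_dendrogram.leaf_ids) != list(matrix.species_ids):
        raise ValueError("species dendrogram leaves do not match matrix columns")

    prefix = Path(path_prefix)
    cdt, gtr, atr = (prefix.with_suffix(s) for s in (".cdt", ".gtr", ".atr"))

    gene_order = gene_dendrogram.leaf_order()
    species_order = species_dendrogram.leaf_order()

    with open(gtr, "w") as fh:
        for line in _treeview_tree_lines(gene_dendrogram, "GENE"):
            fh.write(line + "\n")
    with open(atr, "w") as fh:
        for line in _treeview_tree_lines(species_dendrogram, "ARRY"):
            fh.write(line + "\n")

    with open(cdt, "w") as fh:
        species_names = [matrix.species_ids[j] for j in species_order]
        fh.write("\t".join(["GID", "GENE", "NAME", "GWEIGHT", *species_names]) + "\n")
        fh.write(
            "\t".join(["AID", "", "", "",
                       *[f"ARRY{j}X" for j in species_order]]) + "\n"
        )
        fh.write("\t".join(["EWEIGHT", "", "", "",
                            *["1"] * len(species_order)]) + "\n")
        for i in gene_order:
            gene = matrix.gene_ids[i]
            row = matrix.values[i, species_order]
            fh.write(
                "\t".join([f"GENE{i}X", gene, gene, "1",
                           *[_fmt(v) for v in row]]) + "\n"
            )
    return cdt, gtr, atr


def read_cdt_leaf_order(path: str | Path) -> tuple[list[str], list[str]]:
    """Return (gene order, species order) as written in a CDT file."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        species = header[4:]
        fh.readline()  # AID row
        fh.readline()  # EWEIGHT row
        genes = [line.split("\t")[1] for line in fh if line.strip()]
    return genes, species


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: Default thresholds; all values are the pipeline's standard operating point.
DEFAULT_CONFIG: dict = {
    "e_threshold": 0.1,
    "metric": "euclidean",
    "extract_mode": "elbow",
    "conservation_threshold": 0.5,
    "motile_presence_threshold": 0.5,
    "pattern_high_threshold": 2 / 3,
    "pattern_mid_threshold": 1 / 3,
    "significance_threshold": 1,
    "rng_seed": 0,
}


def read_config(path: str | Path) -> dict:
    """Read a flat TOML config; unspecified keys fall back to defaults."""
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg
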