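"""End-to-end orchestration: matrix -> clustering -> cluster extraction ->
robustness -> loss inference -> pattern classification -> prediction.

Every run writes its reports plus a manifest recording, per stage, the
parameters used and a SHA-256 digest of every output file, so identical
config + inputs provably give identical results.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import evolution, io_formats, profiling, synthetic
from .io_formats import SpeciesAnnotation, logger
from .orthology import BBHParameters, ProfileMatrix, build_matrix

try:
    __version__ = _pkg_version("ciliaprofile")
except PackageNotFoundError:  # pragma: no cover - editable quirk
    __version__ = "unknown"

STAGES = (
    "build_matrix",
    "cluster",
    "order_leaves",
    "extract",
    "robustness",
    "losses",
    "patterns",
    "predict",
)


@dataclass
class RunManifest:
    """Audit trail of one pipeline run."""

    tool_version: str
    rng_seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, params: Mapping, outputs: Sequence[Path]) -> None:
        self.stages.append(
            {
                "stage": name,
                "params": {k: _jsonable(v) for k, v in params.items()},
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tool_version": self.tool_version,
                    "rng_seed": self.rng_seed,
                    "stages": self.stages,
                },
                fh, indent=2,
            )

    @property
    def digests(self) -> dict[str, str]:
        out = {}
        for stage in self.stages:
            out.update(stage["outputs"])
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def validate_config(config: Mapping) -> None:
    """Fail fast, before any stage runs."""
    if not config.get("seed_gene"):
        raise ValueError("config must name a seed_gene")
    sources = [k for k in ("matrix", "hits_dir", "simulate") if config.get(k)]
    if len(sources) != 1:
        raise ValueError(
            "config must name exactly one matrix source "
            "(matrix / hits_dir / simulate)"
        )
    mode = config.get("extract_mode", "elbow")
    if mode not in ("fixed_height", "elbow", "target_size"):
        raise ValueError(f"unknown extract_mode {mode!r}")
    if mode != "elbow" and config.get("extract_param") is None:
        raise ValueError(f"extract_mode {mode!r} requires extract_param")


def run_pipeline(config: Mapping, out_dir: str | Path) -> RunManifest:
    """Execute all stages; any failure aborts naming the failing stage."""
    cfg = dict(io_formats.DEFAULT_CONFIG)
    cfg.update(config)
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(tool_version=__version__, rng_seed=int(cfg["rng_seed"]))

    state: dict = {}
    for stage in STAGES:
        try:
            _STAGE_FUNCS[stage](cfg, out, state, manifest)
        except Exception as exc:  # noqa: BLE001 - contract: name the stage
            raise PipelineError(stage, exc) from exc
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_build_matrix(cfg, out, state, manifest) -> None:
    if cfg.get("simulate"):
        overrides = cfg["simulate"] if isinstance(cfg["simulate"], dict) else {}
        sim_cfg = synthetic.SimulationConfig(
            rng_seed=int(cfg["rng_seed"]), **overrides
        )
        matrix, truth, annotations = synthetic.simulate(sim_cfg)
        state["truth"] = truth
    elif cfg.get("matrix"):
        matrix = io_formats.read_profile_matrix(cfg["matrix"])
        annotations = io_formats.read_species_annotations(cfg["species_annotations"])
    else:
        hits_dir = Path(cfg["hits_dir"])
        annotations = io_formats.read_species_annotations(cfg["species_annotations"])
        gmap = state["gene_map"] = _read_gene_map(cfg["gene_map"])
        params = BBHParameters(e_threshold=float(cfg["e_threshold"]))
        species = [a.species_id for a in annotations]
        forward = {
            s: io_formats.read_hit_table(hits_dir / f"{s}.fwd.tsv", s)
            for s in species
        }
        reverse = {
            s: io_formats.read_hit_table(hits_dir / f"{s}.rev.tsv", s)
            for s in species
        }
        matrix = build_matrix(gmap.gene_ids, species, forward, reverse, gmap, params)
    state["matrix"] = matrix
    state["annotations"] = annotations
    path = out / "matrix.tsv"
    io_formats.write_profile_matrix(matrix, path)
    ann_path = out / "species_annotations.csv"
    io_formats.write_species_annotations(annotations, ann_path)
    manifest.record(
        "build_matrix",
        {"source": "simulate" if cfg.get("simulate") else "file",
         "n_genes": matrix.shape[0], "n_species": matrix.shape[1]},
        [path, ann_path],
    )


def _stage_cluster(cfg, out, state, manifest) -> None:
    metric = cfg["metric"]
    gene_tree, species_tree = profiling.cluster_matrix(state["matrix"], metric)
    state["gene_tree"], state["species_tree"] = gene_tree, species_tree
    manifest.record("cluster", {"metric": metric, "linkage": "average"}, [])


def _stage_order_leaves(cfg, out, state, manifest) -> None:
    ann = {a.species_id: a for a in state["annotations"]}
    order = profiling.order_leaves_ciliated_left(state["species_tree"], ann)
    state["species_order"] = order
    paths = io_formats.write_treeview_bundle(
        state["matrix"], state["gene_tree"], state["species_tree"],
        out / "profile",
    )
    manifest.record("order_leaves", {"rule": "ciliated_left"}, list(paths))


def _stage_extract(cfg, out, state, manifest) -> None:
    result = profiling.extract_seed_cluster(
        state["gene_tree"], state["matrix"], cfg["seed_gene"],
        cfg.get("extract_mode", "elbow"), cfg.get("extract_param"),
    )
    state["cluster"] = result
    path = out / "cluster.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene_id", "is_seed"])
        for g in sorted(result.member_gene_ids):
            writer.writerow([g, int(g == result.seed_gene_id)])
    trace_path = out / "growth_trace.csv"
    with open(trace_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["height", "cluster_size"])
        writer.writerows(result.growth_trace)
    manifest.record(
        "extract",
        {"seed_gene": cfg["seed_gene"], "mode": cfg.get("extract_mode", "elbow"),
         "param": cfg.get("extract_param"), "cluster_size": result.size,
         "cut_height": result.cut_height},
        [path, trace_path],
    )


def _stage_robustness(cfg, out, state, manifest) -> None:
    fractions = cfg.get("robustness_fractions", [0.25, 0.5, 0.75])
    rows = []
    for frac in fractions:
        retained, _ = profiling.robustness_subsample(
            state["matrix"], state["annotations"], cfg["seed_gene"],
            fraction=float(frac), mode=cfg.get("extract_mode", "elbow"),
            param=cfg.get("extract_param"), metric=cfg["metric"],
            rng_seed=int(cfg["rng_seed"]),
        )
        rows.append([frac, retained, state["cluster"].size])
    path = out / "robustness.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fraction_removed", "retained", "full_cluster_size"])
        writer.writerows(rows)
    manifest.record(
        "robustness",
        {"fractions": list(fractions), "rng_seed": int(cfg["rng_seed"])},
        [path],
    )


def _stage_losses(cfg, out, state, manifest) -> None:
    annotations = state["annotations"]
    if cfg.get("species_tree"):
        tree = evolution.read_species_tree(cfg["species_tree"])
    elif "truth" in state:
        tree = synthetic.eukaryote_subtree(state["truth"], annotations)
    else:
        tree = evolution.tree_from_annotations(annotations)
    trait = {
        a.species_id: a.is_ciliated for a in annotations
        if a.major_group != "prokaryote"
    }
    report = evolution.count_independent_losses(tree, trait, annotations)
    state["loss_report"] = report
    path = out / "losses.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["loss_index", "major_group", "n_species", "species"])
        group_of = {a.species_id: a.major_group for a in annotations}
        for k, edge in enumerate(report.loss_edges):
            groups = "+".join(sorted({group_of[s] for s in edge}))
            writer.writerow([k, groups, len(edge), ";".join(sorted(edge))])
    manifest.record(
        "losses", {"total_losses": report.total_losses}, [path]
    )


def _stage_patterns(cfg, out, state, manifest) -> None:
    cluster_genes = state["cluster"].member_gene_ids
    categories: dict[str, str] | None = None
    if cfg.get("gene_categories"):
        categories = {}
        with open(cfg["gene_categories"], newline="") as fh:
            for row in csv.DictReader(fh):
                categories[row["gene_id"]] = row["category"]
        categories = {g: c for g, c in categories.items() if g in cluster_genes}
    elif "truth" in state:
        categories = {
            g: state["truth"].module_of[g]
            for g in cluster_genes
            if state["truth"].module_of.get(g, "background") != "background"
        }
    if not categories:
        categories = {g: "cluster" for g in cluster_genes}
    patterns, n_distinct = evolution.classify_loss_patterns(
        state["matrix"], categories,
        high_threshold=float(cfg["pattern_high_threshold"]),
        mid_threshold=float(cfg["pattern_mid_threshold"]),
    )
    state["patterns"], state["n_patterns"] = patterns, n_distinct
    path = out / "patterns.csv"
    cats = sorted({c for c, _ in patterns[0].per_category_state}) if patterns else []
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_id", *cats])
        for p in patterns:
            states = p.states()
            writer.writerow([p.species_id, *[states[c] for c in cats]])
    manifest.record("patterns", {"n_distinct": n_distinct}, [path])


def _stage_predict(cfg, out, state, manifest) -> None:
    matrix: ProfileMatrix = state["matrix"]
    annotations = state["annotations"]
    path = out / "predictions.csv"
    calls = {"biogenesis": 0, "motility": 0, "no_prediction": 0}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene_id", "call", "conservation_fraction"])
        for g in sorted(state["cluster"].member_gene_ids):
            pred = evolution.predict_gene_function(
                g, matrix.row(g), annotations,
                conservation_threshold=float(cfg["conservation_threshold"]),
                motile_presence_threshold=float(cfg["motile_presence_threshold"]),
            )
            calls[pred.call] += 1
            writer.writerow([g, pred.call, f"{pred.conservation_fraction:.4f}"])
    universal = evolution.universally_conserved_genes(
        matrix.subset_genes(sorted(state["cluster"].member_gene_ids)),
        annotations,
    )
    upath = out / "universal_genes.csv"
    with open(upath, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene_id"])
        for g in universal:
            writer.writerow([g])
    state["universal"] = universal
    manifest.record(
        "predict", {"calls": calls, "n_universal": len(universal)}, [path, upath]
    )


def _read_gene_map(path) -> io_formats.GeneMap:
    protein_to_gene, representative = {}, {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            protein_to_gene[row["protein_id"]] = row["gene_id"]
            if row.get("is_representative", "0").strip().lower() in ("1", "true", "yes"):
                representative[row["gene_id"]] = row["protein_id"]
    return io_formats.GeneMap(protein_to_gene=protein_to_gene, representative=representative)


_STAGE_FUNCS = {
    "build_matrix": _stage_build_matrix,
    "cluster": _stage_cluster,
    "order_leaves": _stage_order_leaves,
    "extract": _stage_extract,
    "robustness": _stage_robustness,
    "losses": _stage_losses,
    "patterns": _stage_patterns,
    "predict": _stage_predict,
}
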