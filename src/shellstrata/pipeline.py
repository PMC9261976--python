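"""End-to-end orchestration: simulate -> markers -> ortho -> strata -> report.

A single :class:`PipelineConfig` (loadable from YAML) drives the whole
synthetic analysis: gene families are simulated on the species tree,
sequences evolved and clustered into orthogroups, a single-cell matrix with
planted shell-field markers is generated and tested, and each recovered
marker gene is classified onto its tree node.  One global seed is split
into independent per-stage streams, so identical configs give identical
bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, expr, ortho, seqfeat, strata, synth
from .markers import MarkerParams, find_markers
from .tree import SpeciesTree

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_ORIGINATION = {
    "Metazoa": 0.35,
    "Protostomia": 0.08,
    "Lophotrochozoa": 0.08,
    "Mollusca": 0.08,
    "Conchifera": 0.06,
    "Bivalvia_Gastropoda": 0.06,
    "Bivalvia": 0.09,
    "DRERO": 0.20,
}


@dataclass
class PipelineConfig:
    """Every stage parameter plus the global seed, YAML-serializable."""

    tree_path: str | None = None  # packaged 31-leaf tree when None
    focal_species: str = datasets.FOCAL_SPECIES
    seed: int = 0
    mode: str = "strict"
    coverage_threshold: float = 0.7
    precision_rule: str = "default"
    # family simulation
    n_families: int = 500
    origination_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORIGINATION)
    )
    loss_prob: float = 0.15
    paralog_rate: float = 0.2
    # sequence evolution + orthogroup inference
    root_length: int = 120
    subst_prob: float = 0.03
    kmer_size: int = 5
    similarity_threshold: float = 0.2
    cluster_method: str = "components"
    # single-cell stage
    n_cells_per_cluster: int = 100
    n_clusters: int = 3
    n_planted_markers: int = 25
    marker_log2fc: float = 1.5
    marker_expressed_fraction: float = 0.8
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    marker_params: MarkerParams = field(default_factory=MarkerParams)
    # time course
    stage_labels: list[str] = field(
        default_factory=lambda: [
            "2hpf", "4hpf", "8hpf", "13hpf", "24hpf", "36hpf", "48hpf",
        ]
    )
    timecourse_noise_cv: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mp = raw.pop("marker_params", None)
        cfg = cls(**raw)
        if mp:
            cfg.marker_params = MarkerParams(**mp)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Writes: proteomes/, matrix/, orthogroups.tsv, markers.tsv,
    assignments.tsv, summary.tsv, summary.json, features.tsv,
    heatmap_matrix.tsv, families_truth.tsv, pipeline.log.  Returns the
    in-memory results keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("shellstrata")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    seeds = _stage_seeds(config.seed)
    tree = (
        datasets.load_metazoa_tree()
        if config.tree_path is None
        else SpeciesTree.from_newick(config.tree_path)
    )
    focal = config.focal_species
    logger.info("stage=tree leaves=%d seed=%d", len(tree.leaves), config.seed)
    (outdir / "species_tree.nwk").write_text(tree.to_newick())

    # -- families ------------------------------------------------------
    fams = synth.simulate_gene_families(
        tree,
        synth.FamilySimParams(
            n_families=config.n_families,
            origination_weights=config.origination_weights,
            loss_prob=config.loss_prob,
            paralog_rate=config.paralog_rate,
            seed=seeds[0],
        ),
    )
    fams.write_truth_tsv(outdir / "families_truth.tsv")
    logger.info("stage=families n=%d", config.n_families)

    # -- sequences + orthogroups ---------------------------------------
    proteomes = synth.evolve_family_sequences(
        fams, tree, config.root_length, config.subst_prob, seed=seeds[1]
    )
    synth.write_proteome_fastas(proteomes, outdir / "proteomes")
    edges = ortho.pairwise_similarity(proteomes, k=config.kmer_size)
    orthogroups = ortho.build_orthogroups(
        edges,
        fams.gene_map(),
        threshold=config.similarity_threshold,
        method=config.cluster_method,
    )
    ortho.write_orthogroups_tsv(
        orthogroups, outdir / "orthogroups.tsv", species=list(tree.leaves)
    )
    logger.info(
        "stage=ortho genes=%d edges=%d orthogroups=%d",
        len(fams.family_of_gene), len(edges), len(orthogroups),
    )

    # -- single-cell stage ---------------------------------------------
    focal_genes = sorted(fams.genes[focal])
    if not focal_genes:
        raise ValueError(f"no simulated genes for focal species {focal!r}")
    rng = np.random.default_rng(seeds[2])
    n_mark = min(config.n_planted_markers, len(focal_genes))
    planted_idx = np.sort(rng.choice(len(focal_genes), size=n_mark, replace=False))
    sc_params = synth.ScSimParams(
        n_genes=len(focal_genes),
        n_cells_per_cluster=config.n_cells_per_cluster,
        n_clusters=config.n_clusters,
        marker_spec=[
            (int(i), 0, config.marker_log2fc, config.marker_expressed_fraction)
            for i in planted_idx
        ],
        nb_mean=config.nb_mean,
        nb_dispersion=config.nb_dispersion,
        seed=seeds[3],
    )
    matrix, truth = synth.simulate_cell_counts(sc_params)
    matrix.gene_ids = focal_genes  # name simulated genes after focal proteins
    matrix.write_mtx_dir(outdir / "matrix")
    truth["gene_id"] = [focal_genes[int(i)] for i in planted_idx]
    truth.to_csv(outdir / "planted_markers.tsv", sep="\t", index=False)

    markers_df = find_markers(matrix, config.marker_params, target_cluster=0)
    markers_df.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    marker_genes = markers_df["gene_id"].tolist()
    logger.info(
        "stage=markers planted=%d recovered_records=%d", n_mark, len(marker_genes)
    )

    # -- strata ---------------------------------------------------------
    assignments = strata.assign_genes(
        marker_genes, orthogroups, tree, focal,
        mode=config.mode, coverage_threshold=config.coverage_threshold,
    )
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    scheme = sorted(tree.internal_labels) + [
        strata.LINEAGE_SPECIFIC, strata.SCATTERED,
    ]
    summary = strata.summarize_strata(
        assignments, precision_rule=config.precision_rule, strata=scheme
    )
    summary.table.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    summary_json = {
        "n_genes": summary.n_genes,
        "n_genes_in_orthogroups": summary.n_genes_in_orthogroups,
        "n_orthogroups": summary.n_orthogroups,
        "mode": config.mode,
        "strata": {
            rec["stratum"]: {
                "gene_count": int(rec["gene_count"]),
                "orthogroup_count": int(rec["orthogroup_count"]),
                "pct_of_genes": rec["pct_of_genes"],
            }
            for rec in summary.table.to_dict("records")
        },
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary_json, indent=2, sort_keys=True) + "\n"
    )
    logger.info("stage=strata genes=%d", summary.n_genes)

    # -- sequence features on lineage-specific genes --------------------
    ls_genes = assignments.loc[
        assignments["stratum"] == strata.LINEAGE_SPECIFIC, "gene_id"
    ]
    feats = seqfeat.annotate_proteome(
        {g: proteomes[focal][g] for g in ls_genes if g in proteomes[focal]}
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False)

    # -- developmental time course for the marker genes ------------------
    peak_choices = ["13hpf", "24hpf", "36hpf"]
    tc_rng = np.random.default_rng(seeds[4])
    shapes = {
        g: (peak_choices[tc_rng.integers(0, len(peak_choices))],
            float(tc_rng.uniform(5, 50)))
        for g in marker_genes
    }
    lengths = pd.Series(
        tc_rng.integers(300, 3000, size=len(marker_genes)).astype(float),
        index=list(shapes),
    )
    tc_params = synth.TimecourseParams(
        stage_labels=config.stage_labels,
        profile_shapes=shapes,
        noise_cv=config.timecourse_noise_cv,
        seed=seeds[5],
    )
    if shapes:
        counts, lengths = synth.simulate_timecourse(tc_params, lengths)
        tpm = expr.tpm_matrix(counts, lengths)
        heat = expr.median_center(tpm)
        heat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    logger.info("stage=expr genes=%d", len(shapes))

    return {
        "tree": tree,
        "families": fams,
        "orthogroups": orthogroups,
        "matrix": matrix,
        "planted_markers": truth,
        "markers": markers_df,
        "assignments": assignments,
        "summary": summary,
        "summary_json": summary_json,
        "features": feats,
    }
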