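"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators replace the study's deposited raw data:

* a gene-family birth–death process on the species tree (per-branch
  Bernoulli loss, Poisson within-species paralogs), yielding the
  presence/absence patterns the stratum classifier consumes plus
  ground-truth birth nodes;
* a uniform-substitution protein evolver over those families, yielding
  per-species FASTA proteomes for the orthogroup inference stage;
* a negative-binomial single-cell count simulator with planted cluster
  markers, and a unimodal developmental time course with lognormal noise.

Every generator is deterministic under its seed, and every planted truth
is emitted alongside the data so recovery is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import CellCountMatrix
from .tree import SpeciesTree

__all__ = [
    "FamilySimParams",
    "ScSimParams",
    "TimecourseParams",
    "FamilySet",
    "simulate_gene_families",
    "evolve_family_sequences",
    "simulate_cell_counts",
    "simulate_timecourse",
    "write_proteome_fastas",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------
@dataclass
class FamilySimParams:
    """Birth–death settings for gene-family presence simulation.

    ``origination_weights`` gives, per tree-node label, the probability mass
    that a family is born at that node; ``loss_prob`` is the per-branch
    Bernoulli probability that a family present at the parent is lost;
    ``paralog_rate`` is the Poisson mean of extra within-species copies.
    """

    n_families: int = 500
    origination_weights: dict[str, float] = field(default_factory=dict)
    loss_prob: float = 0.15
    paralog_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must lie in [0, 1]")
        if self.paralog_rate < 0:
            raise ValueError("paralog_rate must be >= 0")
        if self.origination_weights:
            if any(w < 0 for w in self.origination_weights.values()):
                raise ValueError("origination weights must be nonnegative")
            if sum(self.origination_weights.values()) <= 0:
                raise ValueError("origination weights must sum to > 0")


@dataclass
class ScSimParams:
    """Negative-binomial single-cell simulator with planted markers.

    ``marker_spec`` rows are (gene_index, target_cluster, log2-fold effect,
    expressed fraction): the marker's mean in its target cluster is
    multiplied by 2**effect and its detection fraction set to the stated
    value.  An effect of 0 is the identity (no signal planted).
    """

    n_genes: int = 500
    n_cells_per_cluster: int = 200
    n_clusters: int = 3
    marker_spec: list[tuple[int, int, float, float]] = field(default_factory=list)
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_cluster < 1:
            raise ValueError("n_genes and n_cells_per_cluster must be positive")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        seen: set[tuple[int, int]] = set()
        for g, c, _eff, frac in self.marker_spec:
            if not 0 <= g < self.n_genes or not 0 <= c < self.n_clusters:
                raise ValueError(f"marker ({g}, {c}) out of range")
            if (g, c) in seen:
                raise ValueError(f"duplicate marker gene {g} for cluster {c}")
            seen.add((g, c))
            if not 0 < frac <= 1:
                raise ValueError("expressed fraction must lie in (0, 1]")


@dataclass
class TimecourseParams:
    """Unimodal developmental expression profiles with lognormal noise.

    ``profile_shapes`` maps gene -> (peak stage label, amplitude); the
    deterministic profile is a Gaussian bump (width ``peak_width`` stages)
    over the ordered stages plus a small floor, scaled by amplitude.
    """

    stage_labels: list[str] = field(default_factory=list)
    profile_shapes: dict[str, tuple[str, float]] = field(default_factory=dict)
    noise_cv: float = 0.0
    peak_width: float = 1.5
    baseline: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.stage_labels)) != len(self.stage_labels):
            raise ValueError("stage labels must be unique")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for gene, (peak, _amp) in self.profile_shapes.items():
            if peak not in self.stage_labels:
                raise ValueError(f"unknown peak stage {peak!r} for gene {gene!r}")


# ---------------------------------------------------------------------------
# gene families on the tree
# ---------------------------------------------------------------------------
@dataclass
class FamilySet:
    """Simulated families: presence matrix, birth nodes, per-species genes."""

    presence: pd.DataFrame  # family x species bool
    birth_nodes: pd.Series  # family -> node label
    genes: dict[str, list[str]]  # species -> species-qualified gene IDs
    family_of_gene: dict[str, str]

    def gene_map(self) -> dict[str, str]:
        """gene_id -> species, the universe build_orthogroups expects."""
        return {g: s for s, gs in self.genes.items() for g in gs}

    def write_truth_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "family": self.birth_nodes.index,
                "birth_node": self.birth_nodes.to_numpy(),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def gene_id(species: str, family: str, copy: int) -> str:
    return f"{species}|{family}|{copy}"


def parse_gene_id(gid: str) -> tuple[str, str, int]:
    species, family, copy = gid.split("|")
    return species, family, int(copy)


def simulate_gene_families(
    tree: SpeciesTree, params: FamilySimParams
) -> FamilySet:
    """Simulate family presence by birth at a node and Bernoulli branch loss.

    A family is present at a leaf iff the leaf descends from its birth node
    and no loss event occurred on the path from birth node to leaf.  Families
    lost everywhere are re-drawn (same birth node), i.e. the process is
    conditioned on survival so ``n_families`` is exact.
    """
    weights = params.origination_weights or {tree.root_label: 1.0}
    unknown = set(weights) - set(tree.node_labels)
    if unknown:
        raise KeyError(f"origination node(s) not in tree: {sorted(unknown)}")
    labels = sorted(weights)
    w = np.array([weights[x] for x in labels], dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(params.seed)

    species = list(tree.leaves)
    presence = np.zeros((params.n_families, len(species)), dtype=bool)
    births = []
    fam_ids = [f"F{i:05d}" for i in range(params.n_families)]
    for i in range(params.n_families):
        birth = labels[rng.choice(len(labels), p=w)]
        births.append(birth)
        while True:
            surviving = _drop_losses(tree, birth, params.loss_prob, rng)
            if surviving:
                break
        for s in surviving:
            presence[i, species.index(s)] = True

    genes: dict[str, list[str]] = {s: [] for s in species}
    family_of_gene: dict[str, str] = {}
    for i, fam in enumerate(fam_ids):
        for j, s in enumerate(species):
            if not presence[i, j]:
                continue
            n_copies = 1 + (
                rng.poisson(params.paralog_rate) if params.paralog_rate > 0 else 0
            )
            for c in range(n_copies):
                gid = gene_id(s, fam, c)
                genes[s].append(gid)
                family_of_gene[gid] = fam
    return FamilySet(
        presence=pd.DataFrame(presence, index=fam_ids, columns=species),
        birth_nodes=pd.Series(births, index=fam_ids, name="birth_node"),
        genes=genes,
        family_of_gene=family_of_gene,
    )


def _drop_losses(
    tree: SpeciesTree, birth: str, loss_prob: float, rng
) -> set[str]:
    """Leaves retaining the family after per-branch Bernoulli loss below birth."""
    surviving: set[str] = set()

    def walk(node: str) -> None:
        kids = tree.children(node)
        if not kids:
            surviving.add(node)
            return
        for child in kids:
            if loss_prob == 0.0 or rng.random() >= loss_prob:
                walk(child)

    walk(birth)
    return surviving


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------
def evolve_family_sequences(
    families: FamilySet,
    tree: SpeciesTree,
    root_length: int = 120,
    subst_prob_per_branch: float = 0.03,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Evolve one protein per family down the tree; per-site substitution.

    Each family gets a uniform-random ancestral sequence at its birth node;
    along every branch each site independently mutates with probability
    ``subst_prob_per_branch`` to one of the 19 other residues (uniform).
    Returns proteomes: species -> {gene_id: sequence}; paralog copies within
    a species are identical to the species' sequence.
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    if not 0.0 <= subst_prob_per_branch < 1.0:
        raise ValueError("subst_prob_per_branch must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    proteomes: dict[str, dict[str, str]] = {s: {} for s in tree.leaves}

    for fam in families.presence.index:
        birth = families.birth_nodes[fam]
        present = set(families.presence.columns[families.presence.loc[fam]])
        root_seq = aa[rng.integers(0, 20, size=root_length)]

        def walk(node: str, seq: np.ndarray) -> None:
            kids = tree.children(node)
            if not kids:
                if node in present:
                    text = seq.tobytes().decode()
                    for gid in families.genes[node]:
                        if families.family_of_gene[gid] == fam:
                            proteomes[node][gid] = text
                return
            for child in kids:
                walk(child, _mutate(seq, subst_prob_per_branch, aa, rng))

        walk(birth, root_seq)
    return proteomes


def _mutate(seq: np.ndarray, p: float, aa: np.ndarray, rng) -> np.ndarray:
    if p == 0.0:
        return seq
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < p)
    for i in hits:
        choices = aa[aa != out[i]]
        out[i] = choices[rng.integers(0, choices.size)]
    return out


def write_proteome_fastas(
    proteomes: dict[str, dict[str, str]], outdir: str | Path
) -> Path:
    """One ``<species>.fasta`` per species (wrapped at 60 columns)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for species, seqs in proteomes.items():
        lines = []
        for gid, seq in seqs.items():
            lines.append(f">{gid}")
            lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        (outdir / f"{species}.fasta").write_text("\n".join(lines) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------
def simulate_cell_counts(
    params: ScSimParams,
) -> tuple[CellCountMatrix, pd.DataFrame]:
    """Simulate a gene x cell count matrix with planted cluster markers.

    Baseline counts are NB(mean, dispersion) i.i.d.; for each marker with a
    nonzero effect, counts in the target cluster are redrawn at mean
    ``2**effect * nb_mean`` and gated so the detected (nonzero) fraction
    equals the specified expressed fraction.  Returns the matrix (true
    cluster labels attached) and the planted-marker ground-truth table.
    """
    rng = np.random.default_rng(params.seed)
    n_cells = params.n_cells_per_cluster * params.n_clusters
    labels = np.repeat(np.arange(params.n_clusters), params.n_cells_per_cluster)

    counts = _nb_draw(
        rng, params.nb_mean, params.nb_dispersion, (params.n_genes, n_cells)
    )
    truth_rows = []
    for g, c, eff, frac in params.marker_spec:
        truth_rows.append(
            {
                "gene_id": f"g{g:05d}",
                "cluster": c,
                "log2_effect": eff,
                "expressed_fraction": frac,
            }
        )
        if eff == 0.0:
            continue
        cells = np.flatnonzero(labels == c)
        boosted = _nb_draw(
            rng, params.nb_mean * 2.0**eff, params.nb_dispersion, cells.size
        )
        on = rng.random(cells.size) < frac
        boosted = np.where(on, np.maximum(boosted, 1), 0)
        counts[g, cells] = boosted

    m = CellCountMatrix(
        counts=counts,
        gene_ids=[f"g{i:05d}" for i in range(params.n_genes)],
        cell_barcodes=[f"cell{i:05d}" for i in range(n_cells)],
        cluster_labels=labels,
    )
    return m, pd.DataFrame(
        truth_rows,
        columns=["gene_id", "cluster", "log2_effect", "expressed_fraction"],
    )


def _nb_draw(rng, mean: float, dispersion: float, shape) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mean, size=shape)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=shape)


# ---------------------------------------------------------------------------
# developmental time course
# ---------------------------------------------------------------------------
def simulate_timecourse(
    params: TimecourseParams, lengths: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-stage expected counts following each gene's unimodal profile.

    ``lengths`` are per-gene effective lengths (> 0); counts scale with
    length so downstream TPM recovers the length-free profile.  Multiplicative
    lognormal noise with coefficient of variation ``noise_cv`` is applied
    (``noise_cv=0`` leaves the deterministic profile).
    """
    if (lengths <= 0).any():
        raise ValueError("all effective lengths must be > 0")
    missing = set(params.profile_shapes) - set(lengths.index)
    if missing:
        raise ValueError(f"lengths missing for genes: {sorted(missing)}")
    rng = np.random.default_rng(params.seed)
    stage_idx = {s: i for i, s in enumerate(params.stage_labels)}
    n_stages = len(params.stage_labels)
    rows = {}
    for gene, (peak, amp) in params.profile_shapes.items():
        x = np.arange(n_stages, dtype=float)
        profile = params.baseline + amp * np.exp(
            -0.5 * ((x - stage_idx[peak]) / params.peak_width) ** 2
        )
        profile = profile * float(lengths[gene])
        if params.noise_cv > 0:
            sigma = np.sqrt(np.log1p(params.noise_cv**2))
            noise = rng.lognormal(-(sigma**2) / 2, sigma, size=n_stages)
            profile = profile * noise
        rows[gene] = profile
    counts = pd.DataFrame.from_dict(
        rows, orient="index", columns=params.stage_labels
    )
    return counts, lengths.loc[counts.index]
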