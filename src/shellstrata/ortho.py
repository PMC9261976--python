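"""Desk-scale orthogroup construction and standard-format ingestion.

The all-vs-all protein similarity step is a shared-k-mer score computed
through an inverted k-mer index (near-linear in total k-mer occurrences,
identical to the naive pairwise definition), followed by either
connected-components or a lightweight Markov clustering of the thresholded
similarity graph.  The table parser ingests the standard ``Orthogroups.tsv``
layout (one row per orthogroup, one tab-separated column per species holding
a comma-space separated gene list) so results from a full orthology pipeline
can be analyzed in place of the built-in inference.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityEdge",
    "Orthogroup",
    "pairwise_similarity",
    "build_orthogroups",
    "presence_matrix",
    "parse_orthogroups_tsv",
    "write_orthogroups_tsv",
    "annotate_best_hit",
    "read_proteomes",
]


@dataclass(frozen=True)
class SimilarityEdge:
    """Symmetric similarity between two species-qualified genes."""

    gene_a: str
    gene_b: str
    score: float
    normalized_score: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self-edges are not allowed")
        if self.score < 0 or not 0 <= self.normalized_score <= 1:
            raise ValueError("score must be >= 0 and normalized_score in [0, 1]")


@dataclass
class Orthogroup:
    og_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    unassigned: bool = False

    @property
    def species(self) -> frozenset[str]:
        return frozenset(s for s, genes in self.members.items() if genes)

    @property
    def genes(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.members.values())


def read_proteomes(fasta_dir: str | Path) -> dict[str, dict[str, str]]:
    """Load per-species FASTA files (``<species>.fasta``) into dicts."""
    proteomes: dict[str, dict[str, str]] = {}
    for path in sorted(Path(fasta_dir).glob("*.fasta")):
        species = path.stem
        proteomes[species] = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
    if not proteomes:
        raise FileNotFoundError(f"no *.fasta files in {fasta_dir}")
    return proteomes


def _distinct_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_similarity(
    proteomes: dict[str, dict[str, str]],
    k: int = 5,
    min_normalized: float = 0.0,
    include_within_species: bool = True,
) -> list[SimilarityEdge]:
    """All-vs-all shared-k-mer similarity over every gene in every species.

    score = number of distinct k-mers shared by the two sequences;
    normalized_score = score / min(distinct k-mer count of either sequence).
    Candidate pairs are found through an inverted k-mer index, so pairs with
    no shared k-mer are never enumerated (and produce no edge).  Sequences
    shorter than ``k`` contribute no k-mers (logged).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    gene_ids: list[str] = []
    kmer_sets: list[set[str]] = []
    species_of: list[str] = []
    for species in sorted(proteomes):
        for gid, seq in proteomes[species].items():
            if not seq:
                raise ValueError(f"empty sequence for {gid}")
            kms = _distinct_kmers(seq, k)
            if not kms:
                logger.warning("sequence %s shorter than k=%d; no k-mers", gid, k)
            gene_ids.append(gid)
            kmer_sets.append(kms)
            species_of.append(species)

    index: dict[str, list[int]] = defaultdict(list)
    for i, kms in enumerate(kmer_sets):
        for km in kms:
            index[km].append(i)

    shared: dict[tuple[int, int], int] = defaultdict(int)
    for hits in index.values():
        for ai in range(len(hits)):
            for bi in range(ai + 1, len(hits)):
                shared[(hits[ai], hits[bi])] += 1

    edges = []
    for (i, j), score in sorted(shared.items()):
        if not include_within_species and species_of[i] == species_of[j]:
            continue
        denom = min(len(kmer_sets[i]), len(kmer_sets[j]))
        norm = score / denom if denom else 0.0
        if norm >= min_normalized and norm > 0:
            edges.append(SimilarityEdge(gene_ids[i], gene_ids[j], score, norm))
    return edges


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------
def build_orthogroups(
    edges: list[SimilarityEdge],
    genes: dict[str, str],
    threshold: float = 0.2,
    method: str = "components",
) -> list[Orthogroup]:
    """Cluster the thresholded similarity graph into orthogroups.

    Parameters
    ----------
    edges:
        Similarity edges; only those with ``normalized_score >= threshold``
        enter the graph.
    genes:
        Map gene_id -> species for the full gene universe.  Genes with no
        retained edge become single-member orthogroups flagged
        ``unassigned=True``, so membership always partitions the universe.
    method:
        ``"components"`` (connected components) or ``"mcl_lite"`` (Markov
        clustering, expansion 2 / inflation 2, <= 100 iterations).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if method not in ("components", "mcl_lite"):
        raise ValueError(f"unknown method {method!r}")
    gene_list = sorted(genes)
    gidx = {g: i for i, g in enumerate(gene_list)}
    kept = [e for e in edges if e.normalized_score >= threshold]
    for e in kept:
        if e.gene_a not in gidx or e.gene_b not in gidx:
            raise KeyError(f"edge references unknown gene {e.gene_a}/{e.gene_b}")

    n = len(gene_list)
    if method == "components" or not kept:
        comp = _connected_components(n, [(gidx[e.gene_a], gidx[e.gene_b]) for e in kept])
    else:
        comp = _mcl_lite(n, kept, gidx)

    clusters: dict[int, list[str]] = defaultdict(list)
    for g, c in zip(gene_list, comp):
        clusters[c].append(g)
    ordered = sorted(clusters.values(), key=lambda gs: min(gs))
    out = []
    for i, members in enumerate(ordered):
        by_sp: dict[str, list[str]] = defaultdict(list)
        for g in members:
            by_sp[genes[g]].append(g)
        out.append(
            Orthogroup(
                og_id=f"OG{i:07d}",
                members={s: sorted(v) for s, v in sorted(by_sp.items())},
                unassigned=len(members) == 1,
            )
        )
    return out


def _connected_components(n: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    g = sp.coo_matrix(
        (np.ones(len(pairs)), tuple(zip(*pairs)) if pairs else ([], [])),
        shape=(n, n),
    )
    _, comp = sp.csgraph.connected_components(g, directed=False)
    return comp

def _mcl_lite(n: int, edges: list, gidx: dict[str, int]) -> np.ndarray:
    rows, cols, vals = [], [], []
    for e in edges:
        i, j = gidx[e.gene_a], gidx[e.gene_b]
        rows += [i, j]
        cols += [j, i]
        vals += [e.normalized_score] * 2
    rows += list(range(n))  # self loops stabilize the walk
    cols += list(range(n))
    vals += [1.0] * n
    m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def colnorm(a):
        s = np.asarray(a.sum(axis=0)).ravel()
        s[s == 0] = 1.0
        return a.multiply(sp.csc_matrix(1.0 / s)).tocsc()

    m = colnorm(m)
    for _ in range(100):
        prev = m
        m = m @ m                      # expansion
        m = m.power(2)                 # inflation
        m = colnorm(m)
        m.data[m.data < 1e-6] = 0.0
        m.eliminate_zeros()
        if (m - prev).nnz == 0 or abs(m - prev).max() < 1e-8:
            break
    # clusters: connected components of the attractor support
    _, comp = sp.csgraph.connected_components(m, directed=False)
    return comp


def presence_matrix(
    orthogroups: list[Orthogroup], species: list[str] | None = None
) -> pd.DataFrame:
    """Boolean orthogroup x species membership matrix."""
    if species is None:
        species = sorted({s for og in orthogroups for s in og.species})
    data = {
        og.og_id: [s in og.species for s in species] for og in orthogroups
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(species))
    if len(df) and not df.any(axis=1).all():
        raise ValueError("presence matrix has an all-absent orthogroup")
    return df


# ---------------------------------------------------------------------------
# standard formats
# ---------------------------------------------------------------------------
def write_orthogroups_tsv(
    orthogroups: list[Orthogroup], path: str | Path, species: list[str] | None = None
) -> None:
    if species is None:
        species = sorted({s for og in orthogroups for s in og.species})
    lines = ["Orthogroup\t" + "\t".join(species)]
    for og in orthogroups:
        cells = [", ".join(og.members.get(s, [])) for s in species]
        lines.append(og.og_id + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def parse_orthogroups_tsv(path: str | Path) -> list[Orthogroup]:
    """Parse the standard Orthogroups.tsv layout.

    Raises on a gene ID appearing in more than one row (the downstream
    gene -> orthogroup lookup must be a function).
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty orthogroups file (header required)")
    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "Orthogroup":
        raise ValueError("first header column must be 'Orthogroup'")
    species = header[1:]
    seen: dict[str, str] = {}
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        og_id = cells[0]
        members: dict[str, list[str]] = {}
        for sp_name, cell in zip(species, cells[1:]):
            genes = [g for g in (x.strip() for x in cell.split(",")) if g]
            if genes:
                members[sp_name] = genes
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g!r} appears in both {seen[g]} and {og_id}"
                        )
                    seen[g] = og_id
        og = Orthogroup(og_id, members)
        og.unassigned = og.n_genes == 1
        out.append(og)
    return out


_BLAST_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def annotate_best_hit(
    blast_path: str | Path, mode: str = "best_evalue"
) -> dict[str, tuple[str, float, float]]:
    """Pick one annotation hit per query from 12-column tabular output.

    ``best_evalue`` keeps the most significant (lowest) E-value;
    ``highest_evalue`` is the literal converse.  Ties break by higher
    bitscore, then lexicographic subject ID.  Malformed lines are skipped
    with their line number logged.
    """
    if mode not in ("best_evalue", "highest_evalue"):
        raise ValueError(f"unknown mode {mode!r}")
    best: dict[str, tuple[str, float, float]] = {}
    sign = 1.0 if mode == "best_evalue" else -1.0
    with open(blast_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                logger.warning("line %d: expected 12 columns, got %d", ln, len(fields))
                continue
            try:
                q, s = fields[0], fields[1]
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError:
                logger.warning("line %d: unparsable numeric field", ln)
                continue
            key = (sign * evalue, -bits, s)
            if q not in best or key < best[q][0]:
                best[q] = (key, (s, evalue, bits))
    return {q: rec for q, (_, rec) in best.items()}
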