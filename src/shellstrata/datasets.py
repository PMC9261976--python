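"""Packaged reference inputs.

Two kinds of data ship with the package:

* a 31-leaf class-level metazoan tree (one focal bivalve leaf, ``DRERO``)
  whose labeled internal nodes are the strata of the shell-field
  classification scheme;
* the published per-stratum gene/orthogroup counts for the 357
  differentially expressed shell-field genes of the *Dreissena
  rostriformis* trochophore, used to reproduce the printed percentages
  through :func:`shellstrata.strata.summarize_strata`.

Counts that were never printed (flagged ``gene_count_printed == 0``) are
reconciled from the printed totals; see the column in the TSV.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tree import SpeciesTree

__all__ = [
    "FOCAL_SPECIES",
    "load_metazoa_tree",
    "load_published_stratum_counts",
    "published_assignments",
    "synthetic_lineage_specific_features",
]

FOCAL_SPECIES = "DRERO"

_DATA = resources.files("shellstrata") / "data"


def load_metazoa_tree() -> SpeciesTree:
    """31-leaf fixture tree mirroring the study's class-level taxon sampling."""
    return SpeciesTree.from_newick((_DATA / "metazoa31.nwk").read_text())


def load_published_stratum_counts() -> pd.DataFrame:
    """Per-stratum gene and orthogroup counts for the 357 shell-field genes."""
    with resources.as_file(_DATA / "shellfield_stratum_counts.tsv") as p:
        return pd.read_csv(p, sep="\t")


def published_assignments() -> pd.DataFrame:
    """Expand the published counts into a per-gene assignment table.

    Genes and orthogroup IDs are synthetic placeholders (``SFG0001`` ...),
    but the stratum marginals — and hence every percentage computed from
    them — are the published ones.  Within a stratum with more genes than
    orthogroups, surplus genes are packed into the leading orthogroups.
    """
    counts = load_published_stratum_counts()
    rows = []
    g = 0
    o = 0
    for rec in counts.itertuples(index=False):
        n_genes = int(rec.gene_count)
        n_ogs = int(rec.orthogroup_count)
        if rec.stratum == "LINEAGE_SPECIFIC" or n_ogs == 0:
            og_of_gene = [None] * n_genes
        else:
            # first (n_genes - n_ogs) orthogroups absorb one extra gene each
            og_ids = [f"OG{o + i:07d}" for i in range(n_ogs)]
            o += n_ogs
            og_of_gene = og_ids + og_ids[: n_genes - n_ogs]
            og_of_gene.sort()
        for og in og_of_gene:
            rows.append(
                {
                    "gene_id": f"SFG{g:04d}",
                    "og_id": og,
                    "stratum": rec.stratum,
                }
            )
            g += 1
    return pd.DataFrame(rows)


def synthetic_lineage_specific_features(
    n_genes: int = 86, n_tm: int = 39, n_sp: int = 41, n_either: int = 42
) -> pd.DataFrame:
    """Synthetic feature table for the lineage-specific gene subset.

    A deterministic stand-in (not derived from real sequences) with the
    published marginals: of 86 *Dreissena*-specific shell-field genes, 39
    carry transmembrane segments and 41 signal peptides, with "almost
    half" carrying at least one of the two — here ``n_either`` = 42, so
    38 genes carry both.
    """
    n_both = n_tm + n_sp - n_either
    if n_both < 0 or n_either > n_genes:
        raise ValueError("inconsistent marginals")
    flags = (
        [(True, True)] * n_both
        + [(True, False)] * (n_tm - n_both)
        + [(False, True)] * (n_sp - n_both)
        + [(False, False)] * (n_genes - n_either)
    )
    return pd.DataFrame(
        {
            "gene_id": [f"LSG{i:03d}" for i in range(n_genes)],
            "has_tm": [t for t, _ in flags],
            "has_signal_peptide": [s for _, s in flags],
            "source": "synthetic",
        }
    )
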