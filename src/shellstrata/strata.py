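"""Phylostratigraphic classification of orthogroups onto a species tree.

Each orthogroup containing a focal-species gene is mapped to the node of
the phylogeny it is attributed to: the MRCA of the species in which it is
present, provided the presence pattern "fills" that clade.  In strict mode
the orthogroup must be present in *every* leaf under the MRCA; in relaxed
mode a coverage fraction suffices.  Patterns failing the test are
``SCATTERED`` (phylogenetically diffuse); genes with no orthogroup outside
the focal species are ``LINEAGE_SPECIFIC`` (orphans).  Per-node gene and
orthogroup counts with percentages are the end product of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ortho import Orthogroup
from .tree import SpeciesTree, TreeError

__all__ = [
    "SCATTERED",
    "LINEAGE_SPECIFIC",
    "PhylostratumClassifier",
    "classify_orthogroup",
    "assign_genes",
    "summarize_strata",
    "StratumSummary",
]

SCATTERED = "SCATTERED"
LINEAGE_SPECIFIC = "LINEAGE_SPECIFIC"


class PhylostratumClassifier(BaseEstimator):
    """Assign presence/absence patterns to species-tree nodes.

    Parameters
    ----------
    tree:
        A :class:`SpeciesTree` or a newick string with labeled internal
        nodes.
    focal_species:
        Leaf whose genes are being stratified; every classified pattern
        must include it.
    mode:
        ``"strict"`` — the MRCA's clade must be completely present;
        ``"relaxed"`` — present-leaf fraction under the MRCA must reach
        ``coverage_threshold``.
    coverage_threshold:
        Clade coverage required in relaxed mode, in (0, 1].

    After :meth:`fit`, ``classes_`` holds the reachable stratum labels and
    ``predict`` maps a boolean orthogroup x species frame (or array with
    ``species_`` column order) to stratum labels.
    """

    def __init__(
        self,
        tree: SpeciesTree | str,
        focal_species: str,
        mode: str = "strict",
        coverage_threshold: float = 0.7,
    ):
        self.tree = tree
        self.focal_species = focal_species
        self.mode = mode
        self.coverage_threshold = coverage_threshold

    def _resolve(self) -> SpeciesTree:
        t = self.tree
        return t if isinstance(t, SpeciesTree) else SpeciesTree.from_newick(t)

    def fit(self, X=None, y=None):
        if self.mode not in ("strict", "relaxed"):
            raise ValueError("mode must be 'strict' or 'relaxed'")
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must lie in (0, 1]")
        tree = self._resolve()
        if self.focal_species not in tree.leaves:
            raise TreeError(f"focal species {self.focal_species!r} is not a leaf")
        self.tree_ = tree
        self.species_ = list(tree.leaves)
        self.classes_ = np.array(
            sorted(tree.node_labels) + [LINEAGE_SPECIFIC, SCATTERED]
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "tree_"):
            self.fit()
        if isinstance(X, pd.DataFrame):
            cols = list(X.columns)
            unknown = set(cols) - set(self.species_)
            if unknown:
                raise TreeError(f"species not in tree: {sorted(unknown)}")
            values, species = X.to_numpy(dtype=bool), cols
        else:
            values, species = np.asarray(X, dtype=bool), self.species_
            if values.shape[1] != len(species):
                raise ValueError("array input must have one column per tree leaf")
        out = []
        for row in values:
            present = {s for s, v in zip(species, row) if v}
            out.append(self._classify(present))
        return np.array(out)

    def _classify(self, present: set[str]) -> str:
        if not present:
            raise ValueError("presence vector has no true entries")
        if self.focal_species not in present:
            raise ValueError(
                f"focal species {self.focal_species!r} absent from presence pattern"
            )
        if present == {self.focal_species}:
            return LINEAGE_SPECIFIC
        mrca = self.tree_.mrca(present)
        clade = self.tree_.leaf_set(mrca)
        if self.mode == "strict":
            return mrca if clade == present else SCATTERED
        coverage = len(present) / len(clade)
        return mrca if coverage >= self.coverage_threshold else SCATTERED


def classify_orthogroup(
    presence: Mapping[str, bool] | Iterable[str] | pd.Series,
    tree: SpeciesTree,
    focal: str,
    mode: str = "strict",
    coverage_threshold: float = 0.7,
) -> str:
    """Stratum label for one orthogroup's presence pattern.

    ``presence`` may be a set/list of present species, a bool mapping, or a
    bool Series indexed by species.
    """
    if isinstance(presence, (pd.Series, Mapping)):
        present = {s for s, v in dict(presence).items() if v}
    else:
        present = set(presence)
    clf = PhylostratumClassifier(tree, focal, mode, coverage_threshold).fit()
    return clf._classify(present)


@dataclass
class StratumSummary:
    """Aggregate of an assignment table: the per-node result object."""

    table: pd.DataFrame  # stratum, gene_count, orthogroup_count, pct columns
    n_genes: int
    n_genes_in_orthogroups: int
    n_orthogroups: int


def assign_genes(
    genes: Iterable[str],
    orthogroups: list[Orthogroup],
    tree: SpeciesTree,
    focal: str,
    mode: str = "strict",
    coverage_threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-gene stratum assignments for a focal gene list.

    Each gene inherits its orthogroup's classification.  Genes in no
    orthogroup, or in orthogroups whose members are all focal-species
    genes, are ``LINEAGE_SPECIFIC``.  A gene claimed by two orthogroups is
    a hard error.
    """
    clf = PhylostratumClassifier(tree, focal, mode, coverage_threshold).fit()
    og_of: dict[str, Orthogroup] = {}
    for og in orthogroups:
        for g in og.genes:
            if g in og_of:
                raise ValueError(
                    f"gene {g!r} claimed by both {og_of[g].og_id} and {og.og_id}"
                )
            og_of[g] = og
    og_stratum: dict[str, tuple[str, str, int]] = {}
    rows = []
    for gene in genes:
        og = og_of.get(gene)
        if og is None:
            rows.append((gene, None, LINEAGE_SPECIFIC, 1, focal))
            continue
        if og.og_id not in og_stratum:
            present = set(og.species)
            if present <= {focal}:
                og_stratum[og.og_id] = (LINEAGE_SPECIFIC, focal, max(len(present), 1))
            else:
                label = clf._classify(present)
                og_stratum[og.og_id] = (label, tree.mrca(present), len(present))
        label, mrca, n_present = og_stratum[og.og_id]
        rows.append((gene, og.og_id, label, n_present, mrca))
    return pd.DataFrame(
        rows, columns=["gene_id", "og_id", "stratum", "presence_count", "mrca_label"]
    )


def _round_pct(pct: float, rule: str) -> float:
    if rule == "integer":
        return float(round(pct))
    if rule == "one_decimal":
        return round(pct, 1)
    if rule == "default":  # >=10% to the integer, below to one decimal
        return float(round(pct)) if pct >= 10 else round(pct, 1)
    if rule == "fine":  # additionally: below 3% to two decimals
        if pct >= 10:
            return float(round(pct))
        return round(pct, 2) if pct < 3 else round(pct, 1)
    raise ValueError(f"unknown precision rule {rule!r}")


def summarize_strata(
    assignments: pd.DataFrame,
    precision_rule: str = "default",
    strata: Iterable[str] | None = None,
) -> StratumSummary:
    """Per-stratum gene/orthogroup counts and percentages.

    Percentages are computed over genes (``pct_of_genes``) and, as the
    alternative denominator, over orthogroups (``pct_of_orthogroups``, with
    orthogroup-less strata contributing nothing); both the rounded and
    unrounded values are emitted.  ``strata`` forces zero-count rows for
    labels absent from the table (so every node of the reporting scheme
    appears even when empty).

    LINEAGE_SPECIFIC rows count as orthogroup-less even when they carry a
    focal-only orthogroup ID: the "genes in orthogroups" total means
    orthogroups shared beyond the focal lineage.
    """
    if assignments.empty:
        raise ValueError("assignment table is empty")
    n_genes = len(assignments)
    has_og = assignments["og_id"].notna() & (
        assignments["stratum"] != LINEAGE_SPECIFIC
    )
    n_in_og = int(has_og.sum())
    n_ogs = assignments.loc[has_og, "og_id"].nunique()
    groups = {s: grp for s, grp in assignments.groupby("stratum", sort=False)}
    labels = list(groups)
    if strata is not None:
        labels += [s for s in strata if s not in groups]
    recs = []
    for stratum in labels:
        grp = groups.get(stratum, assignments.iloc[0:0])
        g = len(grp)
        if stratum == LINEAGE_SPECIFIC:
            o = 0
        else:
            o = grp.loc[grp["og_id"].notna(), "og_id"].nunique()
        pct_g = 100.0 * g / n_genes
        pct_o = 100.0 * o / n_ogs if n_ogs else 0.0
        recs.append(
            {
                "stratum": stratum,
                "gene_count": g,
                "orthogroup_count": o,
                "pct_of_genes": _round_pct(pct_g, precision_rule),
                "pct_of_genes_raw": pct_g,
                "pct_of_orthogroups": _round_pct(pct_o, precision_rule),
                "pct_of_orthogroups_raw": pct_o,
            }
        )
    table = (
        pd.DataFrame(recs)
        .sort_values(["gene_count", "stratum"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return StratumSummary(
        table=table,
        n_genes=n_genes,
        n_genes_in_orthogroups=n_in_og,
        n_orthogroups=int(n_ogs),
    )
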