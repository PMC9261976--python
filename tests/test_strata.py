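import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import clade_oracle
from shellstrata import datasets, synth
from shellstrata.ortho import Orthogroup
from shellstrata.strata import (
    LINEAGE_SPECIFIC,
    SCATTERED,
    PhylostratumClassifier,
    assign_genes,
    classify_orthogroup,
    summarize_strata,
)
from shellstrata.tree import SpeciesTree


# ---------------------------------------------------------------------------
# classify_orthogroup
# ---------------------------------------------------------------------------
class TestClassify:
    def test_full_presence_maps_to_root(self, metazoa_tree):
        label = classify_orthogroup(
            set(metazoa_tree.leaves), metazoa_tree, "DRERO"
        )
        assert label == "Metazoa"

    def test_focal_only_is_lineage_specific(self, metazoa_tree):
        assert (
            classify_orthogroup({"DRERO"}, metazoa_tree, "DRERO")
            == LINEAGE_SPECIFIC
        )

    def test_complete_clades_return_their_node(self, metazoa_tree):
        for node in ("Bivalvia", "Mollusca", "Protostomia", "Lophotrochozoa"):
            present = set(metazoa_tree.leaf_set(node))
            assert classify_orthogroup(present, metazoa_tree, "DRERO") == node

    def test_incomplete_clade_is_scattered_in_strict_mode(self, metazoa_tree):
        present = set(metazoa_tree.leaf_set("Bivalvia")) - {"CGIG"}
        assert len(present) > 1
        assert (
            classify_orthogroup(present, metazoa_tree, "DRERO", mode="strict")
            == SCATTERED
        )

    def test_relaxed_mode_tolerates_gaps(self, metazoa_tree):
        present = set(metazoa_tree.leaf_set("Bivalvia")) - {"CGIG"}
        assert (
            classify_orthogroup(
                present, metazoa_tree, "DRERO", mode="relaxed",
                coverage_threshold=0.7,
            )
            == "Bivalvia"
        )

    def test_empty_or_nonfocal_presence_rejected(self, metazoa_tree):
        with pytest.raises(ValueError):
            classify_orthogroup(set(), metazoa_tree, "DRERO")
        with pytest.raises(ValueError):
            classify_orthogroup({"HSAP"}, metazoa_tree, "DRERO")

    def test_random_vectors_match_exhaustive_clade_oracle(self, toy_tree, rng):
        leaves = list(toy_tree.leaves)
        clf = PhylostratumClassifier(toy_tree, "A", mode="strict").fit()
        for _ in range(1000):
            mask = rng.random(6) < 0.5
            mask[0] = True  # focal A always present
            present = {s for s, m in zip(leaves, mask) if m}
            assert clf._classify(present) == clade_oracle(present, toy_tree, "A")

    def test_exhaustive_vectors_match_oracle(self, toy_tree):
        leaves = list(toy_tree.leaves)
        clf = PhylostratumClassifier(toy_tree, "A", mode="strict").fit()
        for bits in itertools.product([0, 1], repeat=6):
            if not bits[0]:
                continue
            present = {s for s, b in zip(leaves, bits) if b}
            assert clf._classify(present) == clade_oracle(present, toy_tree, "A")

    def test_strict_label_implies_same_relaxed_label(self, toy_tree, rng):
        leaves = list(toy_tree.leaves)
        strict = PhylostratumClassifier(toy_tree, "A", "strict").fit()
        for cov in (0.3, 0.7, 1.0):
            relaxed = PhylostratumClassifier(toy_tree, "A", "relaxed", cov).fit()
            for _ in range(200):
                mask = rng.random(6) < 0.5
                mask[0] = True
                present = {s for s, m in zip(leaves, mask) if m}
                s_label = strict._classify(present)
                if s_label not in (SCATTERED,):
                    assert relaxed._classify(present) == s_label

    def test_irrelevant_taxon_invariance(self):
        """Adding an absent species outside the MRCA never changes the label."""
        small = SpeciesTree.from_newick("((A,B)AB,(C,D)CD)R;")
        big = SpeciesTree.from_newick("(((A,B)AB,(C,D)CD)Inner,E)R;")
        for present in ({"A", "B"}, {"A", "C"}, {"A"}, {"A", "B", "C", "D"}):
            lab_small = classify_orthogroup(present, small, "A")
            lab_big = classify_orthogroup(present, big, "A")
            if lab_small == "R":  # whole small tree = Inner clade of big tree
                assert lab_big == "Inner"
            else:
                assert lab_big == lab_small

    def test_predict_on_dataframe(self, toy_tree):
        clf = PhylostratumClassifier(toy_tree, "A").fit()
        X = pd.DataFrame(
            [
                dict.fromkeys(toy_tree.leaves, True),
                {s: s in {"A", "B"} for s in toy_tree.leaves},
                {s: s == "A" for s in toy_tree.leaves},
            ]
        )
        assert list(clf.predict(X)) == ["R", "AB", LINEAGE_SPECIFIC]


# ---------------------------------------------------------------------------
# assign_genes
# ---------------------------------------------------------------------------
class TestAssign:
    def _og(self, og_id, **members):
        return Orthogroup(og_id, {s: list(g) for s, g in members.items()})

    def test_gene_without_orthogroup_is_lineage_specific(self, toy_tree):
        asg = assign_genes(["A|x|0"], [], toy_tree, "A")
        assert asg.iloc[0]["stratum"] == LINEAGE_SPECIFIC
        assert asg.iloc[0]["og_id"] is None

    def test_focal_only_orthogroup_is_lineage_specific(self, toy_tree):
        og = self._og("OG1", A=["A|x|0", "A|y|0"])
        asg = assign_genes(["A|x|0", "A|y|0"], [og], toy_tree, "A")
        assert set(asg["stratum"]) == {LINEAGE_SPECIFIC}

    def test_shared_orthogroup_counted_once(self, toy_tree):
        og = self._og("OG1", A=["A|x|0", "A|y|0"], B=["B|x|0"])
        asg = assign_genes(["A|x|0", "A|y|0"], [og], toy_tree, "A")
        assert list(asg["stratum"]) == ["AB", "AB"]
        summ = summarize_strata(asg)
        row = summ.table.set_index("stratum").loc["AB"]
        assert row["gene_count"] == 2
        assert row["orthogroup_count"] == 1

    def test_duplicate_claim_is_hard_error(self, toy_tree):
        og1 = self._og("OG1", A=["A|x|0"])
        og2 = self._og("OG2", A=["A|x|0"])
        with pytest.raises(ValueError, match="claimed by both"):
            assign_genes(["A|x|0"], [og1, og2], toy_tree, "A")

    def test_simulated_no_loss_families_assign_to_birth_nodes(self, metazoa_tree):
        """With loss_prob=0 and perfect orthogroups every assignment equals
        the configured birth node (focal births map to LINEAGE_SPECIFIC)."""
        weights = {
            "Metazoa": 0.3, "Protostomia": 0.1, "Mollusca": 0.2,
            "Bivalvia": 0.2, "DRERO": 0.2,
        }
        fams = synth.simulate_gene_families(
            metazoa_tree,
            synth.FamilySimParams(
                n_families=200, origination_weights=weights,
                loss_prob=0.0, paralog_rate=0.0, seed=11,
            ),
        )
        ogs = [
            Orthogroup(fam, {
                s: [g for g in fams.genes[s] if fams.family_of_gene[g] == fam]
                for s in metazoa_tree.leaves
                if any(fams.family_of_gene[g] == fam for g in fams.genes[s])
            })
            for fam in fams.presence.index
        ]
        focal_genes = fams.genes["DRERO"]
        asg = assign_genes(focal_genes, ogs, metazoa_tree, "DRERO")
        for _, row in asg.iterrows():
            birth = fams.birth_nodes[fams.family_of_gene[row["gene_id"]]]
            expected = LINEAGE_SPECIFIC if birth == "DRERO" else birth
            assert row["stratum"] == expected

    def test_stratum_distribution_matches_origination_weights(self, metazoa_tree):
        """loss_prob=0 + perfect orthogroups: per-family stratum distribution
        is exactly the birth-node distribution."""
        weights = {"Metazoa": 0.5, "Bivalvia": 0.5}
        fams = synth.simulate_gene_families(
            metazoa_tree,
            synth.FamilySimParams(
                n_families=100, origination_weights=weights,
                loss_prob=0.0, paralog_rate=0.0, seed=3,
            ),
        )
        clf = PhylostratumClassifier(metazoa_tree, "DRERO").fit()
        got = fams.presence.apply(
            lambda row: clf._classify(set(row.index[row])), axis=1
        )
        pd.testing.assert_series_equal(
            got, fams.birth_nodes, check_names=False
        )


# ---------------------------------------------------------------------------
# summarize_strata
# ---------------------------------------------------------------------------
class TestSummarize:
    def _assignments(self, spec):
        """spec: list of (stratum, n_genes, n_ogs)."""
        rows = []
        g = o = 0
        for stratum, n_genes, n_ogs in spec:
            ogs = [f"OG{o + i}" for i in range(n_ogs)] or [None]
            o += n_ogs
            for i in range(n_genes):
                rows.append(
                    {"gene_id": f"g{g}", "og_id": ogs[i % len(ogs)],
                     "stratum": stratum}
                )
                g += 1
        return pd.DataFrame(rows)

    def test_lineage_specific_quarter_rounds_to_24(self):
        asg = self._assignments(
            [(LINEAGE_SPECIFIC, 86, 0), (SCATTERED, 271, 100)]
        )
        summ = summarize_strata(asg)
        row = summ.table.set_index("stratum").loc[LINEAGE_SPECIFIC]
        assert summ.n_genes == 357
        assert row["pct_of_genes"] == 24.0

    def test_small_fraction_two_decimal_mode(self):
        asg = self._assignments(
            [("Protostomia", 8, 6), (SCATTERED, 349, 100)]
        )
        summ = summarize_strata(asg, precision_rule="fine")
        row = summ.table.set_index("stratum").loc["Protostomia"]
        assert row["pct_of_genes"] == 2.24

    def test_empty_stratum_reports_zero(self):
        asg = self._assignments([(SCATTERED, 10, 5)])
        summ = summarize_strata(asg, strata=["Bivalvia"])
        row = summ.table.set_index("stratum").loc["Bivalvia"]
        assert row["gene_count"] == 0
        assert row["pct_of_genes"] == 0.0

    def test_counts_partition_and_percentages_recompute(self, rng):
        spec = [
            ("Metazoa", 30, 10), (SCATTERED, 50, 40),
            (LINEAGE_SPECIFIC, 20, 0),
        ]
        asg = self._assignments(spec)
        summ = summarize_strata(asg)
        assert summ.table["gene_count"].sum() == summ.n_genes == 100
        assert summ.n_genes_in_orthogroups == 80
        for _, row in summ.table.iterrows():
            assert row["pct_of_genes_raw"] == pytest.approx(
                100 * row["gene_count"] / summ.n_genes
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_strata(pd.DataFrame(columns=["gene_id", "og_id", "stratum"]))


# ---------------------------------------------------------------------------
# published-count reproduction helpers
# ---------------------------------------------------------------------------
def test_published_assignment_expansion_matches_counts():
    counts = datasets.load_published_stratum_counts()
    asg = datasets.published_assignments()
    assert len(asg) == counts["gene_count"].sum() == 357
    by = asg.groupby("stratum")
    for rec in counts.itertuples(index=False):
        grp = by.get_group(rec.stratum)
        assert len(grp) == rec.gene_count
        n_ogs = grp["og_id"].dropna().nunique()
        if rec.stratum != LINEAGE_SPECIFIC:
            assert n_ogs == rec.orthogroup_count
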