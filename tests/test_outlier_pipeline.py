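"""Outlier workflow: clustering, classification, sources, network summary."""

import warnings

import numpy as np
import pandas as pd
import pytest

from driftscape import outlier_pipeline as op
from driftscape import synthdata as sd
from driftscape.genodata import PERIOD_NAMES

from conftest import counts_from_calls

CFG = op.WorkflowConfig()


class TestUpgmaClusters:
    def test_hand_worked_three_point_case(self):
        # UPGMA merges {1,2} at 0.5, then 3 joins at (3.0+3.5)/2 = 3.25 > 1.3
        d = np.array([[0, 0.5, 3.0], [0.5, 0, 3.5], [3.0, 3.5, 0]])
        labels = op.upgma_flat_clusters(d, cutoff=1.3)
        assert labels[0] == labels[1] != labels[2]

    def test_all_zero_one_cluster(self):
        labels = op.upgma_flat_clusters(np.zeros((4, 4)), cutoff=1.3)
        assert len(set(labels)) == 1

    def test_all_large_singletons(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        labels = op.upgma_flat_clusters(d, cutoff=1.3)
        assert len(set(labels)) == 4

    def test_missing_pairs_imputed_with_warning(self):
        d = np.array([[0, np.nan, 0.2], [np.nan, 0, 0.3], [0.2, 0.3, 0]])
        with pytest.warns(UserWarning, match="imputed"):
            labels = op.upgma_flat_clusters(d, cutoff=1.3)
        assert len(labels) == 3


class TestClassification:
    @pytest.mark.parametrize(
        "size,total,expected",
        [
            (2, 20, "outlier_candidate"),   # <=2 members, despite 10%
            (4, 100, "outlier_candidate"),  # 4% < 5%
            (3, 60, "majority"),            # exactly 5%, >2 members
        ],
    )
    def test_size_rules(self, size, total, expected):
        labels = np.array([1] * size + [2] * (total - size))
        periods = ["Iron Age"] * total
        out = op.classify_clusters(labels, periods, CFG)
        assert out[1] == expected

    def test_denominator_counts_time_window_only(self):
        # 4 of 24 clustered, but 20 of the rest are Copper Age (outside the
        # Bronze->Early Modern window): total=4, so cluster 1 is 100%
        labels = np.array([1] * 4 + [2] * 20)
        periods = ["Iron Age"] * 4 + ["Copper Age"] * 20
        out = op.classify_clusters(labels, periods, CFG)
        assert out[1] == "majority"


class TestSplitByPeriod:
    def test_period_split_conserves_members(self):
        ids = [f"i{k}" for k in range(6)]
        labels = np.array([1, 1, 1, 1, 2, 2])
        periods = ["Iron Age", "Iron Age", "Imperial Rome & Late Antiquity",
                   "Iron Age", "Bronze Age", "Bronze Age"]
        clusters = op.split_by_period(ids, labels, periods, "regionX",
                                      {1: "majority", 2: "outlier_candidate"})
        assert sum(c.size for c in clusters) == 6
        parent1 = [c for c in clusters if c.cluster_id == 1]
        assert {(c.period, c.size) for c in parent1} == {
            ("Iron Age", 3), ("Imperial Rome & Late Antiquity", 1)
        }
        assert all(c.classification == "majority" for c in parent1)


class TestPeriodPrioritisation:
    def _cluster(self, region, period):
        return op.RegionPeriodCluster(region, period, 1, ["x"])

    def test_same_period_preferred(self):
        srcs = [self._cluster("A", "Iron Age"),
                self._cluster("B", "Imperial Rome & Late Antiquity")]
        kept = op.prioritize_sources_by_period(srcs, "Imperial Rome & Late Antiquity")
        assert [s.region for s in kept] == ["B"]

    def test_nearest_earlier_period(self):
        srcs = [self._cluster("A", "Bronze Age"), self._cluster("B", "Copper Age")]
        kept = op.prioritize_sources_by_period(srcs, "Imperial Rome & Late Antiquity")
        assert [s.region for s in kept] == ["A"]

    def test_ties_all_kept(self):
        srcs = [self._cluster("A", "Iron Age"), self._cluster("B", "Iron Age")]
        kept = op.prioritize_sources_by_period(srcs, "Iron Age")
        assert len(kept) == 2


class TestSexBias:
    def test_chi_square_matches_direct_formula(self):
        table = np.array([[20, 20], [3, 2], [2, 3]])
        chi2, p, df = op.sex_outlier_chi2(table)
        # independent oracle: direct Pearson formula
        expected = table.sum(1)[:, None] * table.sum(0)[None, :] / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(chi2_hand, rel=1e-12)
        assert df == 2


class TestPairwiseDissimilarity:
    def test_null_pairs_cluster_together(self, standard_panel):
        """Individuals drawn from one leaf have d mostly below the cutoff."""
        p = standard_panel
        rng = np.random.default_rng(20)
        counts = dict(p["counts"])
        ids = []
        dip = sd.genotypes_from_freqs(p["freqs"]["L3"], 6, rng)
        ph = sd.pseudohaploidize(dip, 0.25, rng)
        for j in range(6):
            counts[f"n{j}"] = counts_from_calls(ph[:, j:j + 1])
            ids.append(f"n{j}")
        dmat, log = op.pairwise_dissimilarity(ids, p["rights"], counts, p["blocks"])
        assert np.allclose(np.diag(dmat), 0)
        assert np.allclose(dmat, dmat.T)
        off = dmat[np.triu_indices(6, 1)]
        assert np.median(off) < 1.3
        labels = op.upgma_flat_clusters(dmat, CFG.cluster_cutoff_d)
        assert len(set(labels)) == 1

    def test_drifted_pair_separates(self, standard_panel):
        p = standard_panel
        rng = np.random.default_rng(21)
        counts = dict(p["counts"])
        ids = []
        for j, leaf in enumerate(["L1", "L1", "L1", "L5", "L5"]):
            dip = sd.genotypes_from_freqs(p["freqs"][leaf], 1, rng)
            counts[f"m{j}"] = counts_from_calls(sd.pseudohaploidize(dip, 0.25, rng))
            ids.append(f"m{j}")
        dmat, _ = op.pairwise_dissimilarity(ids, p["rights"], counts, p["blocks"])
        labels = op.upgma_flat_clusters(dmat, CFG.cluster_cutoff_d)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] != labels[0]


class TestEndToEnd:
    def test_workflow_recovers_planted_migrants(self, workflow_fixture, workflow_result):
        """Pipeline-level ground-truth recovery on the standard fixture:
        planted migrants come out as outliers with the correct source
        region; non-migrants stay in majority clusters."""
        fx = workflow_fixture
        result = workflow_result
        truth = fx.truth.set_index("id")
        asg = result.assignments.set_index("individual")

        migrants = [i for i in truth.index[truth["migrant"]] if i in asg.index]
        assert migrants, "no migrants were clustered"
        outlier_classes = {"outlier_with_source", "outlier_without_source"}
        detected = [m for m in migrants
                    if asg.loc[m, "classification"] in outlier_classes]
        sensitivity = len(detected) / len(migrants)
        assert sensitivity >= 0.8

        correct = 0
        attributed = [m for m in migrants
                      if asg.loc[m, "classification"] == "outlier_with_source"]
        for m in attributed:
            sources = {s.split("|")[0] for s in asg.loc[m, "sources"].split(";") if s}
            correct += truth.loc[m, "true_source_region"] in sources
        if attributed:
            assert correct / len(attributed) >= 0.8

        non_migrants = [i for i in asg.index if not truth.loc[i, "migrant"]]
        fp = sum(asg.loc[i, "classification"] in outlier_classes
                 for i in non_migrants)
        assert fp / len(non_migrants) <= 0.05

    def test_totals_conserved_and_network_consistent(self, workflow_fixture, workflow_result):
        fx = workflow_fixture
        result = workflow_result
        meta = fx.metadata.set_index("id")
        clustering_ids = [
            s for s in fx.matrix.samples
            if s not in fx.right_groups
            and meta.loc[s, "period"] in CFG.clustering_periods
        ]
        assert len(result.assignments) == len(clustering_ids)
        assert result.assignments["individual"].is_unique
        prop = result.network.proportions
        assert ((prop["outlier_proportion"].dropna() >= 0)
                & (prop["outlier_proportion"].dropna() <= 1)).all()
        if len(result.network.edges):
            assert (result.network.edges["count"] >= 1).all()

    def test_outputs_written(self, workflow_result, tmp_path):
        result = workflow_result
        result.write(tmp_path)
        for name in ("clusters.tsv", "edges.tsv", "network.json", "clade_tests.tsv"):
            assert (tmp_path / name).exists()
        clusters = pd.read_csv(tmp_path / "clusters.tsv", sep="\t")
        assert {"individual", "region", "period", "cluster",
                "classification"} <= set(clusters.columns)
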