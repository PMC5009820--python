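"""Stage tables, exact enrichment test, differential mutation testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, kstest
from statsmodels.stats.multitest import multipletests

from mutclust.characterize import (
    dichotomize_stage,
    differential_mutation,
    stage_by_cluster,
    stage_enrichment_exact,
)
from mutclust.scoring import MutationScoreMatrix


def cohort_tables(cluster_specs):
    """Build assignment and stage series from (n_early, n_late, n_unknown) per cluster."""
    assignments, stages = {}, {}
    i = 0
    for cluster, (n_early, n_late, n_unknown) in enumerate(cluster_specs, start=1):
        for stage, count in (("II", n_early), ("III", n_late), ("unknown", n_unknown)):
            for _ in range(count):
                pid = f"P{i:04d}"
                assignments[pid] = cluster
                stages[pid] = stage
                i += 1
    return pd.Series(assignments, name="cluster"), pd.Series(stages, name="stage")


# The published cohort's cluster-by-stage distribution: cluster sizes
# 169/121/68 with staged counts (131,35), (86,34), (41,26).
TABLE1 = [(131, 35, 3), (86, 34, 1), (41, 26, 1)]


class TestStageByCluster:
    def test_dichotomy(self):
        assert dichotomize_stage("I") == "early"
        assert dichotomize_stage("II") == "early"
        assert dichotomize_stage("III") == "late"
        assert dichotomize_stage("IV") == "late"
        assert dichotomize_stage("unknown") is None
        with pytest.raises(ValueError):
            dichotomize_stage("V")

    def test_published_cohort_ratios(self):
        assignments, stages = cohort_tables(TABLE1)
        table = stage_by_cluster(assignments, stages)
        ratios = table.table["ratio"].round(2).tolist()
        assert ratios == [3.74, 2.53, 1.58]

    def test_unknown_patients_counted_and_excluded(self):
        assignments, stages = cohort_tables(TABLE1)
        table = stage_by_cluster(assignments, stages)
        assert table.excluded_unknown == 5
        assert table.table["n_patients"].tolist() == [169, 121, 68]
        assert (table.table["n_early"] + table.table["n_late"]).tolist() == [166, 120, 67]

    def test_no_late_patients_gives_missing_ratio(self):
        assignments, stages = cohort_tables([(5, 0, 0), (2, 3, 0)])
        table = stage_by_cluster(assignments, stages)
        assert np.isnan(table.table.loc[1, "ratio"])

    def test_missing_patient_rejected_with_ids(self):
        assignments, stages = cohort_tables([(2, 2, 0), (2, 2, 0)])
        assignments.loc["PX999"] = 1
        with pytest.raises(KeyError, match="PX999"):
            stage_by_cluster(assignments, stages)


class TestStageEnrichmentExact:
    def test_published_three_by_two_table(self):
        assignments, stages = cohort_tables(TABLE1)
        table = stage_by_cluster(assignments, stages)
        assert stage_enrichment_exact(table) == pytest.approx(0.02048, abs=5e-6)

    def test_no_association_gives_one(self):
        assert stage_enrichment_exact(np.array([[10, 10], [10, 10]])) == pytest.approx(1.0)

    def test_perfect_separation_small_table(self):
        # two tables are as extreme: the observed and its mirror
        expected = 2.0 / 252.0  # 2 / C(10, 5)
        assert stage_enrichment_exact(np.array([[5, 0], [0, 5]])) == pytest.approx(expected)

    def test_matches_scipy_on_random_two_by_two_tables(self, rng):
        for _ in range(25):
            counts = rng.integers(1, 15, size=(2, 2))
            ours = stage_enrichment_exact(counts)
            theirs = fisher_exact(counts)[1]
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            stage_enrichment_exact(np.array([[0, 0], [3, 4]]))

    def test_cluster_subset_mode(self):
        assignments, stages = cohort_tables(TABLE1)
        table = stage_by_cluster(assignments, stages)
        pairwise = stage_enrichment_exact(table, clusters=[1, 3])
        assert pairwise == pytest.approx(fisher_exact([[131, 35], [41, 26]])[1], rel=1e-9)


class TestDifferentialMutation:
    @staticmethod
    def matrix_from(values, patients):
        return MutationScoreMatrix(
            pd.DataFrame(values, index=[f"G{i}" for i in range(len(values))], columns=patients)
        )

    def test_identical_vectors_give_p_one(self):
        m = self.matrix_from([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], list("abcdef"))
        out = differential_mutation(m, list("abc"), list("def"))
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_exact_rank_sum_three_vs_three(self):
        # complete separation of {1,2,3} vs {4,5,6}: the two most extreme
        # of the C(6,3)=20 equally likely rank splits, two-sided p = 2/20
        m = self.matrix_from([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], list("abcdef"))
        out = differential_mutation(m, list("abc"), list("def"))
        assert out["p_value"].iloc[0] == pytest.approx(0.1)
        assert out["direction"].iloc[0] == "b"

    def test_overlapping_or_tiny_groups_rejected(self):
        m = self.matrix_from([[1.0, 2.0, 3.0, 4.0]], list("abcd"))
        with pytest.raises(ValueError):
            differential_mutation(m, ["a", "b"], ["b", "c"])
        with pytest.raises(ValueError):
            differential_mutation(m, ["a"], ["b", "c"])

    def test_null_p_values_approximately_uniform(self, rng):
        # continuous null scores, 30 vs 30 patients, 200 genes
        patients = [f"P{i}" for i in range(60)]
        m = self.matrix_from(rng.normal(10, 2, size=(200, 60)) + 20, patients)
        out = differential_mutation(m, patients[:30], patients[30:])
        assert kstest(out["p_value"], "uniform").pvalue > 0.001

    def test_planted_signature_recovery_power(self, default_cohort):
        cohort = default_cohort
        clusters = cohort.true_cluster
        late_cluster = cohort.true_cluster.max()  # last cluster carries the lowest early odds
        group_late = clusters.index[clusters == late_cluster].tolist()
        group_other = clusters.index[clusters == 1].tolist()
        out = differential_mutation(cohort.score_matrix, group_late, group_other)
        planted = set(cohort.signature_genes[late_cluster])
        hits = out[out["significant"] & (out["direction"] == "a")]["gene"]
        power = len(planted & set(hits)) / len(planted)
        assert power >= 0.8


class TestBenjaminiHochberg:
    @staticmethod
    def step_up(p):
        # independent brute-force BH: min over j >= i of p_(j) * m / j
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p)
        adjusted = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            adjusted[order[rank - 1]] = min(1.0, running)
        return adjusted

    def test_differential_fdr_matches_brute_force(self, rng):
        patients = [f"P{i}" for i in range(20)]
        m = MutationScoreMatrix(
            pd.DataFrame(rng.gamma(1.0, 5.0, size=(40, 20)),
                         index=[f"G{i}" for i in range(40)], columns=patients)
        )
        out = differential_mutation(m, patients[:10], patients[10:])
        np.testing.assert_allclose(out["fdr"], self.step_up(out["p_value"]), atol=1e-12)
        assert (np.diff(out["fdr"]) >= -1e-12).all()  # monotone along sorted p

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_step_up_oracle_agrees_with_library(self, p_values):
        _, fdr, _, _ = multipletests(p_values, method="fdr_bh")
        np.testing.assert_allclose(fdr, self.step_up(p_values), atol=1e-12)
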