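"""Expression screen: TPM, replicate QC, CV selection, clustering, network."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from xomap import (
    CandidateCriteria,
    candidate_filter,
    correlation_network,
    fuzzy_cmeans,
    replicate_correlation,
    simulate_stage_profiles,
    stage_means,
    standardize_rows,
    top_cv_genes,
    tpm,
)


def _counts(values, genes=None, samples=None):
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples, dtype=float)


class TestTPM:
    def test_single_gene_takes_the_whole_million(self):
        out = tpm(_counts([[50.0]]), pd.Series([2000.0], index=["g0"]))
        assert out.iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalisation_hand_computation(self):
        counts = _counts([[100.0], [200.0]])
        lengths = pd.Series([1000.0, 2000.0], index=["g0", "g1"])
        out = tpm(counts, lengths)
        assert out["s0"].tolist() == pytest.approx([500_000.0, 500_000.0])

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng.integers(0, 500, size=(30, 6)))
        lengths = pd.Series(rng.integers(500, 5000, size=30).astype(float),
                            index=counts.index)
        out = tpm(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_all_zero_sample_warns_and_stays_zero(self):
        counts = _counts([[0.0, 5.0], [0.0, 5.0]])
        lengths = pd.Series([1000.0, 1000.0], index=counts.index)
        with pytest.warns(UserWarning, match="all-zero"):
            out = tpm(counts, lengths)
        assert (out["s0"] == 0).all()
        assert not out.isna().any().any()


class TestReplicateCorrelation:
    SAMPLES = pd.DataFrame(
        {"stage": ["A1", "A1", "A2", "A2"], "replicate": [1, 2, 1, 2]},
        index=["A1_r1", "A1_r2", "A2_r1", "A2_r2"],
    )

    def test_duplicated_replicate_has_r2_one(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 50, size=200)
        values = pd.DataFrame(
            {"A1_r1": x, "A1_r2": x, "A2_r1": x, "A2_r2": 2 * x},
            index=[f"g{i}" for i in range(200)],
        )
        out = replicate_correlation(values, self.SAMPLES).set_index("stage")
        assert out.loc["A1", "r2"] == pytest.approx(1.0)

    def test_independent_noise_has_low_r2(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(
            rng.gamma(2, 50, size=(5000, 4)),
            index=[f"g{i}" for i in range(5000)],
            columns=self.SAMPLES.index,
        )
        out = replicate_correlation(values, self.SAMPLES)
        assert (out["r2"] < 0.05).all()


class TestTopCVGenes:
    MEANS = pd.DataFrame(
        {
            "A1": [10.0, 10.0, 0.0, 0.0],
            "A2": [10.0, 80.0, 40.0, 0.0],
            "A3": [10.0, 10.0, 0.0, 0.0],
        },
        index=["constant", "peaked_mild", "peaked_hard", "silent"],
    )

    def test_stage_restricted_expression_outranks_uniform(self):
        order = list(top_cv_genes(self.MEANS, n=3))
        assert order.index("peaked_hard") < order.index("peaked_mild")
        assert order.index("peaked_mild") < order.index("constant")

    def test_zero_mean_genes_excluded(self):
        assert "silent" not in top_cv_genes(self.MEANS, n=10)

    def test_n_larger_than_gene_count_returns_all_eligible(self):
        assert len(top_cv_genes(self.MEANS, n=100)) == 3


class TestFuzzyCMeans:
    def test_single_cluster_gets_full_membership(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(20, 8)))
        res = fuzzy_cmeans(standardize_rows(data), c=1, seed=0)
        assert np.allclose(res.membership.to_numpy(), 1.0)

    def test_membership_rows_sum_to_one_and_objective_non_increasing(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(size=(60, 8)))
        res = fuzzy_cmeans(standardize_rows(data), c=4, m=1.5, seed=1)
        assert np.allclose(res.membership.sum(axis=1), 1.0)
        assert all(b <= a + 1e-9 for a, b in zip(res.objective, res.objective[1:]))

    def test_well_separated_groups_recovered_with_high_membership(self):
        counts, lengths, samples, labels = simulate_stage_profiles(
            n_per_group=50, noise_cv=0.1, seed=5
        )
        means = stage_means(tpm(counts, lengths), samples)
        res = fuzzy_cmeans(standardize_rows(means), c=2, m=1.25, seed=2)
        own = res.membership.max(axis=1)
        assert (own > 0.95).mean() > 0.98
        # hard assignment is a relabeling of the planted groups
        hard = res.hard
        for cluster, sub in labels.groupby(hard):
            assert sub.nunique() == 1

    def test_same_seed_identical_result(self):
        rng = np.random.default_rng(6)
        data = standardize_rows(pd.DataFrame(rng.normal(size=(40, 8))))
        r1 = fuzzy_cmeans(data, c=3, seed=9)
        r2 = fuzzy_cmeans(data, c=3, seed=9)
        pd.testing.assert_frame_equal(r1.membership, r2.membership)

    def test_gene_on_a_center_takes_membership_one(self):
        data = pd.DataFrame(
            [[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [-1.0, 0.0, 1.0]],
            index=["a", "b", "c"],
        )
        res = fuzzy_cmeans(data, c=2, m=2.0, seed=0, max_iter=50)
        assert np.allclose(res.membership.max(axis=1), 1.0, atol=1e-6)


class TestCorrelationNetwork:
    def test_identical_and_orthogonal_profiles(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        orth = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        profiles = pd.DataFrame([base, base * 2, orth], index=["a", "b", "c"])
        net = correlation_network(profiles)
        assert len(net.edges) == 1
        assert set(net.edges.iloc[0][["gene_a", "gene_b"]]) == {"a", "b"}
        assert net.degrees.tolist() == [1, 1, 0]

    def test_degenerate_thresholds_give_complete_graph(self):
        rng = np.random.default_rng(7)
        profiles = pd.DataFrame(rng.normal(size=(12, 8)))
        net = correlation_network(profiles, r_threshold=-1.0, p_threshold=1.1)
        assert len(net.edges) == 12 * 11 // 2

    def test_matches_scipy_brute_force(self):
        """Vectorised r/p equal scipy.stats.pearsonr pair by pair."""
        rng = np.random.default_rng(8)
        profiles = pd.DataFrame(
            rng.normal(size=(60, 8)), index=[f"g{i}" for i in range(60)]
        )
        net = correlation_network(profiles, r_threshold=0.3, p_threshold=0.5)
        edges = {
            frozenset((a, b)): (r, p)
            for a, b, r, p in net.edges.itertuples(index=False)
        }
        brute = {}
        for i in range(60):
            for j in range(i + 1, 60):
                r, p = sps.pearsonr(profiles.iloc[i], profiles.iloc[j])
                if abs(r) > 0.3 and p < 0.5:
                    brute[frozenset((f"g{i}", f"g{j}"))] = (r, p)
        assert set(edges) == set(brute)
        for key, (r, p) in brute.items():
            assert edges[key][0] == pytest.approx(r)
            assert edges[key][1] == pytest.approx(p, abs=1e-10)


class TestCandidateFilter:
    def _network(self):
        base = np.linspace(0, 1, 8)
        profiles = pd.DataFrame(
            [base, base, base, -base], index=["a", "b", "c", "known"]
        )
        return correlation_network(profiles, r_threshold=0.9)

    def test_copy_number_cap(self):
        net = self._network()
        cn = pd.Series({"a": 1, "b": 5, "c": 2, "known": 1})
        out = candidate_filter(net, cn, CandidateCriteria(degree_min=0, degree_max=10))
        assert "b" not in set(out["gene"])
        assert set(out["gene"]) == {"a", "c", "known"}

    def test_known_gene_excluded_regardless_of_degree(self):
        net = self._network()
        cn = pd.Series(1, index=net.degrees.index)
        out = candidate_filter(
            net,
            cn,
            CandidateCriteria(
                degree_min=0, degree_max=10, known_gene_exclusion=frozenset({"known"})
            ),
        )
        assert "known" not in set(out["gene"])

    def test_sorted_by_degree_descending(self):
        net = self._network()
        cn = pd.Series(1, index=net.degrees.index)
        out = candidate_filter(net, cn, CandidateCriteria(degree_min=0, degree_max=10))
        assert list(out["degree"]) == sorted(out["degree"], reverse=True)


def test_planted_groups_recovered_with_high_agreement():
    """End-to-end screen on planted profiles: adjusted agreement > 0.9."""
    from sklearn.metrics import adjusted_rand_score

    counts, lengths, samples, labels = simulate_stage_profiles(
        n_per_group=80, noise_cv=0.15, seed=10
    )
    tpm_values = tpm(counts, lengths)
    rep = replicate_correlation(tpm_values, samples)
    assert (rep["r2"] > 0.9).all()  # replicates of planted data are consistent
    means = stage_means(tpm_values, samples)
    top = top_cv_genes(means, n=len(means))
    res = fuzzy_cmeans(standardize_rows(means.loc[top]), c=2, m=1.25, seed=3)
    hard = res.hard.reindex(labels.index)
    codes = pd.Categorical(hard).codes
    assert adjusted_rand_score(labels.to_numpy(), codes) > 0.9
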