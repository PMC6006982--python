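"""Directed conditional entropies, resampling confirmation and serial flows."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from entroflow import (
    ClusteringComposition,
    CovariateGroupSpec,
    FixtureConfig,
    FlowConfig,
    InformationFlow,
    build_information_flow_raw,
    flow_entropy,
    majority_error_rate,
    make_planted_dataset,
    resampling_pvalues,
    serial_error_rate,
    shannon_entropy,
)


def comp(labels):
    return ClusteringComposition.from_labels(labels)


class TestFlowEntropy:
    def test_pure_clusters_zero_entropy(self):
        resp = comp([0, 0, 1, 1, 2, 2])
        cov = comp([0, 0, 1, 1, 2, 2])
        link = flow_entropy(resp, cov)
        assert all(v == pytest.approx(0.0) for v in
                   link.per_cluster_entropy.values())
        assert link.overall_entropy == pytest.approx(0.0)

    def test_single_covariate_cluster_gives_response_entropy(self):
        resp = comp([0, 1, 0, 1, 1])
        cov = comp([0, 0, 0, 0, 0])
        link = flow_entropy(resp, cov)
        assert link.overall_entropy == pytest.approx(shannon_entropy(resp))

    def test_planted_mixed_cluster_by_direct_count(self):
        # 3 covariate clusters: two response-pure, one exactly 50/50
        resp = comp([0] * 4 + [1] * 4 + [0, 0, 1, 1])
        cov = comp([0] * 4 + [1] * 4 + [2] * 4)
        link = flow_entropy(resp, cov)
        per = link.per_cluster_entropy
        assert per[0] == pytest.approx(0.0)
        assert per[1] == pytest.approx(0.0)
        assert per[2] == pytest.approx(np.log(2))
        assert link.overall_entropy == pytest.approx(np.log(2) / 3)

    def test_overall_never_exceeds_response_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            resp = comp(rng.integers(0, 3, 40))
            cov = comp(rng.integers(0, 4, 40))
            link = flow_entropy(resp, cov)
            assert link.overall_entropy <= link.response_entropy + 1e-12

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            flow_entropy(comp([0, 1]), comp([0, 1, 2]))


class TestResamplingPvalues:
    def test_pure_cluster_in_balanced_binary_is_significant(self):
        # pure cluster of 20 inside a balanced binary response of 100:
        # the chance a permutation keeps it pure is the hypergeometric mass
        # of drawing 20 same-label subjects, which is astronomically small
        labels = np.array([0] * 50 + [1] * 50)
        cov = comp([0] * 20 + [1] * 80)
        labels_pure = np.array([0] * 20 + [0] * 30 + [1] * 50)
        p = resampling_pvalues(labels_pure, cov, n_sims=1000, rng_seed=1)
        chance = 2 * hypergeom.pmf(20, 100, 50, 20)
        assert chance < 1e-6
        assert p[0] < 0.005
        assert p[0] == pytest.approx(1 / 1001)

    def test_cluster_of_all_subjects_not_significant(self):
        labels = np.array([0, 1] * 30)
        cov = comp([0] * 60)
        p = resampling_pvalues(labels, cov, n_sims=200, rng_seed=2)
        # every permutation preserves the whole-ensemble entropy exactly
        assert p[0] == pytest.approx(1.0)

    def test_pvalues_invariant_to_cluster_relabeling(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, 50)
        c1 = comp(np.array([0] * 25 + [1] * 25))
        c2 = comp(np.array([7] * 25 + [2] * 25))
        p1 = resampling_pvalues(labels, c1, n_sims=300, rng_seed=9)
        p2 = resampling_pvalues(labels, c2, n_sims=300, rng_seed=9)
        assert sorted(p1.values()) == sorted(p2.values())

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, 60)
        cov = comp(rng.integers(0, 3, 60))
        assert resampling_pvalues(labels, cov, 300, rng_seed=5) == \
            resampling_pvalues(labels, cov, 300, rng_seed=5)


class TestErrorRates:
    def test_pure_clusters_zero_error(self):
        link = flow_entropy(comp([0, 0, 1, 1]), comp([0, 0, 1, 1]))
        per, overall = majority_error_rate(link)
        assert overall == 0.0
        assert all(v == 0.0 for v in per.values())

    def test_sixty_forty_majority_error(self):
        resp = comp([0] * 6 + [1] * 4)
        cov = comp([0] * 10)
        link = flow_entropy(resp, cov)
        per, overall = majority_error_rate(link, rule="majority")
        assert per[0] == pytest.approx(0.4)
        assert overall == pytest.approx(0.4)

    def test_randomized_rule_on_even_split(self):
        resp = comp([0, 0, 1, 1])
        cov = comp([0, 0, 0, 0])
        _, overall = majority_error_rate(flow_entropy(resp, cov),
                                         rule="randomized")
        assert overall == pytest.approx(0.5)

    def test_majority_tie_prefers_globally_frequent_label(self):
        # cluster 0 ties 2-2; label 1 is globally more frequent
        resp = comp([0, 0, 1, 1, 1, 1, 1, 0])
        cov = comp([0, 0, 0, 0, 1, 1, 1, 1])
        link = flow_entropy(resp, cov)
        assert link.majority_labels[0] == 1


class TestSerialErrorRate:
    def test_single_link_equals_majority_error(self):
        resp = comp([0] * 6 + [1] * 4)
        cov = comp([0] * 5 + [1] * 5)
        link = flow_entropy(resp, cov)
        _, overall = majority_error_rate(link)
        flow = InformationFlow(["r"], [link])
        assert serial_error_rate(flow) == pytest.approx(overall)

    def test_near_zero_entropy_link_dominates(self):
        resp = comp([0] * 10 + [1] * 10)
        perfect = flow_entropy(resp, comp([0] * 10 + [1] * 10))
        rng = np.random.default_rng(0)
        noisy = flow_entropy(resp, comp(rng.integers(0, 2, 20)))
        flow = InformationFlow(["r"], [perfect, noisy], epsilon=1e-6)
        assert serial_error_rate(flow) == pytest.approx(0.0)
        assert flow.weights[0] > 0.999

    def test_serial_no_worse_than_best_single_link(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            r = np.random.default_rng(seed)
            resp_lab = r.integers(0, 2, 60)
            # two informative covariate partitions with independent noise
            c1 = np.where(r.random(60) < 0.85, resp_lab, 1 - resp_lab)
            c2 = np.where(r.random(60) < 0.75, resp_lab, 1 - resp_lab)
            resp = comp(resp_lab)
            links = [flow_entropy(resp, comp(c1)), flow_entropy(resp, comp(c2))]
            flow = InformationFlow(["r"], links)
            errs = [majority_error_rate(l)[1] for l in links]
            assert serial_error_rate(flow) <= min(errs) + 1e-9


class TestBuildInformationFlow:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted_result():
        cfg = FixtureConfig(
            n_subjects=100,
            n_response_features=2,
            n_response_clusters=2,
            n_latent_clusters=3,
            response_map={0: 0, 1: 1, 2: 1},
            noise=0.3,
            covariate_groups=[
                CovariateGroupSpec(n_features=4, n_clusters=3, linked=True,
                                   exclusivity=1.0),
                CovariateGroupSpec(n_features=4, n_clusters=2, linked=False),
            ],
            seed=0,
        )
        resp, cov, truth = make_planted_dataset(cfg)
        result = build_information_flow_raw(resp, cov, rng_seed=0)
        return result, truth

    def test_feature_groups_match_planted_partition(self, planted_result):
        result, truth = planted_result
        groups = {frozenset(g) for g in result.covariate_groups}
        planted = {}
        for name, gi in truth["feature_groups"].items():
            planted.setdefault(gi, set()).add(name)
        assert groups == {frozenset(v) for v in planted.values()}

    def test_exclusive_link_found_and_confirmed(self, planted_result):
        result, _ = planted_result
        flow = result.flows[0]
        best = flow.links[0]
        assert all(v < 0.05 for v in best.per_cluster_entropy.values())
        assert all(p < 0.01 for p in best.pvalues.values())

    def test_unlinked_group_carries_no_information(self, planted_result):
        result, _ = planted_result
        flow = result.flows[0]
        worst = flow.links[-1]
        assert worst.overall_entropy > 0.8 * worst.response_entropy

    def test_links_ordered_by_ascending_entropy_and_weights_sum_to_one(
        self, planted_result
    ):
        result, _ = planted_result
        flow = result.flows[0]
        ents = [l.overall_entropy for l in flow.links]
        assert ents == sorted(ents)
        assert flow.weights.sum() == pytest.approx(1.0)
        assert (flow.weights > 0).all()
        assert flow.serial_error is not None and flow.serial_error < 0.1

    def test_response_duplicated_as_covariate_gives_zero_entropy_link(self):
        from entroflow import FeatureSpec, RawDataMatrix

        cfg = FixtureConfig(
            n_subjects=60, n_response_features=2, n_response_clusters=2,
            covariate_groups=[], noise=0.2, seed=5,
        )
        resp, _, _ = make_planted_dataset(cfg)
        cov_frame = resp.values.rename(columns={"R0": "C0", "R1": "C1"})
        cov = RawDataMatrix(
            cov_frame,
            [FeatureSpec(c, "continuous", "covariate")
             for c in cov_frame.columns],
        )
        result = build_information_flow_raw(
            resp, cov, FlowConfig(n_sims=500), rng_seed=5
        )
        link = result.flows[0].links[0]
        assert link.overall_entropy < 0.05
        assert max(link.pvalues.values()) < 0.01
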