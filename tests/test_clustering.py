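import json

import numpy as np
import pytest
from scipy import optimize, special
from sklearn.metrics import adjusted_rand_score

from methsig.clustering import (
    crosstab_clusters,
    fit_beta_mixture,
    rpmm_cluster,
    select_variable_probes,
    ward_cluster,
)
from methsig.core_io import ProbeMatrix

from conftest import make_sheet, random_beta_matrix


class TestSelectVariableProbes:
    def test_constant_probe_excluded_alternating_included(self):
        values = np.array([[0.5, 0.5, 0.5, 0.5], [0.0, 1.0, 0.0, 1.0]])
        m = ProbeMatrix(["const", "alt"], ["a", "b", "c", "d"], values, "beta")
        assert select_variable_probes(m, 0.16) == ["alt"]

    def test_matches_bruteforce_sd_scan(self):
        m = random_beta_matrix(200, 15, seed=8, missing_rate=0.05)
        selected = set(select_variable_probes(m, 0.16))
        expected = set()
        for pid, row in zip(m.probe_ids, m.values):
            vals = row[np.isfinite(row)]
            if len(vals) >= 2 and np.std(vals, ddof=1) > 0.16:
                expected.add(pid)
        assert selected == expected

    def test_threshold_is_strict(self):
        # SD of (0.3, 0.5) with ddof=1 is exactly 0.1414...; at that
        # threshold the probe is excluded
        values = np.array([[0.3, 0.5]])
        m = ProbeMatrix(["p"], ["a", "b"], values, "beta")
        sd = np.std([0.3, 0.5], ddof=1)
        assert select_variable_probes(m, sd) == []
        assert select_variable_probes(m, sd - 1e-9) == ["p"]


def beta_loglik(x, mu, phi):
    a, b = mu * phi, (1 - mu) * phi
    return np.sum((a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - special.betaln(a, b))


class TestBetaMixtureFit:
    def test_single_component_matches_numeric_optimizer(self):
        """k=1 fit reaches the same maximum likelihood as an independent
        2-parameter numeric optimization (within 1e-6)."""
        rng = np.random.default_rng(2)
        x = rng.beta(0.3 * 40, 0.7 * 40, size=(120, 1))
        model = fit_beta_mixture(x, k=1)

        def neg(params):
            mu, log_phi = params
            return -beta_loglik(np.clip(x, 1e-3, 1 - 1e-3), mu, np.exp(log_phi))

        best = optimize.minimize(neg, [0.5, np.log(10)], method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-10})
        assert model.loglik == pytest.approx(-best.fun, abs=1e-6)

    def test_two_separated_components_recovered(self):
        """Planted components at means 0.2 / 0.8 (phi = 50, 200 samples):
        fitted means within 0.05."""
        rng = np.random.default_rng(3)
        J = 20
        X = np.vstack(
            [rng.beta(0.2 * 50, 0.8 * 50, (100, J)), rng.beta(0.8 * 50, 0.2 * 50, (100, J))]
        )
        model = fit_beta_mixture(X, k=2, seed=0)
        comp_means = np.sort(model.means.mean(axis=1))
        assert comp_means[0] == pytest.approx(0.2, abs=0.05)
        assert comp_means[1] == pytest.approx(0.8, abs=0.05)
        labels = model.labels()
        truth = np.repeat([0, 1], 100)
        assert adjusted_rand_score(truth, labels) > 0.95

    def test_single_component_data_rarely_prefers_two(self):
        """On homogeneous data, BIC prefers k=1 in >= 90% of 20 seeded runs."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            X = rng.beta(0.4 * 30, 0.6 * 30, size=(40, 25))
            m1 = fit_beta_mixture(X, k=1, seed=seed)
            m2 = fit_beta_mixture(X, k=2, seed=seed)
            if m2.bic(40) >= m1.bic(40):
                wins += 1
        assert wins >= 18

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.beta(2, 2, size=(30, 10))
        m1 = fit_beta_mixture(X, k=2, seed=11)
        m2 = fit_beta_mixture(X, k=2, seed=11)
        assert m1.loglik == m2.loglik
        np.testing.assert_array_equal(m1.means, m2.means)

    def test_weights_on_simplex(self):
        rng = np.random.default_rng(5)
        X = rng.beta(2, 5, size=(50, 8))
        m = fit_beta_mixture(X, k=2, seed=0)
        assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (m.precisions > 0).all()


def _planted_cohort(n_per_cluster, shifts, n_probes=120, seed=0, phi=50.0):
    """Samples drawn in blocks; block means 0.1 + shift on half the probes."""
    rng = np.random.default_rng(seed)
    blocks = []
    labels = []
    for k, (n, shift) in enumerate(zip(n_per_cluster, shifts)):
        mu = np.full(n_probes, 0.15)
        mu[: n_probes // 2] += shift
        blocks.append(rng.beta(mu * phi, (1 - mu) * phi, size=(n, n_probes)))
        labels += [k] * n
    X = np.vstack(blocks)
    sample_ids = [f"s{i:03d}" for i in range(X.shape[0])]
    probe_ids = [f"p{i}" for i in range(n_probes)]
    return (
        ProbeMatrix(probe_ids, sample_ids, X.T, "beta"),
        np.array(labels),
    )


class TestRpmm:
    def test_homogeneous_cohort_single_leaf(self):
        matrix, _ = _planted_cohort([40], [0.0], seed=1)
        tree = rpmm_cluster(matrix, seed=1)
        assert len(tree.leaves) == 1

    def test_two_planted_clusters_recovered(self):
        matrix, truth = _planted_cohort([20, 20], [0.0, 0.45], seed=2)
        tree = rpmm_cluster(matrix, seed=2)
        assign = tree.assignments()[matrix.sample_ids]
        ari = adjusted_rand_score(truth, assign.to_numpy())
        assert len(tree.leaves) == 2
        assert ari >= 0.9

    def test_three_planted_clusters_recovered(self):
        rng = np.random.default_rng(6)
        n_probes, phi = 120, 50.0
        mus = [np.full(n_probes, 0.15) for _ in range(3)]
        mus[1][:60] += 0.45
        mus[2][60:] += 0.45
        blocks = [rng.beta(mu * phi, (1 - mu) * phi, size=(18, n_probes)) for mu in mus]
        X = np.vstack(blocks)
        matrix = ProbeMatrix(
            [f"p{i}" for i in range(n_probes)],
            [f"s{i:03d}" for i in range(54)],
            X.T,
            "beta",
        )
        truth = np.repeat([0, 1, 2], 18)
        tree = rpmm_cluster(matrix, seed=3)
        assign = tree.assignments()[matrix.sample_ids]
        assert len(tree.leaves) >= 3
        assert adjusted_rand_score(truth, assign.to_numpy()) >= 0.8

    def test_sample_order_invariance(self):
        matrix, _ = _planted_cohort([15, 15], [0.0, 0.45], seed=4)
        perm = np.random.default_rng(0).permutation(matrix.n_samples)
        shuffled = matrix.subset(samples=[matrix.sample_ids[i] for i in perm])
        t1 = rpmm_cluster(matrix, seed=5)
        t2 = rpmm_cluster(shuffled, seed=5)
        a1, a2 = t1.assignments(), t2.assignments()
        assert (a1 == a2[a1.index]).all()

    def test_small_cohort_single_leaf(self):
        matrix, _ = _planted_cohort([6], [0.0], seed=7)
        tree = rpmm_cluster(matrix, min_leaf=5, seed=0)
        assert len(tree.leaves) == 1

    def test_tree_exports(self, tmp_path):
        matrix, _ = _planted_cohort([20, 20], [0.0, 0.45], seed=8)
        tree = rpmm_cluster(matrix, seed=0)
        tree.to_json(tmp_path / "tree.json")
        payload = json.loads((tmp_path / "tree.json").read_text())
        assert "r" in payload
        newick = tree.to_newick()
        assert newick.endswith(";")
        leaves = tree.leaves
        covered = sorted(s for leaf in leaves for s in leaf.sample_ids)
        assert covered == sorted(matrix.sample_ids)


class TestCrosstab:
    def test_aligned_clusters_give_diagonal_and_leaf_fraction(self):
        matrix, truth = _planted_cohort([22, 18], [0.0, 0.45], seed=9)
        tree = rpmm_cluster(matrix, seed=1)
        groups = np.where(truth == 0, "nonCIMP_CC", "CIMP_CC")
        # plant a 14/22 composition in the first cluster's metadata field
        batches = np.array(["G1"] * 14 + ["G2"] * 8 + ["G2"] * 18)
        sheet = make_sheet(
            [
                {"sample_id": s, "group": g, "batch": b}
                for s, g, b in zip(matrix.sample_ids, groups, batches)
            ]
        )
        table, enrich = crosstab_clusters(tree, sheet, "group")
        assert table.to_numpy().max(axis=1).sum() == matrix.n_samples  # diagonal
        table_b, _ = crosstab_clusters(tree, sheet, "batch")
        leaf0 = table_b.loc[table_b["G1"].idxmax()]
        assert leaf0["G1"] / leaf0.sum() == pytest.approx(14 / 22, abs=1e-9)

    def test_unknown_field_rejected(self):
        matrix, truth = _planted_cohort([20, 20], [0.0, 0.45], seed=10)
        tree = rpmm_cluster(matrix, seed=1)
        sheet = make_sheet(
            [{"sample_id": s, "group": "HNM"} for s in matrix.sample_ids]
        )
        with pytest.raises(KeyError):
            crosstab_clusters(tree, sheet, "no_such_field")


def test_ward_alternative_recovers_planted_clusters():
    matrix, truth = _planted_cohort([20, 20], [0.0, 0.45], seed=11)
    labels = ward_cluster(matrix, 2)
    assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9
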