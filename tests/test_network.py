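"""MI estimation, independence thresholding, DPI pruning, cohort networks."""

import numpy as np
import pandas as pd
import pytest

import mirnet as mn
from mirnet.network import NetworkParams

from conftest import brute_force_dpi


def gaussian_pair(rho, n, seed):
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], n)


class TestMutualInformation:
    def test_independent_profiles_near_zero(self):
        z = gaussian_pair(0.0, 2000, 1)
        assert mn.mutual_information(z[:, 0], z[:, 1]) < 0.02

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_kernel_matches_gaussian_closed_form(self, rho):
        z = gaussian_pair(rho, 2000, 2)
        mi = mn.mutual_information(z[:, 0], z[:, 1])
        assert mi == pytest.approx(-0.5 * np.log(1 - rho**2), abs=0.05)

    def test_gaussian_copula_zero_correlation(self):
        params = NetworkParams(estimator="gaussian_copula")
        x = np.arange(16, dtype=float)
        y = np.array([1, -1] * 8, dtype=float)  # rank-uncorrelated
        assert mn.mutual_information(x, y, params) < 0.01

    def test_constant_vector_warns_zero(self):
        with pytest.warns(UserWarning):
            assert mn.mutual_information(np.ones(10), np.arange(10.0)) == 0.0

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            mn.mutual_information(np.arange(10.0), np.arange(9.0))
        with pytest.raises(ValueError):
            mn.mutual_information(np.arange(5.0), np.arange(5.0))


class TestMiMatrix:
    def test_duplicate_row_is_row_maximum(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(5, 40)), index=list("abcde"))
        data.loc["e"] = data.loc["a"]  # exact duplicate, untied values
        m = mn.mi_matrix(data, NetworkParams(seed=0))
        assert m.loc["a", "e"] == pytest.approx(m.loc["a"].max())

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(size=(4, 30)))
        perm = rng.permutation(30)
        m1 = mn.mi_matrix(data, NetworkParams(seed=0))
        m2 = mn.mi_matrix(data.iloc[:, perm], NetworkParams(seed=0))
        assert np.allclose(m1, m2, atol=1e-9)

    def test_symmetry_and_nonnegativity(self, small_cohort):
        counts, sheet, _ = small_cohort
        sub = mn.size_factors(mn.filter_expressed(counts)).log_matrix.iloc[:25]
        m = mn.mi_matrix(sub, NetworkParams(seed=1)).to_numpy()
        assert np.allclose(m, m.T)
        assert (m >= 0).all()

    def test_planted_block_has_higher_mi(self):
        cfg = mn.SimConfig(
            n_mirnas=60,
            group_sizes={"dnPD": 30, "CTR": 30},
            module_spec=[(10, 0.6)],
            seed=6,
        )
        counts, _, truth = mn.generate_cohort(cfg)
        log_m = mn.size_factors(counts).log_matrix
        m = mn.mi_matrix(log_m, NetworkParams(seed=2))
        block = truth.module_membership[truth.module_membership == 0].index
        rest = truth.module_membership[truth.module_membership == "none"].index
        within = m.loc[block, block].to_numpy()
        within = within[np.triu_indices_from(within, 1)]
        cross = m.loc[block, rest].to_numpy().ravel()
        assert np.median(within) > np.median(cross)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            mn.mi_matrix(pd.DataFrame(np.ones((3, 5))))


class TestIndependenceThreshold:
    def test_fixed_mode_passthrough(self):
        params = NetworkParams(threshold_mode="fixed", eps=0.123)
        assert mn.independence_threshold(pd.DataFrame(np.ones((2, 10))), params) == 0.123

    def test_eps_zero_removes_nothing(self):
        """With eps=0 every positive-MI pair survives thresholding."""
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(8, 30)))
        params = NetworkParams(estimator="gaussian_copula", threshold_mode="fixed", eps=0.0)
        m = mn.mi_matrix(data, params).to_numpy()
        surviving = int((m > 0.0).sum() / 2)
        assert surviving == 8 * 7 // 2  # all pairs: copula MI is a.s. positive

    def test_null_calibration(self):
        """On independent data ~alpha of pairs survive the threshold."""
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(size=(50, 40)))
        params = NetworkParams(estimator="gaussian_copula", alpha=0.1, seed=3)
        m = mn.mi_matrix(data, params).to_numpy()
        eps = mn.independence_threshold(data, params)
        frac = (m[np.triu_indices(50, 1)] > eps).mean()
        assert 0.04 <= frac <= 0.18

    def test_eps_monotone_in_alpha(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(size=(20, 30)))
        eps = [
            mn.independence_threshold(
                data, NetworkParams(alpha=a, seed=11, estimator="gaussian_copula")
            )
            for a in (0.01, 0.05, 0.2)
        ]
        assert eps[0] >= eps[1] >= eps[2]


class TestApplyDpi:
    def test_printed_toy_triangle(self):
        """M(a,b)=0.50, M(b,c)=0.40, M(a,c)=0.10 at tau=0.15: the weakest
        edge fails both inequalities (0.10 < 0.34 and 0.10 < 0.425)."""
        m = pd.DataFrame(
            [[0, 0.50, 0.10], [0.50, 0, 0.40], [0.10, 0.40, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        net = mn.apply_dpi(m, eps=0.0, tau=0.15)
        kept = {frozenset(e) for e in zip(net.edges["source"], net.edges["target"])}
        assert kept == {frozenset("ab"), frozenset("bc")}

    def test_two_node_noop(self):
        m = pd.DataFrame([[0, 0.3], [0.3, 0]], index=list("ab"), columns=list("ab"))
        net = mn.apply_dpi(m, eps=0.0, tau=0.15)
        assert len(net.edges) == 1

    @pytest.mark.parametrize("tau", [0.0, 0.15, 0.3])
    def test_matches_brute_force_oracle(self, tau):
        rng = np.random.default_rng(int(tau * 100))
        for _ in range(20):
            a = rng.random((12, 12))
            m = (a + a.T) / 2
            np.fill_diagonal(m, 0.0)
            mdf = pd.DataFrame(m)
            net = mn.apply_dpi(mdf, eps=0.3, tau=tau)
            ours = {
                (min(s, t), max(s, t))
                for s, t in zip(net.edges["source"], net.edges["target"])
            }
            assert ours == brute_force_dpi(m, 0.3, tau)

    def test_never_adds_edges(self):
        rng = np.random.default_rng(8)
        a = rng.random((15, 15))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 0.0)
        net = mn.apply_dpi(pd.DataFrame(m), eps=0.4, tau=0.15)
        thresholded = int((m > 0.4).sum() / 2)
        assert len(net.edges) <= thresholded


class TestBuildNetwork:
    def test_deterministic_given_seed(self, small_cohort):
        counts, sheet, _ = small_cohort
        params = NetworkParams(seed=5, estimator="gaussian_copula")
        n1 = mn.build_network(counts.iloc[:60], sheet, "dnPD", params)
        n2 = mn.build_network(counts.iloc[:60], sheet, "dnPD", params)
        assert n1.edges.equals(n2.edges)

    def test_node_bookkeeping(self, small_cohort):
        counts, sheet, _ = small_cohort
        cohort = sheet.index[sheet["group"] == "dnPD"]
        expressed = mn.filter_expressed(counts.loc[:, cohort])
        net = mn.build_network(
            counts, sheet, "dnPD", NetworkParams(seed=1, estimator="gaussian_copula")
        )
        assert len(net.nodes) == len(expressed)

    def test_block_edge_density_enrichment(self):
        """Within-block edge density exceeds cross-block density >= 5x."""
        cfg = mn.SimConfig(
            n_mirnas=80,
            group_sizes={"dnPD": 60, "CTR": 10},
            module_spec=[(20, 0.6)] * 4,
            seed=2,
        )
        counts, sheet, truth = mn.generate_cohort(cfg)
        net = mn.build_network(counts, sheet, "dnPD", NetworkParams(seed=2))
        mem = truth.module_membership
        within = sum(mem[a] == mem[b] for a, b in zip(net.edges["source"], net.edges["target"]))
        cross = len(net.edges) - within
        n_within_pairs = 4 * (20 * 19 // 2)
        n_cross_pairs = 80 * 79 // 2 - n_within_pairs
        assert (within / n_within_pairs) >= 5 * max(cross / n_cross_pairs, 1e-9)

    def test_unknown_group(self, small_cohort):
        counts, sheet, _ = small_cohort
        with pytest.raises(ValueError):
            mn.build_network(counts, sheet, "nope", NetworkParams(seed=0))
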