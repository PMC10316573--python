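import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ceconet import (
    AbundanceTable,
    NetworkConfig,
    bh_adjust,
    build_network,
    midrank,
    spearman_matrix,
)


# -- independent oracles -----------------------------------------------------


def brute_force_midrank(values):
    """Textbook midranks: mean of the 1-based positions a tie group spans."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def brute_force_spearman(x, y):
    """Pearson formula applied to brute-force midranks."""
    rx, ry = brute_force_midrank(x), brute_force_midrank(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5


def brute_force_bh(p):
    """Step-up BH by explicit scan: adj_i = min over p_j >= p_i of m p_j / rank_j."""
    m = len(p)
    ranked = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for pos, i in enumerate(ranked):
        candidates = [
            m * p[j] / (rpos + 1)
            for rpos, j in enumerate(ranked)
            if rpos >= pos
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


# -- midrank -----------------------------------------------------------------


class TestMidrank:
    @pytest.mark.parametrize(
        "vec, expected",
        [([10, 20, 30], [1, 2, 3]), ([1, 2, 2, 3], [1, 2.5, 2.5, 4])],
    )
    def test_examples(self, vec, expected):
        assert list(midrank(vec)) == expected

    def test_rank_sum_conservation(self, rng):
        for _ in range(20):
            v = rng.integers(0, 4, size=5)  # heavy ties
            assert midrank(v).sum() == 15

    def test_rejects_short_or_nonfinite(self):
        with pytest.raises(ValueError):
            midrank([1.0])
        with pytest.raises(ValueError):
            midrank([1.0, np.nan, 2.0])


# -- spearman ----------------------------------------------------------------


class TestSpearmanMatrix:
    def _matrix(self, cols):
        df = pd.DataFrame(cols, index=[f"s{i}" for i in range(len(next(iter(cols.values()))))])
        return spearman_matrix(AbundanceTable(df.abs()))

    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        corr = self._matrix({"x": x, "y": np.exp(x)})
        assert corr.rho.loc["x", "y"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_tied_example(self):
        # midranks of [1,2,2,3] vs [1,2,3,4]: rho = 4.5 / sqrt(22.5)
        corr = self._matrix({"x": [1.0, 2.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0, 4.0]})
        assert corr.rho.loc["x", "y"] == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)

    def test_matches_brute_force_oracle_with_ties(self, rng):
        """1,000 random 10-vectors incl. ties, against the midrank-Pearson oracle."""
        for _ in range(1000):
            x = rng.integers(0, 6, size=10).astype(float)
            y = rng.integers(0, 6, size=10).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            corr = self._matrix({"x": x, "y": y})
            assert corr.rho.loc["x", "y"] == pytest.approx(
                brute_force_spearman(x, y), abs=1e-10
            )

    def test_agrees_with_scipy_pairwise(self, rng):
        data = pd.DataFrame(rng.random((12, 6)), columns=list("abcdef"))
        corr = spearman_matrix(AbundanceTable(data))
        for i, a in enumerate(data.columns):
            for b in data.columns[i + 1:]:
                rho, p = stats.spearmanr(data[a], data[b])
                assert corr.rho.loc[a, b] == pytest.approx(rho, abs=1e-10)
                assert corr.p_raw.loc[a, b] == pytest.approx(p, abs=1e-8)

    def test_symmetry_and_unit_diagonal(self, rng):
        data = pd.DataFrame(rng.random((10, 8)))
        data.columns = [f"t{i}" for i in range(8)]
        corr = spearman_matrix(AbundanceTable(data))
        assert np.allclose(corr.rho.to_numpy(), corr.rho.to_numpy().T, atol=1e-12)
        assert np.allclose(np.diag(corr.rho), 1.0)
        assert ((corr.p_adj.to_numpy() - corr.p_raw.to_numpy()) >= -1e-12).all()

    def test_constant_taxon_flagged_not_fatal(self, rng):
        data = pd.DataFrame({"a": rng.random(8), "b": rng.random(8), "c": [0.3] * 8})
        corr = spearman_matrix(AbundanceTable(data))
        assert corr.constant_taxa == ("c",)
        assert corr.rho.loc["a", "c"] == 0.0
        assert corr.p_raw.loc["a", "c"] == 1.0

    def test_too_few_samples(self):
        data = pd.DataFrame(np.random.default_rng(0).random((3, 4)))
        data.columns = list("abcd")
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(AbundanceTable(data))

    def test_permutation_p_close_to_t_approx(self, rng):
        data = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        t_based = spearman_matrix(AbundanceTable(data))
        perm = spearman_matrix(AbundanceTable(data), n_permutations=2000, seed=0)
        diff = np.abs(t_based.p_raw.to_numpy() - perm.p_raw.to_numpy())
        assert diff[np.triu_indices(3, 1)].max() < 0.06


# -- BH ----------------------------------------------------------------------


class TestBHAdjust:
    def test_worked_example(self):
        out = bh_adjust([0.002, 0.005, 0.03, 0.04])
        assert np.allclose(out, [0.008, 0.010, 0.040, 0.040])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_matches_independent_implementations(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            p = rng.random(rng.integers(1, 20))
            ours = bh_adjust(p)
            assert np.allclose(ours, brute_force_bh(list(p)), atol=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, sm, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_bounded_below_by_input_and_above_by_one(self, p):
        out = bh_adjust(p)
        assert (out >= np.asarray(p) - 1e-15).all()
        assert (out <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# -- network construction ----------------------------------------------------


def _corrset(rho_entries, p_entries, ids=("t1", "t2", "t3")):
    from ceconet.corrnet import CorrelationMatrixSet

    n = len(ids)
    rho = np.eye(n)
    p = np.zeros((n, n))
    for (i, j), v in rho_entries.items():
        rho[i, j] = rho[j, i] = v
    for (i, j), v in p_entries.items():
        p[i, j] = p[j, i] = v
    rho_df = pd.DataFrame(rho, index=ids, columns=ids)
    p_df = pd.DataFrame(p, index=ids, columns=ids)
    return CorrelationMatrixSet(rho_df, p_df, p_df.copy(), n_samples=16)


class TestBuildNetwork:
    def test_threshold_application(self):
        corr = _corrset(
            {(0, 1): 0.9, (0, 2): 0.9, (1, 2): -0.75},
            {(0, 1): 0.01, (0, 2): 0.2, (1, 2): 0.01},
        )
        net = build_network(corr)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset({"t1", "t2"}), frozenset({"t2", "t3"})
        }
        assert net.graph["t1"]["t2"]["sign"] == "+"
        assert net.graph["t2"]["t3"]["sign"] == "-"

    def test_rho_exactly_at_threshold_is_excluded(self):
        corr = _corrset({(0, 1): 0.7}, {(0, 1): 0.001})
        net = build_network(corr)
        assert net.n_edges == 0

    def test_degenerate_config_gives_complete_graph(self, rng):
        data = pd.DataFrame(rng.random((10, 5)), columns=list("abcde"))
        corr = spearman_matrix(AbundanceTable(data))
        net = build_network(corr, NetworkConfig(rho_threshold=1e-9, alpha=0.999999))
        assert net.n_edges == 5 * 4 // 2

    def test_invariant_under_taxon_permutation(self, rng):
        data = pd.DataFrame(rng.random((14, 8)), columns=[f"t{i}" for i in range(8)])
        cfg = NetworkConfig(rho_threshold=0.3, alpha=0.5, use_adjusted_p=False)
        net1 = build_network(spearman_matrix(AbundanceTable(data)), cfg)
        shuffled = data[list(rng.permutation(data.columns))]
        net2 = build_network(spearman_matrix(AbundanceTable(shuffled)), cfg)
        edges1 = {frozenset(e) for e in net1.graph.edges}
        edges2 = {frozenset(e) for e in net2.graph.edges}
        assert edges1 == edges2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(rho_threshold=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(alpha=1.5)
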