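"""Network construction: correlations, adjacency, TOM, modules, eigengenes.

The TOM and eigengene computations are checked against independent oracles
(brute-force triple sum; eigendecomposition of the sample-space Gram matrix).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cochnet as cn
from cochnet.errors import ConfigError, ValidationError
from cochnet.network import UNASSIGNED, _module_eigengene


def expr_from_array(x: np.ndarray, scale: str = "log2") -> cn.ExpressionMatrix:
    """Wrap a genes x samples array with a minimal consistent design."""
    n = x.shape[1]
    models = ["aging", "noise", "cisplatin"]
    rows = []
    for j in range(n):
        if j < max(2, n - 6):
            rows.append((f"s{j}", "shared", "control", j))
        else:
            m = models[j % 3]
            rows.append((f"s{j}", m, "early" if j % 2 else "late", j))
    design = pd.DataFrame(rows, columns=["sample_id", "model", "stage",
                                         "replicate"])
    values = pd.DataFrame(x, index=[f"g{i}" for i in range(x.shape[0])],
                          columns=design["sample_id"])
    return cn.ExpressionMatrix(values, design, scale=scale)


# ---------------------------------------------------------------------------
# correlations


class TestCorrelationMatrix:
    def test_duplicated_and_negated_rows(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 12)
        x = np.vstack([base, base, -base])
        cor, flags = cn.correlation_matrix(expr_from_array(x))
        assert cor.iloc[0, 1] == pytest.approx(1.0)
        assert cor.iloc[0, 2] == pytest.approx(-1.0)
        assert flags == []

    def test_constant_gene_zeroed_and_flagged(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, 10), np.full(10, 3.0)])
        cor, flags = cn.correlation_matrix(expr_from_array(x))
        assert flags == ["g1"]
        assert cor.iloc[0, 1] == 0.0
        assert cor.iloc[1, 1] == 1.0

    def test_requires_three_samples(self):
        with pytest.raises(ValidationError):
            cn.correlation_matrix(expr_from_array(np.ones((3, 2))))

    def test_requires_log_scale(self):
        m = expr_from_array(np.abs(np.random.default_rng(2).normal(
            3, 1, (4, 8))), scale="linear")
        with pytest.raises(ValidationError):
            cn.correlation_matrix(m)


# ---------------------------------------------------------------------------
# adjacency and scale-free fit


class TestSignedAdjacency:
    @pytest.mark.parametrize("cor, expected", [
        (1.0, 1.0),
        (-1.0, 0.0),
        (0.0, 0.5**15),
    ])
    def test_closed_forms_at_power_15(self, cor, expected):
        a = cn.signed_adjacency(np.array([[1.0, cor], [cor, 1.0]]), 15)
        assert a[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_power_below_one_rejected(self):
        with pytest.raises(ConfigError):
            cn.signed_adjacency(np.eye(2), 0.5)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(2, 19))
    def test_raising_power_shrinks_imperfect_edges(self, beta):
        rng = np.random.default_rng(4)
        c = rng.uniform(-0.99, 0.99, (6, 6))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        lo, hi = cn.signed_adjacency(c, beta), cn.signed_adjacency(c, beta + 1)
        off = ~np.eye(6, dtype=bool)
        assert np.all(hi[off] < lo[off])


class TestScaleFreeFit:
    @staticmethod
    def power_law_degrees(gamma: float = 2.0) -> np.ndarray:
        ks = np.arange(1, 21)
        counts = np.round(20000 * ks**-gamma).astype(int)
        return np.repeat(ks.astype(float), counts)

    def test_exact_power_law_scores_high(self):
        assert cn.scale_free_fit(self.power_law_degrees()) >= 0.95

    def test_uniform_scores_below_power_law(self):
        uniform = np.linspace(1, 20, 2000)
        assert cn.scale_free_fit(uniform) < cn.scale_free_fit(
            self.power_law_degrees()
        )

    def test_degenerate_single_bin_flagged(self):
        assert np.isnan(cn.scale_free_fit(np.full(50, 7.0)))

    def test_increasing_distribution_gets_negative_sign(self):
        ks = np.arange(1, 21)
        counts = np.round(10 * ks**2).astype(int)
        k = np.repeat(ks.astype(float), counts)
        assert cn.scale_free_fit(k) < 0


class TestChoosePower:
    def test_smallest_power_reaching_target(self):
        table = pd.DataFrame({"power": [6, 10, 15, 20],
                              "r_squared": [0.2, 0.84, 0.86, 0.9]})
        assert cn.choose_power(table, 0.85) == 15

    def test_argmax_fallback_warns(self):
        table = pd.DataFrame({"power": [6, 10], "r_squared": [0.5, 0.6]})
        with pytest.warns(UserWarning, match="argmax"):
            assert cn.choose_power(table, 0.85) == 10

    def test_scan_mean_connectivity_non_increasing(self, default_network):
        # scan a thinned matrix to keep the test quick
        logm = default_network.logm
        thin = logm.subset_genes(logm.values.index[::8])
        scan = cn.pick_soft_threshold(thin, candidates=(2, 6, 10, 15),
                                      r2_target=0.8)
        mk = scan.table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(mk) <= 1e-9)
        assert scan.beta in (2, 6, 10, 15)

    def test_empty_candidates_rejected(self, default_network):
        with pytest.raises(ConfigError):
            cn.pick_soft_threshold(default_network.logm, candidates=())


# ---------------------------------------------------------------------------
# topological overlap


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """O(n^3) literal triple-sum oracle."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (L + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestTopologicalOverlap:
    def test_three_gene_hand_example(self):
        """All off-diagonal a = 0.5: k = 1, L_12 = 0.25, TOM_12 = 0.75/1.5."""
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = cn.topological_overlap(a)
        assert tom[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(tom), 1.0)

    def test_zero_adjacency_gives_zero_overlap(self):
        tom = cn.topological_overlap(np.eye(4) * 0.0)
        off = ~np.eye(4, dtype=bool)
        assert np.all(tom[off] == 0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = random_adjacency(rng, 20)
            assert np.max(np.abs(cn.topological_overlap(a)
                                 - tom_bruteforce(a))) < 1e-10

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValidationError):
            cn.topological_overlap(a)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_and_symmetry(self, seed):
        a = random_adjacency(np.random.default_rng(seed), 8)
        tom = cn.topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert np.all((tom >= 0) & (tom <= 1))


# ---------------------------------------------------------------------------
# module detection


class TestClusterModules:
    @staticmethod
    def two_block_expression(rng, per_block=50, n_samples=20):
        u = rng.normal(0, 1, n_samples)
        v = rng.normal(0, 1, n_samples)
        rows = [u * rng.uniform(0.8, 1.2) + rng.normal(0, 0.01, n_samples)
                for _ in range(per_block)]
        rows += [v * rng.uniform(0.8, 1.2) + rng.normal(0, 0.01, n_samples)
                 for _ in range(per_block)]
        return expr_from_array(np.array(rows))

    def test_two_clean_blocks_recovered_exactly(self):
        m = self.two_block_expression(np.random.default_rng(6))
        cor, _ = cn.correlation_matrix(m)
        tom = cn.topological_overlap(cn.signed_adjacency(cor, 15))
        part = cn.cluster_modules(
            pd.DataFrame(tom, index=cor.index, columns=cor.columns), m
        )
        assert len(part.modules()) == 2
        from sklearn.metrics import adjusted_rand_score
        planted = [0] * 50 + [1] * 50
        assert adjusted_rand_score(planted,
                                   part.labels.tolist()) == pytest.approx(1.0)

    def test_small_cluster_goes_unassigned(self):
        rng = np.random.default_rng(7)
        u = rng.normal(0, 1, 20)
        rows = [u * rng.uniform(0.8, 1.2) + rng.normal(0, 0.01, 20)
                for _ in range(10)]
        rows += [rng.normal(0, 1, 20) for _ in range(40)]
        m = expr_from_array(np.array(rows))
        cor, _ = cn.correlation_matrix(m)
        tom = cn.topological_overlap(cn.signed_adjacency(cor, 15))
        part = cn.cluster_modules(
            pd.DataFrame(tom, index=cor.index, columns=cor.columns), m,
            min_module_size=30,
        )
        assert (part.labels == UNASSIGNED).all()

    def test_min_size_below_two_rejected(self, default_network):
        with pytest.raises(ConfigError):
            cn.cluster_modules(default_network.tom, default_network.logm,
                               min_module_size=1)

    def test_default_bundle_recovery(self, default_bundle, default_network):
        ari = cn.module_recovery_ari(default_bundle.truth,
                                     default_network.part)
        assert ari >= 0.8

    def test_labels_ordered_by_decreasing_size(self, default_network):
        part = default_network.part
        sizes = [len(part.members(lab)) for lab in part.modules()]
        assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# eigengenes


def eigengene_oracle(x: np.ndarray) -> np.ndarray:
    """First principal direction via the sample-space Gram eigendecomposition
    (independent of the SVD route used by the implementation)."""
    z = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]
    gram = z.T @ z
    w, v = np.linalg.eigh(gram)
    return v[:, np.argmax(w)]


class TestModuleEigengenes:
    def test_identical_genes_module_reproduces_profile(self):
        rng = np.random.default_rng(8)
        profile = rng.normal(0, 1, 15)
        x = np.tile(profile, (6, 1))
        me = _module_eigengene(x)
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(me, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_first_pc_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(0, 1, (rng.integers(3, 25), rng.integers(5, 27)))
            me = _module_eigengene(x)
            pc = eigengene_oracle(x)
            assert abs(np.corrcoef(me, pc)[0, 1]) >= 1 - 1e-9
            assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_sign_convention_positive_on_mean_profile(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, (8, 12))
        for flip in (1.0, -1.0):
            me = _module_eigengene(flip * x)
            z = flip * x
            z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1,
                                                            keepdims=True)
            assert me @ z.mean(axis=0) >= 0

    def test_single_gene_module_is_normalized_profile(self):
        x = np.array([[1.0, 2.0, 4.0, 8.0]])
        me = _module_eigengene(x)
        z = (x[0] - x[0].mean()) / x[0].std()
        assert np.allclose(me, z / np.linalg.norm(z))

    def test_first_pc_explains_most_variance(self):
        """ME captures at least as much variance as random directions."""
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, (10, 20))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        me = _module_eigengene(x)
        me_var = np.sum((z @ me) ** 2)
        for _ in range(20):
            d = rng.normal(0, 1, 20)
            d /= np.linalg.norm(d)
            assert me_var >= np.sum((z @ d) ** 2) - 1e-9

    def test_missing_gene_rejected(self, default_network):
        part = default_network.part
        bad = cn.ModulePartition(pd.Series(
            ["M1"], index=["not_a_gene"], name="module"))
        with pytest.raises(ValidationError):
            cn.module_eigengenes(default_network.logm, bad)
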