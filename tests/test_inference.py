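"""Correlation, FDR, enhancement and edge-retention tests against
independent oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import estuarnet as en
from estuarnet.inference import CorrelationSet, env_edge_mask
from estuarnet.tables import RelAbundanceTable, SampleMetadata


def rel_from(arr):
    arr = np.asarray(arr, dtype=float)
    arr = arr / arr.sum(axis=0, keepdims=True)
    return RelAbundanceTable(pd.DataFrame(
        arr, index=[f"T{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])]))


def spearman_oracle(x, y):
    """Independent Spearman: explicit midranks + Pearson formula + t p-value."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    mx, my = rx.mean(), ry.mean()
    num = np.sum((rx - mx) * (ry - my))
    den = math.sqrt(np.sum((rx - mx) ** 2) * np.sum((ry - my) ** 2))
    if den == 0:
        return 0.0, 1.0
    rho = num / den
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, p


class TestSpearman:
    def test_monotone_identity(self):
        rel = rel_from([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [10, 8, 6, 4, 2]])
        cs = en.spearman_all_pairs(rel)
        assert cs.rho.loc["T0", "T1"] == pytest.approx(1.0)
        assert cs.rho.loc["T0", "T2"] == pytest.approx(-1.0)

    def test_matrix_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(1, 50, size=(10, 8)).astype(float)
        arr[2] = arr[2].round(-1)  # introduce ties
        rel = rel_from(arr)
        cs = en.spearman_all_pairs(rel)
        vals = rel.values
        for i in range(10):
            for j in range(10):
                rho, p = spearman_oracle(vals[i], vals[j])
                assert cs.rho.iloc[i, j] == pytest.approx(rho, abs=1e-12)
                if i != j:
                    assert cs.p.iloc[i, j] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_taxon_flagged(self):
        arr = np.array([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        rel = RelAbundanceTable(pd.DataFrame(
            arr / arr.sum(axis=0), index=["flat", "up", "down"],
            columns=list("abcd")))
        # make 'flat' exactly constant after normalisation
        rel.frame.loc["flat"] = 0.25
        cs = en.spearman_all_pairs(rel)
        assert "flat" in cs.flagged
        assert cs.rho.loc["flat", "up"] == 0.0
        assert cs.p.loc["flat", "up"] == 1.0

    def test_requires_four_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            en.spearman_all_pairs(rel_from([[1, 2, 3], [3, 2, 1]]))

    def test_symmetry_and_unit_diagonal(self, default_fixture):
        cs = default_fixture["cset"]
        r = cs.rho.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        q = cs.q.to_numpy()
        assert np.allclose(q, q.T)


class TestFDR:
    def test_hand_computed_step_up(self):
        q = en.adjust_fdr(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_ps(self):
        q = en.adjust_fdr(np.full(10, 0.04))
        assert q == pytest.approx(np.full(10, 0.04))

    def test_empty(self):
        assert en.adjust_fdr(np.array([])).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, ps):
        ps = np.array(ps)
        q = en.adjust_fdr(ps)
        assert (q <= 1 + 1e-12).all() and (q >= ps - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_step_up_oracle(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(size=25)
        m = len(ps)
        order = np.argsort(ps)
        q_sorted = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, ps[order[rank - 1]] * m / rank)
            q_sorted[rank - 1] = running
        expected = np.empty(m)
        expected[order] = q_sorted
        assert en.adjust_fdr(ps) == pytest.approx(expected)


def dense_enhance_oracle(W, K, alpha=0.9, tol=1e-9, rescale="node_max"):
    """Literal re-implementation: naive localisation, alternating Sinkhorn,
    iterated recurrence W ← a·T·W·Tᵀ + (1−a)·T, same scale restoration."""
    W = np.array(W, dtype=float)
    n = W.shape[0]
    np.fill_diagonal(W, 0.0)
    S = np.zeros_like(W)
    for i in range(n):
        idx = sorted(range(n), key=lambda j: (W[i, j], j))
        kept = [j for j in idx if j != i][-K:]
        for j in kept:
            S[i, j] = W[i, j]
    S = (S + S.T) / 2
    active = S.sum(axis=1) > 0
    A = S[np.ix_(active, active)]
    d = np.ones(A.shape[0])
    for _ in range(5000):
        r = A @ d
        r[r == 0] = 1
        d = np.sqrt(d / r)
        if np.max(np.abs(d * (A @ d) - 1)) < 1e-13:
            break
    T = np.zeros_like(S)
    T[np.ix_(active, active)] = (A * d[:, None]) * d[None, :]
    T = (T + T.T) / 2
    Wt = T.copy()
    for _ in range(100_000):
        Wn = alpha * T @ Wt @ T.T + (1 - alpha) * T
        if np.max(np.abs(Wn - Wt)) < tol:
            Wt = Wn
            break
        Wt = Wn
    out = (Wt + Wt.T) / 2
    diag = np.clip(np.diag(out).copy(), 0, 1 - 1e-12)
    out = out / (1 - diag)[:, None]
    np.fill_diagonal(out, 0.0)
    out = out * W.sum(axis=1)[:, None]
    out = (out + out.T) / 2
    out[out < 0] = 0
    mo, mw = out.max(axis=1), W.max(axis=1)
    s = np.where(mo > 0, np.sqrt(np.where(mo > 0, mw / np.where(mo > 0, mo, 1), 0)), 0)
    return out * s[:, None] * s[None, :]


def planted_two_block(n=12, strong=0.9, weak=0.1, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0, weak, size=(n, n))
    W = (W + W.T) / 2
    half = n // 2
    for blk in (slice(0, half), slice(half, n)):
        sub = rng.uniform(strong - 0.1, strong, size=(half, half))
        W[blk, blk] = (sub + sub.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


class TestEnhancement:
    def test_matches_dense_recurrence_oracle(self):
        W = planted_two_block(seed=1)
        got = en.network_enhance(W, K=4)
        want = dense_enhance_oracle(W, K=4)
        assert got == pytest.approx(want, abs=1e-4)

    def test_block_contrast_increases(self):
        W = planted_two_block(n=12, seed=2)
        out = en.network_enhance(W, K=4)
        half = 6
        mask_within = np.zeros_like(W, dtype=bool)
        mask_within[:half, :half] = True
        mask_within[half:, half:] = True
        np.fill_diagonal(mask_within, False)
        mask_between = ~mask_within
        np.fill_diagonal(mask_between, False)

        def contrast(M):
            return M[mask_within].mean() / max(M[mask_between].mean(), 1e-12)

        assert contrast(out) > contrast(W)

    def test_dominant_edge_remains_maximum(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(0, 0.2, size=(10, 10))
        W = (W + W.T) / 2
        W[1, 7] = W[7, 1] = 0.95
        np.fill_diagonal(W, 0.0)
        out = en.network_enhance(W, K=3)
        assert np.unravel_index(np.argmax(out), out.shape) in {(1, 7), (7, 1)}

    def test_two_node_single_edge_proportional(self):
        W = np.array([[0.0, 0.7], [0.7, 0.0]])
        out = en.network_enhance(W, K=1)
        assert out == pytest.approx(W)

    def test_never_exceeds_input_maximum(self, default_fixture):
        enh = default_fixture["enh"].to_numpy()
        rho = np.abs(default_fixture["cset"].rho.to_numpy())
        np.fill_diagonal(rho, 0.0)
        assert enh.max() <= rho.max() + 1e-9

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            en.network_enhance(np.array([[0, 1.0], [0.5, 0]]))

    def test_large_K_clamped_with_warning(self):
        W = planted_two_block(n=6, seed=0)
        with pytest.warns(UserWarning, match="clamping"):
            en.network_enhance(W, K=10)


def make_cset(rho, p, q):
    idx = pd.Index([f"T{i}" for i in range(rho.shape[0])], name="taxon")
    return CorrelationSet(rho=pd.DataFrame(rho, index=idx, columns=idx),
                          p=pd.DataFrame(p, index=idx, columns=idx),
                          q=pd.DataFrame(q, index=idx, columns=idx))


class TestBuildNetwork:
    def pair_cset(self, rho_val, p_val=0.001, q_val=0.01):
        rho = np.array([[1.0, rho_val], [rho_val, 1.0]])
        p = np.array([[0.0, p_val], [p_val, 0.0]])
        q = np.array([[0.0, q_val], [q_val, 0.0]])
        return make_cset(rho, p, q)

    def rel2(self):
        return rel_from([[1, 2, 3, 4], [2, 3, 4, 5]])

    def test_passing_pair_kept_with_sign(self):
        cs = self.pair_cset(0.7)
        enh = np.array([[0.0, 0.65], [0.65, 0.0]])
        g = en.build_network(self.rel2(), cs, enh)
        assert g.has_edge("T0", "T1")
        assert g.edges["T0", "T1"]["sign"] == "positive"

    def test_rho_at_cutoff_dropped(self):
        """The robustness bound is strict: |rho| = 0.60 exactly fails."""
        cs = self.pair_cset(0.60)
        enh = np.array([[0.0, 0.9], [0.9, 0.0]])
        with pytest.warns(UserWarning, match="empty"):
            g = en.build_network(self.rel2(), cs, enh)
        assert g.number_of_edges() == 0

    def test_enhancement_gate(self):
        cs = self.pair_cset(0.7)
        enh = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.warns(UserWarning, match="empty"):
            g = en.build_network(self.rel2(), cs, enh)
        assert g.number_of_edges() == 0

    def test_negative_edge_sign_restored(self):
        cs = self.pair_cset(-0.8)
        enh = np.array([[0.0, 0.8], [0.8, 0.0]])
        g = en.build_network(self.rel2(), cs, enh)
        assert g.edges["T0", "T1"]["sign"] == "negative"
        assert g.edges["T0", "T1"]["weight"] == pytest.approx(-0.8)

    def test_permutation_equivariance(self, zero_noise_fixture):
        rel = zero_noise_fixture["rel"]
        rng = np.random.default_rng(0)
        ti = rng.permutation(rel.n_taxa)
        si = rng.permutation(rel.n_samples)
        shuffled = RelAbundanceTable(rel.frame.iloc[ti, si].copy())
        cs = en.spearman_all_pairs(shuffled)
        enh = en.enhanced_weights(cs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net2 = en.build_network(shuffled, cs, enh)
        net1 = zero_noise_fixture["net"]
        assert set(map(frozenset, net2.edges)) == set(map(frozenset, net1.edges))

    def test_all_edges_satisfy_thresholds(self, default_fixture):
        net, cs = default_fixture["net"], default_fixture["cset"]
        for u, v in net.edges:
            assert abs(cs.rho.loc[u, v]) > 0.6
            assert cs.q.loc[u, v] < 0.05
            assert cs.p.loc[u, v] < 0.01


class TestEnvNetwork:
    def make_meta(self, temp):
        rows = [{"sample": f"S{j}", "station": "908", "year": 2003, "month": 8,
                 "temperature": t, "salinity": 5.0 + 0.01 * j}
                for j, t in enumerate(temp)]
        return SampleMetadata(pd.DataFrame(rows).set_index("sample"))

    def test_taxon_tracking_temperature_gets_unit_edge(self):
        temp = [3.0, 8.0, 15.0, 22.0, 27.0, 12.0, 18.0, 25.0]
        arr = np.array([temp, [10.0] * 8]) + 1.0
        rel = rel_from(arr)
        base = en.build_network(rel, en.spearman_all_pairs(rel), None,
                                rho_min=0.0, p_max=1.1, q_max=1.1)
        g = en.build_env_network(rel, self.make_meta(temp), base)
        assert g.has_edge("T0", "temperature")
        assert g.edges["T0", "temperature"]["weight"] == pytest.approx(1.0)

    def test_exact_point_six_kept_for_env(self):
        """The environment-network magnitude rule is inclusive: |r| = 0.6
        exactly passes (unlike the strict taxa-taxa bound)."""
        keep = env_edge_mask(np.array([0.01]), np.array([0.01]), np.array([0.6]))
        assert keep.all()
        drop = env_edge_mask(np.array([0.01]), np.array([0.01]), np.array([0.59]))
        assert not drop.any()

    def test_temperature_guild_connects_salinity_guild_does_not(self, environment):
        """One guild driven by temperature, one by salinity: only the former
        acquires temperature edges."""
        cfg = en.GuildConfig(n_guilds=2, taxa_per_guild=10, gatekeeper_count=0,
                             n_background=30, antagonist_pairs=(),
                             guild_factor_overlap=0.3, noise_sd=0.0, seed=8)
        table, tax, truth = en.generate_community(environment, cfg)
        rel = en.filter_taxa(en.to_relative(table))
        cs = en.spearman_all_pairs(rel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = en.build_network(rel, cs, None)
        g = en.build_env_network(rel, environment, base)
        g0 = [t for t, gl in truth.guild_of.items() if gl == 0 and t in g.nodes]
        g1 = [t for t, gl in truth.guild_of.items() if gl == 1 and t in g.nodes]
        temp_edges_g0 = sum(g.has_edge(t, "temperature") for t in g0)
        temp_edges_g1 = sum(g.has_edge(t, "temperature") for t in g1)
        assert temp_edges_g0 > 0
        assert temp_edges_g1 == 0
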