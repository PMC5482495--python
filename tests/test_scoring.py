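import numpy as np
import pandas as pd
import pytest

import gitscore as gs
from tests.conftest import dense_random_instance


def closed_form(G, F, k):
    """Independent oracle: sum_{m<=k} (-G)^m F by explicit matrix powers."""
    out = np.zeros_like(F)
    P = np.eye(G.shape[0])
    for m in range(k + 1):
        out += P @ F
        P = P @ (-G)
    return out


class TestGitToy:
    def test_hand_worked_one_hop(self, toy_fd, toy_nbh):
        sm = gs.git_hip(toy_fd, toy_nbh)
        assert sm.scores["c1"].tolist() == pytest.approx([-2.5, -2.5, 1.5])
        assert sm.orientation == "low_is_hit"

    def test_first_order_is_the_same_expression(self, toy_fd, toy_nbh):
        a = gs.git_hip(toy_fd, toy_nbh).scores
        b = gs.git_first(toy_fd, toy_nbh).scores
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_hand_worked_two_hop(self, toy_fd, toy_nbh):
        sm = gs.git_hop(toy_fd, toy_nbh)
        # A: -1 - [(-2.5)(-0.5) + (1.5)(0.5)] = -3.0
        assert sm.scores.loc["A", "c1"] == pytest.approx(-3.0)

    def test_no_edges_returns_fd(self, toy_fd):
        empty = gs.TruncatedNeighborhood({}, q=None)
        for fn in (gs.git_hip, gs.git_hop):
            out = fn(toy_fd, empty).scores
            assert np.array_equal(out.to_numpy(), toy_fd.fd.to_numpy())

    def test_missing_own_fd_propagates(self, toy_fd, toy_nbh):
        fd = gs.FitnessMatrix(toy_fd.fd.copy())
        fd.fd.loc["A", "c1"] = np.nan
        hip = gs.git_hip(fd, toy_nbh).scores
        assert np.isnan(hip.loc["A", "c1"])
        # B's neighbor A is missing and contributes 0
        assert hip.loc["B", "c1"] == pytest.approx(-2.0)


class TestGitOracle:
    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_matches_closed_form_on_dense_instances(self, k):
        rng = np.random.default_rng(202)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            fd, net, G = dense_random_instance(rng, n, edge_p=0.6)
            got = gs.git_k(fd, gs.truncate(net, None), k).scores.to_numpy()
            want = closed_form(G, fd.fd.to_numpy(), k)
            assert np.max(np.abs(got - want)) < 1e-10

    def test_k_one_and_two_match_named_scores(self, small_sim):
        fd, nbh = small_sim["fd_hip"], small_sim["nbh"]
        np.testing.assert_array_equal(
            gs.git_k(fd, nbh, 1).scores.to_numpy(),
            gs.git_hip(fd, nbh).scores.to_numpy(),
        )
        np.testing.assert_array_equal(
            gs.git_k(fd, nbh, 2).scores.to_numpy(),
            gs.git_hop(fd, nbh).scores.to_numpy(),
        )

    def test_truncation_to_full_degree_equals_full_network(self, small_sim):
        fd, net = small_sim["fd_hip"], small_sim["net"]
        full = gs.git_hip(fd, gs.truncate(net, None)).scores
        q_big = gs.git_hip(fd, gs.truncate(net, 10**6)).scores
        np.testing.assert_array_equal(full.to_numpy(), q_big.to_numpy())

    def test_linearity_in_fd(self, small_sim):
        fd, nbh = small_sim["fd_hip"], small_sim["nbh"]
        scaled = gs.FitnessMatrix(fd.fd * 3.0)
        for k in (1, 2):
            a = gs.git_k(fd, nbh, k).scores.to_numpy() * 3.0
            b = gs.git_k(scaled, nbh, k).scores.to_numpy()
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_gene_and_compound_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        fd, net, _ = dense_random_instance(rng, 20, edge_p=0.4)
        nbh = gs.truncate(net, None)
        base = gs.git_hop(fd, nbh).scores
        perm_g = rng.permutation(fd.gene_ids)
        perm_c = rng.permutation(fd.compound_ids)
        fd_p = gs.FitnessMatrix(fd.fd.loc[perm_g, perm_c])
        out_p = gs.git_hop(fd_p, nbh).scores
        np.testing.assert_allclose(
            out_p.to_numpy(), base.loc[perm_g, perm_c].to_numpy(), atol=1e-12
        )


class TestRho:
    def _nbh(self, weights):
        net = gs.GINetwork.from_edges(
            [("t", f"n{i}", w) for i, w in enumerate(weights)]
        )
        return net, gs.truncate(net, None)

    def test_perfect_positive_correlation(self):
        net, nbh = self._nbh([0.5, 1.0, 2.0])
        fd = pd.DataFrame(
            {"c1": [0.0, 1.0, 2.0, 4.0]}, index=["t", "n0", "n1", "n2"]
        )
        sm = gs.rho(gs.FitnessMatrix(fd), nbh)
        assert sm.scores.loc["t", "c1"] == pytest.approx(1.0)
        assert sm.orientation == "high_is_hit"

    def test_against_correlation_oracle(self):
        w = [-0.5, 0.3, 0.4]
        fds = [-2.0, 1.0, 0.0]
        net, nbh = self._nbh(w)
        fd = pd.DataFrame({"c1": [0.0] + fds}, index=["t", "n0", "n1", "n2"])
        got = gs.rho(gs.FitnessMatrix(fd), nbh).scores.loc["t", "c1"]
        want = np.corrcoef(fds, w)[0, 1]
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.907, abs=5e-4)

    def test_too_few_neighbors_or_missing_pairs_gives_missing(self):
        net, nbh = self._nbh([0.5, 1.0, 2.0])
        fd = pd.DataFrame(
            {"c1": [0.0, 1.0, np.nan, 4.0]}, index=["t", "n0", "n1", "n2"]
        )
        sm = gs.rho(gs.FitnessMatrix(fd), nbh)  # only 2 usable pairs
        assert np.isnan(sm.scores.loc["t", "c1"])
        net1, nbh1 = self._nbh([0.5])
        fd1 = pd.DataFrame({"c1": [0.0, 1.0]}, index=["t", "n0"])
        assert np.isnan(gs.rho(gs.FitnessMatrix(fd1), nbh1).scores.loc["t", "c1"])

    def test_zero_variance_gives_missing(self):
        net, nbh = self._nbh([1.0, 1.0, 1.0])
        fd = pd.DataFrame(
            {"c1": [0.0, 1.0, 2.0, 3.0]}, index=["t", "n0", "n1", "n2"]
        )
        assert np.isnan(gs.rho(gs.FitnessMatrix(fd), nbh).scores.loc["t", "c1"])

    def test_bounded_wherever_defined(self, small_sim):
        sm = gs.rho(small_sim["fd_hip"], small_sim["nbh"]).scores.to_numpy()
        finite = sm[np.isfinite(sm)]
        assert finite.size > 0
        assert np.all(finite >= -1 - 1e-12) and np.all(finite <= 1 + 1e-12)


class TestCombine:
    def _scores(self, d, method="git_hip"):
        return gs.ScoreMatrix(pd.DataFrame(d), "low_is_hit", method)

    def test_sample_sd_standardization(self):
        hip = self._scores({"c1": {"a": -2.0, "b": 0.0, "c": 2.0}})
        comb = gs.combine_hip_hop(hip, hip)
        assert comb.scores["c1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_identical_z_profiles_average_to_themselves(self, small_sim):
        hip = gs.git_hip(small_sim["fd_hip"], small_sim["nbh"])
        comb = gs.combine_hip_hop(hip, hip)
        z = gs.scoring.zscore_columns(hip.scores)
        np.testing.assert_allclose(
            comb.scores.to_numpy(), z.to_numpy(), atol=1e-12
        )

    def test_gene_policy(self):
        hip = self._scores({"c1": {"a": -2.0, "b": 0.0, "c": 2.0}})
        hop = self._scores({"c1": {"a": -1.0, "b": 1.0}})
        inter = gs.combine_hip_hop(hip, hop, gene_policy="intersection")
        assert set(inter.scores.index) == {"a", "b"}
        union = gs.combine_hip_hop(hip, hop, gene_policy="union")
        # c only in HIP: gets HIP z alone
        z_hip = gs.scoring.zscore_columns(hip.scores)
        assert union.scores.loc["c", "c1"] == pytest.approx(z_hip.loc["c", "c1"])

    def test_compound_missing_from_one_assay_warns(self, caplog):
        hip = self._scores({"c1": {"a": -2.0, "b": 0.0, "c": 2.0}})
        hop = self._scores({"c2": {"a": -2.0, "b": 0.0, "c": 2.0}})
        with caplog.at_level("WARNING"):
            comb = gs.combine_hip_hop(hip, hop)
        assert set(comb.scores.columns) == {"c1", "c2"}

    def test_requires_low_is_hit(self, small_sim):
        r = gs.rho(small_sim["fd_hip"], small_sim["nbh"])
        hip = gs.git_hip(small_sim["fd_hip"], small_sim["nbh"])
        with pytest.raises(ValueError, match="low"):
            gs.combine_hip_hop(hip, r)


class TestExplain:
    def test_toy_decomposition(self, toy_fd, toy_nbh):
        rep = gs.explain(toy_fd, toy_nbh, "A", "c1", method="hip")
        assert rep.terms == [("B", -0.5, -2.0, 1.0), ("C", 0.5, 1.0, 0.5)]
        assert rep.score == pytest.approx(-2.5)
        assert rep.own_fd - sum(t[3] for t in rep.terms) == pytest.approx(rep.score)

    def test_no_neighbors_score_is_fd(self, toy_fd):
        rep = gs.explain(toy_fd, gs.TruncatedNeighborhood({}, None), "A", "c1")
        assert rep.terms == []
        assert rep.score == toy_fd.fd.loc["A", "c1"]

    def test_hop_uses_first_order_neighbor_scores(self, toy_fd, toy_nbh):
        rep = gs.explain(toy_fd, toy_nbh, "A", "c1", method="hop")
        used = {j: s for j, _, s, _ in rep.terms}
        first = gs.git_first(toy_fd, toy_nbh).scores["c1"]
        assert used["B"] == pytest.approx(first["B"])
        assert rep.score == pytest.approx(-3.0)

    def test_reconstruction_identity_on_simulation(self, small_sim):
        fd, nbh = small_sim["fd_hip"], small_sim["nbh"]
        gene = fd.gene_ids[3]
        comp = fd.compound_ids[0]
        for method, fn in (("hip", gs.git_hip), ("hop", gs.git_hop)):
            rep = gs.explain(fd, nbh, gene, comp, method=method)
            assert rep.score == pytest.approx(
                fn(fd, nbh).scores.loc[gene, comp], abs=1e-9
            )

    def test_unknown_ids_raise(self, toy_fd, toy_nbh):
        with pytest.raises(KeyError):
            gs.explain(toy_fd, toy_nbh, "nope", "c1")
        with pytest.raises(KeyError):
            gs.explain(toy_fd, toy_nbh, "A", "nope")


class TestUnsignedHubBias:
    def test_equal_weight_unsigned_network_penalizes_hubs_linearly(self):
        # hub with degree d and constant FD c: score = c * (1 - w*d),
        # so under an unsigned network the expected score falls linearly
        # with degree — the hub-prioritization artifact of unsigned variants
        w, c = 0.1, 1.0
        edges = []
        degrees = {}
        gid = 0
        for d in (1, 3, 6, 10):
            hub = f"hub{d}"
            degrees[hub] = d
            for _ in range(d):
                edges.append((hub, f"leaf{gid}", w))
                gid += 1
        net = gs.GINetwork.from_edges(edges, signed=False)
        genes = sorted({g for e in edges for g in e[:2]})
        fd = gs.FitnessMatrix(
            pd.DataFrame({"c1": [c] * len(genes)}, index=genes)
        )
        sm = gs.git_hip(fd, gs.truncate(net, None)).scores["c1"]
        for hub, d in degrees.items():
            assert sm[hub] == pytest.approx(c * (1 - w * d))
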