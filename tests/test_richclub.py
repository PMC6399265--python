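"""Rich-club coefficient, rewired nulls and node taxonomy against exhaustive
and networkx oracles."""

import numpy as np
import networkx as nx
import pytest

from connhier import (
    classify_nodes, normalized_rich_club, rewire_preserving_degrees,
    rich_club_curve, sfc_class_engagement, stratify_gradient_by_class,
)
from connhier.connectome import SparseConnectome


def _complete(n):
    return np.ones((n, n)) - np.eye(n)


def brute_force_phi_binary(A, k):
    """Exhaustive subgraph oracle: density among nodes of degree > k."""
    deg = A.sum(axis=1)
    keep = np.flatnonzero(deg > k)
    if len(keep) < 2:
        return np.nan
    sub = A[np.ix_(keep, keep)]
    E = sub.sum() / 2
    m = len(keep)
    return 2 * E / (m * (m - 1))


class TestRichClubCurve:
    def test_complete_graph_is_one(self):
        ks, phi = rich_club_curve(_complete(5), mode="binary")
        for k, p in zip(ks, phi):
            if k <= 3:
                assert p == pytest.approx(1.0)

    def test_star_low_k_undefined(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1  # hub degree 5, spokes degree 1
        ks, phi = rich_club_curve(A, mode="binary")
        assert np.isnan(phi[0])  # only the hub has degree > 1

    def test_matches_exhaustive_oracle_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 13))
            A = (rng.random((n, n)) < 0.4).astype(float)
            A = np.triu(A, 1); A = A + A.T
            ks, phi = rich_club_curve(A, mode="binary")
            for k, p in zip(ks, phi):
                expect = brute_force_phi_binary(A, k)
                if np.isnan(expect):
                    assert np.isnan(p)
                else:
                    assert p == pytest.approx(expect, abs=1e-12)

    def test_matches_networkx(self, rng):
        A = (rng.random((12, 12)) < 0.5).astype(float)
        A = np.triu(A, 1); A = A + A.T
        G = nx.from_numpy_array(A)
        G.remove_edges_from(nx.selfloop_edges(G))
        nx_phi = nx.rich_club_coefficient(G, normalized=False)
        ks, phi = rich_club_curve(A, mode="binary")
        for k, p in zip(ks, phi):
            if k in nx_phi and not np.isnan(p):
                assert p == pytest.approx(nx_phi[k], abs=1e-12)

    def test_weighted_mode_denominator(self, rng):
        n = 8
        W = np.triu(rng.uniform(0.1, 1.0, (n, n)) * (rng.random((n, n)) < 0.6), 1)
        W = W + W.T
        ks, phi = rich_club_curve(W, mode="weighted")
        deg = (W > 0).sum(axis=1)
        wsorted = np.sort(W[np.triu_indices(n, 1)])[::-1]
        for k, p in zip(ks, phi):
            keep = np.flatnonzero(deg > k)
            if len(keep) < 2:
                assert np.isnan(p)
                continue
            sub = W[np.ix_(keep, keep)]
            Wk = sub.sum() / 2
            Ek = int((sub > 0).sum() / 2)
            if Ek == 0:
                assert np.isnan(p)
                continue
            assert p == pytest.approx(Wk / wsorted[:Ek].sum(), abs=1e-12)

    def test_negative_weights_rejected(self):
        W = -_complete(4)
        with pytest.raises(ValueError, match="negative"):
            rich_club_curve(W)


class TestRewiring:
    def test_degree_sequence_preserved_exactly(self, rng):
        for trial in range(5):
            n = 20
            W = np.triu(rng.uniform(0.2, 1, (n, n)) * (rng.random((n, n)) < 0.3), 1)
            W = W + W.T
            null = rewire_preserving_degrees(W, seed=trial)
            np.testing.assert_array_equal((null > 0).sum(axis=1), (W > 0).sum(axis=1))

    def test_weight_multiset_preserved(self, rng):
        n = 15
        W = np.triu(rng.uniform(0.2, 1, (n, n)) * (rng.random((n, n)) < 0.4), 1)
        W = W + W.T
        null = rewire_preserving_degrees(W, seed=0)
        np.testing.assert_allclose(
            np.sort(null[np.triu_indices(n, 1)]),
            np.sort(W[np.triu_indices(n, 1)]), atol=1e-15)

    def test_complete_graph_cannot_rewire(self):
        with pytest.warns(RuntimeWarning, match="no swappable"):
            out = rewire_preserving_degrees(_complete(5), seed=0)
        np.testing.assert_array_equal(out, _complete(5))


class TestNormalizedRichClub:
    def test_complete_graph_phi_norm_is_one(self):
        with pytest.warns(RuntimeWarning):
            res = normalized_rich_club(_complete(6), n_null=5, seed=0, mode="binary")
        ok = np.isfinite(res.phi_norm)
        np.testing.assert_allclose(res.phi_norm[ok], 1.0, atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        n = 14
        W = np.triu(rng.uniform(0.2, 1, (n, n)) * (rng.random((n, n)) < 0.4), 1)
        W = W + W.T
        a = normalized_rich_club(W, n_null=10, seed=42)
        b = normalized_rich_club(W, n_null=10, seed=42)
        np.testing.assert_array_equal(a.phi_norm, b.phi_norm)
        assert a.k_prime == b.k_prime

    def test_er_graph_phi_norm_near_one(self, rng):
        """Degree-homogeneous random graphs carry no rich club: phi_norm ~ 1
        within Monte-Carlo tolerance at small k."""
        n, p = 40, 0.3
        A = (rng.random((n, n)) < p).astype(float)
        A = np.triu(A, 1); A = A + A.T
        n_null = 60
        res = normalized_rich_club(A, n_null=n_null, seed=1, mode="binary")
        # recompute null SD for tolerance
        null_vals = []
        import numpy.random as npr
        from connhier.richclub import rich_club_curve as rcc
        for i in range(n_null):
            Wn = rewire_preserving_degrees(A, seed=1000 + i)
            null_vals.append(rcc(Wn, mode="binary")[1])
        null_vals = np.array(null_vals)
        for ki in range(5):
            if not np.isfinite(res.phi_norm[ki]):
                continue
            sd = np.nanstd(null_vals[:, ki])
            mean = np.nanmean(null_vals[:, ki])
            tol = 3 * sd / np.sqrt(n_null) / max(mean, 1e-9) + 1e-9
            assert abs(res.phi_norm[ki] - 1) < max(tol, 0.05)


class TestClassifyNodes:
    def test_hub_and_spokes_all_feeders(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1
        cls = classify_nodes(A, k_prime=5)
        assert cls[0] == "rich"
        assert (cls[1:] == "feeder").all()

    def test_all_local_when_k_prime_above_degrees(self):
        A = np.zeros((8, 8))
        A[:4, :4] = _complete(4)
        A[4:, 4:] = _complete(4)
        with pytest.warns(RuntimeWarning, match="no rich"):
            cls = classify_nodes(A, k_prime=10)
        assert (cls == "local").all()

    def test_matches_per_node_ratio_oracle(self, rng):
        n = 12
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.triu(A, 1); A = A + A.T
        deg = A.sum(axis=1)
        kp = int(np.percentile(deg, 75))
        cls = classify_nodes(A, kp)
        rich = deg >= kp
        for i in range(n):
            if rich[i]:
                assert cls[i] == "rich"
            elif deg[i] > 0:
                frac = A[i, rich].sum() / deg[i]
                assert cls[i] == ("feeder" if frac >= 0.10 else "local")
            else:
                assert cls[i] == "local"

    def test_partitions_nodes(self, rng):
        A = (rng.random((15, 15)) < 0.3).astype(float)
        A = np.triu(A, 1); A = A + A.T
        cls = classify_nodes(A, 3)
        assert set(cls) <= {"rich", "feeder", "local"}
        assert len(cls) == 15


class TestStratification:
    def test_one_subject_per_group_rejected(self, rng):
        g1 = rng.normal(size=(2, 10))
        cls = np.array(["rich"] * 5 + ["local"] * 5, dtype=object)
        with pytest.raises(ValueError, match="2 subjects"):
            stratify_gradient_by_class(g1, cls, np.array(["case", "control"]))

    def test_identical_groups_no_rejections(self, rng):
        """Null calibration: no class is flagged much above the nominal rate."""
        hits = 0
        reps = 60
        for i in range(reps):
            r = np.random.default_rng(i)
            g1 = r.normal(size=(20, 30))
            cls = np.array(["rich"] * 10 + ["feeder"] * 10 + ["local"] * 10,
                           dtype=object)
            groups = np.array(["case"] * 10 + ["control"] * 10)
            df = stratify_gradient_by_class(g1, cls, groups)
            hits += int(df["significant"].any())
        assert hits / reps < 0.25  # BH across 3 classes, nominal q=0.05

    def test_planted_shift_detected(self, rng):
        g1 = rng.normal(size=(30, 30))
        g1[:15, :10] -= 2.0  # cases reduced in rich nodes
        cls = np.array(["rich"] * 10 + ["feeder"] * 10 + ["local"] * 10,
                       dtype=object)
        groups = np.array(["case"] * 15 + ["control"] * 15)
        df = stratify_gradient_by_class(g1, cls, groups)
        row = df[df.node_class == "rich"].iloc[0]
        assert row.t < 0 and row.significant and row.d < 0


class TestEngagement:
    def _profile(self, zmaps):
        from connhier.sfc import SFCProfile
        return SFCProfile(zmaps=zmaps, seed_set=np.array([0]),
                          raw_scale_log=np.zeros(zmaps.shape[1]))

    def test_all_active_ratio_one(self):
        z = np.full((9, 4), 2.0)
        cls = np.array(["rich"] * 3 + ["feeder"] * 3 + ["local"] * 3, dtype=object)
        df = sfc_class_engagement(self._profile(z), cls, theta=1.0)
        assert (df.rich_frac == 1).all() and (df.rich_local_ratio == 1).all()

    def test_no_local_active_ratio_missing(self):
        z = np.full((6, 2), 2.0)
        z[3:] = -2.0
        cls = np.array(["rich"] * 3 + ["local"] * 3, dtype=object)
        df = sfc_class_engagement(self._profile(z), cls, theta=1.0)
        assert df.rich_local_ratio.isna().all()

    def test_counting_oracle(self, rng):
        z = rng.normal(size=(12, 5))
        cls = np.array(["rich"] * 4 + ["feeder"] * 4 + ["local"] * 4, dtype=object)
        df = sfc_class_engagement(self._profile(z), cls, theta=0.5)
        for l in range(5):
            for name, idx in (("rich", slice(0, 4)), ("feeder", slice(4, 8)),
                              ("local", slice(8, 12))):
                expect = (z[idx, l] >= 0.5).mean()
                assert df.loc[l, f"{name}_frac"] == pytest.approx(expect)
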