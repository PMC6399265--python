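"""Synthetic cohort generator: planted structure, determinism, closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from connhier import (
    CohortConfig, make_cohort, make_node_space, make_subject_connectome,
    make_symptom_scores, make_timeseries,
)
from connhier.cohort import COMMUNITY_LEVEL, SubjectSpec


def _noiseless_config(**kw):
    return CohortConfig(
        noise_sd=0, motion_coef=0, site_scale_sd=0, site_offset_sd=0,
        effect_sd=0, **kw,
    )


class TestNodeSpace:
    def test_level_means_ordered(self, node_space):
        means = [
            node_space.hierarchy_score[node_space.hierarchy_level == l].mean()
            for l in (1, 2, 3, 4)
        ]
        assert means == sorted(means)
        assert means[0] < means[3]

    def test_deterministic_given_seed(self):
        a = make_node_space(120, seed=7)
        b = make_node_space(120, seed=7)
        np.testing.assert_array_equal(a.hierarchy_score, b.hierarchy_score)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_distance_tracks_hierarchy_separation_bruteforce(self):
        sizes = {1: 3, 2: 3, 3: 3, 4: 3, 5: 2, 6: 3, 7: 3}
        sp = make_node_space(20, community_sizes=sizes, seed=2)
        # brute force over all pairs
        ds, dhs = [], []
        for i in range(20):
            for j in range(i + 1, 20):
                ds.append(np.linalg.norm(sp.coordinates[i] - sp.coordinates[j]))
                dhs.append(abs(sp.hierarchy_score[i] - sp.hierarchy_score[j]))
        assert pearsonr(ds, dhs).statistic > 0

    def test_bad_community_sizes_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            make_node_space(50, community_sizes={c: 5 for c in range(1, 8)}, seed=0)

    def test_seed_subsets_disjoint_and_in_level1(self, node_space):
        idx = [set(v.tolist()) for v in node_space.seed_nodes.values()]
        assert all(idx[i].isdisjoint(idx[j]) for i in range(3) for j in range(i + 1, 3))
        for nodes in node_space.seed_nodes.values():
            assert set(node_space.hierarchy_level[nodes]) == {1}

    def test_every_community_maps_to_one_level(self, node_space):
        df = pd.DataFrame({"c": node_space.community, "l": node_space.hierarchy_level})
        assert (df.groupby("c")["l"].nunique() == 1).all()
        assert dict(df.drop_duplicates().itertuples(index=False)) == COMMUNITY_LEVEL


class TestSubjectConnectome:
    def test_noiseless_subjects_identical(self, node_space):
        cfg = _noiseless_config()
        sp = SubjectSpec("a", "control", "siteA", 20, "M", 0.0)
        c1 = make_subject_connectome(node_space, sp, cfg, seed=1)
        c2 = make_subject_connectome(node_space, sp, cfg, seed=99)
        np.testing.assert_array_equal(c1.weights, c2.weights)

    def test_matches_closed_form_weight_model(self):
        space = make_node_space(30, community_sizes={1: 5, 2: 5, 3: 4, 4: 4,
                                                     5: 4, 6: 4, 7: 4}, seed=5)
        cfg = _noiseless_config()
        gamma, rho = 0.6, 0.2
        sp = SubjectSpec("a", "case", "siteA", 20, "M", 0.0, gamma=gamma, rho=rho)
        c = make_subject_connectome(space, sp, cfg, seed=0)
        # independent closed-form evaluation, elementwise loops
        h = 0.5 + gamma * (space.hierarchy_score - 0.5)
        for i in range(0, 30, 7):
            for j in range(0, 30, 5):
                if i == j:
                    continue
                w = (np.exp(-abs(h[i] - h[j]) / cfg.tau_h)
                     + cfg.beta_c * (space.community[i] == space.community[j])
                     + cfg.hub_strength * 0.5 * (h[i] ** 2 + h[j] ** 2))
                if np.linalg.norm(space.coordinates[i] - space.coordinates[j]) > cfg.d0:
                    w *= 1 - rho
                assert c.weights[i, j] == pytest.approx(w, abs=1e-12)

    def test_compression_raises_cross_level_weights(self, node_space):
        cfg = _noiseless_config()
        c10 = make_subject_connectome(
            node_space, SubjectSpec("a", "control", "siteA", 20, "M", 0, gamma=1.0),
            cfg, seed=0)
        c06 = make_subject_connectome(
            node_space, SubjectSpec("a", "case", "siteA", 20, "M", 0, gamma=0.6),
            cfg, seed=0)
        lv1 = node_space.level_indices(1)
        lv4 = node_space.level_indices(4)
        block10 = c10.weights[np.ix_(lv1, lv4)]
        block06 = c06.weights[np.ix_(lv1, lv4)]
        # compression pulls the poles together: local-kernel part of every
        # cross-pole weight increases; hub part shrinks less than kernel gains
        assert block06.mean() > block10.mean()

    def test_uniform_attenuation_when_cutoff_below_min_distance(self, node_space):
        cfg0 = _noiseless_config(d0=0.0, hub_strength=0.0)
        base = _noiseless_config(d0=1e9, hub_strength=0.0)
        w_rho = make_subject_connectome(
            node_space, SubjectSpec("a", "case", "siteA", 20, "M", 0, rho=0.5),
            cfg0, seed=0).weights
        w_ref = make_subject_connectome(
            node_space, SubjectSpec("a", "case", "siteA", 20, "M", 0, rho=0.0),
            base, seed=0).weights
        np.testing.assert_allclose(w_rho, 0.5 * w_ref, atol=1e-12)


class TestTimeSeries:
    def test_identity_target_gives_near_zero_offdiag_correlations(self):
        from connhier.connectome import Connectome
        n = 6
        c = Connectome(np.zeros((n, n)))
        ts = make_timeseries(c, 5000, seed=0)
        r = np.corrcoef(ts.values)
        off = r[~np.eye(n, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_two_node_target_correlation_recovered(self):
        from connhier.connectome import Connectome
        # weights scaled so the rescaled target correlation is exactly 0.9
        c = Connectome(np.array([[0.0, 1.0], [1.0, 0.0]]))
        ts = make_timeseries(c, 20000, seed=1)
        r = np.corrcoef(ts.values)[0, 1]
        assert r == pytest.approx(0.9, abs=0.02)

    def test_deterministic(self, node_space, small_cohort):
        _, _, conns = small_cohort
        a = make_timeseries(conns[0], 50, seed=3)
        b = make_timeseries(conns[0], 50, seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestSymptomScores:
    def _cohort_frame(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["case"] * (n // 2) + ["control"] * (n - n // 2),
            "site": ["siteA"] * n,
        }), rng

    def test_noiseless_single_feature_perfect_correlation(self):
        df, rng = self._cohort_frame(60)
        # feature scale large vs the integer rounding of the score
        feats = 20.0 * rng.normal(size=(60, 1))
        cfg = CohortConfig(symptom_coefs=(1.0,), symptom_r2_target=None,
                           symptom_noise_sd=0.0, symptom_intercept=100.0)
        out = make_symptom_scores(df, feats, cfg, seed=1)
        case = out["group"] == "case"
        r = pearsonr(out.loc[case, "score_total"], feats[case.to_numpy(), 0]).statistic
        assert r > 0.999  # integer rounding only

    def test_controls_stay_missing(self):
        df, rng = self._cohort_frame(40)
        out = make_symptom_scores(df, rng.normal(size=(40, 2)), CohortConfig(), seed=0)
        assert out.loc[out.group == "control", "score_total"].isna().all()
        assert out.loc[out.group == "case", "score_total"].notna().all()

    def test_planted_r2_recovered_by_refit(self):
        df, rng = self._cohort_frame(400)
        feats = rng.normal(size=(400, 2))
        cfg = CohortConfig(symptom_coefs=(3.0, 2.0), symptom_r2_target=0.5,
                           symptom_intercept=30.0)
        out = make_symptom_scores(df, feats, cfg, seed=2)
        case = (out.group == "case").to_numpy()
        y = out.loc[case, "score_total"].to_numpy()
        X = np.column_stack([np.ones(case.sum()), feats[case]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid.var() / y.var()
        assert r2 == pytest.approx(0.5, abs=0.07)

    def test_zero_variance_feature_with_nonzero_coef_rejected(self):
        df, _ = self._cohort_frame(40)
        feats = np.ones((40, 1))
        cfg = CohortConfig(symptom_coefs=(1.0,))
        with pytest.raises(ValueError, match="zero feature variance"):
            make_symptom_scores(df, feats, cfg, seed=0)


class TestCohortAssembly:
    def test_bit_reproducible(self):
        cfg = CohortConfig(n_per_group_per_site=2, master_seed=11)
        s1, m1, c1, _ = make_cohort(cfg)
        s2, m2, c2, _ = make_cohort(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_enlarging_cohort_keeps_existing_subjects(self):
        small = CohortConfig(n_per_group_per_site=2, master_seed=11)
        big = CohortConfig(n_per_group_per_site=3, master_seed=11)
        _, ms, cs, _ = make_cohort(small)
        _, mb, cb, _ = make_cohort(big)
        # match on (site, group, order within cell)
        key = ["site", "group"]
        for (site, grp), sub_s in ms.groupby(key):
            sub_b = mb[(mb.site == site) & (mb.group == grp)]
            for k in range(len(sub_s)):
                i_s, i_b = sub_s.index[k], sub_b.index[k]
                assert ms.loc[i_s, "age"] == mb.loc[i_b, "age"]
                np.testing.assert_array_equal(cs[i_s].weights, cb[i_b].weights)

    def test_group_effect_means(self, small_cohort):
        _, manifest, _ = small_cohort
        assert manifest.query("group == 'case'").gamma.mean() < 0.85
        assert manifest.query("group == 'control'").gamma.mean() > 0.9
        assert manifest.query("group == 'case'").rho.mean() > 0.2
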