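import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

import drugrank as dr
from drugrank import io as pio
from drugrank._utils import benjamini_hochberg
from drugrank.discovery import (
    DiscoveryParams,
    DrugSkipped,
    fit_variance_prior,
    make_resample_groups,
    moderated_ttest,
    screen_group_pairs,
    split_sensitive_resistant,
)


class TestSplit:
    def test_median_split(self):
        row = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"), name="d")
        sens, res = split_sensitive_resistant(row, min_group_size=2)
        assert sens == {"c", "d"} and res == {"a", "b"}

    def test_tie_goes_to_sensitive(self):
        row = pd.Series([0.1, 0.5, 0.9], index=list("abc"), name="d")
        sens, res = split_sensitive_resistant(row, min_group_size=1)
        assert sens == {"b", "c"} and res == {"a"}

    def test_degenerate_or_sparse_rows_skip(self):
        with pytest.raises(DrugSkipped, match="degenerate"):
            split_sensitive_resistant(pd.Series([0.5] * 12, index=range(12), name="d"))
        with pytest.raises(DrugSkipped, match="observed"):
            split_sensitive_resistant(pd.Series([0.1, 0.9], index=["a", "b"], name="d"))


class TestResampleGroups:
    def test_leave_one_fold_out_structure(self):
        members = [f"c{i}" for i in range(10)]
        groups = make_resample_groups(members, k=10, seed=1)
        assert len(groups) == 10
        assert all(len(g) == 9 for g in groups)
        # union of a subset with its excluded fold is the full member set
        for g in groups:
            excluded = set(members) - set(g)
            assert set(g) | excluded == set(members)

    def test_fold_sizes_within_one(self):
        groups = make_resample_groups([f"c{i}" for i in range(13)], k=10, seed=0)
        sizes = {13 - len(g) for g in groups}
        assert sizes <= {1, 2}

    def test_deterministic_given_seed(self):
        members = [f"c{i}" for i in range(9)]
        assert make_resample_groups(members, seed=42) == make_resample_groups(members, seed=42)
        assert make_resample_groups(members, seed=42) != make_resample_groups(members, seed=43)


class TestScreen:
    def test_maximal_separation_retains_all_pairs(self):
        aac = pd.Series([0.9] * 10 + [0.1] * 10,
                        index=[f"s{i}" for i in range(10)] + [f"r{i}" for i in range(10)])
        sg = make_resample_groups(aac.index[:10], seed=0)
        rg = make_resample_groups(aac.index[10:], seed=1)
        assert len(screen_group_pairs(sg, rg, aac)) == 100

    def test_no_separation_retains_none(self):
        aac = pd.Series([0.5] * 20, index=[f"c{i}" for i in range(20)])
        sg = make_resample_groups(aac.index[:10], seed=0)
        rg = make_resample_groups(aac.index[10:], seed=1)
        assert screen_group_pairs(sg, rg, aac) == []

    def test_matches_brute_force_welch_per_pair(self):
        rng = np.random.default_rng(2)
        idx = [f"c{i}" for i in range(24)]
        aac = pd.Series(np.concatenate([rng.normal(0.6, 0.15, 12), rng.normal(0.45, 0.15, 12)]),
                        index=idx)
        sg = make_resample_groups(idx[:12], seed=3)
        rg = make_resample_groups(idx[12:], seed=4)
        retained = set(screen_group_pairs(sg, rg, aac))
        expected = set()
        for i in range(10):
            for j in range(10):
                p = stats.ttest_ind(aac[sg[i]], aac[rg[j]], equal_var=False).pvalue
                if p < 0.05:
                    expected.add((i, j))
        assert retained == expected


def _moderated_oracle(values, labels):
    """Independent moderated-t implementation: per-feature loops and a
    bracketed root solve for the trigamma inversion."""
    from scipy.optimize import brentq

    sens_cols = [c for c in values.columns if labels[c] == "sensitive"]
    res_cols = [c for c in values.columns if labels[c] == "resistant"]
    coefs, s2s, dfs, n1s, n2s = [], [], [], [], []
    for _, row in values.iterrows():
        a = row[sens_cols].dropna().to_numpy(dtype=float)
        b = row[res_cols].dropna().to_numpy(dtype=float)
        n1, n2 = len(a), len(b)
        coefs.append(a.mean() - b.mean())
        df = n1 + n2 - 2
        s2s.append(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df)
        dfs.append(df)
        n1s.append(n1)
        n2s.append(n2)
    s2, df = np.array(s2s), np.array(dfs, dtype=float)
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2))
    if evar > 0:
        x = brentq(lambda v: special.polygamma(1, v) - evar, 1e-8, 1e8)
        d0 = 2 * x
        s0 = np.exp(np.mean(e) + special.digamma(x) - np.log(x))
    else:
        d0, s0 = np.inf, float(np.exp(np.mean(e)))
    out = []
    for coef, s2i, dfi, n1, n2 in zip(coefs, s2, df, n1s, n2s):
        post = s0 if np.isinf(d0) else (d0 * s0 + dfi * s2i) / (d0 + dfi)
        t = coef / np.sqrt(post * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), d0 + dfi)
        out.append((coef, t, p))
    return d0, s0, out


class TestModeratedTtest:
    def _simulated(self, seed=0, n_features=50, n1=6, n2=6, hetero=True):
        rng = np.random.default_rng(seed)
        sds = rng.uniform(0.5, 2.0, n_features) if hetero else np.ones(n_features)
        effects = np.where(rng.random(n_features) < 0.3, rng.normal(0, 2, n_features), 0.0)
        vals = np.column_stack([
            rng.normal(effects if i < n1 else 0.0, sds) for i in range(n1 + n2)
        ])
        cols = [f"s{i}" for i in range(n1)] + [f"r{i}" for i in range(n2)]
        values = pd.DataFrame(vals, columns=cols,
                              index=[f"f{i}" for i in range(n_features)])
        labels = pd.Series(["sensitive"] * n1 + ["resistant"] * n2, index=cols)
        return values, labels

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_closed_form_oracle(self, seed):
        values, labels = self._simulated(seed)
        res = moderated_ttest(values, labels)
        d0, s0, rows = _moderated_oracle(values, labels)
        if np.isfinite(d0):
            assert res.d0 == pytest.approx(d0, rel=1e-6)
        else:
            assert np.isinf(res.d0)
        assert res.s0_sq == pytest.approx(s0, rel=1e-6)
        for (coef, t, p), (_, got) in zip(rows, res.table.iterrows()):
            assert got["coef"] == pytest.approx(coef, rel=1e-6, abs=1e-12)
            assert got["t"] == pytest.approx(t, rel=1e-6)
            assert got["p_raw"] == pytest.approx(p, rel=1e-6)

    def test_zero_prior_df_degenerates_to_pooled_t(self):
        # with d0 = 0 the posterior variance is the per-feature s2, so the
        # moderated statistic equals the ordinary pooled t exactly
        values, labels = self._simulated(seed=4)
        res = moderated_ttest(values, labels, prior=(0.0, 1.0))
        for f in values.index:
            a = values.loc[f, labels == "sensitive"]
            b = values.loc[f, labels == "resistant"]
            t_ord = stats.ttest_ind(a, b, equal_var=True)
            assert res.table.loc[f, "t"] == pytest.approx(t_ord.statistic, rel=1e-9)
            assert res.table.loc[f, "p_raw"] == pytest.approx(t_ord.pvalue, rel=1e-9)

    def test_identical_variances_shrink_to_near_pooled_t(self):
        # every feature shares the same s2: shrinkage to the common variance
        # is close to the identity (the closed-form prior scale carries a
        # small log-space bias correction, so agreement is approximate)
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 12)
        shifts = rng.normal(0, 3, 30)
        values = pd.DataFrame([base + (np.arange(12) < 6) * s for s in shifts],
                              index=[f"f{i}" for i in range(30)],
                              columns=[f"c{i}" for i in range(12)])
        labels = pd.Series(["sensitive"] * 6 + ["resistant"] * 6, index=values.columns)
        res = moderated_ttest(values, labels)
        for f in values.index:
            a = values.loc[f, labels == "sensitive"]
            b = values.loc[f, labels == "resistant"]
            t_ord = stats.ttest_ind(a, b, equal_var=True).statistic
            assert res.table.loc[f, "t"] == pytest.approx(t_ord, rel=0.1)

    def test_null_feature_gives_zero_t(self):
        values, labels = self._simulated(seed=5)
        values.iloc[0] = np.tile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], 2)
        res = moderated_ttest(values, labels)
        assert res.table.iloc[0]["coef"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.iloc[0]["t"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.iloc[0]["p_raw"] == pytest.approx(1.0)

    def test_sign_of_t_equals_sign_of_coef(self):
        values, labels = self._simulated(seed=6)
        res = moderated_ttest(values, labels)
        ok = res.table.dropna()
        assert (np.sign(ok["t"]) == np.sign(ok["coef"])).all()

    def test_too_few_features_rejected(self):
        values, labels = self._simulated()
        with pytest.raises(ValueError, match="2 features"):
            moderated_ttest(values.iloc[:1], labels)


class TestVariancePrior:
    def test_zero_spread_gives_infinite_prior_df(self):
        s2 = np.full(40, 1.3)
        d0, s0 = fit_variance_prior(s2, np.full(40, 10.0))
        assert np.isinf(d0)
        assert s0 > 0


class TestBenjaminiHochberg:
    def test_closed_form_example(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(2, 40))
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)


class TestIdentifyEmdr:
    def test_sign_flipped_response_swaps_marker_sides(self, small_panel):
        omics, responses, _ = small_panel
        normed = pio.center_scale_features(omics, stats_from="cell_lines")
        drug = responses.drug_ids[0]
        entry = dr.identify_emdr(normed, responses, drug, seed=9)
        flipped_aac = responses.aac.copy()
        flipped_aac.loc[drug] = 1.0 - flipped_aac.loc[drug]
        flipped = dr.identify_emdr(normed, dr.DrugResponseTable(flipped_aac, scaled=True),
                                   drug, seed=9)
        assert set(flipped.sensitivity) == set(entry.resistance)
        assert set(flipped.resistance) == set(entry.sensitivity)

    def test_deterministic_catalog(self, small_panel):
        omics, responses, _ = small_panel
        normed = pio.center_scale_features(omics, stats_from="cell_lines")
        drugs = responses.drug_ids[:2]
        c1 = dr.build_catalog(normed, responses, seed=11, drugs=drugs)
        c2 = dr.build_catalog(normed, responses, seed=11, drugs=drugs)
        for d in drugs:
            assert c1.entries[d].sensitivity == c2.entries[d].sensitivity
            assert c1.entries[d].support == c2.entries[d].support

    def test_zero_variance_feature_never_a_marker(self, small_panel):
        omics, responses, _ = small_panel
        normed = pio.center_scale_features(omics, stats_from="cell_lines")
        flat = normed.values.copy()
        flat.iloc[0] = 0.0
        from dataclasses import replace
        m = replace(normed, values=flat)
        entry = dr.identify_emdr(m, responses, responses.drug_ids[0], seed=1)
        assert flat.index[0] not in entry.sensitivity
        assert flat.index[0] not in entry.resistance

    def test_support_fractions_within_bounds(self, small_panel):
        omics, responses, _ = small_panel
        normed = pio.center_scale_features(omics, stats_from="cell_lines")
        params = DiscoveryParams()
        entry = dr.identify_emdr(normed, responses, responses.drug_ids[1], params, seed=2)
        assert set(entry.sensitivity) & set(entry.resistance) == set()
        for rec in entry.support.values():
            assert params.consistency <= rec["fraction"] <= 1.0
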