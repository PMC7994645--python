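import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import drugrank as dr
from drugrank.enrichment import (
    delta_enrichment,
    enrich_emdr,
    enrichment_profile,
    read_gmt,
    similarity_scores,
    write_gmt,
)


def _hypergeom_sf_oracle(a, d, c, b):
    """P[X >= a] drawing b from a background of d with c in the set,
    by exhaustive enumeration of the hypergeometric pmf."""
    total = 0.0
    for k in range(a, min(b, c) + 1):
        total += comb(c, k) * comb(d - c, b - k) / comb(d, b)
    return total


class TestEnrich:
    def test_proportional_counts_give_ratio_one(self):
        bg = [f"f{i}" for i in range(1000)]
        sets = {"S": bg[:500]}
        markers = bg[:5] + bg[500:505]  # a=5, b=10, c=500, d=1000
        out = enrich_emdr(markers, sets, bg)
        assert out.loc[0, "ratio"] == pytest.approx(1.0)

    def test_printed_formula_arithmetic(self):
        bg = [f"f{i}" for i in range(1000)]
        sets = {"S": bg[:50]}
        markers = bg[:5] + bg[900:905]  # a=5, b=10, c=50, d=1000
        out = enrich_emdr(markers, sets, bg)
        assert out.loc[0, "ratio"] == pytest.approx(10.0)

    def test_p_matches_exhaustive_enumeration_small_backgrounds(self):
        for d in (10, 16, 20, 25):
            bg = [f"f{i}" for i in range(d)]
            for c in (3, d // 2):
                sets = {"S": bg[:c]}
                for b in (3, min(8, d)):
                    markers = bg[d - b:]
                    out = enrich_emdr(markers, sets, bg)
                    a = int(out.loc[0, "a"])
                    assert out.loc[0, "p"] == pytest.approx(
                        _hypergeom_sf_oracle(a, d, c, b), abs=1e-12)

    def test_ratio_invariant_under_proportional_scaling(self):
        # doubling background and set in proportion leaves the ratio unchanged
        bg1 = [f"f{i}" for i in range(100)]
        bg2 = [f"f{i}" for i in range(200)]
        m = bg1[:6]
        r1 = enrich_emdr(m, {"S": bg1[:20]}, bg1).loc[0, "ratio"]
        r2 = enrich_emdr(m, {"S": bg2[:40]}, bg2).loc[0, "ratio"]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_marker_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich_emdr({"x"}, {"S": ["a"]}, {"a", "b"})

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            enrich_emdr({"a"}, {"S": ["a"]}, set())

    def test_small_sets_skipped(self):
        bg = [f"f{i}" for i in range(30)]
        out = enrich_emdr(bg[:5], {"tiny": bg[:2], "ok": bg[:10]}, bg)
        assert list(out["set_id"]) == ["ok"]


class TestDelta:
    def _records(self, ratios):
        return pd.DataFrame([{"set_id": s, "ratio": r, "a": 1, "b": 1, "c": 1, "d": 1,
                              "p": 0.5} for s, r in ratios.items()])

    def test_equal_sides_cancel(self):
        d = delta_enrichment(self._records({"S": 2.0}), self._records({"S": 2.0}))
        assert d["S"] == 0.0

    def test_swapping_sides_negates(self):
        a, b = self._records({"S": 3.0, "T": 1.0}), self._records({"S": 0.5, "T": 2.0})
        pd.testing.assert_series_equal(delta_enrichment(a, b), -delta_enrichment(b, a))

    def test_missing_side_counts_as_zero(self):
        d = delta_enrichment(self._records({"S": 4.0}), self._records({}))
        assert d["S"] == 4.0

    def test_planted_set_has_maximal_delta(self):
        bg = [f"f{i}" for i in range(200)]
        sens = set(bg[:15])
        res = set(bg[100:115])
        sets = {"planted": bg[:20], "other1": bg[40:80], "other2": bg[120:180]}
        es = enrich_emdr(sens, sets, bg)
        er = enrich_emdr(res, sets, bg)
        delta = delta_enrichment(es, er)
        assert delta.idxmax() == "planted"


class TestSimilarity:
    def _delta_matrix(self, seed=0, n_drugs=8, n_sets=12):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n_drugs, n_sets)),
                            index=[f"d{i}" for i in range(n_drugs)],
                            columns=[f"s{i}" for i in range(n_sets)])

    def test_identical_vectors_have_maximal_scaled_score(self):
        dm = self._delta_matrix()
        dm.loc["d1"] = dm.loc["d0"]
        sim = similarity_scores(dm)
        assert sim.raw_r.loc["d0", "d1"] == pytest.approx(1.0)
        off = sim.scaled.to_numpy()[np.triu_indices(len(dm), 1)]
        assert sim.scaled.loc["d0", "d1"] == pytest.approx(np.nanmax(off))

    def test_scaled_distribution_median_zero_sd_one(self):
        sim = similarity_scores(self._delta_matrix(seed=1))
        off = sim.scaled.to_numpy()[np.triu_indices(len(sim.scaled), 1)]
        off = off[np.isfinite(off)]
        assert np.median(off) == pytest.approx(0.0, abs=1e-9)
        assert np.std(off, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_three_drug_covariance_oracle(self):
        dm = self._delta_matrix(seed=2, n_drugs=3, n_sets=5)
        sim = similarity_scores(dm)
        for a, b in itertools.combinations(dm.index, 2):
            x, y = dm.loc[a].to_numpy(), dm.loc[b].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
            assert sim.raw_r.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_permutation_consistent(self):
        dm = self._delta_matrix(seed=3)
        sim = similarity_scores(dm)
        pd.testing.assert_frame_equal(sim.raw_r, sim.raw_r.T)
        perm = list(dm.index[::-1])
        sim2 = similarity_scores(dm.loc[perm])
        pd.testing.assert_frame_equal(sim2.raw_r.loc[dm.index, dm.index], sim.raw_r)

    def test_constant_vector_yields_missing_pairs(self):
        dm = self._delta_matrix(seed=4)
        dm.loc["d0"] = 1.0
        sim = similarity_scores(dm)
        assert sim.raw_r.loc["d0"].drop("d0").isna().all()

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            similarity_scores(self._delta_matrix(n_drugs=2))


class TestClusterSimilarity:
    def test_within_cluster_similarity_exceeds_between(self):
        """Drugs sharing planted marker features score as more similar."""
        from drugrank.simulate import PanelSpec
        spec = PanelSpec(n_cell_lines=20, n_replicates=2, n_features=600, n_drugs=12,
                         n_clusters=3, n_sens_markers=16, n_res_markers=16,
                         marker_share_fraction=0.5, missing_rate=0.0, seed=21)
        omics, responses, truth = dr.generate_panel(spec)
        from drugrank import io as pio
        normed = pio.center_scale_features(omics, stats_from="cell_lines")
        catalog = dr.build_catalog(normed, responses, seed=3)
        bg = omics.feature_ids
        # gene sets from the per-cluster marker pools plus random sets
        rng = np.random.default_rng(0)
        sets = {}
        for c in range(spec.n_clusters):
            members = sorted(set().union(*[
                truth.sensitivity_markers[d] + truth.resistance_markers[d]
                for d in truth.clusters if truth.clusters[d] == c]))
            sets[f"cluster{c}"] = members
        for i in range(6):
            sets[f"rand{i}"] = list(rng.choice(bg, size=30, replace=False))
        delta = enrichment_profile(catalog, sets, bg)
        sim = similarity_scores(delta)
        within, between = [], []
        for a, b in itertools.combinations(delta.index, 2):
            score = sim.scaled.loc[a, b]
            if not np.isfinite(score):
                continue
            (within if truth.clusters[a] == truth.clusters[b] else between).append(score)
        assert np.mean(within) > np.mean(between)


def test_gmt_round_trip(tmp_path):
    sets = {"SET1": ["a", "b", "c"], "SET2": ["d", "e"]}
    path = tmp_path / "x.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
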