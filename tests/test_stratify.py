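"""Feature selection, consensus clustering, diagnostics and merging."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, spearmanr
from sklearn.metrics import adjusted_rand_score, silhouette_samples

import metastrat as ms
from metastrat._stats import hypergeom_tail
from metastrat.data import KEY_FACTORS
from metastrat.preprocess import NormalizedMatrix
from metastrat.stratify import (StratifyConfig, pearson_distance,
                                second_step_cluster)


def _norm(df, layer="metabolite"):
    return NormalizedMatrix(layer=layer, data=df, mode="zscore")


def _clinical(n, rng, extra=0):
    cols = list(KEY_FACTORS) + [f"X{i}" for i in range(extra)]
    df = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols,
                      index=[f"s{i}" for i in range(n)])
    return ms.ClinicalTable(df)


class TestSelection:
    def test_matches_brute_force_oracle(self, rng):
        n_mol, n_samp = 80, 30
        data = pd.DataFrame(rng.normal(size=(n_mol, n_samp)),
                            index=[f"m{i}" for i in range(n_mol)],
                            columns=[f"s{i}" for i in range(n_samp)])
        clinical = _clinical(n_samp, rng)
        sel = ms.select_clinical_relevant({"metabolite": _norm(data)},
                                          clinical, ms.KeyFactorMap())
        cutoff = int(np.floor(0.3 * n_mol))
        for disease, (f1, f2) in ms.KeyFactorMap().items():
            a1 = data.apply(
                lambda r: abs(spearmanr(r, clinical.data[f1]).statistic), axis=1)
            a2 = data.apply(
                lambda r: abs(spearmanr(r, clinical.data[f2]).statistic), axis=1)
            qualify = set(a1.nlargest(cutoff).index) & \
                set(a2.nlargest(cutoff).index)
            expect = set(((a1 + a2) / 2)[list(qualify)]
                         .nlargest(50).index) if len(qualify) > 50 else qualify
            got = set(sel.selected("metabolite", disease)["molecule_id"])
            assert got == expect

    def test_single_factor_correlation_insufficient(self, rng):
        """A molecule tracking one key factor but not the other is excluded."""
        n_samp = 40
        clinical = _clinical(n_samp, rng)
        rows = {f"noise{i}": rng.normal(size=n_samp) for i in range(30)}
        rows["only_f1"] = clinical.data["BMI"].to_numpy() \
            + 0.01 * rng.normal(size=n_samp)
        data = pd.DataFrame(rows).T
        data.columns = clinical.sample_ids
        sel = ms.select_clinical_relevant({"metabolite": _norm(data)},
                                          clinical, ms.KeyFactorMap())
        obesity = sel.table[(sel.table["disease"] == "obesity")
                            & (sel.table["molecule_id"] == "only_f1")].iloc[0]
        assert obesity["rank_f1"] == 1
        # top-30% in BMI alone does not guarantee selection: WaistCir rank rules
        if obesity["rank_f2"] > int(0.3 * len(data)):
            assert not obesity["selected"]

    def test_cap_keeps_largest_mean_abs(self, rng):
        """With >50 qualifiers exactly the 50 largest mean |rho| survive."""
        n_samp = 40
        clinical = _clinical(n_samp, rng)
        f1 = clinical.data["BMI"].to_numpy()
        f2 = clinical.data["WaistCir"].to_numpy()
        rows = {}
        for i in range(60):  # correlated with both, decreasing strength
            lam = 1.0 - i * 0.012
            rows[f"sig{i:02d}"] = lam * (f1 + f2) + (1 - lam) * \
                rng.normal(size=n_samp)
        for i in range(140):
            rows[f"noise{i:03d}"] = rng.normal(size=n_samp)
        data = pd.DataFrame(rows).T
        data.columns = clinical.sample_ids
        sel = ms.select_clinical_relevant({"metabolite": _norm(data)},
                                          clinical, ms.KeyFactorMap())
        obesity = sel.table[(sel.table["disease"] == "obesity")
                            & sel.table["selected"]]
        assert len(obesity) == 50
        ranked = sel.table[sel.table["disease"] == "obesity"]
        qualify = ranked[(ranked["rank_f1"] <= 60) & (ranked["rank_f2"] <= 60)]
        expect = set(qualify.nlargest(50, "mean_abs_rho")["molecule_id"])
        assert set(obesity["molecule_id"]) == expect


def _blobs(n_per=10, n_feat=40, shift=6.0, seed=1):
    """Two groups with opposite signatures on half the features, so both
    have internal covariation under the 1 - Pearson sample distance."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_feat, n_per))
    b = rng.normal(0, 1, size=(n_feat, n_per))
    a[: n_feat // 2] -= shift / 2
    b[: n_feat // 2] += shift / 2
    data = np.hstack([a, b])
    cols = [f"s{i}" for i in range(2 * n_per)]
    truth = np.array([0] * n_per + [1] * n_per)
    return pd.DataFrame(data, columns=cols), truth


class TestConsensus:
    def test_two_blobs_recovered_with_block_consensus(self):
        m_r, truth = _blobs()
        res = ms.consensus_cluster(m_r, k_final=2, reps=100,
                                   subsample_frac=0.8, seed=1)
        assert adjusted_rand_score(truth, res.labels) == 1.0
        cons = res.consensus.to_numpy()
        same = truth[:, None] == truth[None, :]
        assert cons[same].min() > 0.9
        assert cons[~same].max() < 0.1

    def test_single_rep_full_sample_gives_binary_entries(self):
        m_r, _ = _blobs()
        res = ms.consensus_cluster(m_r, k_final=2, reps=1,
                                   subsample_frac=1.0, seed=0)
        assert set(np.unique(res.consensus.to_numpy())) <= {0.0, 1.0}

    def test_duplicated_sample_reaches_consensus_one(self):
        m_r, _ = _blobs()
        m_r["dup"] = m_r["s0"]
        res = ms.consensus_cluster(m_r, k_final=2, reps=50,
                                   subsample_frac=0.8, seed=3)
        assert res.consensus.loc["s0", "dup"] == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        m_r, _ = _blobs()
        res = ms.consensus_cluster(m_r, k_final=3, reps=60, seed=2)
        cons = res.consensus.to_numpy()
        np.testing.assert_allclose(cons, cons.T)
        assert cons.min() >= 0.0 and cons.max() <= 1.0

    def test_never_cosampled_pair_raises(self):
        m_r, _ = _blobs(n_per=6)
        with pytest.raises(ValueError, match="never co-sampled"):
            ms.consensus_cluster(m_r, k_final=2, reps=1,
                                 subsample_frac=0.5, seed=0)


class TestSilhouette:
    def test_matches_textbook_brute_force_on_six_points(self, rng):
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dist = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        labels = pd.Series(["x", "x", "y", "y", "z", "z"],
                           index=list("abcdef"))
        widths, _ = ms.silhouette_widths(labels, dist)
        for i, s in enumerate("abcdef"):
            own = [j for j in range(6)
                   if labels.iloc[j] == labels.iloc[i] and j != i]
            a = np.mean([d[i, j] for j in own])
            b = min(np.mean([d[i, j] for j in range(6)
                             if labels.iloc[j] == c])
                    for c in labels.unique() if c != labels.iloc[i])
            assert widths[s] == pytest.approx((b - a) / max(a, b))

    def test_agrees_with_sklearn(self, rng):
        pts = rng.normal(size=(20, 4))
        pts[10:] += 3.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        idx = [f"s{i}" for i in range(20)]
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=idx)
        widths, _ = ms.silhouette_widths(labels,
                                         pd.DataFrame(d, index=idx, columns=idx))
        ref = silhouette_samples(d, labels.to_numpy(), metric="precomputed")
        np.testing.assert_allclose(widths.to_numpy(), ref, atol=1e-12)

    def test_tight_distant_clusters_score_high(self):
        m_r, truth = _blobs(shift=10.0)
        labels = pd.Series(np.where(truth == 0, "a", "b"), index=m_r.columns)
        _, per_cluster = ms.silhouette_widths(labels, pearson_distance(m_r))
        assert per_cluster.min() > 0.8

    def test_random_labels_near_zero(self, rng):
        vals = []
        for _ in range(30):
            data = pd.DataFrame(rng.normal(size=(30, 16)),
                                columns=[f"s{i}" for i in range(16)])
            labels = pd.Series(rng.permutation(["a"] * 8 + ["b"] * 8),
                               index=data.columns)
            widths, _ = ms.silhouette_widths(labels, pearson_distance(data))
            vals.append(widths.mean())
        assert abs(np.mean(vals)) < 0.1

    def test_singleton_cluster_width_zero(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 5)),
                            columns=[f"s{i}" for i in range(5)])
        labels = pd.Series(["a", "a", "b", "b", "c"], index=data.columns)
        widths, _ = ms.silhouette_widths(labels, pearson_distance(data))
        assert widths["s4"] == 0.0


def _design_49():
    ids, labels = [], []
    for code in "abcdefg":
        for i in range(7):
            ids.append(f"{code}{i}")
            labels.append(code)
    return ms.CohortDesign(pd.Series(labels, index=ids, name="disease"))


class TestEnrichment:
    def test_reproduces_printed_cluster_p_values(self):
        """Printed compositions give p = 1e-5, 1e-3.7, 1e-2."""
        design = _design_49()
        # C2: 12 samples, all 7 MTS; C4: 7 samples, 5 T2D; C3: 13, 5 HT
        labels = {}
        labels.update({f"c{i}": "C2" for i in range(7)})
        labels.update({f"a{i}": "C2" for i in range(5)})
        labels.update({f"g{i}": "C4" for i in range(5)})
        labels.update({f"b{i}": "C4" for i in range(2)})
        labels.update({f"e{i}": "C3" for i in range(5)})
        labels.update({f"d{i}": "C3" for i in range(4)})
        labels.update({f"f{i}": "C3" for i in range(4)})  # C3 size 13
        rest = [s for s in design.sample_ids if s not in labels]
        for i, s in enumerate(rest):
            labels[s] = "C1" if i < 9 else "C5"
        labels = pd.Series(labels).loc[design.sample_ids]
        enr = ms.cluster_disease_enrichment(labels, design)
        assert enr.loc["C2", "c"] == pytest.approx(9.22e-6, rel=1e-3)
        assert enr.loc["C4", "g"] == pytest.approx(2.139e-4, rel=1e-3)
        assert enr.loc["C3", "e"] == pytest.approx(1.018e-2, rel=1e-3)
        assert np.log10(enr.loc["C2", "c"]) == pytest.approx(-5.0, abs=0.1)
        assert np.log10(enr.loc["C4", "g"]) == pytest.approx(-3.7, abs=0.1)
        assert np.log10(enr.loc["C3", "e"]) == pytest.approx(-2.0, abs=0.1)

    def test_absent_disease_gives_p_one_region(self):
        design = _design_49()
        labels = pd.Series(["C1" if s.startswith(("a", "b"))
                            else "C2" for s in design.sample_ids],
                           index=design.sample_ids)
        enr = ms.cluster_disease_enrichment(labels, design)
        assert enr.loc["C2", "a"] == pytest.approx(1.0)

    def test_matches_scipy_fisher_on_random_tables(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 60))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            ours = hypergeom_tail(k, K, n, N)
            table = [[k, K - k], [n - k, N - K - (n - k)]]
            ref = fisher_exact(table, alternative="greater")[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)


class TestSecondStepAndMerge:
    def _labels(self, sizes):
        ids, labs = [], []
        for c, size in sizes.items():
            for i in range(size):
                ids.append(f"{c}_{i}")
                labs.append(c)
        return pd.Series(labs, index=ids, name="cluster")

    def test_top_half_factor_retention_count(self, rng):
        labels = self._labels({"C1": 5, "C2": 5, "C3": 5, "C4": 5, "C5": 5})
        clinical = ms.ClinicalTable(pd.DataFrame(
            rng.normal(size=(25, 20)),
            columns=list(KEY_FACTORS) + [f"X{i}" for i in range(12)],
            index=labels.index))
        res = second_step_cluster(labels, clinical, min_cluster_size=4)
        assert len(res.retained_factors) == 10

    def test_identical_cluster_means_merge_first(self, rng):
        labels = self._labels({"C1": 4, "C2": 4, "C3": 4})
        base = rng.normal(size=(4, 8))
        data = np.vstack([base, base, base + 5.0])  # C1 == C2 mean profile
        clinical = ms.ClinicalTable(pd.DataFrame(
            data, columns=list(KEY_FACTORS), index=labels.index))
        res = second_step_cluster(labels, clinical, min_cluster_size=4)
        merge = res.propose_merge(2)
        assert sorted(map(sorted, merge.values())) == [["C1", "C2"], ["C3"]]

    def test_small_clusters_excluded(self, rng):
        labels = self._labels({"C1": 6, "C2": 6, "C3": 3, "C4": 1})
        clinical = ms.ClinicalTable(pd.DataFrame(
            rng.normal(size=(16, 8)), columns=list(KEY_FACTORS),
            index=labels.index))
        res = second_step_cluster(labels, clinical, min_cluster_size=4)
        assert res.eligible == ["C1", "C2"] and res.excluded == ["C3", "C4"]

    def test_merge_sizes_match_reported_cluster_sizes(self):
        """Merging (C1,C3),(C2,C5),(C4) with sizes 9/12/13/7/4 gives 22/16/7."""
        labels = self._labels({"C1": 9, "C2": 12, "C3": 13, "C4": 7,
                               "C5": 4, "C6": 3, "C7": 1})
        merged = ms.merge_groups(labels, {"G1": ["C1", "C3"],
                                          "G2": ["C2", "C5"], "G3": ["C4"]})
        counts = merged.value_counts()
        assert counts["G1"] == 22 and counts["G2"] == 16 and counts["G3"] == 7
        assert int(merged.isna().sum()) == 4  # C6 + C7 left unlabeled

    def test_identity_merge_map(self):
        labels = self._labels({"C1": 4, "C2": 4})
        merged = ms.merge_groups(labels, {"G1": ["C1"], "G2": ["C2"]})
        assert (merged[labels == "C1"] == "G1").all()

    def test_overlapping_merge_map_rejected(self):
        labels = self._labels({"C1": 4, "C2": 4})
        with pytest.raises(ValueError, match="both"):
            ms.merge_groups(labels, {"G1": ["C1", "C2"], "G2": ["C2"]})


class TestModelDeterminism:
    def test_fixed_seed_reproduces_fit(self, default_cohort):
        mats, clin, design = default_cohort
        cfg = StratifyConfig(reps=100)
        r1 = ms.StratificationModel(mats, clin, design, config=cfg).fit(seed=5)
        r2 = ms.StratificationModel(mats, clin, design, config=cfg).fit(seed=5)
        pd.testing.assert_series_equal(r1.first_labels, r2.first_labels)
        pd.testing.assert_frame_equal(r1.consensus.consensus,
                                      r2.consensus.consensus)
        assert r1.merge_map == r2.merge_map

    def test_summary_mentions_groups(self, fitted):
        text = fitted.summary()
        assert "G1" in text and "first-step clusters" in text
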