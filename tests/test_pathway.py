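"""Fisher pathway enrichment and the per-sample signed GSEA score."""

import numpy as np
import pandas as pd
import pytest
from math import comb
from scipy.stats import kstest

import metastrat as ms
from metastrat.pathway import (GseaNullCache, gsea_sample_score,
                               map_peptides_to_proteins,
                               pathway_group_contrasts, score_source)
from metastrat.preprocess import NormalizedMatrix


def _db(**sets):
    return ms.PathwayDB({k: {"members": list(v)} for k, v in sets.items()})


class TestFisherEnrichment:
    def test_closed_form_fully_nested_query(self):
        universe = {f"x{i}" for i in range(100)}
        pathway = {f"x{i}" for i in range(20)}
        query = {f"x{i}" for i in range(10)}
        out = ms.fisher_pathway_enrichment(query, universe, _db(p=pathway))
        expect = comb(20, 10) / comb(100, 10)  # only k=10 possible
        assert out.loc["p", "p_value"] == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(1.07e-8, rel=0.01)

    def test_disjoint_query_near_one(self):
        universe = {f"x{i}" for i in range(50)}
        out = ms.fisher_pathway_enrichment(
            {f"x{i}" for i in range(40, 50)}, universe,
            _db(p={f"x{i}" for i in range(10)}))
        assert out.loc["p", "p_value"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ms.fisher_pathway_enrichment({"ghost"}, {"x"}, _db(p={"x"}))

    def test_pathway_without_universe_members_skipped(self):
        out = ms.fisher_pathway_enrichment(
            {"x1"}, {"x1", "x2"}, _db(inside={"x1"}, outside={"y1"}))
        assert list(out.index) == ["inside"]


class TestGseaScore:
    def _profile(self, n=50):
        return pd.Series(np.linspace(3, -3, n),
                         index=[f"g{i}" for i in range(n)])

    def test_members_at_top_give_positive_score(self):
        profile = self._profile()
        es, p, gs = gsea_sample_score(profile, {"g0", "g1", "g2", "g3"},
                                      nperm=200, seed=1)
        assert es > 0 and gs > 0
        assert p == pytest.approx(1 / 201)
        assert gs == pytest.approx(-np.log10(p))

    def test_members_at_bottom_give_negative_score(self):
        profile = self._profile()
        es, p, gs = gsea_sample_score(profile, {"g46", "g47", "g48", "g49"},
                                      nperm=200, seed=1)
        assert es < 0 and gs < 0
        assert gs == pytest.approx(np.log10(p))

    def test_sign_symmetry_under_profile_negation(self, rng):
        for _ in range(10):
            profile = pd.Series(rng.normal(size=40),
                                index=[f"g{i}" for i in range(40)])
            members = set(rng.choice(profile.index, size=6, replace=False))
            es1, p1, gs1 = gsea_sample_score(profile, members, nperm=100,
                                             seed=3)
            es2, p2, gs2 = gsea_sample_score(-profile, members, nperm=100,
                                             seed=3)
            assert p2 == pytest.approx(p1)
            if abs(es1 - es2) < 1e-9:  # up/down tie: direction ambiguous
                assert gs2 == pytest.approx(gs1, abs=1e-12)
            else:
                assert es2 == pytest.approx(-es1, abs=1e-12)
                assert gs2 == pytest.approx(-gs1, abs=1e-12)

    def test_p_bounds_respected(self, rng):
        profile = self._profile()
        cache = GseaNullCache(nperm=99, seed=0)
        for _ in range(20):
            members = set(rng.choice(profile.index, size=5, replace=False))
            _, p, _ = gsea_sample_score(profile, members, nperm=99,
                                        cache=cache)
            assert 1 / 100 <= p <= 1.0

    def test_null_sets_give_uniform_p(self, rng):
        profile = pd.Series(rng.normal(size=80),
                            index=[f"g{i}" for i in range(80)])
        cache = GseaNullCache(nperm=500, seed=9)
        ps = [gsea_sample_score(
            profile, set(rng.choice(profile.index, size=8, replace=False)),
            nperm=500, cache=cache)[1] for _ in range(200)]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            gsea_sample_score(self._profile(), {"g0", "g1"}, nperm=10)

    def test_seeded_determinism(self):
        profile = self._profile()
        members = {"g5", "g10", "g40", "g45"}
        out1 = gsea_sample_score(profile, members, nperm=100, seed=4)
        out2 = gsea_sample_score(profile, members, nperm=100, seed=4)
        assert out1 == out2


class TestPeptideMapping:
    def test_mean_aggregation(self):
        mat = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]],
                           index=["pep1", "pep2"], columns=["s1", "s2"])
        out = map_peptides_to_proteins(mat, {"pep1": "P1", "pep2": "P1"})
        assert out.loc["P1"].tolist() == [2.0, 3.0]
        assert list(out.columns) == ["s1", "s2"]

    def test_unannotated_dropped_and_counted(self):
        mat = pd.DataFrame([[1.0], [2.0]], index=["pep1", "pep2"],
                           columns=["s1"])
        with pytest.warns(UserWarning, match="coverage"):
            out = map_peptides_to_proteins(mat, {"pep1": "P1"})
        assert out.attrs["n_dropped_peptides"] == 1
        assert list(out.index) == ["P1"]

    def test_median_option(self):
        mat = pd.DataFrame([[1.0], [2.0], [9.0]],
                           index=["a", "b", "c"], columns=["s1"])
        ann = {"a": "P", "b": "P", "c": "P"}
        out = map_peptides_to_proteins(mat, ann, agg="median")
        assert out.loc["P", "s1"] == 2.0


class TestScoreSourceAndContrasts:
    def test_planted_lipid_pathway_up_in_dyslipidemia_group(self, fitted):
        mats = fitted.model.matrices
        db = ms.generate_pathway_db(mats, fitted.model.design, seed=11)
        score = score_source(fitted.zmats["metabolite"], db, "metabolomics",
                             nperm=300, seed=11)
        contrasts = pathway_group_contrasts(
            score, fitted.group_labels.dropna(), seed=11)
        lipid = contrasts[contrasts["pathway_id"] == "lipid_metab"]
        assert len(lipid), "planted pathway missing from top-ranked set"
        # in the fitted cohort the dyslipidemia-like group is the one
        # enriched for MTS; its min-subtracted lipid score runs higher
        merged = [c for cs in fitted.merge_map.values() for c in cs]
        mts_cluster = fitted.enrichment.loc[merged, "c"].idxmin()
        g2_like = [g for g, cs in fitted.merge_map.items()
                   if mts_cluster in cs][0]
        row = lipid[lipid["group"] == g2_like].iloc[0]
        assert row["log2fc"] > 0 and row["p_value"] < 0.05

    def test_min_subtraction_non_negative(self, fitted):
        mats = fitted.model.matrices
        db = ms.generate_pathway_db(mats, fitted.model.design, seed=11)
        score = score_source(fitted.zmats["metabolite"], db, "metabolomics",
                             nperm=100, seed=11)
        shifted = score.gs.sub(score.gs.min(axis=1), axis=0)
        assert (shifted.to_numpy() >= 0).all()

    def test_permuted_groups_nominal_rate(self, fitted, rng):
        """With shuffled groups the planted pathway is significant at about
        the nominal rate, not systematically."""
        mats = fitted.model.matrices
        db = ms.generate_pathway_db(mats, fitted.model.design, seed=11)
        score = score_source(fitted.zmats["metabolite"], db, "metabolomics",
                             nperm=100, seed=11)
        labeled = fitted.group_labels.dropna()
        hits = 0
        n_shuffles = 20
        for _ in range(n_shuffles):
            shuffled = pd.Series(rng.permutation(labeled.to_numpy()),
                                 index=labeled.index)
            contrasts = pathway_group_contrasts(score, shuffled, seed=0)
            lipid = contrasts[(contrasts["pathway_id"] == "lipid_metab")]
            hits += bool(len(lipid) and (lipid["p_value"] < 0.05).any())
        assert hits <= n_shuffles // 2

    def test_decoys_share_few_members_with_planted(self, default_cohort):
        mats, _, design = default_cohort
        db = ms.generate_pathway_db(mats, design, seed=1)
        planted = set(db.members("lipid_metab")) | \
            set(db.members("complement_cascade"))
        for pid, entry in db:
            if entry["category"] != "decoy":
                continue
            members = set(entry["members"])
            assert len(members & planted) / len(members) < 0.2

    def test_peptidomics_uses_source_proteins(self, fitted):
        mats = fitted.model.matrices
        db = ms.generate_pathway_db(mats, fitted.model.design, seed=11)
        score = score_source(fitted.zmats["peptide"], db, "peptidomics",
                             annotations=mats["peptide"].annotations,
                             nperm=100, seed=11)
        assert "complement_cascade" in score.gs.index
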