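"""Diversity, Bray-Curtis/PCoA, PERMANOVA, Procrustes, Kendall, prevalence."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strainflow import ecology_stats as eco


@pytest.fixture
def rel_table(rng):
    tab = pd.DataFrame(
        rng.dirichlet(np.ones(8) * 2, size=30),
        index=[f"s{i}" for i in range(30)],
        columns=[f"g{j}" for j in range(8)],
    )
    return tab


class TestAggregation:
    def test_single_species(self):
        tab = pd.DataFrame({"B. breve": [0.3], "Escherichia": [0.5]})
        with pytest.warns(UserWarning):
            agg = eco.aggregate_infant_type_bifido(tab)
        assert agg.iloc[0] == pytest.approx(0.3)

    def test_all_four_summed_including_subspecies(self):
        tab = pd.DataFrame(
            {
                "B. longum subsp. infantis": [0.05],
                "B. longum subsp. longum": [0.05],
                "B. breve": [0.1],
                "B. bifidum": [0.1],
                "B. scardovii": [0.1],
                "Escherichia": [0.6],
            }
        )
        agg = eco.aggregate_infant_type_bifido(tab)
        assert agg.iloc[0] == pytest.approx(0.4)

    def test_aggregate_dominates_infantis(self, rng):
        """Containment: the four-species sum ≥ B. infantis alone, every sample."""
        tab = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=50),
            columns=["B. longum subsp. infantis", "B. longum subsp. longum",
                     "B. breve", "B. bifidum", "Escherichia"],
        )
        with pytest.warns(UserWarning):  # B. scardovii absent
            agg = eco.aggregate_infant_type_bifido(tab)
        assert (agg >= tab["B. longum subsp. infantis"] - 1e-12).all()


class TestAlphaDiversity:
    def test_uniform_shannon(self):
        tab = pd.DataFrame([[0.25, 0.25, 0.25, 0.25]])
        res = eco.alpha_diversity(tab)
        assert res["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert res["richness"].iloc[0] == 4

    def test_single_taxon_zero(self):
        res = eco.alpha_diversity(pd.DataFrame([[1.0, 0.0]]))
        assert res["shannon"].iloc[0] == 0.0 and res["richness"].iloc[0] == 1

    def test_all_zero_flagged(self):
        res = eco.alpha_diversity(pd.DataFrame([[0.0, 0.0]]))
        assert res["all_zero"].iloc[0]
        assert res["shannon"].iloc[0] == 0.0 and res["richness"].iloc[0] == 0

    def test_merging_taxa_never_increases_shannon(self, rng):
        for _ in range(30):
            p = rng.dirichlet(np.ones(6))
            merged = np.concatenate([[p[0] + p[1]], p[2:]])
            h = eco.alpha_diversity(pd.DataFrame([p]))["shannon"].iloc[0]
            hm = eco.alpha_diversity(pd.DataFrame([merged]))["shannon"].iloc[0]
            assert hm <= h + 1e-12


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        tab = pd.DataFrame([[0.5, 0.5, 0.0, 0.0],
                            [0.5, 0.5, 0.0, 0.0],
                            [0.0, 0.0, 0.6, 0.4]])
        d = eco.bray_curtis(tab).data
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(1.0)

    def test_matches_bruteforce(self, rng):
        tab = pd.DataFrame(rng.random((20, 10)))
        d = eco.bray_curtis(tab).data
        arr = tab.to_numpy()
        for i in range(20):
            for j in range(20):
                a, b = arr[i], arr[j]
                want = 1 - 2 * np.minimum(a, b).sum() / (a.sum() + b.sum())
                assert d[i, j] == pytest.approx(want, abs=1e-12)


class TestPermanova:
    def test_single_term_matches_bruteforce(self, rng):
        """Pseudo-F on a 6-sample 2-group toy equals a from-scratch computation."""
        tab = pd.DataFrame(rng.dirichlet(np.ones(4), size=6),
                           index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"grp": ["a"] * 3 + ["b"] * 3}, index=tab.index)
        dm = eco.bray_curtis(tab)
        res = eco.permanova(dm, meta, ["grp"], n_perm=99, seed=0)
        # brute force: SS_total from all pairs, SS_within from within-group pairs
        d = dm.data
        n = 6
        ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
        ss_within = 0.0
        for g in ("a", "b"):
            idx = np.where(meta["grp"] == g)[0]
            sub = d[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        ss_between = ss_total - ss_within
        f_want = (ss_between / 1) / (ss_within / (n - 2))
        assert res["F"].iloc[0] == pytest.approx(f_want, rel=1e-9)
        assert res["R2"].iloc[0] == pytest.approx(ss_between / ss_total, rel=1e-9)

    def test_matches_vegan_adonis2_marginal(self, rng, tmp_path):
        """Marginal SS/F/R² agree with R vegan adonis2(by='margin')."""
        tab = pd.DataFrame(rng.dirichlet(np.ones(6) * 2, size=16),
                           index=[f"s{i}" for i in range(16)])
        meta = pd.DataFrame({"grp": ["a"] * 8 + ["b"] * 8,
                             "cov": rng.normal(size=16)}, index=tab.index)
        res = eco.permanova(eco.bray_curtis(tab), meta, ["grp", "cov"],
                            n_perm=99, seed=1)
        tab.to_csv(tmp_path / "tab.csv")
        meta.to_csv(tmp_path / "meta.csv")
        script = (
            "suppressMessages(library(vegan));"
            f"tab<-read.csv('{tmp_path}/tab.csv',row.names=1);"
            f"meta<-read.csv('{tmp_path}/meta.csv',row.names=1);"
            "d<-vegdist(tab,method='bray');"
            "r<-adonis2(d~grp+cov,data=meta,permutations=99,by='margin');"
            "cat(r$SumOfSqs[1:2],r$F[1:2],r$R2[1:2],sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        assert res["ss"].to_numpy() == pytest.approx(vals[0:2], rel=1e-5)
        assert res["F"].to_numpy() == pytest.approx(vals[2:4], rel=1e-5)
        assert res["R2"].to_numpy() == pytest.approx(vals[4:6], rel=1e-5)

    def test_planted_shift_detected(self, rng):
        base = rng.dirichlet(np.ones(5) * 5, size=40)
        shifted = base.copy()
        shifted[20:, 0] = shifted[20:, 0] + 0.4
        shifted /= shifted.sum(axis=1, keepdims=True)
        tab = pd.DataFrame(shifted, index=[f"s{i}" for i in range(40)])
        meta = pd.DataFrame({"grp": ["a"] * 20 + ["b"] * 20}, index=tab.index)
        res = eco.permanova(eco.bray_curtis(tab), meta, ["grp"], n_perm=199, seed=2)
        assert res["p"].iloc[0] <= 0.05

    def test_collinear_terms_error(self, rng):
        tab = pd.DataFrame(rng.dirichlet(np.ones(4), size=10),
                           index=[f"s{i}" for i in range(10)])
        meta = pd.DataFrame({"a": ["x"] * 5 + ["y"] * 5}, index=tab.index)
        meta["b"] = meta["a"]
        with pytest.raises(ValueError, match="collinear"):
            eco.permanova(eco.bray_curtis(tab), meta, ["a", "b"], n_perm=9, seed=0)

    def test_pvalue_never_zero(self, rng):
        tab = pd.DataFrame(rng.dirichlet(np.ones(4), size=12),
                           index=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame({"grp": ["a"] * 6 + ["b"] * 6}, index=tab.index)
        res = eco.permanova(eco.bray_curtis(tab), meta, ["grp"], n_perm=99, seed=3)
        assert res["p"].iloc[0] >= 1 / 100


class TestPcoa:
    def test_planted_euclidean_recovered(self, rng):
        """PCoA of Euclidean distances of 2-D points recovers the layout."""
        pts = rng.normal(size=(25, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        res = eco.pcoa(d)
        rec = res.samples.to_numpy()[:, :2]
        from scipy.spatial import procrustes

        _, _, m2 = procrustes(pts, rec)
        assert m2 < 1e-8

    def test_eigenvalue_sum_is_trace(self, rel_table):
        dm = eco.bray_curtis(rel_table)
        res = eco.pcoa(dm)
        g = eco._gower_center(dm.data)
        assert res.eigvals.sum() == pytest.approx(np.trace(g), abs=1e-8)


class TestProcrustes:
    def test_rotated_copy_prc_one(self, rng):
        a = rng.normal(size=(20, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        b = 3.0 * a @ rot + 5.0
        res = eco.procrustes_correlation(a, b, n_perm=99, seed=0)
        assert res["prc"] == pytest.approx(1.0, abs=1e-9)

    def test_invariance_to_similarity_transforms(self, rng):
        a = rng.normal(size=(15, 2))
        b = rng.normal(size=(15, 2))
        base = eco.procrustes_correlation(a, b, n_perm=9, seed=1)["prc"]
        rot = np.array([[0, -1], [1, 0]])
        again = eco.procrustes_correlation(a * 2 + 1, (b @ rot) * 0.5 - 3,
                                           n_perm=9, seed=1)["prc"]
        assert again == pytest.approx(base, abs=1e-9)

    def test_independent_near_zero(self, rng):
        a = rng.normal(size=(200, 2))
        b = rng.normal(size=(200, 2))
        res = eco.procrustes_correlation(a, b, n_perm=99, seed=2)
        assert res["prc"] < 0.25

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            eco.procrustes_correlation(np.zeros((2, 2)), np.zeros((2, 2)))


class TestKendall:
    def test_perfectly_concordant(self):
        taxa = pd.DataFrame({"t": [1.0, 2, 3, 4]}, index=list("abcd"))
        bio = pd.DataFrame({"b": [2.0, 4, 6, 8]}, index=list("abcd"))
        res = eco.kendall_associations(taxa, bio, min_mean_abundance=0)
        assert res["tau"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_tau(self):
        taxa = pd.DataFrame({"t": [1.0, 2, 3, 4]}, index=list("abcd"))
        bio = pd.DataFrame({"b": [1.0, 3, 2, 4]}, index=list("abcd"))
        res = eco.kendall_associations(taxa, bio, min_mean_abundance=0)
        assert res["tau"].iloc[0] == pytest.approx(2 / 3)

    def test_constant_vector_flagged(self):
        taxa = pd.DataFrame({"t": [1.0, 1, 1, 1]}, index=list("abcd"))
        bio = pd.DataFrame({"b": [1.0, 3, 2, 4]}, index=list("abcd"))
        res = eco.kendall_associations(taxa, bio, min_mean_abundance=0)
        assert np.isnan(res["tau"].iloc[0])

    def test_abundance_filter_with_nominated_taxa(self, rng):
        taxa = pd.DataFrame({"rare": rng.random(10) * 0.001,
                             "common": rng.random(10),
                             "Bifidobacterium": rng.random(10) * 0.001})
        bio = pd.DataFrame({"b": rng.random(10)})
        res = eco.kendall_associations(taxa, bio, min_mean_abundance=0.01,
                                       always_include=["Bifidobacterium"])
        assert set(res["taxon"]) == {"common", "Bifidobacterium"}


class TestPathogens:
    def test_printed_count_arithmetic(self):
        """15/865 samples = 1.7%; 14/218 infants = 6.4%; 9/218 = 4.13%."""
        samples = [f"s{i}" for i in range(865)]
        # 215 infants with 4 samples each, then 3 infants sharing the last 5
        extra = {860: "i215", 861: "i216", 862: "i216", 863: "i217", 864: "i217"}
        infant = pd.Series(
            {s: extra.get(j, f"i{j // 4}") for j, s in enumerate(samples)}
        )
        det = pd.DataFrame(False, index=samples, columns=["EPEC_ETEC", "Campylobacter"])
        # 15 positive samples from 14 distinct infants
        pos = [f"s{4 * j}" for j in range(14)] + ["s1"]
        det.loc[pos, "EPEC_ETEC"] = True
        det.loc[[f"s{4 * j}" for j in range(9)], "Campylobacter"] = True
        res = eco.pathogen_prevalence(det, infant).set_index("pathogen")
        assert res.loc["EPEC_ETEC", "pct_samples"] == pytest.approx(100 * 15 / 865)
        assert round(res.loc["EPEC_ETEC", "pct_samples"], 1) == 1.7
        assert res.loc["EPEC_ETEC", "pct_infants"] == pytest.approx(100 * 14 / 218)
        assert round(res.loc["EPEC_ETEC", "pct_infants"], 1) == 6.4
        assert round(res.loc["Campylobacter", "pct_infants"], 2) == 4.13

    def test_zero_detections(self):
        det = pd.DataFrame(False, index=["s1", "s2"], columns=["X"])
        infant = pd.Series({"s1": "i1", "s2": "i1"})
        res = eco.pathogen_prevalence(det, infant)
        assert res["pct_samples"].iloc[0] == 0.0
        assert res["pct_infants"].iloc[0] == 0.0
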