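"""Consensus calling, filters, distances, tree, and categorization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from strainflow import strain_typing as st
from strainflow.synthetic_cohort import (
    CohortConfig,
    GeneCatalog,
    PROBIOTIC_ID,
    OUTGROUP_ID,
    simulate_cohort,
    simulate_pileups,
)


def _counts(rows):
    return np.asarray(rows, dtype=np.int64)


class TestConsensus:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([95, 0, 5, 0], 0),    # 0.95 >= 0.90 -> call A
            ([89, 0, 11, 0], -1),  # 0.89 < 0.90 -> uncalled
            ([90, 0, 10, 0], 0),   # exactly at threshold, inclusive
            ([0, 0, 0, 0], -1),    # no coverage
            ([2, 1, 0, 0], -1),    # below min_depth 4
        ],
    )
    def test_threshold_boundaries(self, row, expected):
        calls, _, _ = st.call_consensus(_counts([row]), af_threshold=0.90, min_depth=4)
        assert calls[0] == expected

    def test_empty_pileup_all_uncalled(self):
        calls, depth, _ = st.call_consensus(np.zeros((100, 4), dtype=int))
        assert (calls == -1).all() and (depth == 0).all()

    def test_matches_bruteforce_recount(self, rng):
        """Vectorized caller agrees with a per-position recount on 1e5 positions."""
        counts = rng.integers(0, 40, size=(100_000, 4))
        calls, _, _ = st.call_consensus(counts, af_threshold=0.9, min_depth=4)
        idx = rng.choice(100_000, 3000, replace=False)
        for i in idx:
            d = counts[i].sum()
            exp = -1
            if d >= 4:
                b = int(np.argmax(counts[i]))
                if counts[i][b] / d >= 0.9:
                    exp = b
            assert calls[i] == exp

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st_hyp.integers(0, 2**31 - 1))
    def test_raising_threshold_never_calls_more(self, seed):
        counts = np.random.default_rng(seed).integers(0, 30, size=(500, 4))
        lo, _, _ = st.call_consensus(counts, af_threshold=0.85)
        hi, _, _ = st.call_consensus(counts, af_threshold=0.95)
        assert ((hi >= 0) <= (lo >= 0)).all()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            st.call_consensus(np.zeros((1, 4)), af_threshold=0.4)


class TestFilters:
    @pytest.mark.parametrize(
        "reads,genes,expected",
        [(250, 10, True), (249, 50, False), (10000, 9, False), (251, 11, True)],
    )
    def test_read_gene_filter_boundaries(self, reads, genes, expected):
        assert st.sample_passes_typing_filter(reads, genes) is expected

    def test_gene_exclusion_boundary(self):
        """20/100 low-AF positions retained; 21/100 excluded; clean retained."""
        catalog = GeneCatalog(["g1", "g2", "g3"], np.array([100, 100, 100]),
                              np.zeros(300, dtype=np.int8))

        def make(depth_rows):
            return np.asarray(depth_rows)

        counts = np.zeros((300, 4), dtype=int)
        counts[:, 0] = 100
        counts[:20, 1] = 30      # g1: 20 low-AF positions -> retained
        counts[100:121, 1] = 30  # g2: 21 low-AF positions -> excluded
        depth = counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            major_af = counts.max(axis=1) / np.maximum(depth, 1)
        retained, excluded = st.exclude_noisy_genes(depth, major_af, catalog)
        assert retained == ["g1", "g3"] and excluded == ["g2"]

    def test_zero_coverage_gene_excluded(self):
        catalog = GeneCatalog(["g1", "g2"], np.array([50, 50]), np.zeros(100, dtype=np.int8))
        counts = np.zeros((100, 4), dtype=int)
        counts[:50, 0] = 20
        depth = counts.sum(axis=1)
        major_af = np.where(depth > 0, 1.0, np.nan)
        retained, excluded = st.exclude_noisy_genes(depth, major_af, catalog)
        assert retained == ["g1"] and excluded == ["g2"]


class TestProfilesDistances:
    def test_profile_length_and_concatenation(self, catalog):
        counts = np.zeros((catalog.total_length, 4), dtype=int)
        counts[np.arange(catalog.total_length), catalog.sequence] = 50
        prof = st.build_profile("s", counts, catalog)
        assert prof.calls.shape[0] == catalog.total_length
        assert prof.called_positions == catalog.total_length
        assert np.array_equal(prof.calls, catalog.sequence)
        assert prof.genes_retained == catalog.n_genes

    def test_noiseless_profile_equals_truth(self, strains):
        cfg = CohortConfig(arm_sizes=(5, 5, 5), seed=21, mixture_prob=0.0,
                           trace_detection_prob=0.0)
        truth = simulate_cohort(cfg, strains)
        pile = simulate_pileups(truth, error_rate=0.0, library_factor_sd=0.0, seed=22)
        row = truth.samples[truth.samples["abundance"] > 0.02].iloc[0]
        prof = st.build_profile(row.sample_id, pile.counts[row.sample_id], strains.catalog)
        called = prof.calls >= 0
        assert called.mean() > 0.95
        assert np.array_equal(prof.calls[called], strains.sequences[row.strain][called])

    def test_distance_identities(self):
        a = np.array([0, 1, 2, 3, -1, 0], dtype=np.int8)
        b = np.array([0, 1, 2, 3, 1, -1], dtype=np.int8)
        raw, shared, norm = st.pairwise_snv_distance(a, a, min_shared=1)
        assert (raw, shared, norm) == (0, 5, 0.0)
        raw, shared, norm = st.pairwise_snv_distance(a, b, min_shared=1)
        raw2, shared2, _ = st.pairwise_snv_distance(b, a, min_shared=1)
        assert raw == raw2 and shared == shared2 == 4

    def test_disjoint_called_sets_flagged(self):
        a = np.array([0, 0, -1, -1], dtype=np.int8)
        b = np.array([-1, -1, 1, 1], dtype=np.int8)
        raw, shared, norm = st.pairwise_snv_distance(a, b, min_shared=1)
        assert shared == 0 and np.isnan(norm)

    def test_planted_snv_count_recovered(self, strains):
        """Error-free profiles differ at exactly the planted SNV positions."""
        ref = st.reference_profile(PROBIOTIC_ID, strains.sequences[PROBIOTIC_ID])
        for sid in strains.autochthonous_ids[:3]:
            other = st.reference_profile(sid, strains.sequences[sid])
            raw, _, _ = st.pairwise_snv_distance(ref, other, min_shared=1)
            assert raw == len(strains.snv_positions[sid])


class TestTree:
    def test_probiotic_samples_are_siblings(self):
        """4-point additive matrix: the two near tips join first under NJ."""
        labels = ["p1", "p2", "a1", OUTGROUP_ID]
        d = np.array(
            [
                [0.0, 0.001, 0.01, 0.02],
                [0.001, 0.0, 0.01, 0.02],
                [0.01, 0.01, 0.0, 0.02],
                [0.02, 0.02, 0.02, 0.0],
            ]
        )
        tree = st.build_strain_tree(d, labels)
        p1 = tree.find("p1")
        siblings = {t.name for t in p1.parent.children}
        assert "p2" in siblings

    def test_equal_distances_no_crash(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        labels = [f"t{i}" for i in range(n)]
        tree = st.build_strain_tree(d, labels, outgroup="t0")
        assert {t.name for t in tree.tips()} == set(labels)

    def test_two_tips_trivial_tree(self):
        with pytest.warns(UserWarning):
            tree = st.build_strain_tree(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        assert {t.name for t in tree.tips()} == {"a", "b"}

    def test_branch_lengths_nonnegative(self, strains):
        ids = [PROBIOTIC_ID] + strains.autochthonous_ids[:4] + [OUTGROUP_ID]
        profs = [st.reference_profile(s, strains.sequences[s]) for s in ids]
        d, labels = st.distance_matrix(profs, min_shared=100)
        tree = st.build_strain_tree(d, labels)
        assert all((n.length or 0) >= 0 for n in tree.traverse())


class TestClassification:
    def _clean_profile(self):
        return st.StrainProfile("s", np.zeros(5000, dtype=np.int8), 5000, 30, 30,
                                0.0, 5000)

    @pytest.mark.parametrize(
        "abundance,dist,expected",
        [
            (0.0, 0.0, "NotDetected"),
            (0.0015, 0.0, "UntypedLow"),          # strict-less boundary
            (0.0016, 0.0, "LMG11588"),            # at threshold, typed
            (0.01, 0.0005, "LMG11588"),
            (0.01, 0.003, "OtherInfantis"),
        ],
    )
    def test_rule_order_and_boundaries(self, abundance, dist, expected):
        cat = st.classify_strain(abundance, self._clean_profile(), dist, 5000)
        assert cat == expected

    def test_heterogeneous_profile_untyped(self):
        prof = self._clean_profile()
        prof.heterogeneity_fraction = 0.01  # above het_max 0.002
        assert st.classify_strain(0.01, prof, 0.0, 5000) == "UntypedHet"

    def test_failed_filter_untyped(self):
        prof = self._clean_profile()
        prof.passed_filter = False
        assert st.classify_strain(0.01, prof, 0.0, 5000) == "UntypedHet"

    def test_too_few_shared_untyped(self):
        assert st.classify_strain(0.01, self._clean_profile(), 0.0, 500) == "UntypedHet"

    def test_invalid_abundance(self):
        with pytest.raises(ValueError):
            st.classify_strain(1.5, self._clean_profile(), 0.0, 5000)

    def test_mixture_sample_classified_heterogeneous(self, strains):
        """A 50/50 two-subclade mixture at good depth triggers UntypedHet."""
        cfg = CohortConfig(arm_sizes=(30, 1, 1), seed=31, mixture_prob=1.0,
                           baseline_colonization_prob=1.0,
                           log10_abund_mean=-1.3, log10_abund_sd=0.01)
        truth = simulate_cohort(cfg, strains)
        pile = simulate_pileups(truth, depth_per_unit_abundance=4000,
                                error_rate=0.0, library_factor_sd=0.0, seed=32)
        abund = truth.samples.set_index("sample_id")["abundance"]
        classes, _ = st.type_samples(pile, abund, strains.sequences)
        merged = classes.merge(truth.samples, on="sample_id")
        mixtures = merged[merged["mixture"] & (merged["abundance_x"] > 0.0016)]
        assert len(mixtures) > 5
        assert (mixtures["category"] == "UntypedHet").mean() > 0.9


class TestRecovery:
    def test_category_recovery_and_tree_concordance(self, strains):
        """Error-free simulation: every typed sample recovers its true
        category, and all probiotic-radius calls sit inside the minimal
        NJ clade containing the probiotic reference."""
        cfg = CohortConfig(arm_sizes=(15, 15, 15), seed=41, mixture_prob=0.0)
        truth = simulate_cohort(cfg, strains)
        pile = simulate_pileups(truth, error_rate=0.0, library_factor_sd=0.0, seed=42)
        abund = truth.samples.set_index("sample_id")["abundance"]
        classes, profiles = st.type_samples(pile, abund, strains.sequences)
        merged = classes.merge(truth.samples[["sample_id", "true_category"]], on="sample_id")
        well = merged[merged["abundance"] >= 0.005]
        assert (well["category"] == well["true_category"]).all()

        tips = st.placeable_profiles(profiles, classes, strains.sequences)
        d, labels = st.distance_matrix(tips, min_shared=1000)
        ok = ~np.isnan(d).any(axis=1)
        tree = st.build_strain_tree(d[np.ix_(ok, ok)],
                                    [l for l, k in zip(labels, ok) if k])
        tip_names = {t.name for t in tree.tips()}
        lmg = set(merged.loc[merged["category"] == "LMG11588", "sample_id"]) & tip_names
        other = set(merged.loc[merged["category"] == "OtherInfantis", "sample_id"]) & tip_names
        assert lmg and other
        # radius/tree concordance: each placed sample's nearest reference by
        # tree path length belongs to its called clade
        td = tree.tip_tip_distances()
        ref_names = [n for n in tip_names if n.startswith(("LMG11588", "auto_"))]
        truth_by_sample = merged.set_index("sample_id")["category"]
        for s in lmg | other:
            dists = {r: td[s, r] for r in ref_names}
            nearest = min(dists, key=dists.get)
            if truth_by_sample[s] == "LMG11588":
                assert nearest.startswith("LMG11588")
            else:
                assert nearest.startswith("auto_")
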