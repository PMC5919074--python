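"""Immunological distance pipeline: PCA, distances, summaries, MDS, infections."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ecoimmune.immune import (
    classical_mds, immune_distance, immune_pca, infection_descriptives,
    measures_frame, site_distance_summary, within_distance_vs_n,
)
from ecoimmune.records import IMMUNE_MEASURES
from ecoimmune.simulate import implied_covariance_observed
from conftest import make_mouse


class TestImmunePca:
    def test_rank_one_data_concentrates_on_pc1(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        X = np.outer(base, rng.uniform(0.5, 2.0, size=10))
        pcs = immune_pca(X)
        assert pcs.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_variable_eigenvalues_match_closed_form(self):
        # for two standardized variables the correlation matrix eigenvalues
        # are 1 +/- rho; build data whose sample correlation is exactly 0.5
        rho = 0.5
        n = 40
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(n, 2))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        # orthogonalize then mix to the target correlation
        q, _ = np.linalg.qr(Z)
        a = q[:, 0] / q[:, 0].std(ddof=1)
        b = q[:, 1] / q[:, 1].std(ddof=1)
        x = a
        y = rho * a + np.sqrt(1 - rho ** 2) * b
        pcs = immune_pca(np.column_stack([x, y]), n_components=2)
        total = pcs.variance_explained.sum()
        assert pcs.variance_explained[0] / total * 2 == pytest.approx(1.5, abs=1e-9)
        assert pcs.variance_explained[0] == pytest.approx(0.75, abs=1e-9)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 5))
        ids = [f"m{i}" for i in range(15)]
        pcs = immune_pca(X, ids)
        perm = rng.permutation(15)
        pcs_p = immune_pca(X[perm], [ids[i] for i in perm])
        lookup = dict(zip(pcs_p.mouse_ids, pcs_p.scores))
        for mid, row in zip(pcs.mouse_ids, pcs.scores):
            np.testing.assert_allclose(lookup[mid], row, atol=1e-9)

    def test_incomplete_rows_excluded_and_counted(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        X[2, 1] = np.nan
        pcs = immune_pca(X, n_components=2)
        assert pcs.n_excluded == 1
        assert len(pcs.mouse_ids) == 11

    def test_constant_column_and_too_few_mice_raise(self):
        with pytest.raises(ValueError, match="constant column"):
            immune_pca(np.column_stack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="at least 4"):
            immune_pca(np.random.default_rng(0).normal(size=(3, 5)))

    def test_loading_recovery_against_generating_covariance(self):
        # dual route: sample PCA loadings vs eigenvectors of the closed-form
        # implied correlation matrix of the generating model
        from ecoimmune.simulate import SyntheticConfig, gen_cohort

        cfg = SyntheticConfig(seed=5, site_sizes={"HW": 5000},
                              site_sd={"adaptive": 0, "innate": 0, "humoral": 0})
        records, _ = gen_cohort(cfg)
        pcs = immune_pca(measures_frame(records))
        labels, C, _ = implied_covariance_observed(cfg)
        sub = [labels.index(m) for m in IMMUNE_MEASURES]
        C10 = C[np.ix_(sub, sub)]
        d = np.sqrt(np.diag(C10))
        corr = C10 / np.outer(d, d)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        for j in range(3):
            v = eigvec[:, order[j]]
            cos = abs(v @ pcs.loadings[:, j])
            assert cos > 0.95, f"component {j + 1}: cosine {cos:.3f}"


class TestImmuneDistance:
    def test_identical_scores_give_zero(self):
        df = pd.DataFrame({"mouse_id": ["a", "b"], "pc1": [1.0, 1.0],
                           "pc2": [2.0, 2.0], "pc3": [0.5, 0.5]})
        dm = immune_distance(df)
        assert dm["a", "b"] == 0.0

    def test_three_four_five(self):
        df = pd.DataFrame({"mouse_id": ["a", "b"], "pc1": [0.0, 3.0],
                           "pc2": [0.0, 4.0], "pc3": [0.0, 0.0]})
        assert immune_distance(df)["a", "b"] == pytest.approx(5.0)

    def test_triangle_inequality_on_random_scores(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(12, 3)), columns=["pc1", "pc2", "pc3"])
        df.insert(0, "mouse_id", [f"m{i}" for i in range(12)])
        d = immune_distance(df).data
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestSiteSummary:
    def _dm_and_sites(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        ids = [f"m{i}" for i in range(10)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        sites = {m: ("HW" if i < 5 else "BM") for i, m in enumerate(ids)}
        return dm, sites

    def test_pair_conservation_and_weighted_decomposition(self):
        dm, sites = self._dm_and_sites()
        summaries, overall = site_distance_summary(dm, sites)
        n = 10
        assert overall["n_within_pairs"] + overall["n_among_pairs"] == n * (n - 1) // 2
        # overall within mean = pair-weighted mean of per-site means
        w = sum(s.within_mean * s.n_pairs for s in summaries)
        assert overall["within_mean"] == pytest.approx(
            w / overall["n_within_pairs"])
        grand = dm.data[np.triu_indices(n, 1)].mean()
        combined = (
            overall["within_mean"] * overall["n_within_pairs"]
            + overall["among_mean"] * overall["n_among_pairs"]
        ) / (n * (n - 1) / 2)
        assert combined == pytest.approx(grand)

    def test_two_mouse_site_reports_missing_se(self):
        dm = DistanceMatrix([[0, 2.0], [2.0, 0]], ids=["a", "b"])
        summaries, overall = site_distance_summary(dm, {"a": "HW", "b": "HW"})
        assert summaries[0].within_mean == pytest.approx(2.0)
        assert summaries[0].within_se is None

    def test_single_mouse_site_excluded_with_warning(self):
        dm, sites = self._dm_and_sites()
        sites["m9"] = "PF"
        with pytest.warns(UserWarning, match="PF"):
            summaries, _ = site_distance_summary(dm, sites)
        assert {s.site for s in summaries} == {"BM", "HW"}


class TestWithinDistanceVsN:
    def _summaries(self, means, counts):
        from ecoimmune.immune import SiteDistanceSummary

        return [
            SiteDistanceSummary(f"S{i}", m, 0.1, c, c * (c - 1) // 2)
            for i, (m, c) in enumerate(zip(means, counts))
        ]

    def test_perfect_correlation(self):
        res = within_distance_vs_n(self._summaries([2, 3, 4, 5], [2, 3, 4, 5]),
                                   n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_vector_flagged_undefined(self):
        res = within_distance_vs_n(self._summaries([2, 2, 2], [3, 4, 5]))
        assert res.undefined and np.isnan(res.r)

    def test_permutation_p_matches_exhaustive_for_four_sites(self):
        from itertools import permutations

        means = [1.0, 2.5, 2.0, 4.0]
        counts = [5, 3, 8, 4]
        res = within_distance_vs_n(self._summaries(means, counts),
                                   n_perm=200000, seed=1)
        x, y = np.array(means), np.array(counts, dtype=float)
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        hits = sum(
            abs(np.corrcoef(x, y[list(p)])[0, 1]) >= r_obs - 1e-12
            for p in permutations(range(4))
        )
        assert res.p == pytest.approx(hits / 24, abs=0.01)


class TestClassicalMds:
    def test_two_points(self):
        dm = DistanceMatrix([[0, 3.0], [3.0, 0]], ids=["a", "b"])
        X = classical_mds(dm, k=1)
        assert abs(X[0, 0] - X[1, 0]) == pytest.approx(3.0)

    def test_equilateral_triangle(self):
        dm = DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        X = classical_mds(dm, k=2)
        d = squareform(pdist(X))
        np.testing.assert_allclose(d[np.triu_indices(3, 1)], 1.0, atol=1e-9)

    def test_euclidean_realizable_recovered_exactly(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 2))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(8)])
        X = classical_mds(dm, k=2)
        np.testing.assert_allclose(squareform(pdist(X)), dm.data, atol=1e-9)

    def test_requesting_too_many_dimensions_raises(self):
        dm = DistanceMatrix([[0, 3.0], [3.0, 0]], ids=["a", "b"])
        with pytest.raises(ValueError, match="positive eigenvalues"):
            classical_mds(dm, k=2)


class TestInfectionDescriptives:
    def test_all_zero_scores(self):
        mice = [make_mouse(f"m{i}") for i in range(5)]
        desc = infection_descriptives(mice)
        assert desc.seroprevalence == 0.0
        assert all(v == 0.0 for v in desc.prevalence.values())
        assert all(b == 0 for b in desc.burden.values())

    def test_prevalence_counting_rules(self):
        mice = [
            make_mouse("m1", infection_scores={"noro": 2, "mhv": 0},
                       worm_count=12, mite_count_class=0),
            make_mouse("m2", infection_scores={"noro": 0, "mhv": 0},
                       worm_count=0, mite_count_class=3),
            make_mouse("m3", infection_scores={"noro": 1, "mhv": 4},
                       worm_count=5, mite_count_class=None),
            make_mouse("m4", infection_scores={}),
        ]
        desc = infection_descriptives(mice)
        assert desc.n_tested == 3
        assert desc.seroprevalence == pytest.approx(2 / 3)
        assert desc.prevalence["noro"] == pytest.approx(2 / 3)
        assert desc.worm_prevalence == pytest.approx(2 / 3)
        assert desc.mite_prevalence == pytest.approx(1 / 2)

    def test_burden_rises_with_age_in_generated_cohort(self, flat_cohort):
        _, records, _ = flat_cohort
        desc = infection_descriptives(records)
        for sex, res in desc.burden_age_by_sex.items():
            assert res.r > 0
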