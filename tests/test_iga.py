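"""Coating scores, strong/reliable classification, permutation null,
correlations, and abundance-structure relations."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fmtrack import iga, simulate
from fmtrack.iga import (
    IgaScoreMatrix,
    bimodality_coefficient,
    coating_correlation,
    coating_score,
    permutation_test,
    reliability,
    score_abundance_relations,
    strain_specificity,
    strong_classification,
)
from fmtrack.tables import FeatureTable
from fmtrack._util import DegenerateInputError, ParameterError


def tables_from(coated_rows, uncoated_rows, n=None):
    coated_rows = np.atleast_2d(np.asarray(coated_rows, dtype=float))
    uncoated_rows = np.atleast_2d(np.asarray(uncoated_rows, dtype=float))
    ids = [f"s{i}" for i in range(coated_rows.shape[0])]
    cols = [f"a{i}" for i in range(coated_rows.shape[1])]
    return (
        FeatureTable(pd.DataFrame(coated_rows, index=ids, columns=cols)),
        FeatureTable(pd.DataFrame(uncoated_rows, index=ids, columns=cols)),
    )


class TestCoatingScore:
    def test_equal_relative_abundance_scores_zero(self):
        c, u = tables_from([100, 300], [100, 300])
        m = coating_score(c, u)
        np.testing.assert_allclose(m.scores.to_numpy(), 0.0, atol=1e-12)

    def test_twofold_enrichment_approaches_one(self):
        # coated relative abundance 2x uncoated; large counts make the
        # pseudocount negligible
        c, u = tables_from([20000, 10000], [10000, 20000])
        m = coating_score(c, u)
        assert float(m.scores.iloc[0, 0]) == pytest.approx(1.0, abs=1e-3)

    def test_all_zero_fraction_is_degenerate(self):
        c, u = tables_from([0, 0], [5, 5])
        with pytest.raises(DegenerateInputError):
            coating_score(c, u)

    def test_low_count_asvs_unscored(self):
        c, u = tables_from([4, 100], [3, 100])
        m = coating_score(c, u, min_reads=5)
        assert np.isnan(m.scores.iloc[0, 0])
        assert np.isfinite(m.scores.iloc[0, 1])

    @given(
        counts=arrays(np.float64, (2, 6), elements=st.integers(0, 500).map(float)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_under_fraction_swap(self, counts):
        coated = counts + 1.0  # keep fractions non-degenerate
        uncoated = counts[::-1] + 1.0
        c, u = tables_from(coated, uncoated)
        forward = coating_score(c, u, min_reads=1).scores.to_numpy()
        backward = coating_score(u, c, min_reads=1).scores.to_numpy()
        np.testing.assert_allclose(forward, -backward, atol=1e-12)

    def test_planted_score_recovery(self):
        recovered = []
        for rep in range(30):
            lat = np.zeros((1, 150))
            lat[:, 0], lat[:, 1] = 2.0, -2.0
            c, u, _ = simulate.simulate_iga_fractions(
                n_samples=1, n_asvs=150, latent_scores=lat, seed=300 + rep
            )
            m = coating_score(c, u)
            recovered.append(float(m.scores.iloc[0, 0]))
        assert np.mean(recovered) == pytest.approx(2.0, abs=0.1)


class TestStrongClassification:
    def test_symmetric_scores_give_symmetric_classes(self):
        scores = pd.DataFrame(
            [[-3.0, -1.0, 0.0, 1.0, 3.0]], index=["s"],
            columns=[f"a{i}" for i in range(5)],
        )
        cls = strong_classification(IgaScoreMatrix(scores)).loc["s"]
        assert (cls == "coated").sum() == (cls == "uncoated").sum() == 1

    def test_zero_sd_classifies_everything_neutral(self):
        scores = pd.DataFrame([[2.0, 2.0, 2.0]], index=["s"], columns=list("abc"))
        cls = strong_classification(IgaScoreMatrix(scores)).loc["s"]
        assert (cls == "neutral").all()

    def test_undersized_sample_skipped(self):
        scores = pd.DataFrame([[1.0, 2.0, np.nan]], index=["s"], columns=list("abc"))
        cls = strong_classification(IgaScoreMatrix(scores))
        assert cls.loc["s"].isna().all()

    def test_normal_scores_tail_fraction(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.normal(size=(40, 400)))
        cls = strong_classification(IgaScoreMatrix(scores))
        frac_coated = (cls == "coated").sum(axis=1) / 400
        # one-sided tail beyond mean + 1 SD of a normal: ~15.9%
        assert float(frac_coated.mean()) == pytest.approx(0.159, abs=0.02)


class TestReliability:
    def test_constant_positive_scores_reliably_coated(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            np.column_stack([
                np.full(10, 3.0) + rng.normal(0, 1e-3, 10),
                rng.normal(0, 1.0, 10),
            ]),
            columns=["hot", "null"],
        )
        rel = reliability(IgaScoreMatrix(scores), min_samples=5)
        assert rel.loc["hot", "class"] == "reliably_coated"

    def test_min_samples_validated(self):
        m = IgaScoreMatrix(pd.DataFrame(np.zeros((3, 3))))
        with pytest.raises(ParameterError):
            reliability(m, min_samples=1)

    def test_null_false_call_rate_within_fdr(self):
        rng = np.random.default_rng(2)
        false_fracs = []
        for _ in range(200):
            scores = pd.DataFrame(rng.normal(size=(20, 100)))
            rel = reliability(IgaScoreMatrix(scores), min_samples=5)
            false_fracs.append(
                (rel["class"].isin(["reliably_coated", "reliably_uncoated"])).mean()
            )
        # under the global null BH keeps the any-discovery rate near the
        # nominal FDR; the mean fraction of false calls is far below it
        assert np.mean(false_fracs) <= 0.1

    def test_vectorized_count_matches_public_reliability(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(25, 200))
        vals[:, :7] += 1.5
        m = IgaScoreMatrix(pd.DataFrame(vals))
        rel = reliability(m, min_samples=5, fdr=0.1)
        n_public = int(rel["class"].isin(
            ["reliably_coated", "reliably_uncoated"]).sum())
        n_vec = int(iga._bh_reject_count(iga._t_pvalues(vals, 5), 0.1)[0])
        assert n_public == n_vec

    def test_bh_counts_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(50) ** 2
            ours = int(iga._bh_reject_count(p, 0.1)[0])
            theirs = int(multipletests(p, alpha=0.1, method="fdr_bh")[0].sum())
            assert ours == theirs


class TestPermutationTest:
    def test_seed_determinism(self):
        m, _ = simulate.simulate_score_matrix(n_samples=10, n_asvs=50, seed=0)
        r1 = permutation_test(m, n_perm=100, seed=5)
        r2 = permutation_test(m, n_perm=100, seed=5)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)

    def test_strong_structure_hits_p_floor(self):
        m, _ = simulate.simulate_score_matrix(
            n_samples=30, n_asvs=100, n_coated=20, n_uncoated=10, seed=1
        )
        res = permutation_test(m, n_perm=200, seed=2)
        assert res.p_value == pytest.approx(1 / 201)

    def test_type_one_error_at_most_nominal(self):
        # validity: under exchangeable nulls the rejection rate at alpha
        # never exceeds alpha (within Monte Carlo error)
        rng = np.random.default_rng(6)
        rejections = 0
        n_datasets = 60
        for _ in range(n_datasets):
            m = IgaScoreMatrix(pd.DataFrame(rng.normal(size=(15, 80))))
            res = permutation_test(m, n_perm=200, seed=rng)
            if res.p_value <= 0.05:
                rejections += 1
        assert rejections / n_datasets <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_datasets)

    def test_n_perm_validated(self):
        m = IgaScoreMatrix(pd.DataFrame(np.zeros((3, 3))))
        with pytest.raises(ParameterError):
            permutation_test(m, n_perm=0)


class TestCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=20), index=[f"a{i}" for i in range(20)])
        res = coating_correlation(s, s)
        assert res.r == pytest.approx(1.0)

    def test_too_few_shared_asvs_undeterminable(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        assert coating_correlation(a, a) is None

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(50):
            idx = [f"a{i}" for i in range(100)]
            a = pd.Series(rng.normal(size=100), index=idx)
            b = pd.Series(rng.normal(size=100), index=idx)
            rs.append(coating_correlation(a, b).r)
        assert abs(np.mean(rs)) < 0.05

    def test_shared_host_effect_reproduces_variance_ratio_correlation(self):
        # scores = shared + private noise; expected r = var_shared / total var
        rng = np.random.default_rng(2)
        var_ratio = 0.6
        rs = []
        for _ in range(100):
            idx = [f"a{i}" for i in range(200)]
            shared = rng.normal(0, np.sqrt(var_ratio), 200)
            a = pd.Series(shared + rng.normal(0, np.sqrt(1 - var_ratio), 200), index=idx)
            b = pd.Series(shared + rng.normal(0, np.sqrt(1 - var_ratio), 200), index=idx)
            rs.append(coating_correlation(a, b).r)
        assert np.mean(rs) == pytest.approx(var_ratio, abs=0.05)


class TestStrainSpecificity:
    def test_identical_subsets_would_overlap(self):
        donor = pd.Series(np.arange(6, dtype=float), index=list("abcdef"))
        with pytest.raises(ParameterError, match="overlap"):
            strain_specificity(donor, donor, ["a", "b", "c"], ["a", "d", "e"])

    def test_same_generating_law_gives_near_zero_difference(self):
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(50):
            idx = [f"a{i}" for i in range(40)]
            donor = pd.Series(rng.normal(size=40), index=idx)
            patient = pd.Series(donor + rng.normal(0, 0.5, 40), index=idx)
            res = strain_specificity(
                donor, patient, idx[:20], idx[20:], n_boot=20, seed=rng
            )
            diffs.append(res.difference)
        assert abs(np.mean(diffs)) < 0.1

    def test_strain_specific_model_detected(self):
        rng = np.random.default_rng(4)
        wins = 0
        for _ in range(50):
            sh = [f"sh{i}" for i in range(25)]
            tr = [f"tr{i}" for i in range(25)]
            donor = pd.Series(rng.normal(0, 1.5, 50), index=sh + tr)
            patient = pd.Series(index=sh + tr, dtype=float)
            patient[tr] = donor[tr] + rng.normal(0, 0.5, 25)
            patient[sh] = rng.normal(0, 1.5, 25)
            res = strain_specificity(donor, patient, sh, tr, n_boot=20, seed=rng)
            if res.r_transferred > res.r_shared:
                wins += 1
        assert wins / 50 >= 0.95


class TestScoreAbundanceRelations:
    def test_bimodality_of_symmetric_two_point_distribution(self):
        x = np.array([0.0, 1.0] * 20)
        assert bimodality_coefficient(x) == pytest.approx(1.0, abs=0.01)
        assert bimodality_coefficient(x) > 5 / 9

    def test_constant_relative_abundance_has_zero_variance(self):
        scores = IgaScoreMatrix(
            pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                         index=[f"s{i}" for i in range(5)],
                         columns=["a0", "a1", "a2"])
        )
        abund = FeatureTable(
            pd.DataFrame({"a0": [0.4] * 5,
                          "a1": [0.1, 0.5, 0.1, 0.5, 0.1],
                          "a2": [0.5, 0.1, 0.5, 0.1, 0.5]},
                         index=[f"s{i}" for i in range(5)]),
            kind="relative",
        )
        per_asv, _ = score_abundance_relations(scores, abund)
        assert per_asv.loc["a0", "variance"] == pytest.approx(0.0)
        assert per_asv.loc["a1", "variance"] > 0

    def test_independent_scores_uncorrelated_with_abundance(self):
        rng = np.random.default_rng(5)
        n_s, n_a = 30, 150
        ids = [f"a{i}" for i in range(n_a)]
        scores = IgaScoreMatrix(
            pd.DataFrame(rng.normal(size=(n_s, n_a)),
                         index=[f"s{i}" for i in range(n_s)], columns=ids)
        )
        abund = FeatureTable(
            pd.DataFrame(rng.lognormal(size=(n_s, n_a)),
                         index=[f"s{i}" for i in range(n_s)], columns=ids)
        )
        _, cors = score_abundance_relations(scores, abund)
        assert abs(cors.loc["mean_abundance", "r"]) < 0.2
        assert cors.loc["mean_abundance", "p_value"] > 0.01
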