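"""Diversity, distance, ordination, and windowed-comparison statistics.

PERMANOVA, Mantel, and PCoA are additionally cross-checked against
scikit-bio's independent implementations on random data.
"""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fmtrack.community import (
    DistanceMatrix,
    bray_curtis,
    compare_arms,
    mann_whitney,
    mantel,
    pcoa,
    permanova,
    richness,
    shannon,
    windowed_mean,
)
from fmtrack.tables import FeatureTable
from fmtrack._util import DegenerateInputError, ParameterError, ValidationError


def rel_table(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(rows))]
    df = pd.DataFrame(rows, index=ids, columns=[f"f{i}" for i in range(rows.shape[1])])
    return FeatureTable(df, kind="relative")


class TestAlphaDiversity:
    def test_shannon_uniform_and_single(self):
        t = FeatureTable(
            pd.DataFrame([[5.0, 5.0, 5.0, 5.0], [9.0, 0.0, 0.0, 0.0]],
                         index=["u", "m"], columns=list("abcd"))
        )
        h = shannon(t)
        assert h["u"] == pytest.approx(math.log(4), abs=1e-12)
        assert h["m"] == 0.0

    def test_shannon_hand_value(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397...
        t = rel_table([[0.5, 0.25, 0.25]])
        assert shannon(t)["s0"] == pytest.approx(1.0397207708399179, abs=1e-10)

    def test_shannon_zero_total_is_degenerate(self):
        t = FeatureTable(pd.DataFrame([[0.0, 0.0]], index=["s"], columns=["a", "b"]))
        with pytest.raises(DegenerateInputError):
            shannon(t)

    def test_richness(self):
        t = FeatureTable(
            pd.DataFrame([[1.0, 0.0, 2.0, 0.0, 9.0]], index=["s"],
                         columns=list("abcde"))
        )
        assert richness(t)["s"] == 3
        assert richness(t, min_count=10)["s"] == 0


class TestBrayCurtis:
    def test_identical_disjoint_and_half(self):
        t = rel_table(
            [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0], [0.5, 0.0, 0.5]],
            ids=["a", "a2", "b", "c"],
        )
        dm = bray_curtis(t)
        assert dm.between("a", "a2") == pytest.approx(0.0, abs=1e-12)
        assert dm.between("a", "b") == pytest.approx(1.0, abs=1e-12)
        assert dm.between("a", "c") == pytest.approx(0.5, abs=1e-12)

    def test_counts_kind_rejected(self, tiny_table):
        with pytest.raises(ValidationError, match="relative"):
            bray_curtis(tiny_table)

    @given(
        counts=arrays(np.float64, (4, 6), elements=st.integers(1, 100).map(float))
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_properties_on_random_tables(self, counts):
        t = FeatureTable(
            pd.DataFrame(counts, index=list("wxyz"),
                         columns=[f"f{i}" for i in range(6)])
        ).to_relative()
        dm = bray_curtis(t)
        v = dm.values
        assert np.allclose(v, v.T, atol=1e-12)
        assert np.all(np.diag(v) == 0)
        assert np.all(v >= 0) and np.all(v <= 1 + 1e-12)


class TestPCoA:
    def test_three_equidistant_points_give_equal_eigenvalues(self):
        dm = DistanceMatrix(("a", "b", "c"), np.array(
            [[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]]))
        res = pcoa(dm, k=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-10)

    def test_duplicated_sample_gets_coincident_coordinates(self):
        dm = DistanceMatrix(
            ("a", "a2", "b"),
            np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]),
        )
        res = pcoa(dm, k=1)
        assert res.coordinates.loc["a"].to_numpy() == pytest.approx(
            res.coordinates.loc["a2"].to_numpy(), abs=1e-10
        )

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(8)), d)
        res = pcoa(dm, k=2)
        coords = res.coordinates.to_numpy()
        d_rec = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        assert np.max(np.abs(d_rec - d)) < 1e-8

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(6)), d)
        ours = pcoa(dm, k=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, list(dm.ids)))
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.to_numpy()[:3], atol=1e-8
        )


def brute_force_permanova(d, codes, n_groups):
    """Independent enumeration oracle: pseudo-F over all distinct label
    arrangements, p = #{F >= F_obs} / #arrangements."""

    def f_stat(assign):
        n = len(assign)
        total = sum(d[i][j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        within = 0.0
        for g in range(n_groups):
            members = [i for i in range(n) if assign[i] == g]
            if len(members) > 1:
                ss = sum(
                    d[i][j] ** 2
                    for a, i in enumerate(members)
                    for j in members[a + 1:]
                )
                within += ss / len(members)
        among = total - within
        return (among / (n_groups - 1)) / (within / (n - n_groups))

    f_obs = f_stat(codes)
    arrangements = set(itertools.permutations(codes))
    hits = sum(1 for a in arrangements if f_stat(a) >= f_obs - 1e-12)
    return f_obs, hits / len(arrangements)


class TestPermanova:
    def test_single_group_rejected(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ParameterError):
            permanova(dm, ["g", "g"])

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 2.0
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(6)), d)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, labels, exhaustive=True)
        f_ref, p_ref = brute_force_permanova(d, [0, 0, 0, 1, 1, 1], 2)
        assert res.statistic == pytest.approx(f_ref, rel=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ids = tuple(f"s{i}" for i in range(6))
        labels = pd.Series(["a", "b", "a", "b", "a", "b"], index=ids)
        dm = DistanceMatrix(ids, d)
        perm = [3, 1, 4, 0, 5, 2]
        dm2 = dm.reorder([ids[i] for i in perm])
        f1 = permanova(dm, labels, n_perm=9, seed=0).statistic
        f2 = permanova(dm2, labels, n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_matches_scikit_bio_statistic(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ids = [f"s{i}" for i in range(8)]
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        ours = permanova(DistanceMatrix(tuple(ids), d), labels, n_perm=9, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(d, ids), labels, permutations=9)
        assert ours.statistic == pytest.approx(float(theirs["test statistic"]), rel=1e-10)


class TestMantel:
    def test_identity_and_monotone_transform_give_r_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ids = tuple(f"s{i}" for i in range(5))
        dm1 = DistanceMatrix(ids, d)
        dm2 = DistanceMatrix(ids, d**2)  # monotone transform
        assert mantel(dm1, dm1, n_perm=9, seed=0).r == pytest.approx(1.0)
        assert mantel(dm1, dm2, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_exhaustive_matches_brute_force(self):
        import scipy.stats

        rng = np.random.default_rng(9)
        a = rng.random((5, 5))
        b = rng.random((5, 5))
        a = (a + a.T) / 2
        b = (b + b.T) / 2
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        ids = tuple(f"s{i}" for i in range(5))
        res = mantel(DistanceMatrix(ids, a), DistanceMatrix(ids, b), exhaustive=True)

        import scipy.spatial.distance as ssd

        x = ssd.squareform(a, checks=False)
        r_obs = scipy.stats.spearmanr(x, ssd.squareform(b, checks=False)).statistic
        hits = total = 0
        for perm in itertools.permutations(range(5)):
            total += 1
            y = ssd.squareform(b[np.ix_(perm, perm)], checks=False)
            if scipy.stats.spearmanr(x, y).statistic >= r_obs - 1e-12:
                hits += 1
        assert res.r == pytest.approx(float(r_obs), abs=1e-12)
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_matches_scikit_bio_statistic(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(4)
        a = rng.random((7, 7))
        b = a + rng.random((7, 7)) * 0.3
        a, b = (a + a.T) / 2, (b + b.T) / 2
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        ids = tuple(f"s{i}" for i in range(7))
        ours = mantel(DistanceMatrix(ids, a), DistanceMatrix(ids, b), n_perm=9, seed=0)
        r_sk = sk_mantel(a, b, method="spearman", permutations=9)[0]
        assert ours.r == pytest.approx(float(r_sk), abs=1e-10)


class TestWindowing:
    def test_half_open_windows_anchored_at_zero(self):
        obs = pd.DataFrame(
            {"subject_id": ["p"] * 3, "day": [0, 2, 5], "value": [1.0, 3.0, 10.0]}
        )
        w = windowed_mean(obs, window=5)
        w0 = w[w["window_start"] == 0].iloc[0]
        w1 = w[w["window_start"] == 5].iloc[0]
        assert w0["mean"] == pytest.approx(2.0) and w0["n"] == 2
        assert w1["mean"] == pytest.approx(10.0) and w1["n"] == 1

    def test_single_value_is_its_own_mean(self):
        w = windowed_mean(
            pd.DataFrame({"subject_id": ["p"], "day": [13], "value": [4.0]})
        )
        assert len(w) == 1 and w.iloc[0]["mean"] == 4.0 and w.iloc[0]["window_start"] == 10


def brute_force_mw_two_sided(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2

    def u_of(group1):
        rest = list(pooled)
        for v in group1:
            rest.remove(v)
        return sum(1 for a in group1 for b in rest if a > b)

    u_obs = u_of(list(x))
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        g1 = [pooled[i] for i in comb]
        if abs(u_of(g1) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitneyAndArms:
    def test_exact_small_sample_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = list(rng.choice(100, size=3, replace=False))
            y = list(rng.choice(200, size=4, replace=False) + 100)
            u, p = mann_whitney(x, y)
            u_ref, p_ref = brute_force_mw_two_sided(x, y)
            assert u == u_ref
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_label_swap_flips_u(self):
        x, y = [5.0, 9.0, 1.0], [7.0, 3.0]
        u_xy, _ = mann_whitney(x, y)
        u_yx, _ = mann_whitney(y, x)
        assert u_xy + u_yx == len(x) * len(y)

    def test_compare_arms_skips_one_armed_windows(self):
        w = pd.DataFrame(
            {
                "subject_id": ["p1", "p2", "p3", "p4", "p1"],
                "window_start": [0, 0, 0, 0, 5],
                "mean": [1.0, 2.0, 3.0, 4.0, 9.0],
                "n": [1] * 5,
            }
        )
        arm_of = {"p1": "fmt", "p2": "fmt", "p3": "placebo", "p4": "placebo"}
        out = compare_arms(w, arm_of)
        assert list(out["window_start"]) == [0]
        assert out.iloc[0]["p_value"] == pytest.approx(1 / 3, abs=1e-12)
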