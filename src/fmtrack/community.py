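"""Community-level diversity, distance, ordination, and trajectory statistics.

Implements the whole-community analytics used to describe a longitudinal FMT
cohort: Shannon diversity and richness per sample, Bray-Curtis dissimilarity,
classical principal-coordinate analysis (PCoA), PERMANOVA and Mantel
permutation tests (with exhaustive enumeration on small sample sets), and
5-day-window trajectory means compared between treatment arms with
Mann-Whitney U tests.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats

from ._util import (
    AlignmentError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
    log,
    rng_from,
)
from .tables import FeatureTable


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def shannon(table: FeatureTable) -> pd.Series:
    """Shannon index H = -sum p_i ln p_i per sample (natural log).

    Accepts counts or relative tables; counts are converted to proportions
    per sample first. Zero-total samples are degenerate.
    """
    rel = table if table.kind == "relative" else table.to_relative()
    p = rel.data.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return pd.Series(terms.sum(axis=1), index=rel.data.index, name="shannon")


def richness(table: FeatureTable, min_count: int = 1) -> pd.Series:
    """Number of features present (count >= min_count) per sample."""
    totals = table.data.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise DegenerateInputError(f"sample {bad!r} has zero total count")
    return table.presence(min_count).sum(axis=1).rename("richness")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValidationError("ids must match matrix dimension")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sample ids in distance matrix")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix must be symmetric (tol 1e-12)")
        if np.diagonal(v).any():
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if (v < 0).any():
            raise ValidationError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper triangle in scipy condensed order."""
        return ssd.squareform(self.values, checks=False)

    def between(self, a: str, b: str) -> float:
        ia, ib = self.ids.index(a), self.ids.index(b)
        return float(self.values[ia, ib])

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = 1 - sum_i min(a_i, b_i).

    Requires a relative-kind table (call :meth:`FeatureTable.to_relative`
    first) so that values are guaranteed to lie in [0, 1].
    """
    if table.kind != "relative":
        raise ValidationError("bray_curtis requires a relative-kind table; call to_relative()")
    mat = ssd.squareform(ssd.pdist(table.data.to_numpy(), metric="braycurtis"))
    np.fill_diagonal(mat, 0.0)
    mat = (mat + mat.T) / 2.0  # enforce exact symmetry against fp jitter
    return DistanceMatrix(tuple(table.sample_ids), mat)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame      # samples x retained axes
    eigenvalues: np.ndarray        # positive eigenvalues, descending
    proportion_explained: np.ndarray
    n_negative_discarded: int


def pcoa(dm: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical (metric) multidimensional scaling.

    Double-centers -d^2/2, eigendecomposes, and keeps the top-``k`` axes with
    positive eigenvalues. Negative eigenvalues (from non-Euclidean distances)
    are discarded without correction; their count is reported. Proportion
    explained is computed over the positive eigenvalues only.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    d2 = dm.values**2
    n = len(dm)
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    n_pos = int(positive.sum())
    n_neg = int((eigvals < -tol).sum())
    if k > n_pos:
        log.warning("pcoa: requested %d axes but only %d positive eigenvalues", k, n_pos)
        k = max(n_pos, 1)
    kept = eigvals[:k].clip(min=0.0)
    coords = eigvecs[:, :k] * np.sqrt(kept)
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    pos_sum = eigvals[positive].sum() if n_pos else 1.0
    return PCoAResult(
        coordinates=frame,
        eigenvalues=eigvals[:n_pos],
        proportion_explained=(eigvals[:n_pos] / pos_sum) if n_pos else np.array([]),
        n_negative_discarded=n_neg,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    exhaustive: bool = False


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        return math.inf
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dm: DistanceMatrix,
    grouping: Mapping[str, str] | pd.Series | Sequence[str],
    n_perm: int = 999,
    seed=None,
    strata: Mapping[str, str] | pd.Series | Sequence[str] | None = None,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic compares among-group to within-group sums of
    squared distances. Significance comes from permuting group labels, freely
    or within ``strata`` when given. With ``exhaustive=True`` all distinct
    label arrangements are enumerated (feasible only for small n) and
    p = #{F_perm >= F_obs} / #arrangements, the identity arrangement included;
    otherwise p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) over random
    permutations.
    """
    labels = _as_label_array(grouping, dm.ids, "grouping")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ParameterError("permanova requires at least two groups")
    d2 = dm.values**2
    f_obs = _pseudo_f(d2, codes, len(uniq))

    if exhaustive:
        if strata is not None:
            raise ParameterError("exhaustive enumeration does not support strata")
        count = 0
        total = 0
        for perm in _distinct_arrangements(tuple(codes)):
            total += 1
            if _pseudo_f(d2, np.array(perm), len(uniq)) >= f_obs - 1e-12:
                count += 1
        return PermutationTestResult(f_obs, count / total, total, exhaustive=True)

    rng = rng_from(seed)
    strata_arr = None if strata is None else _as_label_array(strata, dm.ids, "strata")
    count = 0
    for _ in range(n_perm):
        perm_codes = _permute_labels(codes, rng, strata_arr)
        if _pseudo_f(d2, perm_codes, len(uniq)) >= f_obs - 1e-12:
            count += 1
    return PermutationTestResult(f_obs, (1 + count) / (1 + n_perm), n_perm)


def _as_label_array(labels, ids: tuple[str, ...], what: str) -> np.ndarray:
    if isinstance(labels, pd.Series):
        missing = set(ids) - set(labels.index)
        if missing:
            raise AlignmentError(f"{what} missing samples: {sorted(missing)}")
        return labels.loc[list(ids)].to_numpy()
    if isinstance(labels, Mapping):
        missing = set(ids) - set(labels)
        if missing:
            raise AlignmentError(f"{what} missing samples: {sorted(missing)}")
        return np.array([labels[i] for i in ids])
    arr = np.asarray(list(labels))
    if len(arr) != len(ids):
        raise AlignmentError(f"{what} length {len(arr)} != number of samples {len(ids)}")
    return arr


def _permute_labels(codes: np.ndarray, rng, strata: np.ndarray | None) -> np.ndarray:
    if strata is None:
        return rng.permutation(codes)
    out = codes.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = out[idx][rng.permutation(len(idx))]
    return out


def _distinct_arrangements(codes: tuple[int, ...]):
    """All distinct arrangements of a label multiset (small n only)."""
    seen = set()
    for perm in itertools.permutations(codes):
        if perm not in seen:
            seen.add(perm)
            yield perm


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    exhaustive: bool = False


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed=None,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test of correlation between two distance matrices.

    Correlates the vectorized upper triangles (Spearman by default) and
    assesses significance by permuting the sample order of the second matrix.
    """
    if set(d1.ids) != set(d2.ids):
        raise AlignmentError("mantel requires matching sample sets")
    d2 = d2.reorder(d1.ids)
    x = d1.condensed()
    corr = _corr_func(method)

    def stat(mat: np.ndarray) -> float:
        return corr(x, ssd.squareform(mat, checks=False))

    r_obs = stat(d2.values)
    better = _tail_comparator(alternative, r_obs)

    n = len(d1)
    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            mat = d2.values[np.ix_(perm, perm)]
            if better(stat(mat)):
                count += 1
        return MantelResult(r_obs, count / total, total, exhaustive=True)

    rng = rng_from(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if better(stat(d2.values[np.ix_(perm, perm)])):
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm)


def _corr_func(method: str):
    if method == "spearman":
        return lambda a, b: float(scipy.stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return lambda a, b: float(scipy.stats.pearsonr(a, b).statistic)
    raise ParameterError(f"unknown correlation method {method!r}")


def _tail_comparator(alternative: str, r_obs: float):
    eps = 1e-12
    if alternative == "greater":
        return lambda r: r >= r_obs - eps
    if alternative == "less":
        return lambda r: r <= r_obs + eps
    if alternative == "two-sided":
        return lambda r: abs(r) >= abs(r_obs) - eps
    raise ParameterError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# Windowed trajectories
# ---------------------------------------------------------------------------


def windowed_mean(
    observations: pd.DataFrame, window: int = 5
) -> pd.DataFrame:
    """Per-subject means of a statistic within non-overlapping day windows.

    ``observations`` needs columns ``subject_id``, ``day``, ``value``. Windows
    are half-open intervals [k*window, (k+1)*window) anchored at day 0 (the
    colonoscopic transplant), so day 5 falls in window 1, not window 0. Empty
    windows are simply absent from the output.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    df = observations.copy()
    if not np.isfinite(df["day"].to_numpy(dtype=float)).all():
        raise ParameterError("days must be finite")
    df["window_start"] = (np.floor(df["day"].to_numpy(dtype=float) / window) * window).astype(int)
    grouped = (
        df.groupby(["subject_id", "window_start"])["value"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    return grouped


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the combined sample size is <= 10 and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ParameterError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 10 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_arms(
    windowed: pd.DataFrame,
    arm_of: Mapping[str, str] | pd.Series,
    arms: tuple[str, str] = ("fmt", "placebo"),
) -> pd.DataFrame:
    """Mann-Whitney comparison of per-subject window means between two arms.

    ``windowed`` is the output of :func:`windowed_mean`. Windows where either
    arm has no subjects are skipped with a log notice. Returns one row per
    tested window with group sizes, U (for the first arm), and the two-sided
    p-value.
    """
    if isinstance(arm_of, pd.Series):
        arm_of = arm_of.to_dict()
    df = windowed.copy()
    df["arm"] = df["subject_id"].map(arm_of)
    rows = []
    for start, sub in df.groupby("window_start"):
        a = sub.loc[sub["arm"] == arms[0], "mean"].to_numpy()
        b = sub.loc[sub["arm"] == arms[1], "mean"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            log.info("compare_arms: window %s has an empty arm; skipped", start)
            continue
        u, p = mann_whitney(a, b)
        rows.append(
            {"window_start": start, f"n_{arms[0]}": len(a), f"n_{arms[1]}": len(b),
             "u": u, "p_value": p}
        )
    return pd.DataFrame(rows)
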