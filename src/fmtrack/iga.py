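"""IgA-seq coating scores, reliability calls, and coating correlations.

IgA-seq sorts stool bacteria into IgA-coated and IgA-uncoated fractions and
16S-sequences each. The coating score of an ASV in a sample is the log2 fold
change of its relative abundance between the coated and uncoated fractions
(positive = coated). Per sample, strongly coated/uncoated ASVs lie beyond the
sample mean +/- 1 SD of scores. Across samples, reliably coated/uncoated ASVs
are found with one-sample t tests against zero and Benjamini-Hochberg FDR
control, and the count of reliable ASVs is validated by a permutation test
that shuffles ASV labels independently within every sample. Further analyses
correlate coating scores across samples, hosts, and donor/patient feature
subsets (shared vs transferred) to quantify host- and strain-specificity of
IgA coating.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._util import (
    AlignmentError,
    DegenerateInputError,
    ParameterError,
    log,
    rng_from,
)
from .tables import FeatureTable

RELIABILITY_CLASSES = ("reliably_coated", "reliably_uncoated", "variable", "unscored")


@dataclasses.dataclass(frozen=True)
class IgaScoreMatrix:
    """Samples x ASVs matrix of log2 coating scores; NaN marks unscored cells."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ParameterError("coating scores must be finite where present")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.scores.columns)

    def sample_mean(self) -> pd.Series:
        return self.scores.mean(axis=1)

    def sample_sd(self) -> pd.Series:
        return self.scores.std(axis=1, ddof=1)

    def n_scored(self) -> pd.Series:
        return self.scores.notna().sum(axis=1)


def coating_score(
    coated: FeatureTable,
    uncoated: FeatureTable,
    pseudocount: float = 1.0,
    min_reads: int = 5,
) -> IgaScoreMatrix:
    """Log2 coated/uncoated relative-abundance ratio per sample and ASV.

    A pseudocount (default 1) is added to every ASV count in each fraction
    before converting to relative abundance, then
    s = log2(rel_coated / rel_uncoated). ASVs whose raw count is below
    ``min_reads`` in both fractions of a sample are unscored (NaN) there.
    Swapping the two fractions negates every score exactly.
    """
    if coated.sample_ids != uncoated.sample_ids or coated.feature_ids != uncoated.feature_ids:
        raise AlignmentError("coated and uncoated tables must share both axes")
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")
    c = coated.data.to_numpy(dtype=float)
    u = uncoated.data.to_numpy(dtype=float)
    if (c.sum(axis=1) == 0).any() or (u.sum(axis=1) == 0).any():
        raise DegenerateInputError("a fraction with zero total reads cannot be scored")
    cp = c + pseudocount
    up = u + pseudocount
    rel_c = cp / cp.sum(axis=1, keepdims=True)
    rel_u = up / up.sum(axis=1, keepdims=True)
    # difference of logs (not log of a ratio) so that swapping the fractions
    # negates every score bit-exactly
    s = np.log2(rel_c) - np.log2(rel_u)
    unscored = np.maximum(c, u) < min_reads
    s[unscored] = np.nan
    return IgaScoreMatrix(
        pd.DataFrame(s, index=coated.data.index, columns=coated.data.columns)
    )


def strong_classification(m: IgaScoreMatrix) -> pd.DataFrame:
    """Per-sample ASV classes from the mean +/- 1 SD rule.

    ``coated`` if the score strictly exceeds the sample's mean + 1 SD,
    ``uncoated`` if strictly below mean - 1 SD, otherwise ``neutral``.
    Samples with fewer than three scored ASVs are skipped with a notice.
    NaN marks unscored cells and skipped samples.
    """
    out = pd.DataFrame(
        np.nan, index=m.scores.index, columns=m.scores.columns, dtype=object
    )
    mean, sd, n = m.sample_mean(), m.sample_sd(), m.n_scored()
    for sample in m.sample_ids:
        if n[sample] < 3:
            log.info("strong_classification: sample %r has <3 scored ASVs; skipped", sample)
            continue
        s = m.scores.loc[sample]
        hi, lo = mean[sample] + sd[sample], mean[sample] - sd[sample]
        cls = pd.Series("neutral", index=s.index, dtype=object)
        cls[s > hi] = "coated"
        cls[s < lo] = "uncoated"
        cls[s.isna()] = np.nan
        out.loc[sample] = cls
    return out


def reliability(
    m: IgaScoreMatrix,
    min_samples: int = 5,
    fdr: float = 0.1,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Reliably coated/uncoated calls across samples per ASV.

    A two-sided one-sample t test of each ASV's scores against zero, with
    Benjamini-Hochberg adjustment across all tested ASVs; an ASV scored in at
    least ``min_samples`` samples is ``reliably_coated``/``reliably_uncoated``
    when the adjusted p-value is below ``fdr`` (class by the sign of the mean
    score) and ``variable`` otherwise. ASVs scored in fewer samples are
    ``unscored``. When ``groups`` maps samples to hosts, per-host mean scores
    are tested instead of per-sample scores.
    """
    if min_samples < 2:
        raise ParameterError("min_samples must be >= 2")
    scores = m.scores
    if groups is not None:
        scores = scores.groupby(groups).mean()
    vals = scores.to_numpy(dtype=float)
    n = (~np.isnan(vals)).sum(axis=0)
    tested = n >= min_samples
    t_stat = np.full(vals.shape[1], np.nan)
    p_val = np.full(vals.shape[1], np.nan)
    mean = np.full(vals.shape[1], np.nan)
    if tested.any():
        res = scipy.stats.ttest_1samp(
            vals[:, tested], popmean=0.0, nan_policy="omit", axis=0
        )
        t_stat[tested] = res.statistic
        p_val[tested] = res.pvalue
        mean[tested] = np.nanmean(vals[:, tested], axis=0)
    q_val = np.full(vals.shape[1], np.nan)
    if tested.any():
        q_val[tested] = multipletests(p_val[tested], method="fdr_bh")[1]
    cls = np.where(
        ~tested,
        "unscored",
        np.where(
            (q_val < fdr) & (mean > 0),
            "reliably_coated",
            np.where((q_val < fdr) & (mean < 0), "reliably_uncoated", "variable"),
        ),
    )
    return pd.DataFrame(
        {
            "n_samples": n,
            "mean_score": mean,
            "t": t_stat,
            "p_value": p_val,
            "q_value": q_val,
            "class": cls,
        },
        index=pd.Index(scores.columns, name="asv_id"),
    )


# -- vectorized internals shared with the permutation test ------------------


def _bh_reject_count(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection counts for batched p-value vectors.

    ``p`` has shape (..., m); NaN entries (untested) are ignored. Matches
    statsmodels' fdr_bh rejections (verified by test).
    """
    p = np.atleast_2d(p)
    m = (~np.isnan(p)).sum(axis=-1, keepdims=True)
    ps = np.sort(np.where(np.isnan(p), np.inf, p), axis=-1)
    ranks = np.arange(1, p.shape[-1] + 1)
    passed = ps <= alpha * ranks / np.maximum(m, 1)
    idx = np.where(passed, ranks, 0)
    return idx.max(axis=-1)


def _t_pvalues(vals: np.ndarray, min_samples: int) -> np.ndarray:
    """Two-sided one-sample t-test p-values per column of (..., n, m) scores."""
    n = (~np.isnan(vals)).sum(axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(vals, axis=-2)
        sd = np.nanstd(vals, axis=-2, ddof=1)
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))
    p = np.where((n >= min_samples) & (sd > 0), p, np.nan)
    return p


@dataclasses.dataclass(frozen=True)
class PermutationNullResult:
    observed_count: int
    p_value: float
    n_permutations: int
    null_counts: np.ndarray


def permutation_test(
    m: IgaScoreMatrix,
    n_perm: int = 10000,
    seed=None,
    min_samples: int = 5,
    fdr: float = 0.1,
    batch_size: int = 200,
) -> PermutationNullResult:
    """Permutation null for the count of reliably coated/uncoated ASVs.

    Each permutation shuffles the ASV labels independently within every
    sample's score vector (preserving each sample's score distribution while
    breaking ASV identity), reruns the reliability analysis, and records the
    number of reliable ASVs. p = (1 + #{null count >= observed}) /
    (1 + n_perm).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    vals = m.scores.to_numpy(dtype=float)
    n_samples, n_asvs = vals.shape
    observed = int(_bh_reject_count(_t_pvalues(vals, min_samples), fdr)[0])
    rng = rng_from(seed)
    null_counts = np.empty(n_perm, dtype=int)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        tiled = np.broadcast_to(vals, (b, n_samples, n_asvs)).reshape(-1, n_asvs)
        shuffled = rng.permuted(tiled, axis=1).reshape(b, n_samples, n_asvs)
        p = _t_pvalues(shuffled, min_samples)
        null_counts[done:done + b] = _bh_reject_count(p, fdr)
        done += b
    exceed = int((null_counts >= observed).sum())
    return PermutationNullResult(
        observed_count=observed,
        p_value=(1 + exceed) / (1 + n_perm),
        n_permutations=n_perm,
        null_counts=null_counts,
    )


# ---------------------------------------------------------------------------
# Coating correlations
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def coating_correlation(
    a: pd.Series, b: pd.Series, method: str = "pearson"
) -> CorrelationResult | None:
    """Correlation of two coating-score vectors over jointly scored ASVs.

    ``a`` and ``b`` are score vectors indexed by ASV (a sample's row of an
    :class:`IgaScoreMatrix`, or per-group mean scores). Returns None with a
    notice when fewer than three ASVs are scored in both.
    """
    shared = a.index.intersection(b.index)
    x = a[shared].to_numpy(dtype=float)
    y = b[shared].to_numpy(dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        log.info("coating_correlation: <3 jointly scored ASVs; undeterminable")
        return None
    if method == "pearson":
        res = scipy.stats.pearsonr(x[ok], y[ok])
    elif method == "spearman":
        res = scipy.stats.spearmanr(x[ok], y[ok])
    else:
        raise ParameterError(f"unknown method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(ok.sum()))


@dataclasses.dataclass(frozen=True)
class StrainSpecificityResult:
    r_shared: float
    r_transferred: float
    difference: float
    ci_low: float
    ci_high: float
    n_shared: int
    n_transferred: int


def strain_specificity(
    donor_scores: pd.Series,
    patient_scores: pd.Series,
    shared_set: Iterable[str],
    transferred_set: Iterable[str],
    n_boot: int = 1000,
    seed=None,
) -> StrainSpecificityResult | None:
    """Donor-patient coating correlation: transferred vs shared ASVs.

    Shared ASVs (present in donor and patient before transplant) may mix
    distinct conspecific strains across the two hosts; transferred ASVs
    (donor-source features that colonized) are likely the same strain in
    both. A higher correlation among transferred ASVs indicates
    strain-specific IgA coating. The difference r_transferred - r_shared gets
    a percentile bootstrap CI over ASV resampling within each subset. The two
    subsets must be disjoint; returns None with a notice when either subset
    has fewer than three jointly scored ASVs.
    """
    shared_set, transferred_set = list(shared_set), list(transferred_set)
    overlap = set(shared_set) & set(transferred_set)
    if overlap:
        raise ParameterError(f"shared and transferred sets overlap: {sorted(overlap)}")
    r_sh = coating_correlation(donor_scores[donor_scores.index.intersection(shared_set)],
                               patient_scores)
    r_tr = coating_correlation(
        donor_scores[donor_scores.index.intersection(transferred_set)], patient_scores
    )
    if r_sh is None or r_tr is None:
        log.info("strain_specificity: undersized subset; no difference reported")
        return None
    rng = rng_from(seed)
    boot = np.empty(n_boot)
    sh_ids = _jointly_scored(donor_scores, patient_scores, shared_set)
    tr_ids = _jointly_scored(donor_scores, patient_scores, transferred_set)
    for i in range(n_boot):
        sh = [sh_ids[j] for j in rng.integers(0, len(sh_ids), len(sh_ids))]
        tr = [tr_ids[j] for j in rng.integers(0, len(tr_ids), len(tr_ids))]
        r1 = _plain_r(donor_scores, patient_scores, sh)
        r2 = _plain_r(donor_scores, patient_scores, tr)
        boot[i] = r2 - r1
    boot = boot[~np.isnan(boot)]
    lo, hi = (np.percentile(boot, [2.5, 97.5]) if len(boot) else (np.nan, np.nan))
    return StrainSpecificityResult(
        r_shared=r_sh.r,
        r_transferred=r_tr.r,
        difference=r_tr.r - r_sh.r,
        ci_low=float(lo),
        ci_high=float(hi),
        n_shared=r_sh.n,
        n_transferred=r_tr.n,
    )


def _jointly_scored(a: pd.Series, b: pd.Series, ids: list[str]) -> list[str]:
    keep = [i for i in ids if i in a.index and i in b.index
            and np.isfinite(a[i]) and np.isfinite(b[i])]
    return keep


def _plain_r(a: pd.Series, b: pd.Series, ids: list[str]) -> float:
    x, y = a[ids].to_numpy(float), b[ids].to_numpy(float)
    if len(ids) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Score vs abundance structure
# ---------------------------------------------------------------------------


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient (skewness^2 + 1) / kurtosis.

    Uses population moments (kurtosis not excess). Values above 5/9 suggest
    bimodality; a symmetric two-point distribution attains 1.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3 or np.std(x) == 0:
        return np.nan
    skew = scipy.stats.skew(x)
    kurt = scipy.stats.kurtosis(x, fisher=False)
    return float((skew**2 + 1) / kurt)


def score_abundance_relations(
    m: IgaScoreMatrix,
    abundance: FeatureTable,
    min_samples: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relate mean coating score to abundance structure across ASVs.

    For each ASV present in at least ``min_samples`` samples of the abundance
    table: mean relative abundance, variance of relative abundance across
    samples, and the bimodality coefficient of its abundance distribution.
    Returns the per-ASV frame and the Pearson correlation of each property
    with the ASV's mean coating score.
    """
    rel = abundance if abundance.kind == "relative" else abundance.to_relative()
    shared = [a for a in m.asv_ids if a in rel.data.columns]
    rows = []
    for asv in shared:
        vals = rel.data[asv].to_numpy(dtype=float)
        if (vals > 0).sum() < min_samples:
            continue
        rows.append(
            {
                "asv_id": asv,
                "mean_score": float(np.nanmean(m.scores[asv])),
                "mean_abundance": float(vals.mean()),
                "variance": float(vals.var(ddof=1)),
                "bimodality": bimodality_coefficient(vals),
            }
        )
    per_asv = pd.DataFrame(rows).set_index("asv_id")
    cors = []
    for prop in ("mean_abundance", "variance", "bimodality"):
        sub = per_asv[["mean_score", prop]].dropna()
        if len(sub) >= 3:
            res = scipy.stats.pearsonr(sub["mean_score"], sub[prop])
            cors.append({"property": prop, "r": float(res.statistic),
                         "p_value": float(res.pvalue), "n": len(sub)})
        else:
            cors.append({"property": prop, "r": np.nan, "p_value": np.nan, "n": len(sub)})
    return per_asv, pd.DataFrame(cors).set_index("property")
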