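"""Source tracking and arm comparisons for gene-family abundance tables.

Gene-family profiles (marker-based RPKM-style tables, one row per sample) are
analysed with the same machinery as taxonomic features: a family observed in
the donor but not at patient baseline that appears after transplant is a
transferred function. Category-level richness trajectories are compared
between arms in 5-day windows with Welch t tests, and the quinolone-resistance
response to the antibiotic course is tested with a Mann-Whitney U comparison
of baseline vs the 10 days immediately after antibiotics.
"""
from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd
import scipy.stats

from ._util import ConfigurationError, ParameterError, log
from .community import mann_whitney, windowed_mean
from .sources import SourceAssignment, assign_sources, source_fractions
from .tables import FeatureTable, FunctionCategoryMap, SampleMetadata


def _presence_table(
    profiles: FeatureTable, families: list[str], min_abundance: float
) -> FeatureTable:
    """Binarize a gene-family abundance table at ``abundance > min_abundance``.

    The result is a 0/1 counts table so the taxonomic source-assignment code
    path (presence at min_count=1) applies unchanged to gene families.
    """
    if min_abundance < 0:
        raise ParameterError("min_abundance must be >= 0")
    data = (profiles.data[families] > min_abundance).astype(float)
    return FeatureTable(data, kind="counts")


def function_sources(
    profiles: FeatureTable,
    metadata: SampleMetadata,
    cmap: FunctionCategoryMap,
    patient_id: str,
    category: str,
    min_abundance: float = 0.0,
    donor_scope: str = "induction",
) -> tuple[SourceAssignment, pd.DataFrame]:
    """Provenance and per-sample source fractions of one function category.

    Applies exactly the taxonomic classification rules to the families of
    ``category``, with presence defined as abundance strictly above
    ``min_abundance`` (default 0: marker tables are pre-filtered upstream).
    Returns the assignment and the occurrence-weighted fraction table.
    """
    families = cmap.families_in(category)
    families = [f for f in families if f in profiles.data.columns]
    if not families:
        raise ParameterError(f"no families of category {category!r} in the profile table")
    binary = _presence_table(profiles, families, min_abundance)
    assignment = assign_sources(
        binary, metadata, patient_id, min_count=1, donor_scope=donor_scope
    )
    fractions = source_fractions(assignment, binary, metadata, min_count=1)
    return assignment, fractions


def category_richness(
    profiles: FeatureTable,
    cmap: FunctionCategoryMap,
    category: str,
    min_abundance: float = 0.0,
) -> pd.Series:
    """Per-sample count of families in ``category`` with abundance above
    ``min_abundance``. Monotone non-increasing in the threshold."""
    families = [f for f in cmap.families_in(category) if f in profiles.data.columns]
    if min_abundance < 0:
        raise ParameterError("min_abundance must be >= 0")
    return (profiles.data[families] > min_abundance).sum(axis=1).rename(f"{category}_richness")


def compare_category_richness(
    profiles: FeatureTable,
    metadata: SampleMetadata,
    cmap: FunctionCategoryMap,
    category: str,
    min_abundance: float = 0.0,
    window: int = 5,
    arms: tuple[str, str] = ("fmt", "placebo"),
) -> pd.DataFrame:
    """Welch t test of windowed per-subject category richness between arms.

    Richness series are averaged per subject in 5-day windows; each window
    with subjects in both arms is tested with an unequal-variance t test
    (group sizes in such trials are rarely balanced). Returns one row per
    tested window.
    """
    rich = category_richness(profiles, cmap, category, min_abundance)
    df = metadata.frame.loc[rich.index, ["subject_id", "day", "arm"]].copy()
    df["value"] = rich
    df = df[df["arm"].isin(arms)]
    windowed = windowed_mean(df[["subject_id", "day", "value"]], window=window)
    arm_of = df.drop_duplicates("subject_id").set_index("subject_id")["arm"]
    rows = []
    for start, sub in windowed.groupby("window_start"):
        a = sub.loc[sub["subject_id"].map(arm_of) == arms[0], "mean"].to_numpy()
        b = sub.loc[sub["subject_id"].map(arm_of) == arms[1], "mean"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {"window_start": start, f"n_{arms[0]}": len(a), f"n_{arms[1]}": len(b),
             "t": float(res.statistic), "p_value": float(res.pvalue)}
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class QuinoloneResponse:
    u: float
    p_value: float
    per_patient: pd.DataFrame  # patient, baseline mean, post-abx mean, delta
    baseline_values: np.ndarray
    post_values: np.ndarray


def quinolone_response(
    profiles: FeatureTable,
    metadata: SampleMetadata,
    cmap: FunctionCategoryMap,
    post_days: int = 10,
) -> QuinoloneResponse:
    """Test the quinolone-resistance abundance response to antibiotics.

    Per patient, quinolone-class resistance abundance is summed per sample at
    baseline and in the window of ``post_days`` days immediately after the
    antibiotic course ends (boundary day abx_end + post_days inclusive). The
    two pooled sample sets are compared with a two-sided Mann-Whitney U test;
    per-patient before/after means and deltas are reported for plotting
    (positive delta = the increase expected under quinolone selection).
    """
    quinolone = [
        f for f in cmap.resistance_families("quinolone") if f in profiles.data.columns
    ]
    if not quinolone:
        raise ConfigurationError("no quinolone-class families in the category map")
    sums = profiles.data[quinolone].sum(axis=1)
    baseline_vals: list[float] = []
    post_vals: list[float] = []
    rows = []
    for patient in metadata.subjects(role="patient"):
        base_ids = metadata.samples_of(patient, phases=("baseline",))
        abx_days = metadata.frame.loc[
            metadata.frame["subject_id"].eq(patient)
            & metadata.frame["phase"].eq("antibiotics"),
            "day",
        ]
        if not base_ids or abx_days.empty:
            log.info("quinolone_response: patient %r lacks baseline or antibiotics "
                     "samples; skipped", patient)
            continue
        abx_end = int(abx_days.max())
        post_ids = [
            s for s in metadata.samples_of(patient)
            if abx_end < metadata.day_of(s) <= abx_end + post_days
        ]
        if not post_ids:
            log.info("quinolone_response: patient %r has no samples within %d days "
                     "after antibiotics; skipped", patient, post_days)
            continue
        b = sums[base_ids].to_numpy(dtype=float)
        a = sums[post_ids].to_numpy(dtype=float)
        baseline_vals.extend(b)
        post_vals.extend(a)
        rows.append(
            {"patient_id": patient, "baseline_mean": float(b.mean()),
             "post_abx_mean": float(a.mean()),
             "delta": float(a.mean() - b.mean())}
        )
    if not rows:
        raise ConfigurationError("no patient has both baseline and post-antibiotics samples")
    baseline_arr = np.array(baseline_vals)
    post_arr = np.array(post_vals)
    u, p = mann_whitney(post_arr, baseline_arr)
    return QuinoloneResponse(
        u=u,
        p_value=p,
        per_patient=pd.DataFrame(rows).set_index("patient_id"),
        baseline_values=baseline_arr,
        post_values=post_arr,
    )


def cumulative_abundance(
    profiles: FeatureTable,
    cmap: FunctionCategoryMap,
    category: str,
    log10: bool = False,
    offset: float | None = None,
) -> pd.Series:
    """Per-sample summed abundance over a category's families.

    With ``log10=True`` a pseudo-offset is added before the log; the default
    offset is one tenth of the smallest positive cumulative abundance
    observed, so all-zero samples stay finite.
    """
    families = [f for f in cmap.families_in(category) if f in profiles.data.columns]
    total = profiles.data[families].sum(axis=1).rename(f"{category}_abundance")
    if not log10:
        return total
    if offset is None:
        positive = total[total > 0]
        offset = float(positive.min()) / 10.0 if len(positive) else 1.0
    return np.log10(total + offset).rename(f"{category}_log10_abundance")
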