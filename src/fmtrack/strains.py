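"""Strain comparison from windowed read depths of reference genomes.

Strains of the same species are compared through the read-depth profile of
1,000-bp windows tiled over a reference genome. Conspecific strains share a
core genome but differ in accessory (flexible) segments, so two samples
dominated by the same strain cover the same windows, while samples dominated
by different strains each cover windows the other lacks. The match rule:

    two profiles MATCH when no window with depth above that sample's median
    (in either sample) has zero depth in the other sample; any such window
    makes the comparison AMBIGUOUS (distinct strains or a strain mixture);
    if either sample's median window depth is below the depth gate (default
    5) the comparison is INSUFFICIENT.

The rule is applied symmetrically in both directions. Longitudinal verdict
series against donor samples collapse into six colonization/dominance
patterns. Helpers for single-nucleotide strain deconvolution post-processing
(longitudinal sample pooling and median-depth normalization of strain
frequencies) live here too.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import AlignmentError, ParameterError, ValidationError, log

VERDICTS = ("match", "ambiguous", "insufficient")

PATTERN_LABELS = {
    1: "persistent_dominance",
    2: "temporary_dominance",
    3: "persistent_colonization_temporary_dominance",
    4: "ambiguous_persistent",
    5: "ambiguous_temporary",
    6: "no_colonization",
}


@dataclasses.dataclass(frozen=True)
class WindowDepthProfile:
    """Mean read depth per fixed-size genome window for one sample.

    The median is taken over all retained windows, zero-depth windows
    included, and recomputed on construction.
    """

    genome_id: str
    sample_id: str
    depths: np.ndarray
    window_size: int = 1000

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", d)
        if d.ndim != 1:
            raise ValidationError("depths must be one-dimensional")
        if (d < 0).any():
            raise ValidationError("window depths must be non-negative")
        if self.window_size < 1:
            raise ParameterError("window_size must be >= 1")

    @property
    def median(self) -> float:
        return float(np.median(self.depths)) if len(self.depths) else 0.0

    @property
    def n_windows(self) -> int:
        return len(self.depths)


def window_depths(
    positions: Sequence[int],
    depths: Sequence[float],
    genome_length: int,
    window: int = 1000,
    genome_id: str = "",
    sample_id: str = "",
    one_based: bool = True,
) -> WindowDepthProfile:
    """Aggregate a per-base depth series into mean depth per window.

    ``positions``/``depths`` follow the convention of standard depth tools
    (1-based positions by default); bases absent from the input count as
    depth zero. Windows tile the genome as half-open intervals
    [w*window, (w+1)*window); a trailing window shorter than half the window
    size is dropped. An empty depth series yields an all-zero profile with a
    warning.
    """
    if genome_length < 1:
        raise ParameterError("genome_length must be >= 1")
    n_full, tail = divmod(genome_length, window)
    n_windows = n_full + (1 if tail >= window / 2 else 0)
    if n_windows == 0:
        raise ParameterError("genome shorter than half a window; nothing to retain")
    pos = np.asarray(positions, dtype=np.int64)
    dep = np.asarray(depths, dtype=float)
    if len(pos) != len(dep):
        raise ParameterError("positions and depths must have equal length")
    if len(pos) == 0:
        log.warning("window_depths: empty depth input for %s/%s; all-zero profile",
                    genome_id, sample_id)
        return WindowDepthProfile(genome_id, sample_id, np.zeros(n_windows), window)
    if one_based:
        pos = pos - 1
    if (pos < 0).any() or (pos >= genome_length).any():
        raise ParameterError("positions outside the genome")
    if (dep < 0).any():
        raise ValidationError("per-base depths must be non-negative")
    win_idx = pos // window
    sums = np.bincount(win_idx, weights=dep, minlength=n_full + (1 if tail else 0))
    sums = sums[:n_windows]
    lengths = np.full(n_windows, window, dtype=float)
    if n_windows > n_full:  # retained tail is shorter than a full window
        lengths[-1] = tail
    return WindowDepthProfile(genome_id, sample_id, sums / lengths, window)


@dataclasses.dataclass(frozen=True)
class StrainComparison:
    """Outcome of a pairwise flexible-genome comparison."""

    sample_a: str
    sample_b: str
    verdict: str
    offending_windows: tuple[int, ...]
    median_a: float
    median_b: float


def compare_strains(
    a: WindowDepthProfile, b: WindowDepthProfile, depth_gate: float = 5.0
) -> StrainComparison:
    """Compare the dominant strains of two samples on one genome.

    ``insufficient`` when either profile's median depth is below
    ``depth_gate``; otherwise ``match`` unless some window with depth above
    its own sample's median is entirely absent (depth exactly zero) from the
    other sample, in which case ``ambiguous`` with the offending windows
    reported. Symmetric in its arguments.
    """
    if a.genome_id != b.genome_id or a.window_size != b.window_size \
            or a.n_windows != b.n_windows:
        raise AlignmentError(
            "profiles must share genome, window size, and window count"
        )
    med_a, med_b = a.median, b.median
    if med_a < depth_gate or med_b < depth_gate:
        return StrainComparison(a.sample_id, b.sample_id, "insufficient", (),
                                med_a, med_b)
    off = np.flatnonzero(
        ((a.depths > med_a) & (b.depths == 0))
        | ((b.depths > med_b) & (a.depths == 0))
    )
    verdict = "match" if len(off) == 0 else "ambiguous"
    return StrainComparison(a.sample_id, b.sample_id, verdict,
                            tuple(int(i) for i in off), med_a, med_b)


@dataclasses.dataclass(frozen=True)
class TrajectoryPoint:
    sample_id: str
    followup: bool
    consensus: str
    per_donor: tuple[StrainComparison, ...]


def donor_match_trajectory(
    patient_profiles: Sequence[WindowDepthProfile],
    donor_profiles: Sequence[WindowDepthProfile],
    depth_gate: float = 5.0,
    followup_flags: Sequence[bool] | None = None,
) -> list[TrajectoryPoint]:
    """Verdict time series of patient samples against every donor sample.

    ``patient_profiles`` should be ordered by collection day. The consensus
    verdict per patient sample is ``match`` if any donor sample matches,
    else ``ambiguous`` if any comparison is ambiguous, else ``insufficient``.
    When no donor profile passes the depth gate, every consensus is
    ``insufficient`` (with a notice).
    """
    if followup_flags is None:
        followup_flags = [False] * len(patient_profiles)
    if len(followup_flags) != len(patient_profiles):
        raise ParameterError("followup_flags must align with patient_profiles")
    usable_donor = [d for d in donor_profiles if d.median >= depth_gate]
    if not usable_donor:
        log.warning("donor_match_trajectory: no donor profile passes the depth gate")
    points = []
    for prof, fup in zip(patient_profiles, followup_flags):
        comps = tuple(compare_strains(prof, d, depth_gate) for d in donor_profiles)
        verdicts = [c.verdict for c in comps]
        if "match" in verdicts:
            consensus = "match"
        elif "ambiguous" in verdicts:
            consensus = "ambiguous"
        else:
            consensus = "insufficient"
        points.append(TrajectoryPoint(prof.sample_id, bool(fup), consensus, comps))
    return points


@dataclasses.dataclass(frozen=True)
class StrainPattern:
    patient_id: str
    genome_id: str
    pattern: int

    @property
    def label(self) -> str:
        return PATTERN_LABELS[self.pattern]


def classify_pattern(
    verdicts: Sequence[str],
    followup: Sequence[bool],
    patient_id: str = "",
    genome_id: str = "",
) -> StrainPattern:
    """Collapse a post-transplant verdict series into one of six patterns.

    The trajectory must cover both the treatment period and follow-up. The
    decision is two-staged. Any ``match`` anywhere means the donor strain
    dominated at some point (patterns 1-3), resolved by the follow-up state:
    a follow-up match is persistent dominance (1); follow-up ambiguity means
    the strain community persisted but dominance was lost (3); follow-up
    insufficiency means colonization itself was temporary (2). Without any
    match, ambiguity anywhere means strains colonized from an unresolved
    source (patterns 4-5, split by whether ambiguity persists into
    follow-up); an all-insufficient series is no colonization (6).
    """
    verdicts = list(verdicts)
    followup = list(followup)
    if not verdicts:
        raise ParameterError("empty trajectory")
    if len(verdicts) != len(followup):
        raise ParameterError("verdicts and followup flags must align")
    bad = set(verdicts) - set(VERDICTS)
    if bad:
        raise ParameterError(f"unknown verdicts: {sorted(bad)}")
    if not any(followup) or all(followup):
        raise ParameterError("trajectory must cover both post-FMT and follow-up phases")
    fup = [v for v, f in zip(verdicts, followup) if f]
    fup_match = "match" in fup
    fup_amb = "ambiguous" in fup
    if "match" in verdicts:
        pattern = 1 if fup_match else (3 if fup_amb else 2)
    elif "ambiguous" in verdicts:
        pattern = 4 if fup_amb else 5
    else:
        pattern = 6
    return StrainPattern(patient_id, genome_id, pattern)


# ---------------------------------------------------------------------------
# SNP-haplotype post-processing (sample pooling and depth normalization)
# ---------------------------------------------------------------------------

#: Default mapping of trial phases onto the five pooled time bins used to
#: boost read depth for haplotype deconvolution. Antibiotics samples pool
#: with baseline (both precede the transplant).
DEFAULT_POOL_SCHEME = {
    "baseline": "baseline",
    "antibiotics": "baseline",
    "induction": "induction",
    "capsule": "capsule",
    "alternate_donor": "alternate_donor",
    "followup": "followup",
}


def pool_samples(
    counts: pd.DataFrame,
    bin_of: Mapping[str, str],
    days: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum per-sample count tables within time bins.

    ``counts`` is indexed by sample id (columns are arbitrary count columns,
    e.g. allele or depth tallies). Every sample must map to exactly one bin
    via ``bin_of``. Returns the pooled table (indexed by bin, in first-seen
    order) and a bin summary with the day range covered when ``days`` is
    given.
    """
    missing = [s for s in counts.index if s not in bin_of]
    if missing:
        raise ParameterError(f"samples outside all bins: {missing}")
    bins = pd.Series({s: bin_of[s] for s in counts.index}, name="bin")
    order = list(dict.fromkeys(bins[s] for s in counts.index))
    pooled = counts.groupby(bins).sum().loc[order]
    pooled.index.name = "bin"
    summary_rows = []
    for b in order:
        samples = [s for s in counts.index if bins[s] == b]
        row = {"bin": b, "n_samples": len(samples)}
        if days is not None:
            ds = [days[s] for s in samples]
            row["day_min"], row["day_max"] = min(ds), max(ds)
        summary_rows.append(row)
    return pooled, pd.DataFrame(summary_rows).set_index("bin")


def normalize_strain_frequencies(
    frequencies: pd.DataFrame,
    median_depth: pd.Series,
    coverage_gate: float = 50.0,
    min_bins: int = 2,
) -> pd.DataFrame | None:
    """Scale per-bin strain frequencies by the bin's median marker-gene depth.

    ``frequencies`` is bins x strains with per-bin sums <= 1; ``median_depth``
    gives the genome's median read depth per bin. Genomes whose median depth
    exceeds ``coverage_gate`` in fewer than ``min_bins`` bins are excluded
    (returns None). Within-bin frequency ratios are preserved by the scaling.
    """
    if (frequencies.to_numpy() < 0).any():
        raise ValidationError("strain frequencies must be non-negative")
    sums = frequencies.sum(axis=1)
    if (sums > 1 + 1e-6).any():
        raise ValidationError("per-bin strain frequencies must sum to <= 1")
    depth = median_depth.loc[frequencies.index]
    if int((depth > coverage_gate).sum()) < min_bins:
        log.info(
            "normalize_strain_frequencies: genome fails the coverage gate "
            "(> %s in >= %d bins); excluded", coverage_gate, min_bins
        )
        return None
    return frequencies.mul(depth, axis=0)
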