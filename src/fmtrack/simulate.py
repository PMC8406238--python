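"""Synthetic cohorts with planted ground truth for every analysis stage.

Three generator families emulate the data a longitudinal FMT trial produces,
at desk scale and with known truth, so the downstream modules can be tested
as parameter-recovery problems rather than against deposited sequencing data:

* :func:`simulate_cohort` — longitudinal donor/patient 16S-style count tables
  with planted Shared/Patient/Donor/Unknown provenance, an antibiotic
  perturbation, donor-feature transfer with persistent and temporary fates,
  and environmental invaders appearing after antibiotics.
* :func:`simulate_depth_profiles` — per-window read-depth profiles of a
  reference genome for samples containing mixtures of strains that share a
  core genome but carry distinct accessory segments (Poisson read depth).
* :func:`simulate_iga_fractions` — paired IgA-coated/uncoated fraction count
  tables from planted latent coating scores, multinomial at a configurable
  number of sorted cells per fraction (default 50,000).
  :func:`simulate_score_matrix` plants reliably coated/uncoated ASVs directly
  on the score scale for reliability and permutation-null studies.

Every generator is a pure function of its seed and parameters. Default
parameter values mirror the trial the package is designed around: 12
patients (7 transplant, 5 placebo), 2 donors, 4 transplant patients switched
to an alternate capsule donor mid-trial, weekly-ish sampling with a 7-day
antibiotic course before the day-0 colonoscopic transplant, ~18-week
follow-up, and 50,000 reads or sorted cells per sample.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import ParameterError, rng_from
from .iga import IgaScoreMatrix
from .strains import WindowDepthProfile
from .tables import CATEGORIES, FeatureTable, FunctionCategoryMap, SampleMetadata

#: Default per-phase sampling days (day 0 = colonoscopic transplant).
DEFAULT_SAMPLING_DAYS: dict[str, tuple[int, ...]] = {
    "baseline": (-28, -21, -14),
    "antibiotics": (-10, -7, -4),
    "induction": (0, 4, 7, 11, 14),
    "capsule": (21, 28, 35, 42, 49, 77, 84),
    "alternate_donor": (56, 63, 70),
    "followup": (112, 126),
}

DEFAULT_DONOR_DAYS = (-14, 0, 28, 84)


@dataclasses.dataclass(frozen=True)
class CohortTruth:
    """Planted ground truth of a simulated cohort.

    ``provenance`` maps each patient to a feature -> label series
    (shared/patient/donor/unknown) over that patient's observable universe,
    relative to the union of the patient's assigned donors. ``fate`` labels
    donor-provenance features persistent/temporary/none. ``donor_partition``
    (multi-donor patients only) labels donor features
    both_donors/induction_only/alternate_only.
    """

    provenance: dict[str, pd.Series]
    fate: dict[str, pd.Series]
    donor_partition: dict[str, pd.Series]
    seed: int
    params: dict

    def __post_init__(self) -> None:
        for patient, fates in self.fate.items():
            prov = self.provenance[patient]
            bad = fates[(fates != "none") & (prov[fates.index] != "donor")]
            if len(bad):
                raise ParameterError(
                    f"fate != none planted on non-donor features: {list(bad.index)}"
                )


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value!r}")


def simulate_cohort(
    n_patients: int = 12,
    n_donors: int = 2,
    n_features: int = 300,
    transfer_fraction: float = 0.6,
    persistence_fraction: float = 0.7,
    sampling_days: Mapping[str, Iterable[int]] | None = None,
    donor_sampling_days: Iterable[int] = DEFAULT_DONOR_DAYS,
    n_fmt: int | None = None,
    n_alternate_donor: int = 4,
    alt_transfer_fraction: float = 0.2,
    carriage_fraction: float = 0.55,
    lognorm_sigma: float = 1.0,
    read_depth: int = 50000,
    multinomial: bool = True,
    abx_suppression: float = 100.0,
    abx_fraction: float = 0.8,
    unknown_pool_fraction: float = 0.15,
    unknown_hazard: float = 0.05,
    seed: int = 0,
) -> tuple[FeatureTable, SampleMetadata, CohortTruth]:
    """Simulate a longitudinal FMT cohort with planted provenance and fates.

    Community model: each subject carries a random ``carriage_fraction`` of
    the feature pool with log-normal base abundances (sigma
    ``lognorm_sigma``). During the antibiotic course a random
    ``abx_fraction`` of a patient's features is suppressed
    ``abx_suppression``-fold. From day 0, a ``transfer_fraction`` of the
    induction donor's donor-only features colonizes transplant patients; of
    those, ``persistence_fraction`` persist through follow-up and the rest
    vanish after the treatment period (temporary colonizers). Patients
    switched to an alternate donor additionally acquire an
    ``alt_transfer_fraction`` of alternate-donor-only features during the
    alternate-donor phase. After antibiotics, features outside both patient
    and donor communities invade with a per-sample ``unknown_hazard``.
    Reads are multinomial at ``read_depth`` per sample; with
    ``multinomial=False`` expected counts are emitted directly (zero count
    noise; every active feature is present).
    """
    for name, val in [
        ("transfer_fraction", transfer_fraction),
        ("persistence_fraction", persistence_fraction),
        ("alt_transfer_fraction", alt_transfer_fraction),
        ("carriage_fraction", carriage_fraction),
        ("abx_fraction", abx_fraction),
        ("unknown_pool_fraction", unknown_pool_fraction),
        ("unknown_hazard", unknown_hazard),
    ]:
        _check_fraction(name, val)
    days = {k: tuple(v) for k, v in (sampling_days or DEFAULT_SAMPLING_DAYS).items()}
    n_treatment_days = sum(
        len(days.get(p, ())) for p in ("induction", "capsule", "alternate_donor")
    )
    if (
        len(days.get("baseline", ())) < 2
        or n_treatment_days < 3
        or len(days.get("followup", ())) < 1
    ):
        raise ParameterError(
            "day grid needs >=2 baseline, >=3 treatment, >=1 follow-up days"
        )
    if n_donors < 1 or n_patients < 1 or n_features < 1:
        raise ParameterError("cohort sizes must be positive")

    rng = rng_from(seed)
    features = [f"ASV{i:04d}" for i in range(n_features)]
    donors = [f"D{i + 1}" for i in range(n_donors)]
    if n_fmt is None:
        n_fmt = int(round(n_patients * 7 / 12))
    n_fmt = min(n_fmt, n_patients)
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    arms = {p: ("fmt" if i < n_fmt else "placebo") for i, p in enumerate(patients)}

    n_carried = max(1, int(round(carriage_fraction * n_features)))
    carriage: dict[str, set[str]] = {}
    base_abundance: dict[str, dict[str, float]] = {}
    for subject in donors + patients:
        carried = set(rng.choice(features, size=n_carried, replace=False))
        carriage[subject] = carried
        base_abundance[subject] = {}

    def abundance(subject: str, feature: str) -> float:
        table = base_abundance[subject]
        if feature not in table:
            table[feature] = float(rng.lognormal(mean=0.0, sigma=lognorm_sigma))
        return table[feature]

    # donor assignment: round-robin induction donor; the first
    # n_alternate_donor transplant patients also get the next donor as an
    # alternate capsule donor (only meaningful with >= 2 donors).
    assigned: dict[str, tuple[str, ...]] = {}
    fmt_patients = [p for p in patients if arms[p] == "fmt"]
    for i, p in enumerate(fmt_patients):
        induction = donors[i % n_donors]
        if n_donors >= 2 and i < n_alternate_donor:
            alternate = donors[(i + 1) % n_donors]
            assigned[p] = (induction, alternate)
        else:
            assigned[p] = (induction,)
    for p in patients:
        assigned.setdefault(p, ())

    treatment_days = sorted(
        set(days.get("induction", ()) + days.get("capsule", ()) + days.get("alternate_donor", ()))
    )
    last_treatment_day = max(treatment_days)
    alt_start = min(days["alternate_donor"]) if days.get("alternate_donor") else None

    # plant transfers, fates, unknown invaders, and abx suppression
    transferred: dict[str, dict[str, str]] = {}      # patient -> feature -> fate
    alt_transferred: dict[str, set[str]] = {}
    unknown_sets: dict[str, dict[str, int]] = {}     # patient -> feature -> first day
    suppressed: dict[str, set[str]] = {}
    n_unknown_pool = int(round(unknown_pool_fraction * n_features))
    for p in patients:
        own = carriage[p]
        donor_ids = assigned[p]
        d_ind = carriage[donor_ids[0]] if donor_ids else set()
        d_all = set().union(*(carriage[d] for d in donor_ids)) if donor_ids else set()
        fate: dict[str, str] = {}
        if arms[p] == "fmt" and donor_ids:
            candidates = sorted(d_ind - own)
            n_tr = int(round(transfer_fraction * len(candidates)))
            chosen = list(rng.choice(candidates, size=n_tr, replace=False)) if n_tr else []
            n_persist = int(round(persistence_fraction * len(chosen)))
            for j, f in enumerate(chosen):
                fate[f] = "persistent" if j < n_persist else "temporary"
            if len(donor_ids) >= 2 and alt_start is not None:
                alt_candidates = sorted(carriage[donor_ids[1]] - own - d_ind)
                # the capsule-only alternate-donor route engrafts at a reduced
                # rate; scaling by transfer_fraction keeps zero transfer exact
                n_alt = int(round(alt_transfer_fraction * transfer_fraction
                                  * len(alt_candidates)))
                alt_chosen = (
                    list(rng.choice(alt_candidates, size=n_alt, replace=False)) if n_alt else []
                )
                alt_transferred[p] = set(alt_chosen)
                for f in alt_chosen:
                    fate[f] = "persistent"
        transferred[p] = fate
        alt_transferred.setdefault(p, set())
        pool = sorted(set(features) - own - d_all)
        n_pool = min(n_unknown_pool, len(pool))
        unknown_candidates = (
            list(rng.choice(pool, size=n_pool, replace=False)) if n_pool else []
        )
        # per-sample colonization hazard after antibiotics; once in, stays in
        arrivals: dict[str, int] = {}
        post_days = sorted(d for d in treatment_days + list(days["followup"]))
        for f in unknown_candidates:
            for d in post_days:
                if rng.random() < unknown_hazard:
                    arrivals[f] = d
                    break
        unknown_sets[p] = arrivals
        n_sup = int(round(abx_fraction * len(own)))
        suppressed[p] = set(rng.choice(sorted(own), size=n_sup, replace=False)) if n_sup else set()

    # assemble the sample grid
    meta_rows = []
    sample_plan: list[tuple[str, str, int, str]] = []  # sample, subject, day, phase

    def day_phase(day: int) -> str:
        for phase in ("baseline", "antibiotics", "induction", "capsule",
                      "alternate_donor", "followup"):
            if day in days.get(phase, ()):
                return phase
        raise ParameterError(f"day {day} not on the sampling grid")

    for d in donors:
        for day in sorted(donor_sampling_days):
            phase = "baseline" if day < 0 else ("induction" if day == 0 else "capsule")
            sid = f"{d}.d{day}"
            sample_plan.append((sid, d, day, phase))
            meta_rows.append((sid, d, "donor", "donor", day, phase, ()))
    for p in patients:
        multi = len(assigned[p]) >= 2
        for phase in ("baseline", "antibiotics", "induction", "capsule",
                      "alternate_donor", "followup"):
            for day in days.get(phase, ()):
                eff_phase = phase
                if phase == "alternate_donor" and not multi:
                    eff_phase = "capsule"
                sid = f"{p}.d{day}"
                sample_plan.append((sid, p, day, eff_phase))
                meta_rows.append(
                    (sid, p, "patient", arms[p], day, eff_phase, assigned[p])
                )

    # realize counts
    counts = np.zeros((len(sample_plan), n_features), dtype=float)
    feat_index = {f: i for i, f in enumerate(features)}
    for row, (sid, subject, day, phase) in enumerate(sample_plan):
        weights: dict[str, float] = {}
        if subject in donors:
            for f in carriage[subject]:
                weights[f] = abundance(subject, f)
        else:
            for f in carriage[subject]:
                w = abundance(subject, f)
                if phase == "antibiotics" and f in suppressed[subject]:
                    w /= abx_suppression
                weights[f] = w
            if day >= 0:
                for f, fate in transferred[subject].items():
                    if f in alt_transferred[subject]:
                        active = alt_start is not None and day >= alt_start
                    elif fate == "persistent":
                        active = True
                    else:  # temporary: gone before follow-up
                        active = day <= last_treatment_day
                    if active:
                        weights[f] = abundance(subject, f)
                for f, arrival in unknown_sets[subject].items():
                    if day >= arrival:
                        weights[f] = abundance(subject, f)
        total = sum(weights.values())
        rel = np.zeros(n_features)
        for f, w in weights.items():
            rel[feat_index[f]] = w / total
        if multinomial:
            counts[row] = rng.multinomial(read_depth, rel)
        else:
            expected = rel * read_depth
            active_idx = [feat_index[f] for f in weights]
            expected[active_idx] = np.maximum(expected[active_idx], 1.0)
            counts[row] = expected

    table = FeatureTable(
        pd.DataFrame(counts, index=[s[0] for s in sample_plan], columns=features),
        kind="counts",
    )
    meta = SampleMetadata(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "subject_id", "role", "arm", "day", "phase",
                     "assigned_donor_ids"],
        ).set_index("sample_id")
    )

    # planted truth (relative to the union of assigned donors)
    provenance: dict[str, pd.Series] = {}
    fate_truth: dict[str, pd.Series] = {}
    partition_truth: dict[str, pd.Series] = {}
    for p in patients:
        own = carriage[p]
        donor_ids = assigned[p]
        d_all = set().union(*(carriage[d] for d in donor_ids)) if donor_ids else set()
        observed_unknown = set(unknown_sets[p])
        universe = sorted(own | d_all | observed_unknown)
        labels = {}
        for f in universe:
            if f in own and f in d_all:
                labels[f] = "shared"
            elif f in own:
                labels[f] = "patient"
            elif f in d_all:
                labels[f] = "donor"
            else:
                labels[f] = "unknown"
        prov = pd.Series(labels, name="provenance")
        provenance[p] = prov
        fates = pd.Series("none", index=prov.index, name="fate")
        for f, fate in transferred[p].items():
            fates[f] = fate
        fate_truth[p] = fates
        if len(donor_ids) >= 2:
            d_ind, d_alt = carriage[donor_ids[0]], carriage[donor_ids[1]]
            feats = sorted((d_ind | d_alt) - own)
            partition_truth[p] = pd.Series(
                [
                    "both_donors" if f in d_ind and f in d_alt
                    else ("induction_only" if f in d_ind else "alternate_only")
                    for f in feats
                ],
                index=feats,
                name="donor_partition",
            )

    truth = CohortTruth(
        provenance=provenance,
        fate=fate_truth,
        donor_partition=partition_truth,
        seed=seed if isinstance(seed, int) else -1,
        params={
            "n_patients": n_patients,
            "n_donors": n_donors,
            "n_features": n_features,
            "n_fmt": n_fmt,
            "transfer_fraction": transfer_fraction,
            "persistence_fraction": persistence_fraction,
            "read_depth": read_depth,
            "multinomial": multinomial,
        },
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# Window-depth profiles
# ---------------------------------------------------------------------------


def simulate_depth_profiles(
    genome_length: int = 100_000,
    window: int = 1000,
    core_fraction: float = 0.8,
    strain_accessory_sets: Mapping[str, Iterable[int]] | None = None,
    mixtures: Mapping[str, Mapping[str, float]] | None = None,
    mean_depth: float = 20.0,
    seed: int = 0,
    genome_id: str = "genome",
) -> dict[str, WindowDepthProfile]:
    """Poisson window-depth profiles for samples containing strain mixtures.

    The genome is tiled into windows (trailing window shorter than half the
    window size dropped, as in :func:`fmtrack.strains.window_depths`). The
    first ``core_fraction`` of windows is the core genome carried by every
    strain; each strain additionally carries its accessory windows, which
    must be disjoint across strains and lie outside the core. For a sample
    with strain weights w, the depth of window i is
    Poisson(mean_depth * total weight of strains carrying i); windows carried
    by no strain in the mixture have depth 0.
    """
    _check_fraction("core_fraction", core_fraction)
    if mean_depth < 0:
        raise ParameterError("mean_depth must be >= 0")
    n_full, tail = divmod(genome_length, window)
    n_windows = n_full + (1 if tail >= window / 2 else 0)
    if n_windows < 1:
        raise ParameterError("genome shorter than half a window")
    n_core = int(round(core_fraction * n_windows))
    strain_accessory_sets = {
        s: frozenset(int(i) for i in v) for s, v in (strain_accessory_sets or {}).items()
    }
    seen: set[int] = set()
    for strain, acc in sorted(strain_accessory_sets.items()):
        for i in acc:
            if i < n_core or i >= n_windows:
                raise ParameterError(
                    f"accessory window {i} of strain {strain!r} outside the "
                    f"non-core genome [{n_core}, {n_windows})"
                )
            if i in seen:
                raise ParameterError(f"accessory window {i} assigned to two strains")
            seen.add(i)
    mixtures = mixtures or {"sample": {s: 1.0 for s in strain_accessory_sets} or {"strain": 1.0}}
    rng = rng_from(seed)
    profiles: dict[str, WindowDepthProfile] = {}
    for sample_id, weights in mixtures.items():
        carrier = np.zeros(n_windows)
        total = sum(weights.values())
        carrier[:n_core] = total
        for strain, w in weights.items():
            acc = strain_accessory_sets.get(strain, frozenset())
            for i in acc:
                carrier[i] += w
        depths = rng.poisson(mean_depth * carrier).astype(float)
        profiles[sample_id] = WindowDepthProfile(genome_id, sample_id, depths, window)
    return profiles


# ---------------------------------------------------------------------------
# IgA fraction counts and score matrices
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class IgaTruth:
    latent_scores: pd.DataFrame   # samples x ASVs
    base_abundance: pd.Series     # per-ASV community relative abundance
    coated_ids: tuple[str, ...]
    uncoated_ids: tuple[str, ...]


def simulate_iga_fractions(
    n_samples: int = 30,
    n_asvs: int = 300,
    latent_scores: np.ndarray | pd.DataFrame | None = None,
    cells_per_fraction: int = 50000,
    base_sigma: float = 1.0,
    host_effect_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, IgaTruth]:
    """Paired coated/uncoated fraction counts from planted latent scores.

    Each ASV has a log-normal community abundance b_i shared across samples.
    Given latent score s, the coated fraction samples cells multinomially
    with probabilities proportional to b_i * 2^(s/2) and the uncoated
    fraction proportional to b_i * 2^(-s/2), so the log2 coated/uncoated
    relative-abundance ratio of an ASV approaches its latent score as cell
    counts grow. ``host_effect_sd`` adds an independent N(0, sd) host-by-ASV
    score component.
    """
    if cells_per_fraction <= 0:
        raise ParameterError("cells_per_fraction must be positive")
    rng = rng_from(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    asvs = [f"ASV{i:04d}" for i in range(n_asvs)]
    if latent_scores is None:
        scores = np.zeros((n_samples, n_asvs))
    else:
        scores = np.asarray(
            latent_scores.values if isinstance(latent_scores, pd.DataFrame) else latent_scores,
            dtype=float,
        )
        if scores.ndim == 1:
            scores = np.broadcast_to(scores, (n_samples, n_asvs)).copy()
        if scores.shape != (n_samples, n_asvs):
            raise ParameterError("latent_scores must be (n_samples, n_asvs) or (n_asvs,)")
    if not np.isfinite(scores).all():
        raise ParameterError("latent scores must be finite")
    if host_effect_sd > 0:
        scores = scores + rng.normal(0.0, host_effect_sd, size=scores.shape)
    base = rng.lognormal(mean=0.0, sigma=base_sigma, size=n_asvs)
    coated = np.zeros((n_samples, n_asvs))
    uncoated = np.zeros((n_samples, n_asvs))
    for i in range(n_samples):
        wc = base * np.exp2(scores[i] / 2.0)
        wu = base * np.exp2(-scores[i] / 2.0)
        coated[i] = rng.multinomial(cells_per_fraction, wc / wc.sum())
        uncoated[i] = rng.multinomial(cells_per_fraction, wu / wu.sum())
    mean_scores = scores.mean(axis=0)
    truth = IgaTruth(
        latent_scores=pd.DataFrame(scores, index=samples, columns=asvs),
        base_abundance=pd.Series(base / base.sum(), index=asvs),
        coated_ids=tuple(a for a, s in zip(asvs, mean_scores) if s > 0),
        uncoated_ids=tuple(a for a, s in zip(asvs, mean_scores) if s < 0),
    )
    return (
        FeatureTable(pd.DataFrame(coated, index=samples, columns=asvs)),
        FeatureTable(pd.DataFrame(uncoated, index=samples, columns=asvs)),
        truth,
    )


def simulate_score_matrix(
    n_samples: int = 30,
    n_asvs: int = 300,
    n_coated: int = 28,
    n_uncoated: int = 14,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[IgaScoreMatrix, dict[str, tuple[str, ...]]]:
    """Score matrix with planted reliably coated/uncoated ASVs.

    Coated ASVs score N(+effect, noise_sd) across samples, uncoated
    N(-effect, noise_sd), all others N(0, noise_sd). The planted set sizes
    default to the 28 coated / 14 uncoated ASVs a full-cohort analysis
    reports.
    """
    if n_coated + n_uncoated > n_asvs:
        raise ParameterError("planted sets exceed the number of ASVs")
    rng = rng_from(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    asvs = [f"ASV{i:04d}" for i in range(n_asvs)]
    mu = np.zeros(n_asvs)
    mu[:n_coated] = effect
    mu[n_coated:n_coated + n_uncoated] = -effect
    scores = rng.normal(loc=mu, scale=noise_sd, size=(n_samples, n_asvs))
    matrix = IgaScoreMatrix(pd.DataFrame(scores, index=samples, columns=asvs))
    planted = {
        "coated": tuple(asvs[:n_coated]),
        "uncoated": tuple(asvs[n_coated:n_coated + n_uncoated]),
        "null": tuple(asvs[n_coated + n_uncoated:]),
    }
    return matrix, planted


# ---------------------------------------------------------------------------
# Function profiles (gene families) for end-to-end runs
# ---------------------------------------------------------------------------

RESISTANCE_CLASSES = ("quinolone", "tetracycline", "aminoglycoside")


def simulate_function_profiles(
    n_families: int = 100,
    quinolone_boost: float = 10.0,
    post_abx_days: int = 10,
    seed: int = 0,
    **cohort_kwargs,
) -> tuple[FeatureTable, SampleMetadata, FunctionCategoryMap, CohortTruth]:
    """Gene-family abundance tables with categories and a planted
    quinolone-resistance response.

    Reuses the cohort generator with gene families as features, assigns
    families round-robin to the five functional categories (antimicrobial
    resistance families cycle through quinolone/tetracycline/aminoglycoside
    classes), and multiplies quinolone-class abundances by
    ``quinolone_boost`` in samples collected within ``post_abx_days`` days
    after the end of the antibiotic course, emulating selection by a
    quinolone antibiotic.
    """
    table, meta, truth = simulate_cohort(
        n_features=n_families, seed=seed, **cohort_kwargs
    )
    families = table.feature_ids
    category = {f: CATEGORIES[i % len(CATEGORIES)] for i, f in enumerate(families)}
    amr = [f for f in families if category[f] == "antimicrobial_resistance"]
    resistance_class = {
        f: RESISTANCE_CLASSES[i % len(RESISTANCE_CLASSES)] for i, f in enumerate(amr)
    }
    cmap = FunctionCategoryMap(category=category, resistance_class=resistance_class)
    quinolone = set(cmap.resistance_families("quinolone"))
    data = table.data.copy()
    abx_days = meta.frame.loc[meta.frame["phase"] == "antibiotics", "day"]
    if len(abx_days) and quinolone:
        abx_end = int(abx_days.max())
        for sid in data.index:
            day = meta.day_of(sid)
            if meta.frame.loc[sid, "role"] == "patient" and abx_end < day <= abx_end + post_abx_days:
                data.loc[sid, sorted(quinolone)] *= quinolone_boost
    return FeatureTable(data, kind="counts"), meta, cmap, truth
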