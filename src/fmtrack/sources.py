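"""Provenance assignment and colonization persistence for cohort features.

For every patient, each feature (ASV, metagenomic species, or gene family)
ever observed in that patient's samples or in the assigned donor's samples is
assigned exactly one source:

* ``Shared``  — present in any patient baseline sample AND any donor sample;
* ``Patient`` — present at baseline only;
* ``Donor``   — present in the donor only (candidates for transfer);
* ``Unknown`` — observed only after transplant in the patient, absent from
  baseline and donor (environmental colonizers or endogenous features below
  the detection limit).

"Baseline" means samples in the baseline phase, before antibiotics; samples
taken during the antibiotic course do not count toward the baseline community.
Donor scope is the assigned induction donor's samples; the alternate donor of
multi-donor patients enters only through :func:`partition_multi_donor`.

Donor-source features are then classified by colonization fate: ``persistent``
(present in at least three samples on or after transplant day 0 and in at
least one follow-up sample), ``temporary`` (at least three post-transplant
presences but absent from all follow-up samples), or ``none``.

Source trajectories are summarized per sample by occurrence-weighted
fractions: every present feature counts equally, regardless of abundance,
which suppresses the signal of abundant features whose source may be
misassigned when distinct strains share a marker sequence.
"""
from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd

from ._util import ConfigurationError, ParameterError, log
from .tables import FeatureTable, SampleMetadata

SOURCES = ("Shared", "Patient", "Donor", "Unknown")
FATES = ("persistent", "temporary", "none")
DONOR_PARTITIONS = ("both_donors", "induction_only", "alternate_only")


@dataclasses.dataclass(frozen=True)
class SourceAssignment:
    """Per-patient map from feature id to source category."""

    patient_id: str
    source: pd.Series  # feature_id -> source label
    donor_ids: tuple[str, ...]

    def features_of(self, source: str) -> list[str]:
        if source not in SOURCES:
            raise ParameterError(f"unknown source {source!r}")
        return list(self.source.index[self.source == source])


def assign_sources(
    table: FeatureTable,
    metadata: SampleMetadata,
    patient_id: str,
    min_count: int = 1,
    donor_scope: str = "induction",
) -> SourceAssignment:
    """Assign every observed feature a provenance for one patient.

    ``donor_scope`` is ``"induction"`` (default: samples of the induction
    donor only) or ``"union"`` (samples of all assigned donors).
    """
    metadata.check_covers(table)
    patient_samples = metadata.samples_of(patient_id)
    if not patient_samples:
        raise ConfigurationError(f"no samples for patient {patient_id!r}")
    baseline = metadata.samples_of(patient_id, phases=("baseline",))
    if not baseline:
        raise ConfigurationError(f"patient {patient_id!r} has no baseline samples")
    donors = metadata.assigned_donors(patient_id)
    if donor_scope == "induction":
        donor_ids = donors[:1]
    elif donor_scope == "union":
        donor_ids = donors
    else:
        raise ParameterError(f"unknown donor_scope {donor_scope!r}")
    donor_samples = [s for d in donor_ids for s in metadata.samples_of(d)]

    presence = table.presence(min_count)
    in_patient = presence.loc[patient_samples].any(axis=0)
    in_baseline = presence.loc[baseline].any(axis=0)
    if donor_samples:
        in_donor = presence.loc[donor_samples].any(axis=0)
    else:
        in_donor = pd.Series(False, index=presence.columns)

    universe = in_patient | in_donor
    feats = presence.columns[universe]
    base = in_baseline[feats].to_numpy()
    dnr = in_donor[feats].to_numpy()
    labels = np.where(
        base & dnr, "Shared", np.where(base, "Patient", np.where(dnr, "Donor", "Unknown"))
    )
    return SourceAssignment(
        patient_id=patient_id,
        source=pd.Series(labels, index=feats, name="source"),
        donor_ids=donor_ids,
    )


def source_fractions(
    assignment: SourceAssignment,
    table: FeatureTable,
    metadata: SampleMetadata,
    min_count: int = 1,
) -> pd.DataFrame:
    """Occurrence-weighted source fractions per patient sample.

    For each sample, the fraction attributed to source s is the number of
    present features assigned to s divided by the total number of present
    features; fractions sum to 1. Samples with zero present features are
    omitted with a notice. Rows are ordered by collection day.
    """
    patient_samples = metadata.samples_of(assignment.patient_id)
    days = metadata.frame.loc[patient_samples, "day"]
    ordered = list(days.sort_values(kind="stable").index)
    presence = table.select_samples(ordered).presence(min_count)
    # restrict to the assigned universe; features outside it are unobserved anyway
    known = [f for f in presence.columns if f in assignment.source.index]
    presence = presence[known]
    src = assignment.source[known]
    rows = []
    for sample in ordered:
        mask = presence.loc[sample].to_numpy()
        n_present = int(mask.sum())
        if n_present == 0:
            log.info("source_fractions: sample %r has no present features; omitted", sample)
            continue
        counts = src[mask].value_counts()
        row = {"sample_id": sample, "day": int(days[sample]), "n_present": n_present}
        for s in SOURCES:
            row[s] = counts.get(s, 0) / n_present
        rows.append(row)
    return pd.DataFrame(rows)


def _colonization_status(n_post: int, in_followup: bool) -> str:
    if n_post >= 3 and in_followup:
        return "persistent"
    if n_post >= 3:
        return "temporary"
    return "none"


def classify_colonization(
    assignment: SourceAssignment,
    table: FeatureTable,
    metadata: SampleMetadata,
    min_count: int = 1,
) -> pd.DataFrame:
    """Persistence calls for every Donor-source feature of one patient.

    ``n_post`` counts distinct samples with day >= 0 (follow-up included) in
    which the feature is present; ``in_followup`` is presence in any
    follow-up-phase sample. Without follow-up samples status is
    undeterminable: an empty frame is returned with a notice.
    """
    patient = assignment.patient_id
    post_samples = [
        s for s in metadata.samples_of(patient) if metadata.day_of(s) >= 0
    ]
    followup_samples = metadata.samples_of(patient, phases=("followup",))
    donor_feats = assignment.features_of("Donor")
    if not followup_samples:
        log.warning(
            "classify_colonization: patient %r has no follow-up samples; "
            "calls suppressed", patient
        )
        return pd.DataFrame(
            columns=["feature_id", "n_post", "in_followup", "status"]
        ).set_index("feature_id")
    presence = table.presence(min_count)
    n_post = presence.loc[post_samples, donor_feats].sum(axis=0)
    in_fup = presence.loc[followup_samples, donor_feats].any(axis=0)
    status = [
        _colonization_status(int(n_post[f]), bool(in_fup[f])) for f in donor_feats
    ]
    out = pd.DataFrame(
        {
            "n_post": n_post.astype(int),
            "in_followup": in_fup,
            "status": status,
        },
        index=pd.Index(donor_feats, name="feature_id"),
    )
    return out


def partition_multi_donor(
    table: FeatureTable,
    metadata: SampleMetadata,
    patient_id: str,
    min_count: int = 1,
) -> pd.Series:
    """Label donor-derived features of a two-donor patient by donor origin.

    Considers features absent from the patient's baseline but present in
    either assigned donor (the donor set under union scope) and labels each
    ``both_donors``, ``induction_only``, or ``alternate_only`` by presence in
    the respective donor's samples.
    """
    donors = metadata.assigned_donors(patient_id)
    if len(donors) < 2:
        raise ParameterError(
            f"patient {patient_id!r} has {len(donors)} assigned donor(s); "
            "partition_multi_donor requires two"
        )
    induction, alternate = donors[0], donors[1]
    baseline = metadata.samples_of(patient_id, phases=("baseline",))
    if not baseline:
        raise ConfigurationError(f"patient {patient_id!r} has no baseline samples")
    presence = table.presence(min_count)
    in_base = presence.loc[baseline].any(axis=0)
    in_ind = presence.loc[metadata.samples_of(induction)].any(axis=0)
    in_alt = presence.loc[metadata.samples_of(alternate)].any(axis=0)
    donor_feats = presence.columns[(in_ind | in_alt) & ~in_base]
    labels = np.where(
        in_ind[donor_feats] & in_alt[donor_feats],
        "both_donors",
        np.where(in_ind[donor_feats], "induction_only", "alternate_only"),
    )
    return pd.Series(labels, index=donor_feats, name="donor_partition")
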