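"""Tabular containers and plain-text I/O shared by every analysis stage.

The central object is :class:`FeatureTable`, a samples x features matrix of
non-negative counts (or per-sample relative abundances) with unique axis
labels. :class:`SampleMetadata` carries the per-sample trial context (subject,
donor/patient role, treatment arm, day relative to transplant, trial phase,
assigned donors) that drives source assignment and windowed statistics.
:class:`FunctionCategoryMap` maps gene families to functional categories
(glycoside hydrolases, mucin degradation, butyrate biosynthesis, antimicrobial
resistance, virulence factors).

On-disk convention: tab-separated tables with features as rows and samples as
columns (the common orientation of ASV/species tables), metadata as a TSV with
one row per sample, and the category map as JSON.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    ValidationError,
    log,
)

#: Trial phases in chronological order. ``alternate_donor`` only occurs for
#: patients whose capsules were switched to a second donor mid-trial.
PHASES = (
    "baseline",
    "antibiotics",
    "induction",
    "capsule",
    "alternate_donor",
    "followup",
)

ROLES = ("donor", "patient")
ARMS = ("fmt", "placebo", "donor")

CATEGORIES = (
    "glycoside_hydrolase",
    "mucin_degradation",
    "butyrate_biosynthesis",
    "antimicrobial_resistance",
    "virulence_factor",
)


@dataclasses.dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix of counts or relative abundances.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and feature ids as columns.
    kind:
        ``"counts"`` for raw (possibly real-valued) non-negative counts or
        abundances, ``"relative"`` for per-sample compositions summing to 1.
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValidationError(f"unknown table kind {self.kind!r}")
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dup}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("feature table body must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing cell at sample {df.index[r]!r}, feature {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at sample {df.index[r]!r}, feature {df.columns[c]!r}"
            )
        if self.kind == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                raise ValidationError(
                    f"relative table rows must sum to 1; offending sample "
                    f"{df.index[np.argmax(bad)]!r} sums to {sums[bad][0]!r}"
                )

    # -- axes ---------------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    # -- transforms ---------------------------------------------------------
    def to_relative(self) -> "FeatureTable":
        """Convert to per-sample relative abundances.

        Each row is divided by its total over all features in the table (no
        rarefaction). A sample with zero total carries no information and is
        rejected. Idempotent: applying to an already-relative table returns an
        equal table.
        """
        totals = self.data.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0][0]
            raise DegenerateInputError(f"sample {bad!r} has zero total count")
        return FeatureTable(self.data.div(totals, axis=0), kind="relative")

    def presence(self, min_count: int = 1) -> pd.DataFrame:
        """Boolean presence matrix: count >= ``min_count``.

        Only meaningful for counts-kind tables; the default threshold of one
        read matches a literal "observed in any sample" rule and can be raised
        to guard against cross-sample bleed.
        """
        if self.kind != "counts":
            raise ValidationError("presence is defined on counts tables")
        if not isinstance(min_count, (int, np.integer)) or min_count < 1:
            raise ParameterError(f"min_count must be a positive integer, got {min_count!r}")
        return self.data >= min_count

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)}")
        return FeatureTable(self.data.loc[ids], kind=self.kind)


def read_feature_table(path, orientation: str = "features") -> FeatureTable:
    """Read a TSV feature table.

    ``orientation="features"`` (canonical on disk) expects features as rows and
    samples as columns; ``orientation="samples"`` the transpose. Returns a
    counts-kind table. Duplicated ids, missing cells, or non-numeric cells are
    errors.
    """
    if orientation not in ("features", "samples"):
        raise ParameterError(f"orientation must be 'features' or 'samples', got {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        raise ValidationError(
            f"duplicate row ids in {path}: {raw.index[raw.index.duplicated()].tolist()}"
        )
    if raw.columns.has_duplicates:
        raise ValidationError(
            f"duplicate column ids in {path}: "
            f"{raw.columns[raw.columns.duplicated()].tolist()}"
        )
    body = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise ValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r} in {path}"
            )
        if converted.isna().any():
            row = raw.index[converted.isna()][0]
            raise ValidationError(f"missing cell at row {row!r}, column {col!r} in {path}")
        # numpy's parser is correctly rounded; pd.to_numeric can be 1 ulp off
        body[col] = raw[col].to_numpy(dtype=float)
    if orientation == "features":
        body = body.T
    body.index.name = "sample_id"
    body.columns.name = None
    return FeatureTable(body, kind="counts")


def write_feature_table(table: FeatureTable, path, orientation: str = "features") -> None:
    """Write a feature table as TSV (features as rows by default).

    Values are written with full float precision so a write/read round trip
    reproduces them bit-exactly.
    """
    if orientation not in ("features", "samples"):
        raise ParameterError(f"orientation must be 'features' or 'samples', got {orientation!r}")
    df = table.data.T if orientation == "features" else table.data
    out = df.copy()
    out.index.name = "feature_id" if orientation == "features" else "sample_id"
    # %.17g preserves every float64 exactly across the text round trip
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ("subject_id", "role", "arm", "day", "phase", "assigned_donor_ids")


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Per-sample trial context.

    ``frame`` is indexed by sample id with columns ``subject_id``, ``role``
    (donor/patient), ``arm`` (fmt/placebo/donor), ``day`` (integer days
    relative to the colonoscopic transplant on day 0), ``phase`` (trial phase)
    and ``assigned_donor_ids`` (ordered tuple of donor subject ids; induction
    donor first, alternate donor second; empty for donors and placebo
    patients).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = set(_META_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        bad_role = set(df["role"]) - set(ROLES)
        if bad_role:
            raise ValidationError(f"unknown roles: {sorted(bad_role)}")
        bad_arm = set(df["arm"]) - set(ARMS)
        if bad_arm:
            raise ValidationError(f"unknown arms: {sorted(bad_arm)}")
        bad_phase = set(df["phase"]) - set(PHASES)
        if bad_phase:
            raise ValidationError(f"unknown phases: {sorted(bad_phase)}")
        donors = df["role"] == "donor"
        if (df.loc[donors, "arm"] != "donor").any():
            raise ValidationError("samples with role=donor must have arm=donor")
        if (df.loc[~donors, "arm"] == "donor").any():
            raise ValidationError("arm=donor reserved for donor subjects")
        for sid, val in df["assigned_donor_ids"].items():
            if not isinstance(val, tuple):
                raise ValidationError(
                    f"assigned_donor_ids must be tuples; sample {sid!r} has {type(val)}"
                )
        # chronology: baseline precedes antibiotics; follow-up is last
        for subject, sub in df.groupby("subject_id"):
            abx = sub.loc[sub["phase"] == "antibiotics", "day"]
            base = sub.loc[sub["phase"] == "baseline", "day"]
            if len(abx) and len(base) and base.max() >= abx.min():
                raise ValidationError(
                    f"subject {subject!r}: baseline samples must precede antibiotics"
                )
            fup = sub.loc[sub["phase"] == "followup", "day"]
            treat = sub.loc[sub["phase"].isin(("induction", "capsule", "alternate_donor")), "day"]
            if len(fup) and len(treat) and fup.min() <= treat.max():
                raise ValidationError(
                    f"subject {subject!r}: follow-up samples must come after treatment"
                )

    # -- selectors ----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def check_covers(self, table: FeatureTable) -> None:
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise ConfigurationError(
                f"feature-table samples missing from metadata: {sorted(missing)}"
            )

    def samples_of(self, subject_id: str, phases: Iterable[str] | None = None) -> list[str]:
        df = self.frame
        mask = df["subject_id"] == subject_id
        if phases is not None:
            mask &= df["phase"].isin(list(phases))
        return list(df.index[mask])

    def subjects(self, role: str | None = None) -> list[str]:
        df = self.frame
        if role is not None:
            df = df[df["role"] == role]
        return list(dict.fromkeys(df["subject_id"]))

    def assigned_donors(self, patient_id: str) -> tuple[str, ...]:
        rows = self.frame[self.frame["subject_id"] == patient_id]
        if rows.empty:
            raise ConfigurationError(f"unknown subject {patient_id!r}")
        donors = rows["assigned_donor_ids"].iloc[0]
        for val in rows["assigned_donor_ids"]:
            if val != donors:
                raise ValidationError(
                    f"inconsistent assigned_donor_ids within subject {patient_id!r}"
                )
        return donors

    def day_of(self, sample_id: str) -> int:
        return int(self.frame.loc[sample_id, "day"])

    def phase_of(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "phase"])


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df["day"] = df["day"].astype(int)
    df["assigned_donor_ids"] = [
        tuple(x.split(",")) if isinstance(x, str) and x else () for x in df["assigned_donor_ids"]
    ]
    df.index.name = "sample_id"
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    df["assigned_donor_ids"] = [",".join(x) for x in df["assigned_donor_ids"]]
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Function category map
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FunctionCategoryMap:
    """Maps each gene family to exactly one functional category.

    ``resistance_class`` (e.g. quinolone, tetracycline, aminoglycoside) may
    only be set for families in the antimicrobial_resistance category.
    """

    category: Mapping[str, str]
    resistance_class: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.category.values()) - set(CATEGORIES)
        if bad:
            raise ValidationError(f"unknown function categories: {sorted(bad)}")
        for fam, cls in self.resistance_class.items():
            if self.category.get(fam) != "antimicrobial_resistance":
                raise ValidationError(
                    f"resistance_class set for {fam!r} which is not an "
                    "antimicrobial_resistance family"
                )

    def families_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ParameterError(f"unknown category {category!r}")
        return sorted(f for f, c in self.category.items() if c == category)

    def resistance_families(self, resistance_class: str) -> list[str]:
        return sorted(f for f, c in self.resistance_class.items() if c == resistance_class)


def read_category_map(path) -> FunctionCategoryMap:
    with open(path) as fh:
        obj = json.load(fh)
    return FunctionCategoryMap(
        category=dict(obj["category"]),
        resistance_class=dict(obj.get("resistance_class", {})),
    )


def write_category_map(cmap: FunctionCategoryMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "category": dict(sorted(cmap.category.items())),
                "resistance_class": dict(sorted(cmap.resistance_class.items())),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
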