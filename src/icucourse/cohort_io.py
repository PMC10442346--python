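"""Data model and file I/O for heterogeneous ICU clinical records.

The cohort is stored long-format: one row per observation of one variable
for one patient, either static (no timestamp) or dynamic (hours since ICU
admission).  A separate dictionary file types every variable, and an
outcomes file gives each patient a 7-category ordinal functional-outcome
score (the 8-point GOSE with categories 2 and 3 merged).

All three files are tab-separated UTF-8 with fixed headers; missing values
are written as the literal token ``NA``.  Reading and writing round-trip
bit-exactly after canonical sorting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

MISSING_MARKER = "NA"

#: The 9 variable category groups (counts per group differ by cohort).
VARIABLE_GROUPS = (
    "demographics",
    "history",
    "injury",
    "emergency_care",
    "imaging",
    "labs",
    "medications",
    "vitals_assessments",
    "surgery_neuromonitoring",
)

#: Ordinal outcome labels: 7 categories, GOSE 2 and 3 merged.
OUTCOME_LABELS = ("1", "2_or_3", "4", "5", "6", "7", "8")
N_OUTCOME_CATEGORIES = 7
N_THRESHOLDS = 6  # cuts k=1..6, "outcome above the k-th cut"


class TemporalClass(str, Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"


class ValueClass(str, Enum):
    NUMERIC = "numeric"
    CATEGORICAL = "categorical"
    TEXT = "text"


@dataclass(frozen=True)
class VariableSpec:
    """Dictionary entry typing one clinical variable."""

    name: str
    temporal_class: TemporalClass
    value_class: ValueClass
    group: str
    is_intervention: bool = False
    is_physician_impression: bool = False

    def __post_init__(self) -> None:
        if self.group not in VARIABLE_GROUPS:
            raise ValueError(
                f"unknown variable group {self.group!r}; "
                f"must be one of {VARIABLE_GROUPS}"
            )


@dataclass(frozen=True)
class Observation:
    """One recorded value: static (time_h is None) or dynamic (time_h >= 0)."""

    patient_id: str
    variable: str
    time_h: float | None
    value: str  # raw value as string; MISSING_MARKER for explicit missing

    @property
    def is_missing(self) -> bool:
        return self.value == MISSING_MARKER


@dataclass(frozen=True)
class OrdinalOutcome:
    """7-category ordinal outcome; index 0..6 maps to OUTCOME_LABELS."""

    category_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.category_index < N_OUTCOME_CATEGORIES:
            raise ValueError(
                f"category_index must be in 0..6, got {self.category_index}"
            )

    @property
    def label(self) -> str:
        return OUTCOME_LABELS[self.category_index]


@dataclass
class Stay:
    """One ICU stay: admission at t=0, observations, and the outcome."""

    patient_id: str
    discharge_h: float
    observations: list[Observation] = field(default_factory=list)
    outcome: OrdinalOutcome | None = None

    def validate(self, dictionary: dict[str, VariableSpec]) -> None:
        if self.discharge_h < 24:
            raise ValueError(
                f"stay {self.patient_id}: discharge_h {self.discharge_h} < 24 h "
                "(cohort inclusion requires at least 24 h in ICU)"
            )
        if self.outcome is None:
            raise ValueError(f"stay {self.patient_id}: outcome missing")
        for obs in self.observations:
            spec = dictionary.get(obs.variable)
            if spec is None:
                raise ValueError(
                    f"stay {self.patient_id}: variable {obs.variable!r} "
                    "not in dictionary"
                )
            if spec.temporal_class is TemporalClass.DYNAMIC:
                if obs.time_h is None:
                    raise ValueError(
                        f"stay {self.patient_id}: dynamic observation of "
                        f"{obs.variable!r} lacks a timestamp"
                    )
                if obs.time_h < 0 or obs.time_h >= self.discharge_h:
                    raise ValueError(
                        f"stay {self.patient_id}: observation of {obs.variable!r} "
                        f"at t={obs.time_h} outside [0, discharge={self.discharge_h})"
                    )
            elif obs.time_h is not None:
                raise ValueError(
                    f"stay {self.patient_id}: static observation of "
                    f"{obs.variable!r} carries a timestamp"
                )


@dataclass
class Cohort:
    """A dictionary of variables plus a collection of validated stays."""

    dictionary: dict[str, VariableSpec]
    stays: list[Stay]

    def __len__(self) -> int:
        return len(self.stays)

    def validate(self) -> None:
        seen: set[str] = set()
        for stay in self.stays:
            if stay.patient_id in seen:
                raise ValueError(f"duplicate patient_id {stay.patient_id!r}")
            seen.add(stay.patient_id)
            stay.validate(self.dictionary)

    def subtype_counts(self) -> dict[str, int]:
        """Marginal variable counts by subtype (static/dynamic/flags)."""
        specs = self.dictionary.values()
        return {
            "all": len(self.dictionary),
            "static": sum(s.temporal_class is TemporalClass.STATIC for s in specs),
            "dynamic": sum(s.temporal_class is TemporalClass.DYNAMIC for s in specs),
            "interventions": sum(s.is_intervention for s in specs),
            "physician_impressions": sum(s.is_physician_impression for s in specs),
        }

    def outcomes_array(self):
        import numpy as np

        return np.array([s.outcome.category_index for s in self.stays])


# ---------------------------------------------------------------------------
# File I/O: three TSV files with canonical column order
# ---------------------------------------------------------------------------

OBS_COLUMNS = ["patient_id", "variable", "time_h", "value"]
DICT_COLUMNS = [
    "name",
    "temporal_class",
    "value_class",
    "group",
    "is_intervention",
    "is_physician_impression",
]
OUTCOME_COLUMNS = ["patient_id", "gose_category", "discharge_h"]


def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_dictionary(path: str) -> dict[str, VariableSpec]:
    df = _read_tsv(path)
    specs: dict[str, VariableSpec] = {}
    for row in df.itertuples(index=False):
        if row.name in specs:
            raise ValueError(f"duplicate variable {row.name!r} in dictionary")
        specs[row.name] = VariableSpec(
            name=row.name,
            temporal_class=TemporalClass(row.temporal_class),
            value_class=ValueClass(row.value_class),
            group=row.group,
            is_intervention=row.is_intervention == "1",
            is_physician_impression=row.is_physician_impression == "1",
        )
    return specs


def read_cohort(
    observations_path: str, dictionary_path: str, outcomes_path: str
) -> tuple[Cohort, int]:
    """Read a cohort from its three TSV files.

    Returns (cohort, n_rejected) where n_rejected counts observation rows
    whose variable is absent from the dictionary (rejected with a count, not
    silently dropped one by one).  A patient without an outcome row, or a
    dynamic observation without a timestamp, is a hard error.
    """
    dictionary = read_dictionary(dictionary_path)
    obs_df = _read_tsv(observations_path)
    out_df = _read_tsv(outcomes_path)

    known = obs_df["variable"].isin(dictionary.keys())
    unknown_vars = sorted(obs_df.loc[~known, "variable"].unique())
    n_rejected = int((~known).sum())
    if unknown_vars:
        raise ValueError(
            f"{n_rejected} observation rows reference variables absent from "
            f"the dictionary: {unknown_vars}"
        )

    outcomes: dict[str, OrdinalOutcome] = {}
    discharge: dict[str, float] = {}
    for row in out_df.itertuples(index=False):
        outcomes[row.patient_id] = OrdinalOutcome(
            OUTCOME_LABELS.index(row.gose_category)
        )
        discharge[row.patient_id] = float(row.discharge_h)

    stays: dict[str, Stay] = {}
    for pid in out_df["patient_id"]:
        stays[pid] = Stay(
            patient_id=pid, discharge_h=discharge[pid], outcome=outcomes[pid]
        )
    for row in obs_df.itertuples(index=False):
        stay = stays.get(row.patient_id)
        if stay is None:
            raise ValueError(
                f"observation for patient {row.patient_id!r} but no outcome row"
            )
        spec = dictionary[row.variable]
        if spec.temporal_class is TemporalClass.DYNAMIC and row.time_h == "":
            raise ValueError(
                f"dynamic observation of {row.variable!r} for patient "
                f"{row.patient_id!r} has no timestamp"
            )
        time_h = None if row.time_h == "" else float(row.time_h)
        stay.observations.append(
            Observation(row.patient_id, row.variable, time_h, row.value)
        )

    cohort = Cohort(dictionary=dictionary, stays=list(stays.values()))
    cohort.validate()
    return cohort, n_rejected


def _obs_sort_key(o: Observation):
    return (o.patient_id, o.variable, -1.0 if o.time_h is None else o.time_h, o.value)


def write_cohort(cohort: Cohort, out_dir: str) -> dict[str, str]:
    """Write the three TSV files in the dialect ``read_cohort`` consumes.

    Rows are canonically sorted so write∘read∘write is byte-stable.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "observations": os.path.join(out_dir, "observations.tsv"),
        "dictionary": os.path.join(out_dir, "dictionary.tsv"),
        "outcomes": os.path.join(out_dir, "outcomes.tsv"),
    }

    obs_rows = []
    for stay in cohort.stays:
        for o in sorted(stay.observations, key=_obs_sort_key):
            obs_rows.append(
                (
                    o.patient_id,
                    o.variable,
                    "" if o.time_h is None else repr(o.time_h),
                    o.value,
                )
            )
    obs_rows.sort()
    pd.DataFrame(obs_rows, columns=OBS_COLUMNS).to_csv(
        paths["observations"], sep="\t", index=False, encoding="utf-8"
    )

    dict_rows = [
        (
            s.name,
            s.temporal_class.value,
            s.value_class.value,
            s.group,
            int(s.is_intervention),
            int(s.is_physician_impression),
        )
        for s in sorted(cohort.dictionary.values(), key=lambda s: s.name)
    ]
    pd.DataFrame(dict_rows, columns=DICT_COLUMNS).to_csv(
        paths["dictionary"], sep="\t", index=False, encoding="utf-8"
    )

    out_rows = [
        (s.patient_id, s.outcome.label, repr(s.discharge_h))
        for s in sorted(cohort.stays, key=lambda s: s.patient_id)
    ]
    pd.DataFrame(out_rows, columns=OUTCOME_COLUMNS).to_csv(
        paths["outcomes"], sep="\t", index=False, encoding="utf-8"
    )
    return paths
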