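"""In-memory containers for the two input tables.

A cohort is described by a morphometric feature table (one row per subject,
one column per cortical parcel, holding mean cortical thickness in mm,
gyrification index, or sulcal depth in mm) and a phenotype table (TEQ sum
score, age, gender per subject).  Both are thin, validated wrappers around
numpy arrays with pandas round-trips for CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURES = ("thickness", "gyrification", "depth")
GENDERS = ("male", "female")

#: TEQ sum-score bounds: 7 items, each scored 0-4.
TEQ_MIN, TEQ_MAX = 0, 28


@dataclass
class MorphometryTable:
    """Subjects x parcels matrix for one morphometric measure.

    Parameters
    ----------
    measure : str
        One of ``thickness``, ``gyrification``, ``depth``.
    subject_ids : list of str
        Unique subject identifiers, one per row.
    parcel_labels : list of str
        Unique parcel labels (Schaefer-style), one per column.
    values : ndarray, shape (n_subjects, n_parcels)
        Finite numeric feature values.
    """

    measure: str
    subject_ids: list[str]
    parcel_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"{n} rows but {len(self.subject_ids)} subject ids"
            )
        if p != len(self.parcel_labels):
            raise ValueError(
                f"{p} columns but {len(self.parcel_labels)} parcel labels"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids in morphometry table")
        if len(set(self.parcel_labels)) != p:
            raise ValueError("duplicate parcel labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values after loading")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.parcel_labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def subset(self, row_idx: np.ndarray) -> "MorphometryTable":
        return MorphometryTable(
            self.measure,
            [self.subject_ids[i] for i in row_idx],
            list(self.parcel_labels),
            self.values[row_idx],
        )


@dataclass
class PhenotypeTable:
    """Per-subject TEQ sum score, age and gender."""

    subject_ids: list[str]
    teq: np.ndarray
    age: np.ndarray
    gender: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        self.teq = np.asarray(self.teq)
        self.age = np.asarray(self.age, dtype=float)
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids in phenotype table")
        if len(self.teq) != n or len(self.age) != n or len(self.gender) != n:
            raise ValueError("phenotype columns have inconsistent lengths")
        if not np.all((self.teq >= TEQ_MIN) & (self.teq <= TEQ_MAX)):
            raise ValueError(f"TEQ scores must lie in [{TEQ_MIN}, {TEQ_MAX}]")
        if np.any(self.teq != np.round(self.teq)):
            raise ValueError("TEQ sum scores must be integers")
        self.teq = self.teq.astype(int)
        bad = sorted(set(self.gender) - set(GENDERS))
        if bad:
            raise ValueError(f"unknown gender labels {bad}; expected {GENDERS}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def female(self) -> np.ndarray:
        """Indicator vector: 1 for female, 0 for male."""
        return np.asarray([1.0 if g == "female" else 0.0 for g in self.gender])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "teq": self.teq,
                "age": self.age,
                "gender": self.gender,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def subset(self, row_idx: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(
            [self.subject_ids[i] for i in row_idx],
            self.teq[row_idx],
            self.age[row_idx],
            [self.gender[i] for i in row_idx],
        )
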