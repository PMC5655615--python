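"""The in-memory descriptor/activity table shared by every module.

A :class:`DescriptorTable` is a rectangular block of compounds × numeric
molecular descriptors plus one or more activity columns (continuous response
or 0/1 class labels).  Tables read from SD files additionally carry the
original record objects so that writing back preserves everything that was
not explicitly randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError


@dataclass
class DescriptorTable:
    """Compounds × (descriptors + activities).

    Parameters
    ----------
    record_ids
        Unique compound identifiers, one per row.
    descriptor_names
        Unique descriptor column names, disjoint from ``activity_names``.
    values
        ``(n, p)`` float matrix of descriptor values.
    activity_names, activities
        Activity column names and the ``(n, a)`` float matrix of responses.
        Binary 0/1 columns are allowed for classification.
    molecule_payloads
        Optional per-record opaque payloads (SDF records) enabling byte-
        faithful SDF output; ``None`` for CSV-origin tables.
    metadata
        Free-form provenance (e.g. a synthetic fixture's generating truth).
    """

    record_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    activity_names: list[str] = field(default_factory=list)
    activities: np.ndarray | None = None
    molecule_payloads: list[Any] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.record_ids = [str(r) for r in self.record_ids]
        self.descriptor_names = list(self.descriptor_names)
        self.activity_names = list(self.activity_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.record_ids), -1)
        if self.activities is None:
            self.activities = np.empty((len(self.record_ids), 0))
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.ndim != 2:
            self.activities = self.activities.reshape(len(self.record_ids), -1)
        self._validate()

    def _validate(self) -> None:
        n = len(self.record_ids)
        if len(set(self.record_ids)) != n:
            raise ContractError("record_ids must be unique")
        if self.values.shape[0] != n:
            raise ContractError(
                f"values has {self.values.shape[0]} rows for {n} record ids"
            )
        if self.values.shape[1] != len(self.descriptor_names):
            raise ContractError(
                f"values has {self.values.shape[1]} columns for "
                f"{len(self.descriptor_names)} descriptor names"
            )
        if self.activities.shape != (n, len(self.activity_names)):
            raise ContractError("activities shape does not match names/records")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ContractError("descriptor names must be unique")
        if len(set(self.activity_names)) != len(self.activity_names):
            raise ContractError("activity names must be unique")
        overlap = set(self.descriptor_names) & set(self.activity_names)
        if overlap:
            raise ContractError(
                f"descriptor and activity names overlap: {sorted(overlap)}"
            )
        if self.molecule_payloads is not None and len(self.molecule_payloads) != n:
            raise ContractError("molecule_payloads length must equal record count")

    # -- accessors ---------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def descriptor_index(self, name: str) -> int:
        try:
            return self.descriptor_names.index(name)
        except ValueError:
            raise ConfigError(f"no descriptor column named {name!r}") from None

    def activity_index(self, name: str) -> int:
        try:
            return self.activity_names.index(name)
        except ValueError:
            raise ConfigError(f"no activity column named {name!r}") from None

    def descriptor_column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_index(name)]

    def activity_column(self, name: str) -> np.ndarray:
        return self.activities[:, self.activity_index(name)]

    def descriptor_matrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.descriptor_index(n) for n in names]
        return self.values[:, idx]

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(
            record_ids=list(self.record_ids),
            descriptor_names=list(self.descriptor_names),
            values=self.values.copy(),
            activity_names=list(self.activity_names),
            activities=self.activities.copy(),
            molecule_payloads=(
                None if self.molecule_payloads is None else list(self.molecule_payloads)
            ),
            metadata=dict(self.metadata),
        )

    def select_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        """Return a copy restricted to the given descriptor columns."""
        idx = [self.descriptor_index(n) for n in names]
        return DescriptorTable(
            record_ids=list(self.record_ids),
            descriptor_names=[self.descriptor_names[i] for i in idx],
            values=self.values[:, idx].copy(),
            activity_names=list(self.activity_names),
            activities=self.activities.copy(),
            molecule_payloads=(
                None if self.molecule_payloads is None else list(self.molecule_payloads)
            ),
            metadata=dict(self.metadata),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        for j, name in enumerate(self.activity_names):
            df[name] = self.activities[:, j]
        df.insert(0, "id", self.record_ids)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DescriptorTable):
            return NotImplemented
        return (
            self.record_ids == other.record_ids
            and self.descriptor_names == other.descriptor_names
            and self.activity_names == other.activity_names
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.activities, other.activities)
        )
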