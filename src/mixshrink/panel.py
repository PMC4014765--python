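"""Exposure panel container shared by the generator and the preprocessing
pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemicals import ChemicalRecord


@dataclass
class ExposurePanel:
    """Subjects x chemicals concentration matrix with censoring flags.

    ``values`` holds concentrations in each chemical's native unit; below-LOD
    entries keep whatever was stored (raw draw before substitution, LOD/sqrt(2)
    after) and are marked in ``censored``. ``coding`` is filled in by
    preprocessing: each chemical maps to ``continuous``, ``dichotomous`` or
    ``excluded``.
    """

    chemicals: list[ChemicalRecord]
    values: pd.DataFrame
    censored: pd.DataFrame
    coding: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chemicals]
        if list(self.values.columns) != names:
            raise ValueError("values columns must match chemical names in order")
        if list(self.censored.columns) != names:
            raise ValueError("censored columns must match chemical names in order")
        if self.values.shape != self.censored.shape:
            raise ValueError("values and censored must have the same shape")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chemicals]

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def lods(self) -> pd.Series:
        return pd.Series({c.name: c.lod for c in self.chemicals}, name="lod")

    def record(self, name: str) -> ChemicalRecord:
        for c in self.chemicals:
            if c.name == name:
                return c
        raise KeyError(name)

    def detection_frequency(self) -> pd.Series:
        return 1.0 - self.censored.mean(axis=0)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: subject_id, chemical, value, lod, censored."""
        lods = self.lods
        frames = []
        for name in self.names:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": self.values.index,
                        "chemical": name,
                        "value": self.values[name].to_numpy(),
                        "lod": lods[name],
                        "censored": self.censored[name].to_numpy().astype(int),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, chemicals: list[ChemicalRecord]) -> "ExposurePanel":
        values = long.pivot(index="subject_id", columns="chemical", values="value")
        censored = long.pivot(index="subject_id", columns="chemical", values="censored")
        names = [c.name for c in chemicals]
        values = values[names]
        censored = censored[names].astype(bool)
        values.columns.name = None
        censored.columns.name = None
        return cls(chemicals=chemicals, values=values, censored=censored)

    def copy(self) -> "ExposurePanel":
        return ExposurePanel(
            chemicals=list(self.chemicals),
            values=self.values.copy(),
            censored=self.censored.copy(),
            coding=dict(self.coding),
        )
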