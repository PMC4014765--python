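"""Chemical metadata: record types, the shipped 52-chemical reference panel,
and the wider 70-chemical measurement panel used for filter accounting.

Units follow the reference table: ng/g lipid for serum PCBs, organochlorine
pesticides and brominated flame retardants; ug/g creatinine for urinary
phthalate metabolites and BPA; ug/L for serum PFAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: Recognized chemical classes, in display (panel) order.
CLASSES = ("phthalate", "phenol", "PCB", "OC_pesticide", "BFR", "PFAS")

#: Serum classes whose concentrations are lipid-normalized.
LIPID_CLASSES = frozenset({"PCB", "OC_pesticide", "BFR"})


def _normalization_for(chem_class: str, matrix: str) -> str:
    if matrix == "urine":
        return "creatinine"
    if chem_class in LIPID_CLASSES:
        return "lipid"
    return "none"


@dataclass(frozen=True)
class ChemicalRecord:
    """Analysis-side metadata for one biomarker."""

    name: str
    chem_class: str
    matrix: str
    lod: float = math.nan
    metabolite_group: str = ""

    def __post_init__(self) -> None:
        if self.chem_class not in CLASSES:
            raise ValueError(f"unknown chemical class {self.chem_class!r} for {self.name}")
        if self.matrix not in ("urine", "serum"):
            raise ValueError(f"unknown matrix {self.matrix!r} for {self.name}")

    @property
    def persistent(self) -> bool:
        # persistent chemicals are the serum-measured ones
        return self.matrix == "serum"

    @property
    def normalization(self) -> str:
        return _normalization_for(self.chem_class, self.matrix)


@dataclass(frozen=True)
class ChemicalSpec:
    """Generative description of one biomarker's marginal distribution.

    ``geometric_mean``/``geometric_sd`` describe the lognormal marginal;
    ``detection_target`` is the fraction of samples expected above the LOD,
    from which the LOD itself is derived.
    """

    name: str
    chem_class: str
    matrix: str
    geometric_mean: float
    geometric_sd: float
    detection_target: float
    metabolite_group: str = ""

    def __post_init__(self) -> None:
        if self.chem_class not in CLASSES:
            raise ValueError(f"unknown chemical class {self.chem_class!r} for {self.name}")
        if self.matrix not in ("urine", "serum"):
            raise ValueError(f"unknown matrix {self.matrix!r} for {self.name}")
        if not self.geometric_mean > 0:
            raise ValueError(f"{self.name}: geometric_mean must be > 0")
        if not self.geometric_sd > 1:
            raise ValueError(f"{self.name}: geometric_sd must be > 1")
        if not 0.0 <= self.detection_target <= 1.0:
            raise ValueError(f"{self.name}: detection_target must be in [0, 1]")

    @property
    def persistent(self) -> bool:
        return self.matrix == "serum"

    @property
    def normalization(self) -> str:
        return _normalization_for(self.chem_class, self.matrix)

    def to_record(self, lod: float = math.nan) -> ChemicalRecord:
        return ChemicalRecord(
            name=self.name,
            chem_class=self.chem_class,
            matrix=self.matrix,
            lod=lod,
            metabolite_group=self.metabolite_group,
        )


def _data_path(filename: str):
    return resources.files("mixshrink.data").joinpath(filename)


def load_table1() -> pd.DataFrame:
    """The shipped 52-row reference panel (names, classes, detection %, GM/GSD,
    percentiles and the national-survey median comparison column)."""
    with resources.as_file(_data_path("table1_chemicals.csv")) as path:
        df = pd.read_csv(path, dtype={"metabolite_group": "string"})
    df["metabolite_group"] = df["metabolite_group"].fillna("")
    return df


def load_extra_panel() -> pd.DataFrame:
    """Chemicals measured but excluded by the analysis filters: two members of
    near-perfectly correlated pairs plus sixteen infrequently detected ones."""
    with resources.as_file(_data_path("extra_chemicals.csv")) as path:
        df = pd.read_csv(path, dtype={"metabolite_group": "string", "correlated_with": "string"})
    df["metabolite_group"] = df["metabolite_group"].fillna("")
    df["correlated_with"] = df["correlated_with"].fillna("")
    return df


def _specs_from_frame(df: pd.DataFrame) -> list[ChemicalSpec]:
    return [
        ChemicalSpec(
            name=row["name"],
            chem_class=row["chem_class"],
            matrix=row["matrix"],
            geometric_mean=float(row["gm"]),
            geometric_sd=float(row["gsd"]),
            detection_target=float(row["pct_above_lod"]) / 100.0,
            metabolite_group=str(row["metabolite_group"]),
        )
        for _, row in df.iterrows()
    ]


def default_panel() -> list[ChemicalSpec]:
    """The 52 analyzed chemicals as generative specs."""
    return _specs_from_frame(load_table1())


def full_measurement_panel() -> tuple[list[ChemicalSpec], list[tuple[str, str, float]]]:
    """All 70 measured chemicals plus the extra pairwise correlations that
    reproduce the near-perfect correlated pairs.

    Returns ``(specs, extra_correlations)`` where each extra correlation is
    ``(name_a, name_b, r)``.
    """
    t1 = load_table1()
    extra = load_extra_panel()
    specs = _specs_from_frame(t1) + _specs_from_frame(extra)
    pairs = [
        (row["name"], row["correlated_with"], float(row["corr"]))
        for _, row in extra.iterrows()
        if row["correlated_with"]
    ]
    return specs, pairs
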