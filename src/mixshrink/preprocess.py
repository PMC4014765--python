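"""Biomarker preprocessing: censoring substitution, normalization, averaging
of repeat samples, detection-frequency coding, correlation screening and the
two-standard-deviation rescaling that makes continuous and dichotomous
exposures comparable in the outcome model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemicals import ChemicalRecord
from .panel import ExposurePanel

SQRT2 = math.sqrt(2.0)

CODING_CONTINUOUS = "continuous"
CODING_DICHOTOMOUS = "dichotomous"
CODING_EXCLUDED = "excluded"


def substitute_below_lod(value: float, lod: float, censored: bool) -> float:
    """Below-LOD concentrations are assigned LOD/sqrt(2); detected values pass
    through unchanged."""
    if not censored:
        return value
    if lod is None or not np.isfinite(lod) or lod <= 0:
        raise ValueError("censored value requires a positive, finite LOD")
    return lod / SQRT2


def classify_by_detection(freq: float) -> str:
    """Coding rule: >=80% detected -> continuous, [20%, 80%) -> dichotomous
    (detected vs not), <20% -> excluded."""
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"detection frequency {freq} outside [0, 1]")
    if freq >= 0.80:
        return CODING_CONTINUOUS
    if freq >= 0.20:
        return CODING_DICHOTOMOUS
    return CODING_EXCLUDED


def normalize(value: float, basis_value: float | None, basis: str) -> float:
    """Divide a concentration by its dilution/partition basis.

    * ``creatinine``: value in ug/L, basis in g creatinine/L -> ug/g creatinine.
    * ``lipid``: value in ng/mL serum, basis in g lipid/L serum -> ng/g lipid.
    * ``none``: identity (PFAS are reported per volume serum).
    """
    if basis == "none":
        return value
    if basis_value is None or not basis_value > 0:
        raise ValueError(f"{basis} normalization requires a positive basis value")
    if basis == "creatinine":
        return value / basis_value
    if basis == "lipid":
        return value * 1000.0 / basis_value
    raise ValueError(f"unknown normalization basis {basis!r}")


def average_repeats(samples: list[float]) -> float:
    """Log10-transform then average repeat samples from the same woman;
    returns the mean on the log10 scale."""
    if len(samples) == 0:
        raise ValueError("cannot average an empty list of samples")
    arr = np.asarray(samples, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all samples must be positive for log10 averaging")
    return float(np.mean(np.log10(arr)))


def rescale_2sd(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Divide by twice the sample SD so the result has SD 0.5, the SD of a
    balanced binary indicator."""
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1))
    if not sd > 0:
        raise ValueError("cannot rescale a constant vector (zero SD)")
    out = arr / (2.0 * sd)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def dichotomize(censored: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Detected (not censored) -> 1, nondetectable -> 0."""
    if isinstance(censored, pd.Series):
        return (~censored.astype(bool)).astype(float)
    return (~np.asarray(censored, dtype=bool)).astype(float)


def substitute_panel(panel: ExposurePanel) -> ExposurePanel:
    """Apply the LOD/sqrt(2) substitution to every censored cell."""
    out = panel.copy()
    lods = panel.lods
    for name in out.names:
        mask = out.censored[name].to_numpy(dtype=bool)
        if mask.any():
            lod = lods[name]
            if not np.isfinite(lod) or lod <= 0:
                raise ValueError(f"{name}: censored values but LOD is missing or nonpositive")
            col = out.values[name].to_numpy(dtype=float).copy()
            col[mask] = lod / SQRT2
            out.values[name] = col
    return out


def drop_correlated(
    panel: ExposurePanel,
    r_threshold: float = 0.95,
    coding: dict[str, str] | None = None,
    min_pairs: int = 10,
) -> list[tuple[str, str, float]]:
    """Mark one member of each near-perfectly correlated pair excluded.

    Pearson correlations are computed on log10 concentrations among subjects
    with both chemicals detected. Pairs with r > ``r_threshold`` are processed
    in descending |r| (ties broken by name); the chemical with the lower
    median concentration is excluded. Returns ``(excluded, kept, r)`` tuples
    and updates ``panel.coding`` in place.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be in (0, 1)")
    if coding is None:
        coding = panel.coding
    candidates = [n for n in panel.names if coding.get(n) != CODING_EXCLUDED]
    if len(candidates) < 2:
        return []

    vals = panel.values[candidates].astype(float)
    detected = ~panel.censored[candidates].astype(bool)
    logvals = np.log10(vals.where(vals > 0)).where(detected)
    corr = logvals.corr(min_periods=min_pairs)

    medians = vals.median(axis=0)
    pairs = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > r_threshold:
                pairs.append((a, b, float(r)))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))

    dropped: list[tuple[str, str, float]] = []
    alive = {n: True for n in candidates}
    for a, b, r in pairs:
        if not (alive[a] and alive[b]):
            continue
        # keep the chemical with the higher median concentration
        if medians[a] >= medians[b]:
            keep, drop = a, b
        else:
            keep, drop = b, a
        alive[drop] = False
        coding[drop] = CODING_EXCLUDED
        dropped.append((drop, keep, r))
    return dropped


@dataclass
class ProcessedPanel:
    """Analysis-ready coding of an exposure panel."""

    data: pd.DataFrame  # subjects x analyzed chemicals, coded values
    coding: dict[str, str]
    report: pd.DataFrame  # per-chemical detection %, coding, exclusion reason
    chemicals: list[ChemicalRecord]  # analyzed chemicals, panel order

    @property
    def analyzed(self) -> list[str]:
        return list(self.data.columns)

    def counts(self) -> dict[str, int]:
        reasons = self.report["exclusion_reason"]
        return {
            "measured": len(self.report),
            "low_detection": int((reasons == "low_detection").sum()),
            "correlation_excluded": int(reasons.str.startswith("correlated_with:").sum()),
            "analyzed": len(self.data.columns),
        }


def preprocess_panel(
    panel: ExposurePanel,
    r_threshold: float = 0.95,
    substitute: bool = True,
) -> ProcessedPanel:
    """Full preprocessing pipeline.

    1. substitute LOD/sqrt(2) for censored values (unless ``substitute=False``);
    2. classify each chemical by detection frequency;
    3. exclude one member of every pair with Pearson r above ``r_threshold``;
    4. code continuous chemicals as rescaled log10 concentrations (SD 0.5) and
       dichotomous chemicals as detected-vs-not indicators.
    """
    work = substitute_panel(panel) if substitute else panel.copy()

    detection = work.detection_frequency()
    coding = {name: classify_by_detection(detection[name]) for name in work.names}
    reasons = {
        name: ("low_detection" if coding[name] == CODING_EXCLUDED else "")
        for name in work.names
    }

    for drop, keep, _r in drop_correlated(work, r_threshold=r_threshold, coding=coding):
        reasons[drop] = f"correlated_with:{keep}"

    columns: dict[str, np.ndarray] = {}
    analyzed: list[ChemicalRecord] = []
    for rec in work.chemicals:
        name = rec.name
        if coding[name] == CODING_CONTINUOUS:
            columns[name] = np.asarray(rescale_2sd(np.log10(work.values[name].to_numpy(dtype=float))))
            analyzed.append(rec)
        elif coding[name] == CODING_DICHOTOMOUS:
            columns[name] = np.asarray(dichotomize(work.censored[name]))
            analyzed.append(rec)

    data = pd.DataFrame(columns, index=work.subjects)
    report = pd.DataFrame(
        {
            "chemical": work.names,
            "chem_class": [c.chem_class for c in work.chemicals],
            "detection_frequency": [float(detection[n]) for n in work.names],
            "coding": [coding[n] for n in work.names],
            "exclusion_reason": [reasons[n] for n in work.names],
        }
    )
    work.coding = coding
    return ProcessedPanel(data=data, coding=coding, report=report, chemicals=analyzed)
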