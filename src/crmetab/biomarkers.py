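"""Biomarker normalization: urinary creatinine correction, qPCR mtDNA/nuDNA
ratio, and the bedside glycaemia repeat rule.

Urinary analyte concentrations depend on urine dilution; dividing by the
creatinine concentration (mg mL-1) yields the conventional per-creatinine
units (ng or pg per mg creatinine).  Relative mitochondrial genome copy
number is derived from paired qPCR targets -- a mitochondrial amplicon
(e.g. 12S) and a single-copy nuclear amplicon (e.g. 36B4) -- via the
efficiency-power delta-Ct model

    ratio = E ** (mean Ct_nu - mean Ct_mt)

with amplification efficiency E (2.0 for perfect doubling) configurable.
Blood glucose read at the bedside is repeated when the first strip reading
falls outside the configured normal range; the resolved value is then the
mean of all repeats, flagged as repeated.

Protein-normalized blood antioxidant markers (thiols, GPx) arrive already
per mg protein; no further normalization happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_EFFICIENCY = 2.0
#: default bedside glucose normal range, mg/dL (configured per study)
DEFAULT_GLYCAEMIA_RANGE = (50.0, 150.0)

MT_TARGET = "mt"
NU_TARGET = "nu"


class BiomarkerError(ValueError):
    pass


def normalize_urinary(raw: float, creatinine: float):
    """Per-creatinine urinary value raw / creatinine.

    Returns NaN (the missing marker) when creatinine <= 0; scale-equivariant
    in the sense that multiplying both inputs by the same positive constant
    leaves the result unchanged.
    """
    raw_arr = np.asarray(raw, dtype=float)
    crea = np.asarray(creatinine, dtype=float)
    out = np.where(crea > 0, raw_arr / np.where(crea > 0, crea, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class QpcrRecord:
    """Replicate Ct values for the paired mitochondrial/nuclear targets.

    Each target carries up to 6 replicates (two repeated triplicate runs);
    Ct values must lie in (0, 45) and efficiency in (1, 2].
    """

    sample_id: str
    ct_mt: np.ndarray
    ct_nu: np.ndarray
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self) -> None:
        self.ct_mt = np.asarray(self.ct_mt, dtype=float)
        self.ct_nu = np.asarray(self.ct_nu, dtype=float)
        for name, arr in (("mt", self.ct_mt), ("nu", self.ct_nu)):
            if arr.size == 0:
                raise BiomarkerError(f"sample {self.sample_id}: no {name} replicates")
            if np.any((arr <= 0) | (arr >= 45)):
                raise BiomarkerError(f"sample {self.sample_id}: Ct outside (0, 45)")
        if not (1.0 < self.efficiency <= 2.0):
            raise BiomarkerError("amplification efficiency must be in (1, 2]")


def mtnu_ratio(rec: QpcrRecord) -> float:
    """Relative mtDNA/nuDNA copy number, E**(mean Ct_nu - mean Ct_mt)."""
    delta = float(np.mean(rec.ct_nu) - np.mean(rec.ct_mt))
    return rec.efficiency**delta


@dataclass
class GlycaemiaResult:
    value: float
    repeated: bool
    readings: tuple


def resolve_glycaemia(readings, normal_range=DEFAULT_GLYCAEMIA_RANGE) -> GlycaemiaResult:
    """Apply the repeat rule to a sequence of glucometer readings.

    If the first reading is inside the normal range it stands alone;
    otherwise the resolved value is the mean of all repeats and the result
    is flagged as repeated.
    """
    vals = [float(v) for v in readings]
    if not vals:
        raise BiomarkerError("at least one glycaemia reading required")
    lo, hi = normal_range
    if lo < vals[0] < hi:
        return GlycaemiaResult(vals[0], repeated=False, readings=tuple(vals))
    return GlycaemiaResult(float(np.mean(vals)), repeated=len(vals) > 1, readings=tuple(vals))


# ---------------------------------------------------------------------------
# Panel-level CSV interfaces

URINARY_ANALYTES = ("cortisol", "ohdg8", "estradiol", "testosterone")


def normalize_panel(df: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format biomarker panel -> creatinine-normalized panel.

    Expects columns: animal_id, condition, analyte, value, creatinine
    (creatinine may be NaN for blood analytes, which pass through
    unchanged).  Urinary analytes are divided by creatinine; rows whose
    creatinine is nonpositive get a NaN value and a reason column entry.
    """
    for col in ("animal_id", "condition", "analyte", "value"):
        if col not in df.columns:
            raise BiomarkerError(f"panel missing column {col!r}")
    out = df.copy()
    out["normalized"] = out["value"].astype(float)
    out["reason"] = ""
    urinary = out["analyte"].isin(URINARY_ANALYTES)
    if urinary.any():
        if "creatinine" not in out.columns:
            raise BiomarkerError("urinary analytes present but no creatinine column")
        crea = out.loc[urinary, "creatinine"].astype(float)
        out.loc[urinary, "normalized"] = normalize_urinary(
            out.loc[urinary, "value"].astype(float).to_numpy(), crea.to_numpy()
        )
        bad = urinary & ~(out["creatinine"] > 0)
        out.loc[bad, "reason"] = "nonpositive creatinine"
    return out


def read_qpcr(path, efficiency: float = DEFAULT_EFFICIENCY) -> list[QpcrRecord]:
    """Read a qPCR CSV (sample_id, target, replicate, ct) into records."""
    df = pd.read_csv(path)
    for col in ("sample_id", "target", "ct"):
        if col not in df.columns:
            raise BiomarkerError(f"qPCR CSV missing column {col!r}")
    records = []
    for sid, sub in df.groupby("sample_id", sort=True):
        mt = sub.loc[sub["target"] == MT_TARGET, "ct"].to_numpy(float)
        nu = sub.loc[sub["target"] == NU_TARGET, "ct"].to_numpy(float)
        if mt.size == 0 or nu.size == 0:
            raise BiomarkerError(f"sample {sid}: missing qPCR target")
        records.append(QpcrRecord(str(sid), ct_mt=mt, ct_nu=nu, efficiency=efficiency))
    return records
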