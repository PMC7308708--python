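"""Open-flow (flow-through) respirometry: gas traces to metabolic series.

A pull-mode respirometry chamber is supplied with air at incurrent flow rate
FRi; the analyzer reports fractional O2 and CO2 concentrations of the
incurrent stream (FiO2, FiCO2) and of the water-vapor-scrubbed excurrent
stream (Fe'O2, Fe'CO2).  Mass-specific oxygen consumption for an animal of
body mass m (kg) is

    VO2 = FRi * [(FiO2 - Fe'O2) - Fe'O2 * (Fe'CO2 - FiCO2)] / [(1 - Fe'O2) * m]

in mL O2 kg-1 h-1 when FRi is in mL h-1.  CO2 production is the mirror
expression with denominator (1 - Fe'CO2) * m; this module orients it so that
net CO2 production (excurrent above incurrent) is positive:

    VCO2 = FRi * [(Fe'CO2 - FiCO2) - Fe'CO2 * (FiO2 - Fe'O2)] / [(1 - Fe'CO2) * m]

The respiratory exchange ratio RER = VCO2/VO2 indexes the oxidized fuel mix
(about 1.0 for carbohydrate, about 0.7 for fat), and energy expenditure
follows the oxycaloric relation

    EE = (3.815 + 1.232 * RER) * VO2 * BM        [kcal h-1]

with VO2 in L kg-1 h-1 and BM in kg inside the formula.  An excurrent flow
rate column, if present in input files, is ignored with a logged notice:
with a scrubbed excurrent stream the equations above need only FRi.

Barometric/STP correction and analyzer washout-lag correction are assumed to
have been applied upstream by the instrument.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .photoperiod import MINUTES_PER_DAY, PhotoperiodSchedule

logger = logging.getLogger(__name__)

#: physiological RER range used for flagging (never clipping)
RER_RANGE = (0.7, 1.0)

#: oxycaloric coefficients of EE = (A + B * RER) * VO2[L/kg/h] * BM[kg]
EE_INTERCEPT = 3.815
EE_SLOPE = 1.232


class RespirometryError(ValueError):
    """Invalid gas-trace input."""


@dataclass
class GasTrace:
    """Raw gas concentrations, flow and body mass for one animal recording.

    Fractional concentrations are dimensionless in (0, 1); ``fr_i`` is the
    incurrent flow in mL h-1 (STP-corrected upstream); ``body_mass`` in kg.
    """

    animal_id: str
    timestamps: np.ndarray  # datetime64[s], strictly increasing
    fr_i: np.ndarray
    fi_o2: np.ndarray
    fe_o2: np.ndarray
    fi_co2: np.ndarray
    fe_co2: np.ndarray
    body_mass: float
    condition: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        n = len(self.timestamps)
        for name in ("fr_i", "fi_o2", "fe_o2", "fi_co2", "fe_co2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise RespirometryError(
                    f"{name} length {arr.shape} does not match {n} timestamps"
                )
            if not np.all(np.isfinite(arr)):
                bad = self.timestamps[~np.isfinite(arr)][0]
                raise RespirometryError(f"non-finite {name} at {bad}")
        if n >= 2 and not np.all(np.diff(self.timestamps).astype(int) > 0):
            raise RespirometryError("timestamps must be strictly increasing")
        for name in ("fi_o2", "fe_o2", "fi_co2", "fe_co2"):
            arr = getattr(self, name)
            if np.any(arr <= 0) or np.any(arr >= 1):
                bad = self.timestamps[(arr <= 0) | (arr >= 1)][0]
                raise RespirometryError(
                    f"{name} outside (0, 1) at {bad} (division-by-zero hazard)"
                )
        if np.any(self.fr_i < 0):
            raise RespirometryError("fr_i must be >= 0")
        if not self.body_mass > 0:
            raise RespirometryError("body_mass must be > 0")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def minutes_of_day(self) -> np.ndarray:
        secs = self.timestamps.astype("datetime64[s]").astype("int64")
        return (secs // 60) % MINUTES_PER_DAY


def compute_vo2(trace: GasTrace) -> np.ndarray:
    """Per-timestamp mass-specific oxygen consumption (mL kg-1 h-1)."""
    num = (trace.fi_o2 - trace.fe_o2) - trace.fe_o2 * (trace.fe_co2 - trace.fi_co2)
    return trace.fr_i * num / ((1.0 - trace.fe_o2) * trace.body_mass)


def compute_vco2(trace: GasTrace) -> np.ndarray:
    """Per-timestamp mass-specific CO2 production (mL kg-1 h-1).

    Oriented so that net CO2 production is positive (excurrent minus
    incurrent); see module docstring for the sign convention.
    """
    num = (trace.fe_co2 - trace.fi_co2) - trace.fe_co2 * (trace.fi_o2 - trace.fe_o2)
    return trace.fr_i * num / ((1.0 - trace.fe_co2) * trace.body_mass)


@dataclass
class RerSeries:
    """RER values with per-timestamp quality flags.

    ``values`` is NaN wherever ``undefined`` is set (VO2 == 0); values
    outside the physiological range are flagged in ``out_of_range``, never
    clipped.
    """

    values: np.ndarray
    undefined: np.ndarray
    out_of_range: np.ndarray


def compute_rer(vco2: np.ndarray, vo2: np.ndarray) -> RerSeries:
    """Element-wise respiratory exchange ratio VCO2/VO2."""
    vco2 = np.asarray(vco2, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if vco2.shape != vo2.shape:
        raise RespirometryError("vco2 and vo2 must be aligned")
    undefined = vo2 == 0
    values = np.full(vo2.shape, np.nan)
    np.divide(vco2, vo2, out=values, where=~undefined)
    lo, hi = RER_RANGE
    out_of_range = ~undefined & ((values < lo) | (values > hi))
    return RerSeries(values=values, undefined=undefined, out_of_range=out_of_range)


def compute_ee(
    rer: np.ndarray,
    vo2: np.ndarray,
    body_mass: float,
    *,
    vo2_unit: str = "mL/kg/h",
) -> np.ndarray:
    """Energy expenditure (kcal h-1) from RER, VO2 and body mass (kg).

    The oxycaloric formula takes VO2 in L kg-1 h-1; pass ``vo2_unit="L/kg/h"``
    if the series is already in litres, otherwise the mL default is converted
    internally.  Timestamps with VO2 == 0 yield EE == 0 regardless of the
    (undefined) RER there.
    """
    rer = np.asarray(rer, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if vo2_unit == "mL/kg/h":
        vo2_l = vo2 / 1000.0
    elif vo2_unit == "L/kg/h":
        vo2_l = vo2
    else:
        raise RespirometryError(f"unknown vo2 unit: {vo2_unit!r}")
    ee = (EE_INTERCEPT + EE_SLOPE * rer) * vo2_l * body_mass
    ee = np.where(vo2 == 0, 0.0, ee)
    finite = np.isfinite(ee) & (vo2 != 0)
    if 0.05 <= body_mass <= 0.15 and np.any(
        finite & ((ee <= 0.01) | (ee >= 100.0))
    ):
        warnings.warn(
            "EE outside (0.01, 100) kcal/h for a 50-150 g animal: "
            "check VO2/body-mass units",
            stacklevel=2,
        )
    return ee


@dataclass
class MetabolicSeries:
    """Derived per-timestamp metabolic variables with photoperiod labels."""

    animal_id: str
    timestamps: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    rer: RerSeries
    ee: np.ndarray
    phase: np.ndarray
    body_mass: float
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "condition": self.condition,
                "datetime": self.timestamps,
                "vo2": self.vo2,
                "vco2": self.vco2,
                "rer": self.rer.values,
                "rer_out_of_range": self.rer.out_of_range,
                "ee_kcal_h": self.ee,
                "phase": self.phase,
            }
        )


def derive_series(trace: GasTrace, schedule: PhotoperiodSchedule) -> MetabolicSeries:
    """Full derivation pipeline for one trace: VO2, VCO2, RER, EE, phase."""
    vo2 = compute_vo2(trace)
    vco2 = compute_vco2(trace)
    rer = compute_rer(vco2, vo2)
    ee = compute_ee(rer.values, vo2, trace.body_mass)
    phase = schedule.phase_of(trace.minutes_of_day)
    return MetabolicSeries(
        animal_id=trace.animal_id,
        timestamps=trace.timestamps,
        vo2=vo2,
        vco2=vco2,
        rer=rer,
        ee=ee,
        phase=phase,
        body_mass=trace.body_mass,
        condition=trace.condition,
    )


def aggregate_by_phase(
    series: MetabolicSeries, schedule: PhotoperiodSchedule | None = None
) -> pd.DataFrame:
    """Unweighted day/night means of each derived variable.

    Returns a frame indexed by phase with columns per variable plus ``n``;
    a phase with no observations appears with ``n == 0`` and NaN means (the
    explicit missing-phase marker).  Means ignore undefined RER timestamps
    for the RER column only.
    """
    df = pd.DataFrame(
        {
            "vo2": series.vo2,
            "vco2": series.vco2,
            "rer": series.rer.values,
            "ee_kcal_h": series.ee,
            "phase": series.phase,
        }
    )
    out = {}
    for ph in ("day", "night"):
        sub = df[df["phase"] == ph]
        out[ph] = {
            "vo2": sub["vo2"].mean(),
            "vco2": sub["vco2"].mean(),
            "rer": sub["rer"].mean(),
            "ee_kcal_h": sub["ee_kcal_h"].mean(),
            "n": len(sub),
        }
    res = pd.DataFrame(out).T
    res.index.name = "phase"
    res["n"] = res["n"].astype(int)
    return res


# ---------------------------------------------------------------------------
# CSV interfaces

GAS_CSV_COLUMNS = [
    "animal_id",
    "datetime",
    "fi_o2",
    "fe_o2",
    "fi_co2",
    "fe_co2",
    "fr_i_ml_per_h",
    "body_mass_g",
]


def read_gas_traces(path) -> list[GasTrace]:
    """Read a long-format gas-trace CSV into one GasTrace per animal(-condition).

    Required columns: animal_id, datetime (ISO 8601), fi_o2, fe_o2, fi_co2,
    fe_co2, fr_i_ml_per_h, body_mass_g.  An optional ``condition`` column
    splits recordings of the same animal under different diets.  Any
    excurrent-flow column (``fr_e*``) is ignored with a logged notice.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RespirometryError(f"gas-trace CSV missing columns: {missing}")
    fre_cols = [c for c in df.columns if c.lower().startswith("fr_e")]
    if fre_cols:
        logger.info(
            "ignoring excurrent-flow column(s) %s: equations use FRi only", fre_cols
        )
    df["datetime"] = pd.to_datetime(df["datetime"])
    keys = ["animal_id"] + (["condition"] if "condition" in df.columns else [])
    traces = []
    for key, sub in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        sub = sub.sort_values("datetime")
        traces.append(
            GasTrace(
                animal_id=str(key[0]),
                condition=str(key[1]) if len(key) > 1 else "",
                timestamps=sub["datetime"].to_numpy(),
                fr_i=sub["fr_i_ml_per_h"].to_numpy(),
                fi_o2=sub["fi_o2"].to_numpy(),
                fe_o2=sub["fe_o2"].to_numpy(),
                fi_co2=sub["fi_co2"].to_numpy(),
                fe_co2=sub["fe_co2"].to_numpy(),
                body_mass=float(sub["body_mass_g"].iloc[0]) / 1000.0,
            )
        )
    return traces


def write_metabolic_series(series_list: list[MetabolicSeries], path) -> pd.DataFrame:
    """Write derived series (one row per timestamp) to CSV; returns the frame."""
    frame = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    frame.to_csv(path, index=False)
    return frame
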