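"""Extracellular-flux (mito stress test) metrics from OCR/ECAR plate traces.

A mito stress test measures the oxygen consumption rate (OCR, pmol O2 min-1)
and extracellular acidification rate (ECAR, mpH min-1) of cultured cells
over repeated measurement cycles: three baseline cycles, three after
oligomycin (ATP-synthase inhibition), three after FCCP (uncoupling, maximal
respiration), optionally followed by rotenone/antimycin A cycles that the
metrics below do not use.

All metrics are expressed per well as percentages of that well's own
baseline, which removes the cell-number (seeding-density) bias between
wells; wells are normalized first and averaged after:

* OxCR (oxidative coupling rate) = 100 * (mean baseline OCR - min
  post-oligomycin OCR) / mean baseline OCR -- the ATP-coupled share of
  baseline respiration.
* MtRC (mitochondrial reserve capacity) = 100 * (max post-FCCP OCR - mean
  baseline OCR) / mean baseline OCR -- spare respiratory capacity.
* GlcP (glycolytic potential) = 100 * (mean post-FCCP ECAR - mean baseline
  ECAR) / mean baseline ECAR.  Note the deliberate asymmetry: stressed OCR
  is the max of the three FCCP cycles while stressed ECAR is their mean.
* Metabolic potential: displacement of the stressed phenotype from the
  basal one on the (OCR %, ECAR %) plane, i.e. from (100, 100) to
  (100 + MtRC, 100 + GlcP); its scalar magnitude is the Euclidean norm of
  the displacement (one reasonable scalarization of a 2-D gap; the raw
  displacement is retained so alternatives remain possible).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROTOCOL_PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")
REQUIRED_PHASES = ("baseline", "oligomycin", "fccp")
CYCLES_PER_PHASE = 3


class FluxError(ValueError):
    pass


@dataclass
class WellTrace:
    """Ordered measurement cycles of one well, grouped by injection phase."""

    sample_id: str
    well: str
    ocr: dict  # phase -> np.ndarray of cycle values
    ecar: dict

    def qc_failure(self) -> str | None:
        """Reason this well fails QC, or None if usable."""
        for phase in REQUIRED_PHASES:
            if phase not in self.ocr or len(self.ocr[phase]) < CYCLES_PER_PHASE:
                return f"missing or short phase {phase!r}"
        if np.nanmean(self.ocr["baseline"][:CYCLES_PER_PHASE]) <= 0:
            return "nonpositive baseline OCR"
        if np.nanmean(self.ecar.get("baseline", np.array([np.nan]))[:CYCLES_PER_PHASE]) <= 0:
            return "nonpositive baseline ECAR"
        return None

    def _baseline_ocr(self) -> float:
        return float(np.mean(self.ocr["baseline"][:CYCLES_PER_PHASE]))

    def _baseline_ecar(self) -> float:
        return float(np.mean(self.ecar["baseline"][:CYCLES_PER_PHASE]))


def compute_oxcr(well: WellTrace) -> float:
    """Oxidative coupling rate, % of baseline OCR."""
    base = well._baseline_ocr()
    if base <= 0:
        raise FluxError(f"well {well.well}: baseline OCR mean <= 0")
    oligo_min = float(np.min(well.ocr["oligomycin"][:CYCLES_PER_PHASE]))
    return 100.0 * (base - oligo_min) / base


def compute_mtrc(well: WellTrace) -> float:
    """Mitochondrial reserve capacity, % of baseline OCR.

    Negative values (FCCP response below baseline) are legal degenerate
    plates; they are logged, not rejected.
    """
    base = well._baseline_ocr()
    if base <= 0:
        raise FluxError(f"well {well.well}: baseline OCR mean <= 0")
    fccp_max = float(np.max(well.ocr["fccp"][:CYCLES_PER_PHASE]))
    mtrc = 100.0 * (fccp_max - base) / base
    if mtrc < 0:
        logger.warning("well %s: negative reserve capacity %.1f%%", well.well, mtrc)
    return mtrc


def compute_glcp(well: WellTrace) -> float:
    """Glycolytic potential, % of baseline ECAR (mean of all FCCP cycles)."""
    base = well._baseline_ecar()
    if base <= 0:
        raise FluxError(f"well {well.well}: baseline ECAR mean <= 0")
    stressed = float(np.mean(well.ecar["fccp"][:CYCLES_PER_PHASE]))
    glcp = 100.0 * (stressed - base) / base
    if glcp < 0:
        logger.warning("well %s: negative glycolytic potential %.1f%%", well.well, glcp)
    return glcp


def metabolic_potential(well: WellTrace) -> tuple[float, float, float]:
    """(dOCR%, dECAR%, magnitude) from basal (100, 100) to stressed phenotype."""
    d_ocr = compute_mtrc(well)
    d_ecar = compute_glcp(well)
    return d_ocr, d_ecar, math.hypot(d_ocr, d_ecar)


@dataclass
class MitoMetrics:
    """Per-sample mito-stress metrics (means of per-well % metrics)."""

    sample_id: str
    oxcr: float | None
    mtrc: float | None
    glcp: float | None
    potential_d_ocr: float | None
    potential_d_ecar: float | None
    potential_magnitude: float | None
    n_wells: int
    excluded: list = field(default_factory=list)  # (well, reason)

    @property
    def missing(self) -> bool:
        return self.n_wells == 0


def aggregate_sample(sample_id: str, wells: list[WellTrace]) -> MitoMetrics:
    """Normalize per well, then average across QC-passing wells.

    Wells with a missing protocol phase or nonpositive baseline are excluded
    with a logged reason (culture-contamination attrition); with zero valid
    wells the result is an explicit missing-sample marker, never zero.
    """
    rows, excluded = [], []
    for w in wells:
        reason = w.qc_failure()
        if reason is not None:
            logger.info("sample %s well %s excluded: %s", sample_id, w.well, reason)
            excluded.append((w.well, reason))
            continue
        d_ocr, d_ecar, mag = metabolic_potential(w)  # d_ocr==MtRC, d_ecar==GlcP
        rows.append((compute_oxcr(w), d_ocr, d_ecar, d_ocr, d_ecar, mag))
    if not rows:
        return MitoMetrics(sample_id, None, None, None, None, None, None, 0, excluded)
    arr = np.array(rows)
    m = arr.mean(axis=0)
    return MitoMetrics(
        sample_id,
        oxcr=m[0],
        mtrc=m[1],
        glcp=m[2],
        potential_d_ocr=m[3],
        potential_d_ecar=m[4],
        potential_magnitude=m[5],
        n_wells=len(rows),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# CSV interface

FLUX_CSV_COLUMNS = ["sample_id", "well", "cycle_index", "phase", "ocr_pmol_min", "ecar_mpH_min"]


def read_flux_plate(path) -> dict:
    """Read a flux-plate CSV into {sample_id: [WellTrace, ...]}."""
    df = pd.read_csv(path)
    missing = [c for c in FLUX_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FluxError(f"flux CSV missing columns: {missing}")
    unknown = set(df["phase"].unique()) - set(PROTOCOL_PHASES)
    if unknown:
        raise FluxError(f"unknown injection phases: {sorted(unknown)}")
    samples: dict = {}
    for (sid, well), sub in df.groupby(["sample_id", "well"], sort=True):
        sub = sub.sort_values("cycle_index")
        order = [PROTOCOL_PHASES.index(p) for p in sub["phase"]]
        if order != sorted(order):
            raise FluxError(f"well {well}: phases out of protocol order")
        ocr = {p: g["ocr_pmol_min"].to_numpy(float) for p, g in sub.groupby("phase")}
        ecar = {p: g["ecar_mpH_min"].to_numpy(float) for p, g in sub.groupby("phase")}
        samples.setdefault(str(sid), []).append(
            WellTrace(sample_id=str(sid), well=str(well), ocr=ocr, ecar=ecar)
        )
    return samples


def metrics_table(metrics: list[MitoMetrics], meta: dict | None = None) -> pd.DataFrame:
    """One MitoMetrics row per sample, for CSV export."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "sample_id": m.sample_id,
                "oxcr": m.oxcr,
                "mtrc": m.mtrc,
                "glcp": m.glcp,
                "potential_d_ocr": m.potential_d_ocr,
                "potential_d_ecar": m.potential_d_ecar,
                "potential_magnitude": m.potential_magnitude,
                "n_wells": m.n_wells,
                **(meta or {}),
            }
        )
    return pd.DataFrame(rows)
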