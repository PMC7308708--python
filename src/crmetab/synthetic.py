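"""Synthetic paired-cohort experiment generator.

Generates a complete six-female + six-male paired CTL -> CR experiment with
the statistical structure the downstream stages assume -- circadian gas
traces, triplicate-well flux plates, repeated-triplicate qPCR Cts, and a
creatinine/blood biomarker panel -- parameterized by the published group
means and SDs in :mod:`crmetab.reference`.  Every output is fully
determined by the seed, and the generator records its ground truth (the
per-animal programmed values) in a manifest so that round-trip and
parameter-recovery tests are possible.

Gas traces are built by inverting the respirometry equations rather than
simulating chamber physics: a target VO2 and RER daily profile is chosen
per animal-condition (night plateau with a nocturnal peak, day plateau with
a diurnal trough, smoothed by a fixed-width logistic ramp -- the simplest
shape with unambiguous ground-truth extrema; the CR fuel switch appears
through the lower programmed night RER and the advanced trough time), VCO2
follows as RER * VO2, and the excurrent gas fractions are solved for given
the fixed incurrent composition, flow and body mass.  Measurement noise is
multiplicative on VO2/VCO2 before the inversion, so the noise model lives
on the scale the analysis equations see.

The animal-level spread always follows the published group SDs (that is the
biology); ``noise_scale`` scales only the measurement noise, so
``noise_scale=0`` yields exact round-trips against the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference as ref
from .biomarkers import QpcrRecord
from .flux_assay import WellTrace
from .photoperiod import MINUTES_PER_DAY, PhotoperiodSchedule
from .respirometry import EE_INTERCEPT, EE_SLOPE, GasTrace


class SyntheticError(ValueError):
    pass


@dataclass
class CohortDesign:
    """Parameters of the synthetic experiment.

    Defaults are the study conditions: 6 animals per sex, paired CTL/CR, a
    14 h-light photoperiod (lights off 17:00), 4 recording days sampled
    every 10 min, and effect sizes from the published group table.
    """

    n_per_sex: int = 6
    schedule: PhotoperiodSchedule = field(default_factory=PhotoperiodSchedule)
    sampling_interval_min: int = 10
    n_days: int = 4
    noise_scale: float = 1.0
    well_dropout_p: float = 0.0
    qpcr_efficiency: float = 2.0
    seed: int = 0
    effects: dict = field(default_factory=lambda: ref.GROUP_STATS)
    clock_effects: dict = field(default_factory=lambda: ref.CLOCK_STATS)
    # circadian profile shape (fractions of the local plateau level)
    peak_len_min: int = 180
    trough_len_min: int = 240
    vo2_peak_frac: float = 0.15
    vo2_trough_frac: float = 0.30
    rer_peak_frac: float = 0.025
    rer_trough_frac: float = 0.05
    #: logistic-ramp width for transition smoothing, minutes; the default 0
    #: keeps the square wave exact so programmed extrema times are
    #: unambiguous to within one sampling interval
    ramp_min: float = 0.0
    #: fractional SD of multiplicative measurement noise at noise_scale=1
    gas_noise_frac: float = 0.02
    flux_noise_frac: float = 0.02
    assay_noise_frac: float = 0.05
    ct_jitter_sd: float = 0.08
    glucometer_sd: float = 3.0
    glycaemia_normal_range: tuple = (50.0, 150.0)

    def __post_init__(self) -> None:
        if self.n_per_sex < 1:
            raise SyntheticError("n_per_sex must be >= 1")
        for var, spec in self.effects.items():
            for sex in ("F", "M"):
                for cond in ("CTL", "CR"):
                    mean, sd = spec[sex][cond]
                    if sd < 0:
                        raise SyntheticError(f"{var} {sex}/{cond}: negative SD")
                    if spec["dist"] == "lognormal" and mean <= 0:
                        raise SyntheticError(
                            f"{var} {sex}/{cond}: nonpositive mean for a "
                            "strictly positive analyte"
                        )

    @property
    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, sex) pairs."""
        out = []
        for sex in ("F", "M"):
            out += [(f"{sex}{i + 1}", sex) for i in range(self.n_per_sex)]
        return out


@dataclass
class SyntheticCohort:
    design: CohortDesign
    gas_traces: list  # GasTrace
    flux_wells: dict  # sample_id -> [WellTrace]
    qpcr_records: list  # QpcrRecord
    biomarker_panel: pd.DataFrame
    design_table: pd.DataFrame
    manifest: dict  # "animal|cond" -> ground-truth dict


# ---------------------------------------------------------------------------
# draws


def _lognormal_mean_sd(rng, mean, sd, n):
    if sd == 0:
        return np.full(n, float(mean))
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(s2), size=n))


def _draw(rng, dist, mean, sd, n):
    if dist == "lognormal":
        return _lognormal_mean_sd(rng, mean, sd, n)
    return rng.normal(mean, sd, size=n)


_CLAMPS = {
    # (low, high) clamps applied to animal-level draws, by variable
    "oxcr": (1.0, 99.0),
    "mtrc": (-90.0, None),
    "glcp": (-90.0, None),
    "rer_night_mean": (0.6, 1.15),
    "rer_day_mean": (0.6, 1.15),
    "vo2_night_mean": (200.0, None),
    "vo2_day_mean": (200.0, None),
}


def _clamp(var, x, mean):
    lo, hi = _CLAMPS.get(var, (None, None))
    if lo is None and var not in _CLAMPS:
        # strictly positive floor for everything that is not a % change
        lo = 0.05 * abs(mean) if mean != 0 else None
    if lo is not None:
        x = np.maximum(x, lo)
    if hi is not None:
        x = np.minimum(x, hi)
    return x


def _draw_targets(design: CohortDesign, rng) -> dict:
    """Animal-level programmed values for every scalar endpoint and clock time."""
    targets: dict = {}
    animals = design.animals
    nf = design.n_per_sex
    for var, spec in design.effects.items():
        for cond in ("CTL", "CR"):
            for sex in ("F", "M"):
                mean, sd = spec[sex][cond]
                vals = _draw(rng, spec["dist"], mean, sd, nf)
                vals = _clamp(var, vals, mean)
                ids = [a for a, s in animals if s == sex]
                for aid, v in zip(ids, vals):
                    targets.setdefault((aid, cond), {})[var] = float(v)
    # clock times: normal draws in minutes, clamped into their daily window
    sched = design.schedule
    day_len = MINUTES_PER_DAY - sched.night_length_min
    # leave room for a detectable plateau piece (several samples) between
    # the window edge and the programmed excursion
    margin = 2.0 * design.ramp_min + 4.0 * design.sampling_interval_min
    for var, spec in design.clock_effects.items():
        is_max = var.endswith("hmax")
        length = design.peak_len_min if is_max else design.trough_len_min
        if is_max:
            lo = sched.off_minutes + margin
            hi = sched.off_minutes + sched.night_length_min - length - margin
        else:
            lo = sched.on_minutes + margin
            hi = sched.on_minutes + day_len - length - margin
        for cond in ("CTL", "CR"):
            for sex in ("F", "M"):
                mean, sd = spec[sex][cond]
                # express relative to window start to clamp on a line
                base = sched.off_minutes if is_max else sched.on_minutes
                rel = (mean - base) % MINUTES_PER_DAY + base
                vals = np.clip(rng.normal(rel, sd, size=nf), lo, hi)
                ids = [a for a, s in animals if s == sex]
                for aid, v in zip(ids, vals):
                    targets[(aid, cond)][var] = float(v % MINUTES_PER_DAY)
    return targets


# ---------------------------------------------------------------------------
# gas traces


def _logistic_kernel(ramp_min: float) -> np.ndarray:
    if ramp_min <= 0:
        return np.array([1.0])
    # support confined to +-ramp_min so a transition stays within one
    # sampling interval of its programmed minute
    scale = ramp_min / 6.0
    half = int(np.ceil(ramp_min))
    x = np.arange(-half, half + 1, dtype=float)
    k = 1.0 / (4.0 * scale) / np.cosh(x / (2.0 * scale)) ** 2  # logistic pdf
    return k / k.sum()


def _smooth_circular(day_profile: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if len(kernel) == 1:
        return day_profile
    tripled = np.concatenate([day_profile] * 3)
    sm = np.convolve(tripled, kernel, mode="same")
    n = len(day_profile)
    return sm[n : 2 * n]


def _daily_profile(
    design: CohortDesign,
    day_mean: float,
    night_mean: float,
    peak_start: float,
    trough_start: float,
    peak_frac: float,
    trough_frac: float,
    kernel: np.ndarray,
) -> np.ndarray:
    """Minute-resolution daily profile with the requested phase means.

    Plateau levels are solved so that the (unsmoothed) day-window mean and
    night-window mean equal the targets despite the trough/peak excursions.
    """
    sched = design.schedule
    minutes = np.arange(MINUTES_PER_DAY)
    night = sched.is_night(minutes)
    day_len = MINUTES_PER_DAY - sched.night_length_min
    lam_d = design.trough_len_min / day_len
    lam_n = design.peak_len_min / sched.night_length_min
    d_base = day_mean / (1.0 - trough_frac * lam_d)
    n_base = night_mean / (1.0 + peak_frac * lam_n)
    prof = np.where(night, n_base, d_base).astype(float)
    in_trough = (minutes - trough_start) % MINUTES_PER_DAY < design.trough_len_min
    prof[in_trough] = d_base * (1.0 - trough_frac)
    in_peak = (minutes - peak_start) % MINUTES_PER_DAY < design.peak_len_min
    prof[in_peak] = n_base * (1.0 + peak_frac)
    return _smooth_circular(prof, kernel)


def _invert_gas_fractions(vo2, vco2, mass_kg, flow=ref.FLOW_ML_PER_H):
    """Solve for the excurrent fractions that reproduce (VO2, VCO2).

    Fixed-point iteration on the pair of flow equations; converges in a few
    steps because the cross terms are O(1e-2).
    """
    u = np.asarray(vo2, float) * mass_kg / flow
    v = np.asarray(vco2, float) * mass_kg / flow
    b = ref.FI_CO2 + v
    a = ref.FI_O2 - u
    for _ in range(60):
        a = (ref.FI_O2 - u) / (1.0 + b - ref.FI_CO2 - u)
        b_new = (v + ref.FI_CO2) / (1.0 - ref.FI_O2 + a + v)
        if np.max(np.abs(b_new - b)) < 1e-16:
            b = b_new
            break
        b = b_new
    if np.any((a <= 0) | (a >= 1) | (b <= 0) | (b >= 1)):
        raise SyntheticError(
            "target profile yields gas fractions outside (0, 1); "
            "lower the target VO2/VCO2 or raise the flow"
        )
    return a, b


_CTL_START = np.datetime64("2020-08-24T03:00:00")
_CR_START = np.datetime64("2020-09-14T03:00:00")


def _gen_gas_trace(design, rng, animal_id, cond, tgt, manifest_entry):
    sched = design.schedule
    dt = design.sampling_interval_min
    n = design.n_days * MINUTES_PER_DAY // dt
    rel_min = np.arange(n) * dt  # minutes since recording start (03:00)
    start = _CTL_START if cond == "CTL" else _CR_START
    timestamps = start + rel_min.astype("timedelta64[m]")
    start_mod = (start.astype("datetime64[m]").astype("int64")) % MINUTES_PER_DAY
    mod = (rel_min + start_mod) % MINUTES_PER_DAY

    kernel = _logistic_kernel(design.ramp_min)
    vo2_day = _daily_profile(
        design,
        tgt["vo2_day_mean"],
        tgt["vo2_night_mean"],
        tgt["vo2_hmax"],
        tgt["vo2_hmin"],
        design.vo2_peak_frac,
        design.vo2_trough_frac,
        kernel,
    )
    rer_day = _daily_profile(
        design,
        tgt["rer_day_mean"],
        tgt["rer_night_mean"],
        tgt["rer_hmax"],
        tgt["rer_hmin"],
        design.rer_peak_frac,
        design.rer_trough_frac,
        kernel,
    )
    vo2 = vo2_day[mod]
    rer = rer_day[mod]
    vco2 = rer * vo2
    mass_kg = tgt["body_mass"] / 1000.0
    ee = (EE_INTERCEPT + EE_SLOPE * rer) * (vo2 / 1000.0) * mass_kg

    # ground truth from the realized noiseless profile
    night_mask = sched.is_night(mod)
    for name, series in (("vo2", vo2), ("rer", rer), ("ee", ee)):
        manifest_entry[f"{name}_day_mean_true"] = float(series[~night_mask].mean())
        manifest_entry[f"{name}_night_mean_true"] = float(series[night_mask].mean())
    for key in ("vo2_hmax", "vo2_hmin", "rer_hmax", "rer_hmin"):
        manifest_entry[key + "_true"] = tgt[key]

    sig = design.gas_noise_frac * design.noise_scale
    if sig > 0:
        vo2 = vo2 * np.exp(rng.normal(0, sig, n) - sig**2 / 2)
        vco2 = vco2 * np.exp(rng.normal(0, sig, n) - sig**2 / 2)
    fe_o2, fe_co2 = _invert_gas_fractions(vo2, vco2, mass_kg)
    return GasTrace(
        animal_id=animal_id,
        condition=cond,
        timestamps=timestamps,
        fr_i=np.full(n, ref.FLOW_ML_PER_H),
        fi_o2=np.full(n, ref.FI_O2),
        fe_o2=fe_o2,
        fi_co2=np.full(n, ref.FI_CO2),
        fe_co2=fe_co2,
        body_mass=mass_kg,
    )


# ---------------------------------------------------------------------------
# plates, qPCR, biomarkers


def _noise_factor(rng, frac, scale, size):
    sig = frac * scale
    if sig <= 0:
        return np.ones(size)
    return np.exp(rng.normal(0, sig, size) - sig**2 / 2)


def _extreme_factor_of_three(sigma: float) -> tuple[float, float]:
    """E[min] and E[max] of three iid unit-mean lognormal noise factors.

    The coupling metric takes the min of the oligomycin cycles and the
    reserve metric the max of the FCCP cycles, so unbiased recovery of a
    programmed target requires dividing the programmed plateau by the
    expected extreme of the noise factors (1 at zero noise).  Computed by
    Gauss-Hermite quadrature of 3*E[(1-Phi(Z+s))^2] and 3*E[Phi(Z+s)^2].
    """
    if sigma <= 0:
        return 1.0, 1.0
    from scipy.stats import norm

    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / np.sqrt(2.0 * np.pi)
    cdf = norm.cdf(nodes + sigma)
    c_min = float(3.0 * np.sum(w * (1.0 - cdf) ** 2))
    c_max = float(3.0 * np.sum(w * cdf**2))
    return c_min, c_max


def _gen_flux_sample(design, rng, sample_id, tgt):
    sigma = design.flux_noise_frac * design.noise_scale
    c_min, c_max = _extreme_factor_of_three(sigma)
    wells = []
    for w in range(3):
        if design.well_dropout_p > 0 and rng.random() < design.well_dropout_p:
            continue
        level = 300.0 * float(_lognormal_mean_sd(rng, 1.0, 0.15, 1)[0])
        ecar0 = 10.0 * float(_lognormal_mean_sd(rng, 1.0, 0.15, 1)[0])
        nf = lambda k: _noise_factor(rng, design.flux_noise_frac, design.noise_scale, k)
        ocr = {
            "baseline": level * nf(3),
            "oligomycin": level * (1 - tgt["oxcr"] / 100.0) / c_min * nf(3),
            "fccp": level * (1 + tgt["mtrc"] / 100.0) / c_max * nf(3),
            "rot_aa": level * 0.12 * nf(3),
        }
        ecar = {
            "baseline": ecar0 * nf(3),
            "oligomycin": ecar0 * 1.1 * nf(3),
            "fccp": ecar0 * (1 + tgt["glcp"] / 100.0) * nf(3),
            "rot_aa": ecar0 * 1.05 * nf(3),
        }
        wells.append(WellTrace(sample_id=sample_id, well=f"W{w + 1}", ocr=ocr, ecar=ecar))
    return wells


def _gen_qpcr(design, rng, sample_id, tgt):
    ratio = tgt["mtnu_ratio"]
    e = design.qpcr_efficiency
    ct_nu_center = 25.0
    ct_mt_center = ct_nu_center - np.log(ratio) / np.log(e)
    jit = design.ct_jitter_sd * design.noise_scale
    ct_nu = ct_nu_center + (rng.normal(0, jit, 6) if jit > 0 else np.zeros(6))
    ct_mt = ct_mt_center + (rng.normal(0, jit, 6) if jit > 0 else np.zeros(6))
    return QpcrRecord(sample_id=sample_id, ct_mt=ct_mt, ct_nu=ct_nu, efficiency=e)


_URINARY = ("cortisol", "ohdg8", "estradiol", "testosterone")
_BLOOD = ("thiols", "gpx", "t4", "body_mass")


def _gen_biomarker_rows(design, rng, animal_id, sex, cond, tgt):
    rows = []
    creatinine = float(_lognormal_mean_sd(rng, 1.0, 0.25, 1)[0])
    for analyte in _URINARY:
        fac = float(_noise_factor(rng, design.assay_noise_frac, design.noise_scale, 1)[0])
        rows.append(
            dict(
                animal_id=animal_id,
                sex=sex,
                condition=cond,
                analyte=analyte,
                replicate=1,
                value=tgt[analyte] * creatinine * fac,
                creatinine=creatinine,
            )
        )
    for analyte in _BLOOD:
        fac = float(_noise_factor(rng, design.assay_noise_frac, design.noise_scale, 1)[0])
        rows.append(
            dict(
                animal_id=animal_id,
                sex=sex,
                condition=cond,
                analyte=analyte,
                replicate=1,
                value=tgt[analyte] * fac,
                creatinine=np.nan,
            )
        )
    # bedside glucose with the repeat rule
    sig = design.glucometer_sd * design.noise_scale
    first = tgt["glycaemia"] + (rng.normal(0, sig) if sig > 0 else 0.0)
    readings = [first]
    lo, hi = design.glycaemia_normal_range
    if not (lo < first < hi):
        extra = tgt["glycaemia"] + (rng.normal(0, sig, 2) if sig > 0 else np.zeros(2))
        readings += list(extra)
    for k, r in enumerate(readings, start=1):
        rows.append(
            dict(
                animal_id=animal_id,
                sex=sex,
                condition=cond,
                analyte="glycaemia",
                replicate=k,
                value=float(r),
                creatinine=np.nan,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# top level


def generate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate the full synthetic experiment for a design (seed-determined)."""
    seeds = np.random.SeedSequence(design.seed).spawn(5)
    rng_targets = np.random.default_rng(seeds[0])
    rng_gas = np.random.default_rng(seeds[1])
    rng_flux = np.random.default_rng(seeds[2])
    rng_qpcr = np.random.default_rng(seeds[3])
    rng_bio = np.random.default_rng(seeds[4])

    targets = _draw_targets(design, rng_targets)
    manifest: dict = {}
    gas_traces, qpcr_records, bio_rows = [], [], []
    flux_wells: dict = {}
    for (aid, sex) in design.animals:
        for cond in ("CTL", "CR"):
            tgt = targets[(aid, cond)]
            key = f"{aid}|{cond}"
            entry = {f"{k}_true": v for k, v in tgt.items() if not k.endswith("hmax") and not k.endswith("hmin")}
            entry.update(animal_id=aid, sex=sex, condition=cond)
            gas_traces.append(_gen_gas_trace(design, rng_gas, aid, cond, tgt, entry))
            sample_id = f"{aid}_{cond}"
            flux_wells[sample_id] = _gen_flux_sample(design, rng_flux, sample_id, tgt)
            qpcr_records.append(_gen_qpcr(design, rng_qpcr, sample_id, tgt))
            bio_rows.extend(_gen_biomarker_rows(design, rng_bio, aid, sex, cond, tgt))
            manifest[key] = entry
    panel = pd.DataFrame(bio_rows)
    design_table = pd.DataFrame(
        [{"animal_id": a, "sex": s} for a, s in design.animals]
    )
    return SyntheticCohort(
        design=design,
        gas_traces=gas_traces,
        flux_wells=flux_wells,
        qpcr_records=qpcr_records,
        biomarker_panel=panel,
        design_table=design_table,
        manifest=manifest,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the four fixture CSV families plus the ground-truth manifest.

    Returns the mapping of logical names to file paths.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gas": out / "gas_traces.csv",
        "flux": out / "flux_plates.csv",
        "qpcr": out / "qpcr.csv",
        "biomarkers": out / "biomarkers.csv",
        "design": out / "design.csv",
        "manifest": out / "manifest.json",
    }
    gas_frames = []
    for tr in cohort.gas_traces:
        gas_frames.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "condition": tr.condition,
                    "datetime": tr.timestamps.astype("datetime64[s]").astype(str),
                    "fi_o2": tr.fi_o2,
                    "fe_o2": tr.fe_o2,
                    "fi_co2": tr.fi_co2,
                    "fe_co2": tr.fe_co2,
                    "fr_i_ml_per_h": tr.fr_i,
                    "body_mass_g": tr.body_mass * 1000.0,
                }
            )
        )
    pd.concat(gas_frames, ignore_index=True).to_csv(paths["gas"], index=False)

    flux_rows = []
    for sid, wells in cohort.flux_wells.items():
        for w in wells:
            idx = 0
            for phase in ("baseline", "oligomycin", "fccp", "rot_aa"):
                if phase not in w.ocr:
                    continue
                for c in range(len(w.ocr[phase])):
                    idx += 1
                    flux_rows.append(
                        dict(
                            sample_id=sid,
                            well=w.well,
                            cycle_index=idx,
                            phase=phase,
                            ocr_pmol_min=w.ocr[phase][c],
                            ecar_mpH_min=w.ecar[phase][c],
                        )
                    )
    pd.DataFrame(flux_rows).to_csv(paths["flux"], index=False)

    qpcr_rows = []
    for rec in cohort.qpcr_records:
        for tgt_name, arr in (("mt", rec.ct_mt), ("nu", rec.ct_nu)):
            for k, ct in enumerate(arr, start=1):
                qpcr_rows.append(
                    dict(sample_id=rec.sample_id, target=tgt_name, replicate=k, ct=ct)
                )
    pd.DataFrame(qpcr_rows).to_csv(paths["qpcr"], index=False)

    cohort.biomarker_panel.to_csv(paths["biomarkers"], index=False)
    cohort.design_table.to_csv(paths["design"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(cohort.manifest, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
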