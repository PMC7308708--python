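"""Round-trip and parameter-recovery checks of the synthetic pipeline.

These helpers run the analysis modules over generated cohorts and compare
the results with the generator's ground truth: per-endpoint recovered
values straight from the fixtures, and the rate at which recovered group
means fall within two standard errors of the programmed group means across
independently seeded cohorts.  They are used by the test suite, the
acceptance script and the analysis drivers alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reference as ref
from .biomarkers import mtnu_ratio, resolve_glycaemia
from .flux_assay import aggregate_sample
from .photoperiod import PhotoperiodSchedule
from .respirometry import aggregate_by_phase, derive_series
from .synthetic import CohortDesign, SyntheticCohort, generate_cohort


def recovered_endpoints(cohort: SyntheticCohort) -> pd.DataFrame:
    """Recompute every scalar endpoint from the cohort's raw fixtures.

    One row per animal-condition, one column per endpoint named as in the
    reference table (gas phase means included).
    """
    schedule = cohort.design.schedule
    rec: dict = {}
    for tr in cohort.gas_traces:
        s = derive_series(tr, schedule)
        agg = aggregate_by_phase(s)
        entry = rec.setdefault((tr.animal_id, tr.condition), {})
        for var, col in (("vo2", "vo2"), ("rer", "rer")):
            for ph in ("day", "night"):
                entry[f"{var}_{ph}_mean"] = agg.loc[ph, col]
    for sid, wells in cohort.flux_wells.items():
        aid, cond = sid.rsplit("_", 1)
        m = aggregate_sample(sid, wells)
        rec.setdefault((aid, cond), {}).update(oxcr=m.oxcr, mtrc=m.mtrc, glcp=m.glcp)
    for q in cohort.qpcr_records:
        aid, cond = q.sample_id.rsplit("_", 1)
        rec[(aid, cond)]["mtnu_ratio"] = mtnu_ratio(q)
    panel = cohort.biomarker_panel
    for (aid, cond), sub in panel.groupby(["animal_id", "condition"]):
        entry = rec[(aid, cond)]
        for _, r in sub.iterrows():
            if r.analyte == "glycaemia":
                continue
            entry[r.analyte] = (
                r.value / r.creatinine if np.isfinite(r.creatinine) else r.value
            )
        gly = sub[sub.analyte == "glycaemia"].sort_values("replicate")["value"]
        entry["glycaemia"] = resolve_glycaemia(
            gly.tolist(), cohort.design.glycaemia_normal_range
        ).value
    out = pd.DataFrame(
        [{"animal_id": k[0], "condition": k[1], **v} for k, v in rec.items()]
    )
    sexes = {a: s for a, s in cohort.design.animals}
    out["sex"] = out["animal_id"].map(sexes)
    return out


def two_sem_recovery_rate(
    n_seeds: int = 100, base_seed: int = 0, design_kwargs: dict | None = None
) -> float:
    """Fraction of (variable, sex, condition) group means recovered within
    2 SEM of their programmed values across independently seeded cohorts."""
    checks = []
    for i in range(n_seeds):
        design = CohortDesign(seed=base_seed + i, **(design_kwargs or {}))
        cohort = generate_cohort(design)
        recovered = recovered_endpoints(cohort)
        for var, spec in design.effects.items():
            for sex in ("F", "M"):
                for cond in ("CTL", "CR"):
                    mean, sd = spec[sex][cond]
                    sem = sd / np.sqrt(design.n_per_sex)
                    got = recovered.loc[
                        (recovered.sex == sex) & (recovered.condition == cond), var
                    ].mean()
                    checks.append(abs(got - mean) <= 2 * sem)
    return float(np.mean(checks))


def zero_noise_roundtrip_errors(seed: int = 0, design_kwargs: dict | None = None) -> dict:
    """Worst-case round-trip errors of a noiseless cohort against its manifest.

    Returns the maximum relative error over all phase means / flux metrics /
    copy-number ratios and the maximum circular clock-time error (minutes)
    of the recovered extrema.
    """
    from .circadian import extract_extrema, segment_series, time_shift

    design = CohortDesign(seed=seed, noise_scale=0.0, **(design_kwargs or {}))
    cohort = generate_cohort(design)
    schedule = design.schedule
    recovered = recovered_endpoints(cohort).set_index(["animal_id", "condition"])
    max_rel = 0.0
    for key, truth in cohort.manifest.items():
        aid, cond = key.split("|")
        row = recovered.loc[(aid, cond)]
        for var in ("vo2_day_mean", "vo2_night_mean", "rer_day_mean", "rer_night_mean",
                    "oxcr", "mtrc", "glcp", "mtnu_ratio", "cortisol", "glycaemia"):
            want = truth[f"{var}_true"]
            max_rel = max(max_rel, abs(row[var] - want) / max(abs(want), 1e-12))
    max_time = 0.0
    for tr in cohort.gas_traces:
        truth = cohort.manifest[f"{tr.animal_id}|{tr.condition}"]
        s = derive_series(tr, schedule)
        for var, values in (("vo2", s.vo2), ("rer", s.rer.values)):
            seg = segment_series(values)
            ex = extract_extrema(seg, tr.timestamps, schedule)
            for kind, got in (("hmax", ex.h_max), ("hmin", ex.h_min)):
                err = abs(time_shift(truth[f"{var}_{kind}_true"], got))
                max_time = max(max_time, err)
    return {
        "max_rel_err": max_rel,
        "max_extremum_err_min": max_time,
        "sampling_interval_min": design.sampling_interval_min,
    }
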