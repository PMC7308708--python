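"""End-to-end orchestration: traces -> metrics -> response table -> report.

The pipeline runs the five analysis stages in experiment order --
respirometry, circadian extrema, extracellular flux, biomarkers, cohort
statistics -- from the four input CSV families, and writes a report bundle:
per-timestamp metabolic series, day/night phase means, changepoint extrema
with clock times and CTL->CR shifts, polar-diagram coordinates, flux
metrics, the normalized biomarker panel, a group report with per-individual
percent changes and exact-test annotations, a correlation-network edge
list, PCA exports, and a JSON run log (seed, configuration, per-stage
record counts).  Any stage failure aborts with the stage name and offending
record; outputs of completed stages are left on disk.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biomarkers as bio
from . import circadian as circ
from . import cohort_stats as cs
from . import flux_assay as flux
from . import respirometry as resp
from .photoperiod import PhotoperiodSchedule, format_clock

logger = logging.getLogger(__name__)

GAS_VARIABLES = ("vo2", "rer", "ee")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable, flat keys)."""

    gas_csv: str = ""
    flux_csv: str = ""
    qpcr_csv: str = ""
    biomarker_csv: str = ""
    design_csv: str = ""
    outdir: str = "pipeline_out"
    lights_off: str = "17:00"
    lights_on: str = "03:00"
    changepoint_penalty: float | None = None  # None = scale-aware default
    min_seg_len: int = 3
    qpcr_efficiency: float = 2.0
    glycaemia_low: float = 50.0
    glycaemia_high: float = 150.0
    corr_method: str = "pearson"
    corr_threshold: float = 0.5
    seed: int = 0

    @property
    def schedule(self) -> PhotoperiodSchedule:
        return PhotoperiodSchedule(lights_off=self.lights_off, lights_on=self.lights_on)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate_inputs(self) -> None:
        for name in ("gas_csv", "flux_csv", "qpcr_csv", "biomarker_csv", "design_csv"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name}: missing input file {p!r}")


# ---------------------------------------------------------------------------
# stages


def run_respirometry(config: RunConfig, outdir: Path):
    schedule = config.schedule
    traces = resp.read_gas_traces(config.gas_csv)
    series = [resp.derive_series(t, schedule) for t in traces]
    resp.write_metabolic_series(series, outdir / "metabolic_series.csv")
    rows = []
    for s in series:
        means = resp.aggregate_by_phase(s, schedule)
        for phase in means.index:
            for var in ("vo2", "vco2", "rer", "ee_kcal_h"):
                rows.append(
                    dict(
                        animal_id=s.animal_id,
                        condition=s.condition,
                        phase=phase,
                        variable=var,
                        mean=means.loc[phase, var],
                        n=int(means.loc[phase, "n"]),
                    )
                )
    phase_means = pd.DataFrame(rows)
    phase_means.to_csv(outdir / "phase_means.csv", index=False)
    return series, phase_means


def run_circadian(config: RunConfig, series_list, outdir: Path):
    schedule = config.schedule
    rows = []
    for s in series_list:
        for var in GAS_VARIABLES:
            values = {"vo2": s.vo2, "rer": s.rer.values, "ee": s.ee}[var]
            values = np.nan_to_num(values, nan=float(np.nanmean(values)))
            seg = circ.segment_series(
                values, penalty=config.changepoint_penalty, min_seg_len=config.min_seg_len
            )
            ex = circ.extract_extrema(seg, s.timestamps, schedule, variable=var)
            rows.append(
                dict(
                    animal_id=s.animal_id,
                    condition=s.condition,
                    variable=var,
                    max=ex.max_value,
                    h_max=ex.h_max_clock,
                    h_max_min=ex.h_max,
                    min=ex.min_value,
                    h_min=ex.h_min_clock,
                    h_min_min=ex.h_min,
                )
            )
    extrema = pd.DataFrame(rows)

    # CTL -> CR clock-time shifts per animal and variable
    shifts = []
    for (aid, var), sub in extrema.groupby(["animal_id", "variable"]):
        ctl = sub[sub["condition"] == "CTL"]
        cr = sub[sub["condition"] == "CR"]
        if len(ctl) != 1 or len(cr) != 1:
            continue
        rec = {"animal_id": aid, "variable": var}
        for col, name in (("h_max_min", "shift_hmax_min"), ("h_min_min", "shift_hmin_min")):
            a, b = ctl[col].iloc[0], cr[col].iloc[0]
            rec[name] = circ.time_shift(a, b) if pd.notna(a) and pd.notna(b) else np.nan
        shifts.append(rec)
    shifts = pd.DataFrame(shifts)
    extrema = extrema.merge(shifts, on=["animal_id", "variable"], how="left")
    # shifts describe the CR recording relative to its own CTL baseline
    extrema.loc[extrema["condition"] == "CTL", ["shift_hmax_min", "shift_hmin_min"]] = np.nan
    extrema.to_csv(outdir / "extrema.csv", index=False)

    # polar coordinates: one concentric circle per sex x condition group
    return extrema


def export_polar(extrema: pd.DataFrame, design_table: pd.DataFrame, outdir: Path):
    df = extrema.merge(design_table, on="animal_id", how="left")
    group_rank = {("M", "CR"): 1, ("M", "CTL"): 2, ("F", "CR"): 3, ("F", "CTL"): 4}
    rows = []
    for _, r in df.iterrows():
        rank = group_rank.get((r.get("sex"), r["condition"]), 0)
        for kind, col in (("h_max", "h_max_min"), ("h_min", "h_min_min")):
            if pd.isna(r[col]):
                continue
            rows.append(
                dict(
                    variable=r["variable"],
                    extremum=kind,
                    animal_id=r["animal_id"],
                    sex=r.get("sex"),
                    condition=r["condition"],
                    angle_rad=circ.to_polar(r[col]),
                    radius_rank=rank,
                )
            )
    polar = pd.DataFrame(rows)
    polar.to_csv(outdir / "polar.csv", index=False)
    return polar


def run_flux(config: RunConfig, outdir: Path):
    samples = flux.read_flux_plate(config.flux_csv)
    metrics = [flux.aggregate_sample(sid, wells) for sid, wells in sorted(samples.items())]
    table = flux.metrics_table(metrics)
    split = table["sample_id"].str.rsplit("_", n=1, expand=True)
    table["animal_id"], table["condition"] = split[0], split[1]
    table.to_csv(outdir / "flux_metrics.csv", index=False)
    return table


def run_biomarkers(config: RunConfig, outdir: Path):
    panel = pd.read_csv(config.biomarker_csv)
    norm = bio.normalize_panel(panel)
    # resolve repeated bedside glucose readings per animal-condition
    rows = []
    gly = norm[norm["analyte"] == "glycaemia"]
    for (aid, cond), sub in gly.groupby(["animal_id", "condition"]):
        sub = sub.sort_values("replicate") if "replicate" in sub.columns else sub
        res = bio.resolve_glycaemia(
            sub["value"].tolist(), (config.glycaemia_low, config.glycaemia_high)
        )
        rows.append(
            dict(
                animal_id=aid,
                condition=cond,
                analyte="glycaemia",
                normalized=res.value,
                repeated=res.repeated,
            )
        )
    resolved = pd.DataFrame(rows)
    other = norm[norm["analyte"] != "glycaemia"][
        ["animal_id", "condition", "analyte", "normalized", "reason"]
    ]
    qpcr = bio.read_qpcr(config.qpcr_csv, efficiency=config.qpcr_efficiency)
    qrows = []
    for rec in qpcr:
        aid, cond = rec.sample_id.rsplit("_", 1)
        qrows.append(
            dict(animal_id=aid, condition=cond, analyte="mtnu_ratio", normalized=bio.mtnu_ratio(rec))
        )
    tidy = pd.concat([other, resolved, pd.DataFrame(qrows)], ignore_index=True)
    tidy.to_csv(outdir / "biomarkers_normalized.csv", index=False)
    return tidy


def run_stats(config: RunConfig, tidy_values: pd.DataFrame, outdir: Path):
    """Report, outlier screen, exact contrasts, network and PCA exports."""
    report = cs.build_group_report(tidy_values)
    report.to_csv(outdir / "report.csv", index=False)

    out_rows = []
    for (var, sex, cond), sub in tidy_values.groupby(["variable", "sex", "condition"]):
        vals = sub["value"].dropna()
        if not (3 <= len(vals) <= 13):
            continue
        res = cs.dixon_q(vals)
        out_rows.append(
            dict(
                variable=var,
                sex=sex,
                condition=cond,
                q=res.q,
                critical=res.critical,
                variant=res.variant,
                is_outlier=res.is_outlier,
            )
        )
    pd.DataFrame(out_rows).to_csv(outdir / "dixon_screen.csv", index=False)

    wide = tidy_values.pivot_table(
        index=["animal_id", "sex", "condition"], columns="variable", values="value", aggfunc="mean"
    ).reset_index()
    variables = [c for c in wide.columns if c not in ("animal_id", "sex", "condition")]
    edge_frames = []
    for sex, sub in wide.groupby("sex"):
        edges = cs.correlation_network(
            sub[variables], variables, method=config.corr_method, threshold=config.corr_threshold
        )
        edges.insert(0, "sex", sex)
        edge_frames.append(edges)
    pd.concat(edge_frames, ignore_index=True).to_csv(outdir / "network_edges.csv", index=False)

    groups = wide["sex"] + "_" + wide["condition"]
    pca = cs.pca_describe(wide[variables], groups=groups)
    pca.scores.assign(group=groups.to_numpy()).to_csv(outdir / "pca_scores.csv", index=False)
    pca.loadings.to_csv(outdir / "pca_loadings.csv")
    pd.DataFrame(
        {"component": pca.scores.columns, "variance_pct": pca.variance_pct}
    ).to_csv(outdir / "pca_variance.csv", index=False)
    pca.variable_description.to_csv(outdir / "pca_dimension_variables.csv", index=False)
    pca.category_description.to_csv(outdir / "pca_dimension_categories.csv", index=False)
    return report, pca


def assemble_tidy_values(
    phase_means: pd.DataFrame,
    flux_table: pd.DataFrame,
    biomarker_tidy: pd.DataFrame,
    design_table: pd.DataFrame,
) -> pd.DataFrame:
    """Merge per-stage outputs into the tidy per-animal value table."""
    rows = []
    pm = phase_means[phase_means["variable"].isin(["vo2", "rer", "ee_kcal_h"])]
    for _, r in pm.iterrows():
        var = {"ee_kcal_h": "ee"}.get(r["variable"], r["variable"])
        rows.append(
            dict(
                animal_id=r["animal_id"],
                condition=r["condition"],
                variable=f"{var}_{r['phase']}_mean",
                value=r["mean"],
            )
        )
    for _, r in flux_table.iterrows():
        for var in ("oxcr", "mtrc", "glcp", "potential_magnitude"):
            rows.append(
                dict(
                    animal_id=r["animal_id"],
                    condition=r["condition"],
                    variable=var,
                    value=r[var],
                )
            )
    for _, r in biomarker_tidy.iterrows():
        rows.append(
            dict(
                animal_id=r["animal_id"],
                condition=r["condition"],
                variable=r["analyte"],
                value=r["normalized"],
            )
        )
    tidy = pd.DataFrame(rows)
    tidy = tidy.merge(design_table, on="animal_id", how="left")
    if tidy["sex"].isna().any():
        missing = tidy.loc[tidy["sex"].isna(), "animal_id"].unique()
        raise ValueError(f"animals missing from design table: {list(missing)[:5]}")
    return tidy


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as run log)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    def stage(name, fn, *args):
        try:
            out = fn(*args)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - report stage + cause
            raise PipelineError(name, str(exc)) from exc
        return out

    try:
        config.validate_inputs()
    except FileNotFoundError as exc:
        name = str(exc).split(":", 1)[0].replace("_csv", "")
        stage_name = {
            "gas": "respirometry",
            "flux": "flux_assay",
            "qpcr": "biomarkers",
            "biomarker": "biomarkers",
            "design": "cohort_stats",
        }.get(name, "input-validation")
        raise PipelineError(stage_name, str(exc)) from exc

    design_table = pd.read_csv(config.design_csv)

    series, phase_means = stage("respirometry", run_respirometry, config, outdir)
    log["stages"]["respirometry"] = {"traces": len(series)}

    extrema = stage("circadian", run_circadian, config, series, outdir)
    export_polar(extrema, design_table, outdir)
    log["stages"]["circadian"] = {"extrema_rows": len(extrema)}

    flux_table = stage("flux_assay", run_flux, config, outdir)
    log["stages"]["flux_assay"] = {
        "samples": len(flux_table),
        "missing": int(flux_table["oxcr"].isna().sum()),
    }

    biomarker_tidy = stage("biomarkers", run_biomarkers, config, outdir)
    log["stages"]["biomarkers"] = {"values": len(biomarker_tidy)}

    tidy = stage(
        "cohort_stats", assemble_tidy_values, phase_means, flux_table, biomarker_tidy, design_table
    )
    report, _pca = stage("cohort_stats", run_stats, config, tidy, outdir)
    log["stages"]["cohort_stats"] = {
        "report_variables": len(report),
        "animals": int(tidy["animal_id"].nunique()),
    }

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=str)
    return log
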