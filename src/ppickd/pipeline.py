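"""End-to-end orchestration: simulate → phenotype → exposure → split → fit → report.

Stages communicate only through delimited-text tables in a run directory;
every output carries a provenance header (stage, seed, config hash).  The
same configuration and seed reproduce the run byte-for-byte apart from
timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import counting, exposure, hazard, phenotype, reporting
from .io import read_table, write_table
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True, "n_participants": 2000},
    "phenotype": {"event_rule": "confirming", "exclusion_window_days": 365.0},
    "exposure": {"grace_days": 0.0, "baseline_window_days": 365.0},
    "model": {
        "n_bins": 24,
        "covariates": ["ppi", "age70", "female", "hypertension", "diabetes"],
        "frailty": True,
        "spatial": False,
        "rw1": True,
        "pc_sigma0": 1.0,
        "pc_alpha": 0.01,
    },
    "report": {"figure": True},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _prov(cfg: dict, stage: str) -> dict:
    return {"stage": stage, "seed": cfg.get("seed", 0), "config": cfg}


def stage_simulate(cfg: dict, outdir: Path):
    sim_cfg = {k: v for k, v in cfg.get("simulate", {}).items()
               if k != "enabled"}
    allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim_cfg) - allowed
    if unknown:
        raise KeyError(f"unknown simulate config keys: {sorted(unknown)}")
    config = SimulationConfig(seed=cfg.get("seed", 0), **sim_cfg)
    participants, prescriptions, labs, diagnoses, truth = simulate_cohort(config)
    p = _prov(cfg, "simulate")
    write_table(participants, outdir / "participants.tsv", **p)
    write_table(prescriptions, outdir / "prescriptions.tsv", **p)
    write_table(labs, outdir / "labs.tsv", **p)
    write_table(diagnoses, outdir / "diagnoses.tsv", **p)
    write_table(truth.per_participant, outdir / "truth.tsv", **p)
    write_table(truth.episodes, outdir / "truth_episodes.tsv", **p)
    return participants, prescriptions, labs, diagnoses


def labs_with_egfr(labs: pd.DataFrame,
                   participants: pd.DataFrame) -> pd.DataFrame:
    """Attach recomputed eGFR (CKD-EPI) to each creatinine determination."""
    merged = labs.merge(
        participants[["participant_id", "female", "age_at_start"]],
        on="participant_id", how="inner")
    age = merged["age_at_start"] + merged["day"] / 365.25
    egfr = np.full(len(merged), np.nan)
    has_cr = merged["creatinine"].notna().to_numpy()
    egfr[has_cr] = phenotype.ckd_epi_egfr(
        merged.loc[has_cr, "creatinine"].to_numpy(),
        age[has_cr].to_numpy(),
        merged.loc[has_cr, "female"].to_numpy().astype(bool))
    merged["egfr"] = egfr
    return merged[["participant_id", "day", "egfr", "uacr"]]


def stage_phenotype(cfg: dict, outdir: Path, participants, labs):
    ph = cfg["phenotype"]
    labs_e = labs_with_egfr(labs, participants)
    kept, n_excluded = phenotype.exclude_prevalent_ckd(
        participants, labs_e, window_days=ph["exclusion_window_days"])
    log.info("excluded %d prevalent-CKD participants", n_excluded)
    kept = kept.copy()
    kept["censor_day"] = kept["followup_end_day"]
    ckd = phenotype.detect_cohort_ckd(
        labs_e, kept, followup_start_col="analysis_entry_day",
        followup_end_col="censor_day", event_rule=ph["event_rule"])
    # follow-up for everything downstream ends at the event when incident
    kept = kept.merge(ckd[["participant_id", "incident", "event_day"]],
                      on="participant_id")
    kept["end_day"] = np.where(kept["incident"], kept["event_day"],
                               kept["censor_day"])
    p = _prov(cfg, "phenotype")
    write_table(ckd, outdir / "ckd_status.tsv", **p)
    write_table(kept.drop(columns=["incident", "event_day"]),
                outdir / "participants_analysis.tsv", **p)
    return kept, ckd


def stage_exposure(cfg: dict, outdir: Path, prescriptions, kept):
    ex = cfg["exposure"]
    timelines = exposure.build_cohort_timelines(
        prescriptions, kept, end_col="end_day",
        grace_days=ex["grace_days"],
        baseline_window_days=ex["baseline_window_days"])
    rows = []
    for pid, tl in timelines.items():
        for ep in tl.episodes:
            rows.append({"participant_id": pid, "start": ep.start,
                         "end": ep.end, "dose": ep.dose,
                         "stratum": tl.stratum})
        if not tl.episodes:
            rows.append({"participant_id": pid, "start": np.nan,
                         "end": np.nan, "dose": "", "stratum": tl.stratum})
    write_table(pd.DataFrame(rows), outdir / "exposure_episodes.tsv",
                **_prov(cfg, "exposure"))
    return timelines


def stage_split(cfg: dict, outdir: Path, kept, timelines, ckd):
    table = counting.build_counting_table(
        kept, timelines, ckd, entry_col="analysis_entry_day",
        covariate_cols=tuple(c for c in ("female", "hypertension", "diabetes")
                             if c in kept.columns))
    table = table.merge(kept[["participant_id", "site_id"]],
                        on="participant_id", how="left")
    report = counting.validate_table(table)
    if not report.ok:
        raise RuntimeError("invalid counting-process table: "
                           + "; ".join(report.violations))
    write_table(table, outdir / "counting.tsv", **_prov(cfg, "split"))
    return table


def stage_fit(cfg: dict, outdir: Path, table, participants=None):
    mc = cfg["model"]
    spec = hazard.ModelSpec(
        bin_edges=hazard.default_bin_edges(table, mc["n_bins"]),
        covariates=tuple(c for c in mc["covariates"] if c in table.columns),
        frailty=mc["frailty"], spatial=mc["spatial"], rw1=mc["rw1"],
        pc_prior=hazard.PCPrior(mc["pc_sigma0"], mc["pc_alpha"]))
    site_col = None
    site_coords = None
    if mc["spatial"]:
        site_col = "site_id"
        coords = (participants[["site_id", "site_x", "site_y"]]
                  .drop_duplicates("site_id").sort_values("site_id"))
        site_coords = np.zeros((int(coords["site_id"].max()) + 1, 2))
        site_coords[coords["site_id"].to_numpy()] = coords[
            ["site_x", "site_y"]].to_numpy()
    fit = hazard.fit_model(table, spec, site_col=site_col,
                           site_coords=site_coords)
    p = _prov(cfg, "fit")
    write_table(fit.coefficient_table(), outdir / "coefficients.tsv", **p)
    sidecar = {
        "hyperparameters": fit.hyper,
        "log_marginal": fit.log_marginal,
        "iterations": fit.iterations,
        "grad_norm": fit.grad_norm,
        "degenerate": list(fit.degenerate),
        "bin_edges": fit.spec.bin_edges.tolist(),
        "log_baseline_hazard": fit.mode.lam.tolist(),
    }
    (outdir / "fit.json").write_text(json.dumps(sidecar, indent=2))
    return fit


def stage_report(cfg: dict, outdir: Path, table, timelines, kept, ckd):
    strata = {pid: tl.stratum for pid, tl in timelines.items()}
    curves = reporting.kalbfleisch_prentice(table, strata)
    frames = [c.to_frame() for c in curves.values()]
    p = _prov(cfg, "report")
    write_table(pd.concat(frames, ignore_index=True),
                outdir / "survival_curves.tsv", **p)
    present = {s for s in strata.values()}
    lr = (reporting.log_rank(table, strata) if len(present) >= 2 else None)
    desc_df = kept.merge(ckd[["participant_id", "incident"]].rename(
        columns={"incident": "ckd"}), on="participant_id", how="left") \
        if "incident" not in kept.columns else kept.rename(
            columns={"incident": "ckd"})
    desc_df = desc_df.copy()
    desc_df["stratum"] = desc_df["participant_id"].map(strata)
    desc_df["age70_at_entry"] = (desc_df["age_at_start"]
                                 + desc_df["analysis_entry_day"] / 365.25
                                 >= 70).astype(int)
    variables = {"age_at_start": "continuous", "female": "binary",
                 "age70_at_entry": "binary", "hypertension": "binary",
                 "diabetes": "binary", "ckd": "binary"}
    table1 = reporting.baseline_tables(
        desc_df, "stratum", {k: v for k, v in variables.items()
                             if k in desc_df.columns})
    write_table(table1, outdir / "baseline_table.tsv", **p)
    if lr is not None:
        (outdir / "log_rank.json").write_text(json.dumps({
            "chi2": lr.chi2, "df": lr.df, "p_value": lr.p_value,
            "observed": {str(k): v for k, v in lr.observed.items()},
            "expected": {str(k): v for k, v in lr.expected.items()}},
            indent=2))
    if cfg["report"].get("figure", True):
        reporting.plot_survival(curves, outdir / "survival_curves.png")
    return curves, lr


@dataclasses.dataclass
class AnalysisResult:
    """In-memory result of phenotype → exposure → split → fit."""

    participants: pd.DataFrame       # after prevalent-CKD exclusion
    n_excluded: int
    ckd: pd.DataFrame
    timelines: dict
    table: pd.DataFrame              # counting-process start-stop rows
    fit: hazard.FitResult | None


def analyze(participants: pd.DataFrame, prescriptions: pd.DataFrame,
            labs: pd.DataFrame, *, config: dict | None = None,
            fit_model: bool = True) -> AnalysisResult:
    """Run the analysis chain on in-memory tables (no files written).

    ``config`` takes the same keys as the pipeline configuration
    (phenotype / exposure / model sections).
    """
    cfg = merge_config(config)
    ph_cfg, ex_cfg, mc = cfg["phenotype"], cfg["exposure"], cfg["model"]
    labs_e = labs_with_egfr(labs, participants)
    kept, n_excluded = phenotype.exclude_prevalent_ckd(
        participants, labs_e, window_days=ph_cfg["exclusion_window_days"])
    kept["censor_day"] = kept["followup_end_day"]
    ckd = phenotype.detect_cohort_ckd(
        labs_e, kept, followup_start_col="analysis_entry_day",
        followup_end_col="censor_day", event_rule=ph_cfg["event_rule"])
    kept = kept.merge(ckd[["participant_id", "incident", "event_day"]],
                      on="participant_id")
    kept["end_day"] = np.where(kept["incident"], kept["event_day"],
                               kept["censor_day"])
    timelines = exposure.build_cohort_timelines(
        prescriptions, kept, end_col="end_day",
        grace_days=ex_cfg["grace_days"],
        baseline_window_days=ex_cfg["baseline_window_days"])
    table = counting.build_counting_table(
        kept, timelines, ckd, entry_col="analysis_entry_day",
        covariate_cols=tuple(c for c in ("female", "hypertension", "diabetes")
                             if c in kept.columns))
    if "site_id" in kept.columns:
        table = table.merge(kept[["participant_id", "site_id"]],
                            on="participant_id", how="left")
    fit = None
    if fit_model:
        spec = hazard.ModelSpec(
            bin_edges=hazard.default_bin_edges(table, mc["n_bins"]),
            covariates=tuple(c for c in mc["covariates"]
                             if c in table.columns),
            frailty=mc["frailty"], spatial=mc["spatial"], rw1=mc["rw1"],
            pc_prior=hazard.PCPrior(mc["pc_sigma0"], mc["pc_alpha"]))
        site_col = site_coords = None
        if mc["spatial"]:
            site_col = "site_id"
            coords = (participants[["site_id", "site_x", "site_y"]]
                      .drop_duplicates("site_id").sort_values("site_id"))
            site_coords = np.zeros((int(coords["site_id"].max()) + 1, 2))
            site_coords[coords["site_id"].to_numpy()] = coords[
                ["site_x", "site_y"]].to_numpy()
        fit = hazard.fit_model(table, spec, site_col=site_col,
                               site_coords=site_coords)
    return AnalysisResult(participants=kept, n_excluded=n_excluded, ckd=ckd,
                          timelines=timelines, table=table, fit=fit)


def run_pipeline(config: dict | None, outdir: str | Path) -> Path:
    """Run every stage in order; returns the run directory."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg["simulate"].get("enabled", True):
        participants, prescriptions, labs, _ = stage_simulate(cfg, outdir)
    else:
        paths = cfg.get("inputs", {})
        for key in ("participants", "prescriptions", "labs"):
            if key not in paths or not Path(paths[key]).exists():
                raise FileNotFoundError(
                    f"simulate disabled and input table {key!r} missing")
        participants = read_table(paths["participants"])
        prescriptions = read_table(paths["prescriptions"])
        labs = read_table(paths["labs"])
    kept, ckd = stage_phenotype(cfg, outdir, participants, labs)
    timelines = stage_exposure(cfg, outdir, prescriptions, kept)
    table = stage_split(cfg, outdir, kept, timelines, ckd)
    fit = stage_fit(cfg, outdir, table, participants=kept)
    stage_report(cfg, outdir, table, timelines, kept, ckd)
    log.info("pipeline finished; outputs in %s", outdir)
    return outdir
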