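"""End-to-end orchestration: simulate/load -> PK fit -> enrichment -> stats.

The pipeline consumes four tab-separated tables (subject covariates, plasma
tracer observations, ROI T1 series, plasma biomarker samples), validates
their schemas, runs the population pharmacokinetic fit, the
reference-normalized enrichment chain and the biomarker statistics, and
assembles a machine-readable report: a Day-2 group-comparison table per
biomarker, a clearance-parameter summary per group, per-region enrichment
summaries, and Pearson correlation panels of every clearance/enrichment
index against every overnight biomarker change, separately per group.

Reports carry unrounded values plus display-rounded twins (1 decimal for
concentrations, 3 for ratios) and full provenance (config hash, seed,
package version), and are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, CohortDataset, generate_cohort, write_dataset
from .enrichment import BINS, REGIONS, enrichment_table
from .pk import derive_metrics, fit_population
from .stats import (ab_ratio, day2_group_comparison, fp1_regression,
                    group_day_interaction, overnight_change, pearson_panel)

logger = logging.getLogger("csfclear.pipeline")

__all__ = ["AnalysisReport", "SchemaError", "run", "validate_inputs",
           "load_inputs"]

#: expected columns per input file: name -> (dtype kind, row-level check)
SCHEMAS = {
    "subjects.tsv": {
        "subject_id": ("any", None),
        "group": ("any", lambda s: s.isin(["sleep", "sleep_deprivation"])),
        "age": ("num", lambda s: s > 0),
        "sex": ("any", lambda s: s.isin(["F", "M"])),
        "bmi": ("num", lambda s: s > 0),
        "psqi": ("num", lambda s: (s >= 0) & (s <= 21)),
        "egfr": ("num", lambda s: s > 0),
    },
    "pk_observations.tsv": {
        "subject_id": ("any", None),
        "time_h": ("num", lambda s: s >= 0),
        "conc": ("num", lambda s: s >= 0),
    },
    "roi_signal.tsv": {
        "subject_id": ("any", None),
        "region": ("any", lambda s: s.isin(list(REGIONS))),
        "time_h": ("num", lambda s: s >= 0),
        "t1_signal": ("num", lambda s: s > 0),
    },
    "biomarkers.tsv": {
        "subject_id": ("any", None),
        "biomarker": ("any", None),
        "day": ("num", lambda s: s.isin([1, 2])),
        "clock_time_h": ("num", lambda s: (s >= 0) & (s < 24)),
        "conc_pg_ml": ("num", lambda s: s >= 0),
    },
}


class SchemaError(ValueError):
    """An input table violates its schema (file, column and rows named)."""


@dataclass
class AnalysisReport:
    table2_like: dict       # biomarker -> group means/SE, contrasts, p-values
    table3_like: dict       # group -> mean/SD of PK parameters and metrics
    enrichment_summary: dict  # region -> group -> bin -> mean pct change
    panels: dict            # "index|biomarker|group" -> correlation results
    fp1: dict               # biomarker -> daytime-course fit summary
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True,
                          default=float)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


# --------------------------------------------------------------------------
# validation and loading
# --------------------------------------------------------------------------

def _validate_frame(df: pd.DataFrame, fname: str) -> dict:
    schema = SCHEMAS[fname]
    entry = {"file": fname, "ok": True, "errors": [], "warnings": []}
    for col in df.columns:
        if col not in schema:
            entry["warnings"].append(f"unknown column {col!r} ignored")
    for col, (kind, check) in schema.items():
        if col not in df.columns:
            entry["ok"] = False
            entry["errors"].append(f"missing column {col!r}")
            continue
        s = df[col]
        if kind == "num":
            s = pd.to_numeric(s, errors="coerce")
            bad = s.isna() & df[col].notna()
            if bad.any():
                entry["ok"] = False
                entry["errors"].append(
                    f"column {col!r}: non-numeric values at rows "
                    f"{list(bad[bad].index[:5])}")
                continue
        if check is not None:
            ok = check(s) | s.isna()
            if not ok.all():
                rows = list(ok[~ok].index[:5])
                entry["ok"] = False
                entry["errors"].append(
                    f"column {col!r}: invalid values at rows {rows}")
    return entry


def validate_inputs(input_dir) -> dict:
    """Per-file pass/fail with row-level diagnostics; never mutates inputs."""
    root = Path(input_dir)
    report = {}
    for fname in SCHEMAS:
        path = root / fname
        if not path.exists():
            report[fname] = {"file": fname, "ok": False,
                             "errors": ["file not found"], "warnings": []}
            continue
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # noqa: BLE001 - unreadable is a fail entry
            report[fname] = {"file": fname, "ok": False,
                             "errors": [f"unreadable: {exc}"], "warnings": []}
            continue
        report[fname] = _validate_frame(df, fname)
    return report


def load_inputs(input_dir) -> CohortDataset:
    """Load and schema-check the four TSVs into a dataset bundle."""
    report = validate_inputs(input_dir)
    for fname, entry in report.items():
        if not entry["ok"]:
            raise SchemaError(f"{fname}: " + "; ".join(entry["errors"]))
        for w in entry["warnings"]:
            logger.warning("%s: %s", fname, w)
    root = Path(input_dir)
    subjects = pd.read_csv(root / "subjects.tsv", sep="\t")
    pk_obs = pd.read_csv(root / "pk_observations.tsv", sep="\t")
    roi = pd.read_csv(root / "roi_signal.tsv", sep="\t")
    bio = pd.read_csv(root / "biomarkers.tsv", sep="\t")
    bio = bio.rename(columns={"clock_time_h": "clock_time",
                              "conc_pg_ml": "conc"})
    return CohortDataset(subjects=subjects, pk_observations=pk_obs,
                         roi_signal=roi, biomarkers=bio, ground_truth={})


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _with_ratio(bio: pd.DataFrame) -> pd.DataFrame:
    """Append per-draw Aβ42/Aβ40 ratio rows (paired by subject/day/time)."""
    wide = bio[bio.biomarker.isin(["AB40", "AB42"])].pivot_table(
        index=["subject_id", "day", "clock_time"], columns="biomarker",
        values="conc").reset_index()
    if "AB40" in wide.columns and "AB42" in wide.columns:
        paired = wide.dropna(subset=["AB40", "AB42"])
        paired = paired[paired["AB40"] > 0]
        ratio = paired.assign(biomarker="AB42_AB40_RATIO",
                              conc=ab_ratio(paired["AB42"].to_numpy(),
                                            paired["AB40"].to_numpy()))
        ratio = ratio[["subject_id", "biomarker", "day", "clock_time", "conc"]]
        bio = pd.concat([bio, ratio], ignore_index=True)
    return bio


def _round_for(biomarker: str) -> int:
    return 3 if biomarker == "AB42_AB40_RATIO" else 1


def _table2(bio: pd.DataFrame) -> dict:
    out = {}
    for bm, sub in bio.groupby("biomarker"):
        day2 = sub[sub.day == 2]
        per_subject = day2.groupby(["group", "subject_id"])["conc"].mean()
        grp_stats = {}
        for g, vals in per_subject.groupby(level="group"):
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
            grp_stats[g] = {"mean": mean, "se": se, "n": int(len(vals)),
                            "mean_rounded": round(mean, _round_for(bm)),
                            "se_rounded": round(se, _round_for(bm))}
        try:
            comp = day2_group_comparison(sub)
            est, se_c, p = comp.contrast()
            contrast = {"estimate": float(est), "se": float(se_c),
                        "p": float(p)}
        except ValueError as exc:
            contrast = {"error": str(exc)}
        try:
            inter = group_day_interaction(sub)
            iest, ise, ip = inter.contrast()
            interaction = {"estimate": float(iest), "se": float(ise),
                           "p": float(ip)}
        except ValueError as exc:
            interaction = {"error": str(exc)}
        entry = {"groups": grp_stats, "day2_contrast": contrast,
                 "group_day_interaction": interaction}
        if bm == "AB42_AB40_RATIO":
            # ratio of Day-2 group means, alongside the mean of ratios
            wide = bio[bio.biomarker.isin(["AB40", "AB42"]) & (bio.day == 2)]
            gm = wide.groupby(["group", "biomarker"])["conc"].mean().unstack()
            entry["ratio_of_means"] = {
                g: round(float(ab_ratio(row["AB42"], row["AB40"])), 3)
                for g, row in gm.iterrows()}
        out[bm] = entry
    return out


def _table3(model, subjects: pd.DataFrame) -> dict:
    grp = subjects.set_index("subject_id")["group"]
    rows = {}
    for sid, params in model.individual_estimates.items():
        met = derive_metrics(params)
        rows[sid] = {"group": grp.get(sid, "unknown"),
                     "t_half_abs": met.t_half_abs, "tlag": params.tlag,
                     "auc": met.auc, "cmax": met.cmax, "tmax": met.tmax,
                     "ka": params.ka, "cl": params.cl, "vc": params.vc}
    df = pd.DataFrame(rows).T
    out = {}
    for g, sub in df.groupby("group"):
        vals = sub.drop(columns="group").astype(float)
        out[str(g)] = {col: {"mean": float(vals[col].mean()),
                             "sd": float(vals[col].std(ddof=1))}
                       for col in vals.columns}
    out["population"] = {
        "typical": dataclasses.asdict(model.typical),
        "iiv_sd": model.iiv_sd, "sigma_prop": model.sigma_prop,
        "objective": model.objective, "converged": model.converged,
    }
    return out, df


def _enrichment_summary(enr: pd.DataFrame, subjects: pd.DataFrame) -> dict:
    m = enr.merge(subjects[["subject_id", "group"]], on="subject_id")
    out = {}
    for (region, g, b), sub in m.groupby(["region", "group", "bin"]):
        vals = sub["pct_change"].dropna()
        if len(vals) == 0:
            cell = {"missing": True}
        else:
            cell = {"mean_pct": float(vals.mean()),
                    "sd_pct": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals))}
        out.setdefault(region, {}).setdefault(g, {})[b] = cell
    return out


def _panels(indices: pd.DataFrame, deltas: pd.DataFrame,
            subjects: pd.DataFrame) -> dict:
    """Pearson panels: every index column x every biomarker delta x group."""
    grp = subjects.set_index("subject_id")["group"]
    out = {}
    for bm, dsub in deltas.groupby("biomarker"):
        d = dsub.set_index("subject_id")["delta"]
        for index_name in indices.columns:
            x = indices[index_name]
            common = x.index.intersection(d.index)
            key = f"{index_name}|{bm}"
            try:
                res = pearson_panel(x.loc[common].to_numpy(),
                                    d.loc[common].to_numpy(),
                                    grp.loc[common].to_numpy())
                for g, cr in res.items():
                    out[f"{key}|{g}"] = dataclasses.asdict(cr)
            except ValueError as exc:
                out[f"{key}|insufficient"] = {"error": str(exc)}
    return out


def _fp1_summary(bio: pd.DataFrame) -> dict:
    out = {}
    for bm, sub in bio.groupby("biomarker"):
        try:
            res = fp1_regression(sub["clock_time"].to_numpy(),
                                 sub["conc"].to_numpy(),
                                 sub["subject_id"].to_numpy())
            out[bm] = {"power": res.power,
                       "coefficients": res.coefficients,
                       "robust_se": res.robust_se,
                       "p_values": res.p_values}
        except ValueError as exc:
            out[bm] = {"error": str(exc)}
    return out


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def run(config: CohortConfig | None = None, input_dir=None,
        simulate: bool = False, seed: int | None = None,
        out_dir=None) -> AnalysisReport:
    """Execute the full analysis and optionally write the results bundle.

    Either ``simulate=True`` (a synthetic cohort is generated from
    ``config``/``seed``) or ``input_dir`` must be given.  Deterministic for
    fixed inputs and seed.
    """
    if simulate:
        cfg = config or CohortConfig()
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
        ds = generate_cohort(cfg)
        cfg_hash = cfg.config_hash()
        dose = cfg.pk_typical.dose
        used_seed = cfg.seed
    elif input_dir is not None:
        ds = load_inputs(input_dir)
        cfg = config or CohortConfig()
        cfg_hash = "external-data"
        dose = cfg.pk_typical.dose
        used_seed = seed if seed is not None else 0
    else:
        raise ValueError("either simulate=True or input_dir is required")

    logger.info("stage 1/4: population PK fit")
    pk_df = ds.pk_observations.rename(columns={"time_h": "time"})
    try:
        model = fit_population(pk_df, dose, seed=used_seed)
    except Exception as exc:
        raise RuntimeError(f"stage pk_fit failed: {exc}") from exc

    logger.info("stage 2/4: tracer enrichment")
    try:
        enr = enrichment_table(ds.roi_signal)
    except Exception as exc:
        raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    logger.info("stage 3/4: biomarker statistics")
    bio = ds.biomarkers.merge(ds.subjects[["subject_id", "group"]],
                              on="subject_id")
    bio = _with_ratio(bio)
    bio["group"] = bio.groupby("subject_id")["group"].transform("first")
    try:
        table2 = _table2(bio)
        deltas = overnight_change(bio)
        fp1 = _fp1_summary(bio)
    except Exception as exc:
        raise RuntimeError(f"stage biomarker_stats failed: {exc}") from exc

    logger.info("stage 4/4: correlation panels")
    # correlation indices need between-subject spread: AUC and the
    # absorption half-life vary through the ka/cl random effects, whereas
    # tlag carries no inter-individual variability in this model
    table3, per_subject_pk = _table3(model, ds.subjects)
    idx = per_subject_pk[["auc", "t_half_abs"]].astype(float)
    for region in ("cerebral_cortex", "subcortical_white_matter",
                   "parasagittal_dura", "csf_near_psd"):
        col = enr[(enr.region == region) & (enr.bin == "24h")]
        idx = idx.join(col.set_index("subject_id")["pct_change"]
                       .rename(f"{region}_24h"))
    panels = _panels(idx, deltas, ds.subjects)

    report = AnalysisReport(
        table2_like=table2,
        table3_like=table3,
        enrichment_summary=_enrichment_summary(enr, ds.subjects),
        panels=panels,
        fp1=fp1,
        provenance={"config_hash": cfg_hash, "seed": int(used_seed),
                    "version": __version__,
                    "n_subjects": int(len(ds.subjects))},
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        _write_csv_tables(report, enr, out)
    return report


def _write_csv_tables(report: AnalysisReport, enr: pd.DataFrame, out: Path):
    rows = []
    for bm, entry in report.table2_like.items():
        row = {"biomarker": bm}
        for g, s in entry["groups"].items():
            row[f"{g}_mean"] = s["mean"]
            row[f"{g}_se"] = s["se"]
        row["contrast_p"] = entry["day2_contrast"].get("p")
        row["interaction_p"] = entry["group_day_interaction"].get("p")
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "table2_day2_summary.csv", index=False)

    rows = []
    for key, val in report.panels.items():
        parts = key.split("|")
        if len(parts) != 3 or "error" in val:
            continue
        rows.append({"index": parts[0], "biomarker": parts[1],
                     "group": parts[2], **val})
    pd.DataFrame(rows).to_csv(out / "correlation_panels.csv", index=False)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
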