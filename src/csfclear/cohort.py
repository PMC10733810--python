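"""Synthetic cohorts with the sleep-deprivation study's design.

No patient-level data are deposited for this design, so every pipeline
stage is exercised on simulated cohorts that reproduce its statistical
structure: two groups (free sleep n=21, total sleep deprivation n=7), an
intrathecal 0.5 mmol tracer dose with plasma samples on a post-injection
schedule, T1 ROI series at MRI scan times with a shared per-scan
multiplicative scanner-drift factor (so reference normalization is actually
exercised), and plasma biomarker draws on both study days with subject
random intercepts, per-subject overnight-change heterogeneity and
group-by-day mean structure.

Cross-links between the clearance proxies and overnight biomarker change
are induced through shared per-subject latent Gaussian factors whose
correlation is calibrated analytically (lognormal-AUC factor and
measurement-attenuation factors) so that the *measured* quantities hit the
configured target correlations in expectation.

Every draw comes from one seeded ``numpy.random.Generator`` (PCG64), so a
given seed reproduces the dataset bit for bit; the generating truth is
returned alongside the data for recovery tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pk import PKParameters, conc_at
from .enrichment import BINS, REGIONS

logger = logging.getLogger("csfclear.cohort")

__all__ = ["CohortConfig", "CohortDataset", "generate_cohort", "null_cohort",
           "write_dataset"]

SIM_BIOMARKERS = ("AB40", "AB42", "PTAU181", "GFAP", "NFL")

_num = (int, float)


def _default_day_means():
    # group -> day -> mean (pg/mL); Day-1 means shared between groups, the
    # deprivation group's Day-2 amyloid reduction mirrors the reported
    # Day-2 group contrast; the other biomarkers carry no day effect
    return {
        "AB40": {"sleep": {1: 91.6, 2: 91.6},
                 "sleep_deprivation": {1: 91.6, 2: 79.6}},
        "AB42": {"sleep": {1: 6.3, 2: 6.3},
                 "sleep_deprivation": {1: 6.3, 2: 5.5}},
        "PTAU181": {"sleep": {1: 4.02, 2: 4.02},
                    "sleep_deprivation": {1: 4.02, 2: 4.02}},
        "GFAP": {"sleep": {1: 39.0, 2: 39.0},
                 "sleep_deprivation": {1: 39.0, 2: 39.0}},
        "NFL": {"sleep": {1: 8.5, 2: 8.5},
                "sleep_deprivation": {1: 8.5, 2: 8.5}},
    }


def _default_enrichment_profiles():
    # region -> group -> bin -> mean percent change from baseline; cortical
    # 24/48 h enrichment is higher under deprivation (impaired clearance),
    # white matter / dura / CSF profiles are shared between groups
    shared = {
        "subcortical_white_matter": {"0-4h": 1.0, "4-8h": 4.0, "24h": 10.0,
                                     "48h": 6.0, "4wk": 0.5},
        "parasagittal_dura": {"0-4h": 40.0, "4-8h": 60.0, "24h": 35.0,
                              "48h": 15.0, "4wk": 1.0},
        "csf_near_psd": {"0-4h": 80.0, "4-8h": 50.0, "24h": 20.0,
                         "48h": 8.0, "4wk": 0.5},
    }
    prof = {region: {"sleep": dict(v), "sleep_deprivation": dict(v)}
            for region, v in shared.items()}
    prof["cerebral_cortex"] = {
        "sleep": {"0-4h": 3.0, "4-8h": 8.0, "24h": 15.0, "48h": 8.0,
                  "4wk": 0.5},
        "sleep_deprivation": {"0-4h": 3.0, "4-8h": 9.0, "24h": 25.0,
                              "48h": 14.0, "4wk": 0.5},
    }
    return prof


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults emulate the study design."""

    n_sleep: int = 21
    n_deprived: int = 7
    seed: int = 0

    # tracer pharmacokinetics (typical values; Tmax ~7 h, T1/2abs 3.5 h,
    # terminal disposition fast enough for the 48 h sampling window)
    pk_typical: PKParameters = field(default_factory=lambda: PKParameters(
        ka=0.198, tlag=0.8, cl=1.6, vc=17.0, q=2.0, vp=10.0, dose=0.5))
    pk_iiv_sd: dict = field(default_factory=lambda: {"ka": 0.2, "cl": 0.2,
                                                     "vc": 0.2})
    sigma_prop: float = 0.1

    # plasma biomarker structure (pg/mL)
    biomarker_day_means: dict = field(default_factory=_default_day_means)
    between_subject_sd: dict = field(default_factory=lambda: {
        "AB40": 8.0, "AB42": 0.45, "PTAU181": 2.2, "GFAP": 10.5, "NFL": 0.9})
    within_subject_sd: dict = field(default_factory=lambda: {
        "AB40": 3.0, "AB42": 0.2, "PTAU181": 0.5, "GFAP": 3.0, "NFL": 0.4})
    overnight_sd: dict = field(default_factory=lambda: {
        "AB40": 5.0, "AB42": 0.35, "PTAU181": 0.8, "GFAP": 4.0, "NFL": 0.5})

    # cross-links (Pearson r targets on measured quantities)
    link_auc_dab: float = 0.7      # AUC vs overnight d(Abeta), sleep group
    link_cortex_dptau: float = 0.7  # 24 h cortex enrichment vs d(P-Tau181),
                                    # deprivation group

    # MRI enrichment structure
    enrichment_profiles: dict = field(default_factory=_default_enrichment_profiles)
    enrichment_subject_sd: float = 4.0   # per-subject/region enrichment shift, pct pts
    enrichment_meas_sd: float = 1.5      # per-scan measurement noise, pct pts
    scanner_drift_sd: float = 0.1        # SD of log per-scan greyscale drift
    reference_signal: float = 1000.0     # orbit reference ROI greyscale
    baseline_ratio: dict = field(default_factory=lambda: {
        "cerebral_cortex": 1.2, "subcortical_white_matter": 1.5,
        "parasagittal_dura": 0.9, "csf_near_psd": 0.4})

    # sampling schedules (hours)
    blood_times: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 24.0, 32.0, 48.0)
    mri_times: tuple = (0.0, 2.0, 6.0, 24.0, 48.0, 672.0)
    clock_times: dict = field(default_factory=lambda: {
        1: (9.0, 12.0, 15.0, 18.0), 2: (7.0, 9.0, 11.0, 13.0)})

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pk_typical"] = asdict(self.pk_typical)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "pk_typical" in d and isinstance(d["pk_typical"], dict):
            d["pk_typical"] = PKParameters(**d["pk_typical"])
        for key in ("blood_times", "mri_times"):
            if key in d:
                d[key] = tuple(d[key])
        if "clock_times" in d:
            d["clock_times"] = {int(k): tuple(v)
                                for k, v in d["clock_times"].items()}
        if "biomarker_day_means" in d:
            d["biomarker_day_means"] = {
                bm: {g: {int(day): float(v) for day, v in days.items()}
                     for g, days in grps.items()}
                for bm, grps in d["biomarker_day_means"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        bad = []
        if not (isinstance(self.n_sleep, int) and self.n_sleep >= 1):
            bad.append("n_sleep")
        if not (isinstance(self.n_deprived, int) and self.n_deprived >= 1):
            bad.append("n_deprived")
        for link in ("link_auc_dab", "link_cortex_dptau"):
            v = getattr(self, link)
            if not (isinstance(v, _num) and -1.0 < v < 1.0):
                bad.append(link)
        if not (isinstance(self.sigma_prop, _num) and self.sigma_prop > 0):
            bad.append("sigma_prop")
        for name in ("between_subject_sd", "within_subject_sd", "overnight_sd"):
            d = getattr(self, name)
            if set(d) != set(SIM_BIOMARKERS) or any(v < 0 for v in d.values()):
                bad.append(name)
        if set(self.pk_iiv_sd) != {"ka", "cl", "vc"} or any(
                v < 0 for v in self.pk_iiv_sd.values()):
            bad.append("pk_iiv_sd")
        if set(self.biomarker_day_means) != set(SIM_BIOMARKERS):
            bad.append("biomarker_day_means")
        for region in ("cerebral_cortex", "subcortical_white_matter",
                       "parasagittal_dura", "csf_near_psd"):
            prof = self.enrichment_profiles.get(region, {})
            if set(prof) != {"sleep", "sleep_deprivation"} or any(
                    set(bins) != set(BINS) for bins in prof.values()):
                bad.append(f"enrichment_profiles[{region}]")
        if self.blood_times[0] != 0 or any(np.diff(self.blood_times) <= 0):
            bad.append("blood_times")
        if self.mri_times[0] != 0 or any(np.diff(self.mri_times) <= 0):
            bad.append("mri_times")
        for v in (self.enrichment_subject_sd, self.enrichment_meas_sd,
                  self.scanner_drift_sd):
            if v < 0:
                bad.append("enrichment noise SDs")
                break
        if bad:
            raise ValueError("invalid cohort configuration fields: "
                             + ", ".join(sorted(set(bad))))


@dataclass
class CohortDataset:
    subjects: pd.DataFrame
    pk_observations: pd.DataFrame
    roi_signal: pd.DataFrame
    biomarkers: pd.DataFrame
    ground_truth: dict


# --------------------------------------------------------------------------
# calibration of the latent-factor links
# --------------------------------------------------------------------------

def _lognormal_corr_factor(a: float) -> float:
    """corr(exp(a Z), Z) for standard normal Z: a / sqrt(exp(a^2) - 1)."""
    if a <= 0:
        return 1.0
    return a / math.sqrt(math.expm1(a * a))


def _attenuation(signal_sd: float, noise_var: float) -> float:
    if signal_sd <= 0:
        return 1.0
    return signal_sd / math.sqrt(signal_sd ** 2 + noise_var)


def _calibrated_rho(target: float, *factors) -> float:
    denom = 1.0
    for f in factors:
        denom *= f
    rho = target / denom if denom > 0 else 0.0
    if abs(rho) > 0.999:
        logger.warning("link target %.3f not reachable after attenuation; "
                       "capping latent correlation", target)
        rho = math.copysign(0.999, rho)
    return rho


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _draw_subjects(cfg: CohortConfig, rng) -> pd.DataFrame:
    rows = []
    specs = [("sleep", cfg.n_sleep, 41.2, 13.8, 30.3, 5.6, 9.7, 4.2, 96.1,
              14.1, 16 / 21),
             ("sleep_deprivation", cfg.n_deprived, 44.7, 15.7, 26.2, 3.7,
              8.0, 4.9, 103.7, 10.4, 6 / 7)]
    idx = 0
    for (group, n, age_m, age_s, bmi_m, bmi_s, psqi_m, psqi_s, egfr_m,
         egfr_s, p_female) in specs:
        for _ in range(n):
            idx += 1
            rows.append({
                "subject_id": f"S{idx:03d}",
                "group": group,
                "age": float(np.clip(rng.normal(age_m, age_s), 18.0, 85.0)),
                "sex": "F" if rng.random() < p_female else "M",
                "bmi": float(np.clip(rng.normal(bmi_m, bmi_s), 16.0, 50.0)),
                "psqi": int(np.clip(round(rng.normal(psqi_m, psqi_s)), 0, 21)),
                "egfr": float(np.clip(rng.normal(egfr_m, egfr_s), 30.0, 150.0)),
            })
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Draw one complete synthetic dataset plus its generating truth.

    All randomness comes from ``config.seed`` through a single PCG64
    generator, so the output is reproducible bit for bit.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    subjects = _draw_subjects(cfg, rng)
    n = len(subjects)
    groups = subjects["group"].to_numpy()
    sids = subjects["subject_id"].to_numpy()

    # ---- latent per-subject factors -------------------------------------
    eps = {p: rng.normal(size=n) for p in ("ka", "cl", "vc")}
    cortex_dev = rng.normal(0.0, cfg.enrichment_subject_sd, size=n)

    # ---- individual PK parameters and plasma tracer curves --------------
    typ = cfg.pk_typical
    ka_i = typ.ka * np.exp(cfg.pk_iiv_sd["ka"] * eps["ka"])
    cl_i = typ.cl * np.exp(cfg.pk_iiv_sd["cl"] * eps["cl"])
    vc_i = typ.vc * np.exp(cfg.pk_iiv_sd["vc"] * eps["vc"])
    true_params = {}
    pk_rows = []
    blood = np.asarray(cfg.blood_times, float)
    for i, sid in enumerate(sids):
        p = PKParameters(ka=float(ka_i[i]), tlag=typ.tlag, cl=float(cl_i[i]),
                         vc=float(vc_i[i]), q=typ.q, vp=typ.vp, dose=typ.dose)
        true_params[sid] = p
        curve = conc_at(p, blood)
        noisy = np.maximum(curve * (1.0 + cfg.sigma_prop
                                    * rng.normal(size=len(blood))), 0.0)
        noisy[blood == 0] = 0.0
        for t, c in zip(blood, noisy):
            pk_rows.append({"subject_id": sid, "time_h": float(t),
                            "conc": float(c)})
    pk_observations = pd.DataFrame(pk_rows)

    # ---- overnight-change deviations with calibrated links --------------
    m1 = len(cfg.clock_times[1])
    m2 = len(cfg.clock_times[2])
    delta_noise_var = {bm: cfg.within_subject_sd[bm] ** 2 * (1 / m1 + 1 / m2)
                       for bm in SIM_BIOMARKERS}
    c_auc = _lognormal_corr_factor(cfg.pk_iiv_sd["cl"])
    g_auc = -eps["cl"]  # AUC = dose/cl is increasing in -log cl
    g_ctx = cortex_dev / max(cfg.enrichment_subject_sd, 1e-12)
    c_ctx = _attenuation(cfg.enrichment_subject_sd,
                         cfg.enrichment_meas_sd ** 2)

    over_dev = {}
    for bm in SIM_BIOMARKERS:
        sd = cfg.overnight_sd[bm]
        c_att = _attenuation(sd, delta_noise_var[bm])
        w = rng.normal(size=n)
        if bm in ("AB40", "AB42"):
            rho = _calibrated_rho(cfg.link_auc_dab, c_auc, c_att)
            mix = rho * g_auc + math.sqrt(1 - rho ** 2) * w
            dev = sd * np.where(groups == "sleep", mix, w)
        elif bm == "PTAU181":
            rho = _calibrated_rho(cfg.link_cortex_dptau, c_ctx, c_att)
            mix = rho * g_ctx + math.sqrt(1 - rho ** 2) * w
            dev = sd * np.where(groups == "sleep_deprivation", mix, w)
        else:
            dev = sd * w
        over_dev[bm] = dev

    # ---- biomarker samples ----------------------------------------------
    bio_rows = []
    intercepts = {bm: rng.normal(0.0, cfg.between_subject_sd[bm], size=n)
                  for bm in SIM_BIOMARKERS}
    true_delta = {}
    for bm in SIM_BIOMARKERS:
        means = cfg.biomarker_day_means[bm]
        d_mean = {g: means[g][2] - means[g][1] for g in means}
        true_delta[bm] = {
            sid: float(d_mean[groups[i]] + over_dev[bm][i])
            for i, sid in enumerate(sids)}
        for i, sid in enumerate(sids):
            for day, clocks in cfg.clock_times.items():
                # the subject's own overnight deviation rides on Day 2 only
                base = means[groups[i]][day] + intercepts[bm][i]
                if day == 2:
                    base += over_dev[bm][i]
                for ct in clocks:
                    conc = base + rng.normal(0.0, cfg.within_subject_sd[bm])
                    bio_rows.append({
                        "subject_id": sid, "biomarker": bm, "day": int(day),
                        "clock_time": float(ct),
                        "conc": float(max(conc, 0.0))})
    biomarkers = pd.DataFrame(bio_rows)

    # ---- ROI T1 series with shared scanner drift ------------------------
    mri = np.asarray(cfg.mri_times, float)
    bin_of = {}
    for t in mri[mri > 0]:
        for label, spec in BINS.items():
            if spec[0] == "interval" and spec[1] <= t < spec[2]:
                bin_of[t] = label
            elif spec[0] == "landmark" and abs(t - spec[1]) <= spec[2]:
                bin_of[t] = label
    roi_rows = []
    region_dev = {}
    for i, sid in enumerate(sids):
        drift = np.exp(rng.normal(0.0, cfg.scanner_drift_sd, size=len(mri)))
        devs = {}
        for region in cfg.baseline_ratio:
            if region == "cerebral_cortex":
                devs[region] = float(cortex_dev[i])
            else:
                devs[region] = float(rng.normal(0.0, cfg.enrichment_subject_sd))
        region_dev[sid] = devs
        for j, t in enumerate(mri):
            ref_signal = cfg.reference_signal * drift[j]
            roi_rows.append({"subject_id": sid, "region": "reference_orbit",
                             "time_h": float(t), "t1_signal": float(ref_signal)})
            for region, r0 in cfg.baseline_ratio.items():
                if t == 0:
                    pct = 0.0
                else:
                    prof = cfg.enrichment_profiles[region][groups[i]]
                    pct = (prof[bin_of[t]] + devs[region]
                           + rng.normal(0.0, cfg.enrichment_meas_sd))
                normalized = r0 * (1.0 + pct / 100.0)
                roi_rows.append({"subject_id": sid, "region": region,
                                 "time_h": float(t),
                                 "t1_signal": float(normalized * ref_signal)})
    roi_signal = pd.DataFrame(roi_rows)

    ground_truth = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "pk_parameters": {sid: asdict(p) for sid, p in true_params.items()},
        "auc_true": {sid: p.dose / p.cl for sid, p in true_params.items()},
        "overnight_delta": true_delta,
        "cortex_subject_dev": {sid: float(cortex_dev[i])
                               for i, sid in enumerate(sids)},
        "region_subject_dev": region_dev,
        "latent_eps_cl": {sid: float(eps["cl"][i])
                          for i, sid in enumerate(sids)},
    }
    return CohortDataset(subjects=subjects, pk_observations=pk_observations,
                         roi_signal=roi_signal, biomarkers=biomarkers,
                         ground_truth=ground_truth)


def null_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Same design with every group and overnight effect and link zeroed.

    Both groups share the sleep group's Day-1 means on both days, the
    cortical enrichment profile is the sleep profile for both groups, both
    latent links are zero, and the per-subject overnight-change dispersion
    is zero (in a null world nothing happens overnight, so there is no
    subject-level day-2 random effect either — the data then actually
    satisfy the random-intercept model whose type-I error is being
    calibrated).  Used for type-I-error calibration.
    """
    cfg = dataclasses.replace(config or CohortConfig())
    means = {bm: {g: {1: cfg.biomarker_day_means[bm]["sleep"][1],
                      2: cfg.biomarker_day_means[bm]["sleep"][1]}
                  for g in ("sleep", "sleep_deprivation")}
             for bm in SIM_BIOMARKERS}
    profiles = {region: {g: dict(cfg.enrichment_profiles[region]["sleep"])
                         for g in ("sleep", "sleep_deprivation")}
                for region in cfg.enrichment_profiles}
    cfg = dataclasses.replace(
        cfg, biomarker_day_means=means, enrichment_profiles=profiles,
        link_auc_dab=0.0, link_cortex_dptau=0.0,
        overnight_sd={bm: 0.0 for bm in cfg.overnight_sd})
    return generate_cohort(cfg)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def write_dataset(ds: CohortDataset, out_dir) -> dict:
    """Write the four TSVs plus ground_truth.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    subj = ds.subjects
    paths["subjects"] = out / "subjects.tsv"
    subj.to_csv(paths["subjects"], sep="\t", index=False)
    paths["pk_observations"] = out / "pk_observations.tsv"
    ds.pk_observations.to_csv(paths["pk_observations"], sep="\t", index=False)
    paths["roi_signal"] = out / "roi_signal.tsv"
    ds.roi_signal.to_csv(paths["roi_signal"], sep="\t", index=False)
    paths["biomarkers"] = out / "biomarkers.tsv"
    bio = ds.biomarkers.rename(columns={"clock_time": "clock_time_h",
                                        "conc": "conc_pg_ml"})
    bio.to_csv(paths["biomarkers"], sep="\t", index=False)
    paths["ground_truth"] = out / "ground_truth.json"
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(ds.ground_truth, fh, indent=1, sort_keys=True)
    return paths
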