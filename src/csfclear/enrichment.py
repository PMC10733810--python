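"""Reference-normalized MRI T1 signal and percent enrichment from baseline.

Gadobutrol in CSF or brain tissue shortens T1 and raises the T1-weighted
greyscale signal, a semi-quantitative readout of tracer concentration.
Because the scanner rescales the image greyscale between acquisitions, each
region-of-interest (ROI) signal is divided by the signal of a reference ROI
(posterior orbit, which sees no tracer) from the same scan: the
"normalized T1 signal units".  Tracer enrichment is then the percent
increase of the normalized unit over its pre-injection baseline, summarized
in the time bins 0-4 h, 4-8 h, 24 h, 48 h and 4 weeks.  This per-region
enrichment is the glymphatic-function proxy used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("csfclear.enrichment")

__all__ = [
    "REGIONS",
    "BINS",
    "ROISeries",
    "EnrichmentResult",
    "normalize",
    "percent_change",
    "bin_enrichment",
]

REGIONS = (
    "cerebral_cortex",
    "subcortical_white_matter",
    "parasagittal_dura",
    "csf_near_psd",
    "reference_orbit",
)

#: bin label -> (kind, parameters); interval bins collect every observation
#: in [lo, hi); landmark bins take the observation nearest to the target
#: time within +/- the window (missingness is reported, never imputed)
BINS = {
    "0-4h": ("interval", 0.0, 4.0),
    "4-8h": ("interval", 4.0, 8.0 + 1e-9),
    "24h": ("landmark", 24.0, 6.0),
    "48h": ("landmark", 48.0, 6.0),
    "4wk": ("landmark", 672.0, 72.0),
}


@dataclass(frozen=True)
class ROISeries:
    """T1 signal of one ROI of one subject over the scan times (hours).

    Times are hours since injection; 0 is the pre-injection baseline scan.
    """

    subject_id: str
    region: str
    times: tuple
    signal: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        s = np.asarray(self.signal, float)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if len(t) != len(s):
            raise ValueError("times and signal differ in length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if t[0] != 0:
            raise ValueError("series must include the t=0 baseline scan")
        if np.any(s <= 0):
            raise ValueError("T1 greyscale signal must be positive")


@dataclass
class EnrichmentResult:
    """Per-bin normalized units and percent change for one subject/region."""

    subject_id: str
    region: str
    normalized: dict  # bin label -> mean normalized T1 signal (or None)
    pct_change: dict  # bin label -> mean percent change from baseline (or None)


def normalize(series: ROISeries, reference: ROISeries) -> np.ndarray:
    """Elementwise ratio ROI-signal / reference-signal at matched scan times.

    Both series must come from the same subject and share the exact scan-time
    grid; no interpolation is performed.
    """
    if series.subject_id != reference.subject_id:
        raise ValueError("series and reference belong to different subjects")
    t1 = np.asarray(series.times, float)
    t2 = np.asarray(reference.times, float)
    if len(t1) != len(t2) or np.any(t1 != t2):
        raise ValueError("series and reference scan-time grids do not match")
    ref = np.asarray(reference.signal, float)
    if np.any(ref <= 0):
        raise ValueError("reference signal must be positive at every time")
    return np.asarray(series.signal, float) / ref


def percent_change(normalized, times=None) -> np.ndarray:
    """Percent increase of each value over the first (t=0 baseline) value.

    ``normalized`` is the per-time normalized signal whose first entry is the
    baseline; the baseline entry of the output is exactly 0.
    """
    x = np.asarray(normalized, float)
    if times is not None:
        t = np.asarray(times, float)
        if len(t) == 0 or t[0] != 0:
            raise ValueError("baseline (t=0) value missing")
    if x.size == 0:
        raise ValueError("baseline (t=0) value missing")
    x0 = x[0]
    if not (x0 > 0):
        raise ValueError("baseline normalized value must be positive")
    out = 100.0 * (x - x0) / x0
    out[0] = 0.0
    return out


def _assign_bin(time: float) -> str | None:
    for label, spec in BINS.items():
        if spec[0] == "interval":
            if spec[1] <= time < spec[2]:
                return label
        else:
            target, window = spec[1], spec[2]
            if abs(time - target) <= window:
                return label
    return None


def bin_enrichment(times, values) -> dict:
    """Mean of ``values`` per canonical time bin; missing bins map to None.

    Interval bins (0-4 h, 4-8 h) average every observation inside the
    interval; landmark bins (24 h, 48 h, 4 weeks) average observations within
    their window around the landmark.  The t=0 baseline is excluded.
    Missing bins are data, not errors.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if len(t) != len(v):
        raise ValueError("times and values differ in length")
    out: dict = {label: None for label in BINS}
    sums = {label: [] for label in BINS}
    for ti, vi in zip(t, v):
        if ti == 0:
            continue
        label = _assign_bin(float(ti))
        if label is not None:
            sums[label].append(vi)
    for label, vals in sums.items():
        if vals:
            out[label] = float(np.mean(vals))
    return out


def enrich_subject(rois: dict) -> list:
    """Full enrichment chain for one subject's ROI series.

    ``rois`` maps region name -> :class:`ROISeries` and must contain the
    ``reference_orbit`` series.  Returns an :class:`EnrichmentResult` per
    non-reference region.
    """
    if "reference_orbit" not in rois:
        raise ValueError("subject lacks the reference_orbit series")
    reference = rois["reference_orbit"]
    results = []
    for region, series in rois.items():
        if region == "reference_orbit":
            continue
        norm = normalize(series, reference)
        pct = percent_change(norm, series.times)
        results.append(EnrichmentResult(
            subject_id=series.subject_id,
            region=region,
            normalized=bin_enrichment(series.times, norm),
            pct_change=bin_enrichment(series.times, pct),
        ))
    return results


def enrichment_table(roi_signal: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-region, per-bin enrichment from a long ROI table.

    ``roi_signal`` has columns subject_id, region, time_h, t1_signal.
    Returns a tidy frame with columns subject_id, region, bin,
    normalized_mean, pct_change (missing bins as NaN).
    """
    rows = []
    for sid, grp in roi_signal.groupby("subject_id", sort=True):
        rois = {}
        for region, sub in grp.groupby("region"):
            sub = sub.sort_values("time_h")
            rois[region] = ROISeries(
                subject_id=str(sid), region=str(region),
                times=tuple(sub["time_h"].astype(float)),
                signal=tuple(sub["t1_signal"].astype(float)))
        for res in enrich_subject(rois):
            for label in BINS:
                rows.append({
                    "subject_id": res.subject_id,
                    "region": res.region,
                    "bin": label,
                    "normalized_mean": (np.nan if res.normalized[label] is None
                                        else res.normalized[label]),
                    "pct_change": (np.nan if res.pct_change[label] is None
                                   else res.pct_change[label]),
                })
    return pd.DataFrame(rows)
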