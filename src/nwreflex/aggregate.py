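"""Participant-level response summaries and conduction-velocity estimation.

Response rates count trials, not muscles: a trial is one response in a
window as soon as either tibialis anterior or soleus shows a qualifying
burst there. Conduction velocity follows the two-site approach — the
latency of the same reflex component shifts between the distal (sole of
the foot, FS) and proximal (below the fibula head, FH) stimulation sites
by distance / CV, so CV = distance_m / (median latency shift in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import rectify
from .detect import TrialDetection
from .signal_io import EMGEpoch, MUSCLES

WINDOWS = ("TW1", "TW2")


@dataclass
class ResponseSummary:
    participant_id: str
    site: str
    window: str  # TW1 | TW2 | any
    n_valid_trials: int
    n_response_trials: int
    response_rate_pct: float | None
    responder: bool
    latency_mean_ms: float | None
    latency_sd_ms: float | None
    auc_mean_uVs: float | None
    coactivation_rate_pct: float | None
    pain_rating_mean: float | None
    analgesic: bool


@dataclass
class CVEstimate:
    participant_id: str
    window: str
    distance_m: float
    delta_latency_ms: float | None
    cv_mps: float | None
    n_events_distal: int
    n_events_proximal: int
    defined: bool


def _trial_window_stats(det: TrialDetection, window: str):
    """Earliest onset and summed AUC over a trial's events in one window."""
    evs = [e for e in det.events if e.window == window]
    if not evs:
        return None
    return (min(e.onset_ms for e in evs), sum(e.auc_uVs for e in evs))


def summarize_participant(detections: list[TrialDetection],
                          participant_id: str | None = None
                          ) -> list[ResponseSummary]:
    """One summary per site x window plus an "any" row per site.

    Invalid trials are excluded from every denominator. Window latency per
    trial is the earliest onset among that window's bursts; window AUC is
    the sum over the window's bursts (both muscles).
    """
    if participant_id is not None:
        detections = [d for d in detections if d.participant_id == participant_id]
    out: list[ResponseSummary] = []
    for pid in sorted({d.participant_id for d in detections}):
        for site in sorted({d.site for d in detections if d.participant_id == pid}):
            dets = [d for d in detections
                    if d.participant_id == pid and d.site == site]
            valid = [d for d in dets if d.valid]
            n_valid = len(valid)
            pains = [d.pain_rating for d in valid if d.pain_rating is not None]
            pain_mean = float(np.mean(pains)) if pains else None
            analgesic = bool(pains) and all(p == 0 for p in pains)
            for window in (*WINDOWS, "any"):
                if window == "any":
                    per_trial = [(0.0, 0.0) for d in valid if d.events]
                    lat, auc, coact = None, None, None
                else:
                    stats = [_trial_window_stats(d, window) for d in valid]
                    per_trial = [s for s in stats if s is not None]
                    lats = [s[0] for s in per_trial]
                    aucs = [s[1] for s in per_trial]
                    lat = float(np.mean(lats)) if lats else None
                    auc = float(np.mean(aucs)) if aucs else None
                    n_coact = sum(1 for d in valid if window in d.coactivated_tw)
                    coact = (100.0 * n_coact / len(per_trial)
                             if per_trial else None)
                n_resp = len(per_trial)
                rate = 100.0 * n_resp / n_valid if n_valid else None
                lat_sd = None
                if window != "any":
                    lats = [s[0] for s in per_trial]
                    lat_sd = float(np.std(lats, ddof=1)) if len(lats) > 1 else None
                out.append(ResponseSummary(
                    participant_id=pid, site=site, window=window,
                    n_valid_trials=n_valid, n_response_trials=n_resp,
                    response_rate_pct=rate, responder=n_resp > 0,
                    latency_mean_ms=lat, latency_sd_ms=lat_sd,
                    auc_mean_uVs=auc, coactivation_rate_pct=coact,
                    pain_rating_mean=pain_mean, analgesic=analgesic))
    return out


def summaries_to_frame(summaries: list[ResponseSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def trial_latencies(detections: list[TrialDetection], participant_id: str,
                    site: str, window: str,
                    muscle: str | None = None) -> list[float]:
    """Per-trial earliest onsets for one participant/site/window, optionally
    restricted to one muscle."""
    out = []
    for d in detections:
        if d.participant_id != participant_id or d.site != site or not d.valid:
            continue
        evs = [e for e in d.events if e.window == window
               and (muscle is None or e.muscle == muscle)]
        if evs:
            out.append(min(e.onset_ms for e in evs))
    return out


def estimate_cv(latencies_distal_ms, latencies_proximal_ms, distance_m: float,
                participant_id: str = "", window: str = "TW2",
                min_events: int = 3) -> CVEstimate:
    """CV from the median latency shift between a distal and a proximal site.

    Undefined — not an error — when either site has fewer than
    ``min_events`` responses or when the shift is not positive.
    """
    if distance_m <= 0:
        raise ValueError("distance must be > 0")
    nd, np_ = len(latencies_distal_ms), len(latencies_proximal_ms)
    if nd < min_events or np_ < min_events:
        return CVEstimate(participant_id, window, distance_m, None, None,
                          nd, np_, defined=False)
    delta = float(np.median(latencies_distal_ms)
                  - np.median(latencies_proximal_ms))
    if delta <= 0:
        return CVEstimate(participant_id, window, distance_m, delta, None,
                          nd, np_, defined=False)
    return CVEstimate(participant_id, window, distance_m, delta,
                      distance_m / (delta / 1000.0), nd, np_, defined=True)


def participant_cv(detections: list[TrialDetection], participant_id: str,
                   distance_m: float, window: str = "TW2",
                   distal_site: str = "FS", proximal_site: str = "FH",
                   min_events: int = 3, muscle: str = "TA") -> CVEstimate:
    """CV for one participant from that participant's trial detections.

    Latencies come from one muscle (TA by default) so that co-activated
    soleus bursts with their own onset scatter do not bias the shift.
    """
    lat_d = trial_latencies(detections, participant_id, distal_site, window,
                            muscle)
    lat_p = trial_latencies(detections, participant_id, proximal_site, window,
                            muscle)
    return estimate_cv(lat_d, lat_p, distance_m, participant_id, window,
                       min_events)


def cv_table(detections: list[TrialDetection], records) -> pd.DataFrame:
    """CV estimates for every participant with a known FS–FH distance."""
    rows = []
    for rec in records:
        for window in WINDOWS:
            if rec.distance_FS_FH_m is None:
                rows.append({"participant_id": rec.participant_id,
                             "window": window, "distance_m": np.nan,
                             "delta_latency_ms": np.nan, "cv_mps": np.nan,
                             "defined": False})
                continue
            est = participant_cv(detections, rec.participant_id,
                                 rec.distance_FS_FH_m, window)
            rows.append({"participant_id": rec.participant_id,
                         "window": window, "distance_m": est.distance_m,
                         "delta_latency_ms": est.delta_latency_ms,
                         "cv_mps": est.cv_mps, "defined": est.defined})
    return pd.DataFrame(rows)


def grand_average(epochs: list[EMGEpoch]) -> dict[str, np.ndarray]:
    """Pointwise mean of the rectified epochs, per muscle."""
    if not epochs:
        raise ValueError("grand average needs at least one epoch")
    n = epochs[0].n_samples
    if any(e.n_samples != n for e in epochs):
        raise ValueError("epochs differ in length")
    return {m: np.mean([rectify(e.channel(m)) for e in epochs], axis=0)
            for m in MUSCLES}
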