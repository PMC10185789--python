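"""Threshold-based reflex detection and burst characterization.

A withdrawal reflex is polyphasic EMG activity whose rectified amplitude
exceeds the background mean by two standard deviations of the rectified
pre-stimulus window. Detected bursts are characterized by onset latency,
offset, peak, baseline-corrected area under the rectified curve (AUC), and
phase count, then assigned to one of two latency windows:

* TW1 ``[90, 600)`` ms — compatible with thinly myelinated A-delta afferents,
* TW2 ``[1000, 3000]`` ms — compatible with unmyelinated C afferents,

with onsets in the gap labelled ``intermediate`` (never discarded).

Adding the background *mean* to the threshold makes the criterion invariant
to the positive offset that full-wave rectification introduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import rectify
from .signal_io import (DetectionConfig, EMGEpoch, InvariantError, MUSCLES)


@dataclass
class BackgroundStats:
    """Mean/SD of the rectified pre-stimulus window for one channel."""
    mu_bg_uV: float
    sigma_bg_uV: float
    window_ms: tuple[float, float]

    @property
    def threshold(self) -> float:
        raise AttributeError("use threshold_for(config)")

    def threshold_for(self, config: DetectionConfig) -> float:
        return self.mu_bg_uV + config.threshold_sd_multiplier * self.sigma_bg_uV


@dataclass
class ReflexEvent:
    muscle: str
    onset_ms: float
    offset_ms: float
    peak_uV: float
    auc_uVs: float
    n_phases: int
    window: str = "none"  # TW1 | TW2 | intermediate | none


@dataclass
class TrialDetection:
    participant_id: str
    site: str
    trial_index: int
    background: dict[str, BackgroundStats]
    events: list[ReflexEvent] = field(default_factory=list)
    valid: bool = True
    coactivated_tw: set[str] = field(default_factory=set)
    pain_rating: float | None = None


def estimate_background(epoch: EMGEpoch, muscle: str,
                        config: DetectionConfig | None = None) -> BackgroundStats:
    """Mean and SD of the rectified channel over the pre-stimulus window."""
    config = config or DetectionConfig()
    lo, hi = config.noise_window_ms
    if lo < epoch.t0_offset_ms - 1e-9:
        raise InvariantError("noise window starts before the epoch")
    i0, i1 = epoch.index_of(lo), epoch.index_of(hi)
    seg = rectify(epoch.channel(muscle))[i0:i1]
    if seg.size == 0:
        raise InvariantError("empty noise window")
    return BackgroundStats(mu_bg_uV=float(seg.mean()),
                           sigma_bg_uV=float(seg.std(ddof=0)),
                           window_ms=(lo, hi))


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array into (start, stop, value) spans."""
    if mask.size == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [mask.size]))
    return [(int(bounds[i]), int(bounds[i + 1]), bool(mask[bounds[i]]))
            for i in range(len(bounds) - 1)]


def detect_bursts(rectified: np.ndarray, epoch: EMGEpoch,
                  background: BackgroundStats,
                  config: DetectionConfig | None = None
                  ) -> list[tuple[float, float]]:
    """Supra-threshold burst intervals (onset_ms, offset_ms) in [0, 3000).

    A burst starts at the first of >= ``min_burst_ms`` consecutive samples at
    or above T = mu_bg + k*sigma_bg, keeps absorbing activity until the
    signal stays below T for >= ``offset_hold_ms``, and bursts separated by
    less than ``merge_gap_ms`` are merged.
    """
    config = config or DetectionConfig()
    dt = epoch.dt_ms
    t = config.threshold_sd_multiplier * background.sigma_bg_uV + background.mu_bg_uV
    i0 = epoch.index_of(0.0)
    i1 = epoch.index_of(3000.0)
    x = np.asarray(rectified, dtype=float)[i0:i1]
    mask = x >= t
    min_burst_n = max(1, int(round(config.min_burst_ms / dt)))
    hold_n = max(1, int(round(config.offset_hold_ms / dt)))

    spans = _runs(mask)
    bursts: list[tuple[int, int]] = []
    k = 0
    while k < len(spans):
        s, e, val = spans[k]
        if not (val and e - s >= min_burst_n):
            k += 1
            continue
        # seed found; absorb following activity across sub-hold gaps
        end = e
        j = k + 1
        while j < len(spans):
            gs, ge, gval = spans[j]
            if not gval:  # a quiet gap
                if ge - gs >= hold_n or j == len(spans) - 1:
                    break
                j += 1
            else:
                end = ge
                j += 1
        bursts.append((s, end))
        k = j
    # merge bursts separated by < merge_gap_ms
    merge_n = int(round(config.merge_gap_ms / dt))
    merged: list[tuple[int, int]] = []
    for b in bursts:
        if merged and b[0] - merged[-1][1] < merge_n:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(b)
    off = epoch.t0_offset_ms + i0 * dt
    return [(off + s * dt, off + e * dt) for s, e in merged]


def count_phases(filtered: np.ndarray, epoch: EMGEpoch,
                 interval_ms: tuple[float, float], threshold_uV: float,
                 config: DetectionConfig | None = None) -> int:
    """Phase count of the signed signal inside a burst interval.

    The signal is split at zero crossings into lobes; lobes whose peak
    magnitude reaches ``phase_amplitude_fraction * threshold_uV`` qualify as
    excursions, and the count is 1 + the number of sign changes between
    successive qualifying excursions (0 when none qualifies).
    """
    config = config or DetectionConfig()
    i0 = epoch.index_of(interval_ms[0])
    i1 = epoch.index_of(interval_ms[1])
    x = np.asarray(filtered, dtype=float)[i0:i1]
    if x.size == 0:
        return 0
    floor = config.phase_amplitude_fraction * threshold_uV
    signs = np.sign(x)
    lobes = _runs(signs >= 0)  # split at sign flips (zeros join the + side)
    qual_signs: list[int] = []
    for s, e, pos in lobes:
        peak = float(np.max(np.abs(x[s:e])))
        if peak >= floor:
            qual_signs.append(1 if pos else -1)
    if not qual_signs:
        return 0
    changes = sum(1 for a, b in zip(qual_signs, qual_signs[1:]) if a != b)
    return 1 + changes


def characterize(rectified: np.ndarray, epoch: EMGEpoch,
                 interval_ms: tuple[float, float],
                 background: BackgroundStats, muscle: str = "TA") -> ReflexEvent:
    """Onset, offset, peak and baseline-corrected AUC of one burst.

    AUC integrates the rectified signal above the background mean
    (negative residuals clipped to zero) over the interval, in µV·s.
    """
    i0 = epoch.index_of(interval_ms[0])
    i1 = epoch.index_of(interval_ms[1])
    x = np.asarray(rectified, dtype=float)[i0:i1]
    dt_s = epoch.dt_ms / 1000.0
    excess = np.clip(x - background.mu_bg_uV, 0.0, None)
    return ReflexEvent(
        muscle=muscle,
        onset_ms=float(interval_ms[0]),
        offset_ms=float(interval_ms[1]),
        peak_uV=float(x.max()) if x.size else 0.0,
        auc_uVs=float(excess.sum() * dt_s),
        n_phases=0)


def assign_window(onset_ms: float,
                  config: DetectionConfig | None = None) -> str:
    """TW1 for [90, 600), TW2 for [1000, 3000], intermediate for the gap."""
    config = config or DetectionConfig()
    if config.tw1_ms[0] <= onset_ms < config.tw1_ms[1]:
        return "TW1"
    if config.tw2_ms[0] <= onset_ms <= config.tw2_ms[1]:
        return "TW2"
    if config.tw1_ms[1] <= onset_ms < config.tw2_ms[0]:
        return "intermediate"
    return "none"


def detect_trial(epoch: EMGEpoch,
                 config: DetectionConfig | None = None) -> TrialDetection:
    """Run detection on both channels of a filtered (unrectified) epoch.

    The trial is invalidated (no events) when either channel's background SD
    exceeds ``artifact_sigma_max_uV`` — a movement/electrode artifact guard.
    Co-activation is flagged per window when TA and SO events in that window
    start within ``coactivation_max_dt_ms`` of each other.
    """
    config = config or DetectionConfig()
    background = {m: estimate_background(epoch, m, config) for m in MUSCLES}
    det = TrialDetection(
        participant_id=epoch.participant_id, site=epoch.site,
        trial_index=epoch.trial_index, background=background,
        pain_rating=epoch.pain_rating, valid=epoch.valid)
    if not epoch.valid:
        return det
    if any(b.sigma_bg_uV > config.artifact_sigma_max_uV
           for b in background.values()):
        det.valid = False
        return det
    for muscle in MUSCLES:
        filt = epoch.channel(muscle)
        rect = rectify(filt)
        bg = background[muscle]
        thr = bg.threshold_for(config)
        for interval in detect_bursts(rect, epoch, bg, config):
            n_ph = count_phases(filt, epoch, interval, thr, config)
            if n_ph < config.min_phases:
                continue
            ev = characterize(rect, epoch, interval, bg, muscle)
            ev.n_phases = n_ph
            ev.window = assign_window(ev.onset_ms, config)
            det.events.append(ev)
    for w in ("TW1", "TW2", "intermediate"):
        ta = [e.onset_ms for e in det.events if e.muscle == "TA" and e.window == w]
        so = [e.onset_ms for e in det.events if e.muscle == "SO" and e.window == w]
        if ta and so and min(abs(a - b) for a in ta for b in so) \
                <= config.coactivation_max_dt_ms:
            det.coactivated_tw.add(w)
    return det


def detections_to_frame(dets: list[TrialDetection]) -> pd.DataFrame:
    """Flatten detections into the events table (one row per event; trials
    without events contribute a single row with muscle/window empty so that
    valid-trial denominators survive the round trip)."""
    rows = []
    for d in dets:
        base = {"participant_id": d.participant_id, "site": d.site,
                "trial_index": d.trial_index, "valid": int(d.valid),
                "pain_rating": d.pain_rating}
        if not d.events:
            rows.append({**base, "muscle": "", "onset_ms": np.nan,
                         "offset_ms": np.nan, "peak_uV": np.nan,
                         "auc_uVs": np.nan, "n_phases": 0, "window": "",
                         "coactivated": 0})
        for e in d.events:
            rows.append({**base, "muscle": e.muscle, "onset_ms": e.onset_ms,
                         "offset_ms": e.offset_ms, "peak_uV": e.peak_uV,
                         "auc_uVs": e.auc_uVs, "n_phases": e.n_phases,
                         "window": e.window,
                         "coactivated": int(e.window in d.coactivated_tw)})
    return pd.DataFrame(rows)
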