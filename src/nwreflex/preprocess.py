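"""EMG conditioning: band-pass filtering, epoch segmentation, rectification.

The chain mirrors standard surface-EMG practice for stimulus-locked reflex
recordings: band-pass 1–450 Hz, cut -500 ... +3000 ms epochs around each
stimulus, full-wave rectify. Filtering is a 4th-order Butterworth applied
forward-backward (zero phase) so that detected onset latencies carry no
filter delay; the 450 Hz edge at fs = 1000 Hz sits at 0.9 Nyquist, hence
second-order sections for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .signal_io import (CANONICAL_POST_MS, CANONICAL_T0_MS, EMGEpoch,
                        InvariantError)


@dataclass
class PreprocessConfig:
    band_low_Hz: float = 1.0
    band_high_Hz: float = 450.0
    filter_order: int = 4
    zero_phase: bool = True
    target_rate_Hz: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_Hz < self.band_high_Hz:
            raise InvariantError("need 0 < band_low < band_high")
        if self.band_high_Hz >= self.target_rate_Hz / 2:
            raise InvariantError("band edge must stay below Nyquist")


@lru_cache(maxsize=32)
def _butter_sos(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(trace: np.ndarray, rate_hz: float,
             config: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    config = config or PreprocessConfig()
    if config.band_high_Hz >= rate_hz / 2:
        raise InvariantError(
            f"band edge {config.band_high_Hz} Hz >= Nyquist of {rate_hz} Hz")
    trace = np.asarray(trace, dtype=float)
    sos = _butter_sos(config.filter_order, config.band_low_Hz,
                      config.band_high_Hz, rate_hz)
    if config.zero_phase:
        return sps.sosfiltfilt(sos, trace)
    return sps.sosfilt(sos, trace)


def rectify(trace: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    return np.abs(np.asarray(trace, dtype=float))


def segment(ta: np.ndarray, so: np.ndarray, rate_hz: float,
            stimulus_times_ms: list[float] | np.ndarray,
            participant_id: str = "unknown", site: str = "FS",
            energy_mJ: float = float("nan"),
            pre_ms: float = -CANONICAL_T0_MS,
            post_ms: float = CANONICAL_POST_MS) -> list[EMGEpoch]:
    """Cut stimulus-locked epochs out of a continuous two-channel recording.

    ``stimulus_times_ms`` are marker positions on the recording's own time
    axis (first sample = 0 ms). The epoch sample at t = 0 equals the
    continuous sample at the marker. A marker too close to either edge
    yields an epoch flagged invalid (zero-filled), never a silently dropped
    trial.
    """
    ta = np.asarray(ta, dtype=float)
    so = np.asarray(so, dtype=float)
    if ta.shape != so.shape:
        raise InvariantError("TA and SO traces differ in length")
    dt_ms = 1000.0 / rate_hz
    n_pre = int(round(pre_ms / dt_ms))
    n_post = int(round(post_ms / dt_ms))
    n_epoch = n_pre + n_post + 1
    epochs: list[EMGEpoch] = []
    for k, t_ms in enumerate(stimulus_times_ms):
        i0 = int(round(t_ms / dt_ms))
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > len(ta):
            epochs.append(EMGEpoch(
                participant_id=participant_id, trial_index=k, site=site,
                energy_mJ=energy_mJ, sampling_rate_Hz=rate_hz,
                t0_offset_ms=-pre_ms,
                samples_TA=np.zeros(n_epoch), samples_SO=np.zeros(n_epoch),
                valid=False))
            continue
        epochs.append(EMGEpoch(
            participant_id=participant_id, trial_index=k, site=site,
            energy_mJ=energy_mJ, sampling_rate_Hz=rate_hz,
            t0_offset_ms=-pre_ms,
            samples_TA=ta[lo:hi].copy(), samples_SO=so[lo:hi].copy()))
    return epochs


def preprocess_epoch(epoch: EMGEpoch,
                     config: PreprocessConfig | None = None) -> EMGEpoch:
    """Band-pass filter both channels of an epoch (no rectification).

    Detection thresholds run on the rectified version of this output while
    phase counting runs on the signed signal, so the filtered-but-unrectified
    epoch is the canonical hand-off between preprocessing and detection.
    """
    config = config or PreprocessConfig()
    return EMGEpoch(
        participant_id=epoch.participant_id, trial_index=epoch.trial_index,
        site=epoch.site, energy_mJ=epoch.energy_mJ,
        sampling_rate_Hz=epoch.sampling_rate_Hz,
        t0_offset_ms=epoch.t0_offset_ms,
        samples_TA=bandpass(epoch.samples_TA, epoch.sampling_rate_Hz, config),
        samples_SO=bandpass(epoch.samples_SO, epoch.sampling_rate_Hz, config),
        pain_rating=epoch.pain_rating, valid=epoch.valid)
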