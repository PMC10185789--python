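"""Seeded synthetic cohorts of laser-evoked withdrawal-reflex recordings.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage (preprocessing, detection, aggregation,
statistics) is testable without any recorded data:

* background EMG: band-limited (20–450 Hz) Gaussian noise, SD 5 µV;
* reflex bursts: sums of alternating-sign Hann lobes ("polyphasic" by
  construction) planted in two latency windows, with site- and
  group-specific response probabilities, latencies and amplitudes;
* per-participant response propensities drawn from a Beta distribution
  (concentration 2) around the group/site/window mean rate, reproducing the
  zero-inflated spread of response rates seen clinically;
* inter-site latency shifts follow a per-participant latent conduction
  velocity: latencies are anchored at the sole of the foot (FS) and the
  more proximal sites lead by distance / CV (A-delta-range CV for TW1,
  C-fiber-range CV for TW2);
* spinal-cord-injured (SCI) trials co-activate tibialis anterior and soleus,
  control (NDC) responses are TA-dominant and TW2-only;
* the clinical table carries a configurable inverse association between
  central neuropathic pain and clinically relevant spasticity, generated by
  logit P(spasticity) = log(6) + log(1/18) * 1[CPG = yes].

Two layers are exposed: a fast *plan* layer (participants, propensities and
per-trial planted events, no waveforms) for distributional checks, and a
*render* layer producing full EMG epochs for the detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PreprocessConfig, bandpass
from .signal_io import (CANONICAL_POST_MS, CANONICAL_RATE_HZ, CANONICAL_T0_MS,
                        EMGEpoch, ParticipantRecord, SITES, canonical_n_samples,
                        write_clinical_table, write_epochs, write_manifest)

TWS = ("TW1", "TW2")
ISI_SET_MS = (6000, 7000, 9000)

#: laser energies per site (mJ): lower on hairy skin (FH, FD) than glabrous (FS)
SITE_ENERGIES_MJ = {"FS": (600, 660), "FD": (540, 600), "FH": (540, 600)}


@dataclass
class GroupSimParams:
    """Per-group generator parameters; defaults transcribe the reference
    cohort's response rates, latencies, amplitudes and pain ratings."""

    group: str
    p_respond_tw1: dict[str, float]
    p_respond_tw2: dict[str, float]
    latency_mean_ms: dict[tuple[str, str], float]
    latency_sd_ms: dict[tuple[str, str], float]  # between-participant spread
    trial_jitter_sd_ms: dict[str, float]
    burst_amplitude_uV: dict[str, float]
    burst_duration_ms: dict[str, tuple[float, float]]
    coactivation_prob: float
    ta_only_prob: float
    noise_sd_uV: float
    cv_tw1_mean_mps: float
    cv_tw1_sd_mps: float
    cv_tw2_mean_mps: float
    cv_tw2_sd_mps: float
    cv_jitter_frac: float
    pain_rating_mean: dict[str, float]
    pain_rating_sd: dict[str, float]
    analgesia_prob: dict[str, float]
    propensity_concentration: float = 2.0
    n_phases_range: tuple[int, int] = (3, 6)
    amplitude_rel_range: tuple[float, float] = (0.7, 1.3)
    noise_band_Hz: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self) -> None:
        for d in (self.p_respond_tw1, self.p_respond_tw2):
            for s, p in d.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability out of range for {s}: {p}")
        if any(v < 0 for v in self.latency_sd_ms.values()):
            raise ValueError("latency SDs must be >= 0")
        if any(v <= 0 for v in self.burst_amplitude_uV.values()):
            raise ValueError("amplitudes must be > 0")


def sci_default_params() -> GroupSimParams:
    return GroupSimParams(
        group="SCI",
        p_respond_tw1={"FS": 0.096, "FD": 0.144, "FH": 0.143},
        p_respond_tw2={"FS": 0.199, "FD": 0.207, "FH": 0.162},
        latency_mean_ms={("FS", "TW1"): 187.0, ("FD", "TW1"): 245.0,
                         ("FH", "TW1"): 278.0, ("FS", "TW2"): 1460.0,
                         ("FD", "TW2"): 1172.0, ("FH", "TW2"): 1257.0},
        latency_sd_ms={("FS", "TW1"): 39.0, ("FD", "TW1"): 81.0,
                       ("FH", "TW1"): 111.0, ("FS", "TW2"): 175.0,
                       ("FD", "TW2"): 254.0, ("FH", "TW2"): 158.0},
        trial_jitter_sd_ms={"TW1": 15.0, "TW2": 30.0},
        burst_amplitude_uV={"TW1": 300.0, "TW2": 1000.0},
        burst_duration_ms={"TW1": (80.0, 200.0), "TW2": (150.0, 400.0)},
        coactivation_prob=0.7,
        ta_only_prob=0.6,
        noise_sd_uV=5.0,
        cv_tw1_mean_mps=10.0, cv_tw1_sd_mps=3.0,
        cv_tw2_mean_mps=1.34, cv_tw2_sd_mps=0.46,
        cv_jitter_frac=0.05,
        pain_rating_mean={"FS": 4.2, "FD": 4.5, "FH": 1.7},
        pain_rating_sd={"FS": 7.3, "FD": 6.7, "FH": 2.7},
        analgesia_prob={"FS": 0.46, "FD": 0.40, "FH": 0.50},
    )


def ndc_default_params() -> GroupSimParams:
    # NDC: no TW1 responses at all, small TW2 rates, TA-dominant (78%),
    # no co-activation; TW2 amplitude 1/40 of SCI, duration 1/2.5 (so that
    # burst magnitude (AUC) differs by ~2 orders of magnitude).
    return GroupSimParams(
        group="NDC",
        p_respond_tw1={"FS": 0.0, "FD": 0.0, "FH": 0.0},
        p_respond_tw2={"FS": 0.025, "FD": 0.043, "FH": 0.031},
        latency_mean_ms={("FS", "TW1"): 250.0, ("FD", "TW1"): 250.0,
                         ("FH", "TW1"): 250.0, ("FS", "TW2"): 1571.0,
                         ("FD", "TW2"): 1231.0, ("FH", "TW2"): 1030.0},
        latency_sd_ms={("FS", "TW1"): 50.0, ("FD", "TW1"): 50.0,
                       ("FH", "TW1"): 50.0, ("FS", "TW2"): 153.0,
                       ("FD", "TW2"): 264.0, ("FH", "TW2"): 249.0},
        trial_jitter_sd_ms={"TW1": 15.0, "TW2": 30.0},
        burst_amplitude_uV={"TW1": 25.0, "TW2": 25.0},
        burst_duration_ms={"TW1": (60.0, 160.0), "TW2": (60.0, 160.0)},
        coactivation_prob=0.0,
        ta_only_prob=0.78,
        noise_sd_uV=5.0,
        cv_tw1_mean_mps=10.0, cv_tw1_sd_mps=3.0,
        cv_tw2_mean_mps=1.08, cv_tw2_sd_mps=0.38,
        cv_jitter_frac=0.05,
        pain_rating_mean={"FS": 14.6, "FD": 15.7, "FH": 14.4},
        pain_rating_sd={"FS": 8.9, "FD": 11.0, "FH": 9.1},
        analgesia_prob={"FS": 0.0, "FD": 0.0, "FH": 0.0},
    )


@dataclass
class ClinicalSimParams:
    """Clinical-table generator: cohort sizes and the pain/spasticity model."""
    n_sci: int = 15
    n_ndc: int = 12
    p_cpg: float = 8 / 15
    spasticity_base_odds: float = 6.0        # odds of spasticity when CPG = no
    spasticity_cpg_logodds: float = math.log(1.0 / 18.0)  # approx. -2.89
    n_joints: int = 6
    distance_FS_FH_mean_m: float = 0.42
    distance_FS_FH_sd_m: float = 0.02

    def __post_init__(self) -> None:
        if self.n_sci < 0 or self.n_ndc < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.spasticity_base_odds <= 0:
            raise ValueError("odds must be > 0")


@dataclass
class ParticipantLatent:
    """Per-participant latent state shared by all that participant's trials."""
    cv_tw1_mps: float
    cv_tw2_mps: float
    propensity: dict[tuple[str, str], float]       # (site, TW) -> P(response)
    anchor_latency_ms: dict[str, float]            # TW -> FS-referenced onset
    pain_mean: dict[str, float]
    analgesic_site: dict[str, bool]
    spasticity_relevant: bool | None = None


@dataclass
class PlannedEvent:
    """Ground truth of one planted burst."""
    participant_id: str
    site: str
    trial_index: int
    muscle: str
    tw: str
    latency_ms: float
    duration_ms: float
    amplitude_uV: float
    n_phases: int


_AIS_CHOICES = ("A", "C", "D")
_AIS_PROBS = (0.40, 0.07, 0.53)
_NLI_CHOICES = ("C2", "C3", "C5", "C6", "T1", "T3", "T4", "T5", "T7", "T8")


def _spast_joint_scores(rng: np.random.Generator, relevant: bool,
                        n_joints: int, max_grade: float) -> tuple[float, ...]:
    base = np.clip(rng.normal(0.6, 0.5, n_joints), 0.0, 1.0)
    if relevant:
        k = rng.integers(1, max(2, n_joints // 2))
        idx = rng.choice(n_joints, size=k, replace=False)
        base[idx] = rng.uniform(1.5, max_grade, size=k)
    return tuple(np.round(base * 2) / 2)


def simulate_participant(group: str, gparams: GroupSimParams,
                         cparams: ClinicalSimParams,
                         rng: np.random.Generator,
                         index: int = 0
                         ) -> tuple[ParticipantRecord, ParticipantLatent]:
    """Draw one participant's clinical record and latent reflex physiology."""
    pid = f"{'S' if group == 'SCI' else 'N'}{index + 1:02d}"
    age = float(np.clip(rng.normal(45, 14), 18, 65))
    sex = "M" if rng.random() < 0.5 else "F"
    d_fs_fh = float(np.clip(rng.normal(cparams.distance_FS_FH_mean_m,
                                       cparams.distance_FS_FH_sd_m), 0.30, 0.55))
    if group == "SCI":
        cpg = bool(rng.random() < cparams.p_cpg)
        logit = math.log(cparams.spasticity_base_odds) \
            + (cparams.spasticity_cpg_logodds if cpg else 0.0)
        spast = bool(rng.random() < 1.0 / (1.0 + math.exp(-logit)))
        mas = _spast_joint_scores(rng, spast, cparams.n_joints, 4.0)
        scat = _spast_joint_scores(rng, spast, cparams.n_joints, 3.0)
        scipi_loc = 5.1 if cpg else 2.0
        scipi = int(np.clip(round(rng.normal(scipi_loc, 1.5)), 0, 7))
        nrs_loc = 6.4 if cpg else 2.4
        nrs = int(np.clip(round(rng.normal(nrs_loc, 1.8)), 0, 10))
        nocp = bool((not cpg) and nrs >= 1 and rng.random() < 0.7)
        record = ParticipantRecord(
            participant_id=pid, group="SCI", age_years=round(age, 1), sex=sex,
            AIS=str(rng.choice(_AIS_CHOICES, p=_AIS_PROBS)),
            NLI=str(rng.choice(_NLI_CHOICES)),
            TSI_years=round(float(np.clip(rng.lognormal(1.2, 1.0), 0.8, 35.0)), 1),
            SCIPI_score=scipi, CPG_neuropathic=cpg, NocP=nocp,
            NRS_spontaneous=nrs,
            MAS_joint_scores=mas, SCAT_joint_scores=scat,
            distance_FS_FH_m=round(d_fs_fh, 3), distance_FD_FH_m=0.40)
    else:
        spast = None
        record = ParticipantRecord(
            participant_id=pid, group="NDC", age_years=round(age, 1), sex=sex,
            NRS_spontaneous=0,
            distance_FS_FH_m=round(d_fs_fh, 3), distance_FD_FH_m=0.40)

    c = gparams.propensity_concentration
    propensity: dict[tuple[str, str], float] = {}
    for tw, pmap in (("TW1", gparams.p_respond_tw1), ("TW2", gparams.p_respond_tw2)):
        for site in SITES:
            p = pmap[site]
            if p <= 0:
                propensity[(site, tw)] = 0.0
            elif p >= 1:
                propensity[(site, tw)] = 1.0
            else:
                propensity[(site, tw)] = float(rng.beta(c * p, c * (1 - p)))
    cv1 = float(np.clip(rng.normal(gparams.cv_tw1_mean_mps, gparams.cv_tw1_sd_mps),
                        4.0, 20.0))
    cv2 = float(np.clip(rng.normal(gparams.cv_tw2_mean_mps, gparams.cv_tw2_sd_mps),
                        0.6, 3.0))
    # proximal-site anchor latencies, truncated to stay inside their window
    # (distal sites only add positive conduction delay)
    anchor_min = {"TW1": 95.0, "TW2": 1005.0}
    anchor = {tw: float(max(anchor_min[tw],
                            rng.normal(gparams.latency_mean_ms[("FH", tw)],
                                       gparams.latency_sd_ms[("FH", tw)])))
              for tw in TWS}
    latent = ParticipantLatent(
        cv_tw1_mps=cv1, cv_tw2_mps=cv2, propensity=propensity,
        anchor_latency_ms=anchor,
        pain_mean={s: float(abs(rng.normal(gparams.pain_rating_mean[s],
                                           gparams.pain_rating_sd[s] / 2)))
                   for s in SITES},
        analgesic_site={s: bool(rng.random() < gparams.analgesia_prob[s])
                        for s in SITES},
        spasticity_relevant=spast)
    return record, latent


# --------------------------------------------------------------------------
# burst morphology
# --------------------------------------------------------------------------

def simulate_burst(latency_ms: float, duration_ms: float, amplitude_uV: float,
                   n_phases: int, rng: np.random.Generator,
                   n_samples: int | None = None,
                   rate_hz: float = CANONICAL_RATE_HZ,
                   t0_offset_ms: float = CANONICAL_T0_MS,
                   envelope: str = "hann") -> np.ndarray:
    """Signed (unrectified) burst waveform on the epoch sample grid.

    The burst is a train of alternating-sign lobes (at least ``n_phases`` of
    them; more when the duration allows ~20 ms lobes, the width of motor
    deflections in clinical surface EMG) with peak amplitudes in
    [0.6, 1] x ``amplitude_uV`` (the largest lobe hits ``amplitude_uV``
    exactly), zero outside [latency, latency + duration). Positive and
    negative lobe areas are width-balanced so the waveform integrates to
    ~zero — real EMG carries no DC, and net area would otherwise excite a
    1 Hz high-pass into long baseline tails. ``envelope`` selects the lobe
    shape: ``"hann"`` (sin^2, smooth) or ``"rect"`` (all lobes at the full
    amplitude with a flat top and 5 % cosine ramps, so the rectified
    integral is approx. amplitude x duration).
    """
    if n_phases < 3:
        raise ValueError("polyphasic bursts need n_phases >= 3")
    if duration_ms / 1000.0 * rate_hz < n_phases:
        raise ValueError("duration shorter than n_phases samples")
    if n_samples is None:
        n_samples = canonical_n_samples(rate_hz, t0_offset_ms)
    lobe_target_ms = 20.0
    n_lobes = max(n_phases, int(round(duration_ms / lobe_target_ms)))
    widths = rng.uniform(0.7, 1.3, n_lobes)
    widths = widths / widths.sum()
    if envelope == "rect":
        amps = np.full(n_lobes, float(amplitude_uV))
    else:
        amps = rng.uniform(0.6, 1.0, n_lobes)
        amps = amps / amps.max() * amplitude_uV
    signs = np.empty(n_lobes)
    signs[::2] = 1.0 if rng.random() < 0.5 else -1.0
    signs[1::2] = -signs[0]
    area_factor = 0.5 if envelope == "hann" else 0.95
    pos = signs > 0
    area_p = float((amps[pos] * widths[pos]).sum()) * area_factor
    area_n = float((amps[~pos] * widths[~pos]).sum()) * area_factor
    if area_p > 0 and area_n > 0:
        wp, wn = float(widths[pos].sum()), float(widths[~pos].sum())
        f = 1.0 / (wp + wn * area_p / area_n)
        g = f * area_p / area_n
        widths = np.where(pos, widths * f, widths * g)
    edges = np.concatenate(([0.0], np.cumsum(widths)))
    edges[-1] = 1.0

    t = t0_offset_ms + np.arange(n_samples) * (1000.0 / rate_hz)
    u = (t - latency_ms) / duration_ms
    out = np.zeros(n_samples)
    inside = (u >= 0.0) & (u < 1.0)
    if not inside.any():
        return out
    ui = u[inside]
    lobe = np.clip(np.searchsorted(edges, ui, side="right") - 1, 0, n_lobes - 1)
    v = (ui - edges[lobe]) / widths[lobe]  # position within lobe, [0, 1)
    if envelope == "hann":
        shape = np.sin(np.pi * v) ** 2
    elif envelope == "rect":
        ramp = 0.05
        shape = np.ones_like(v)
        shape = np.where(v < ramp, 0.5 - 0.5 * np.cos(np.pi * v / ramp), shape)
        shape = np.where(v > 1 - ramp,
                         0.5 - 0.5 * np.cos(np.pi * (1 - v) / ramp), shape)
    else:
        raise ValueError(f"unknown envelope {envelope!r}")
    out[inside] = signs[lobe] * amps[lobe] * shape
    return out


def _bandlimited_noise(n: int, rate_hz: float, sd_uV: float,
                       band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    cfg = PreprocessConfig(band_low_Hz=band[0], band_high_Hz=band[1])
    x = bandpass(white, rate_hz, cfg)
    s = x.std()
    return x / s * sd_uV if s > 0 else x


# --------------------------------------------------------------------------
# trial planning and rendering
# --------------------------------------------------------------------------

def _site_latency(latent: ParticipantLatent, site: str, tw: str,
                  gparams: GroupSimParams, record: ParticipantRecord,
                  rng: np.random.Generator) -> float:
    """Planted onset: proximal-site (FH) anchor plus conduction delay.

    The afferent path from the stimulation site to the cord is longest for
    the sole of the foot, so distal sites lag the FH anchor by
    distance / CV. Without a known distance the site's own latency table is
    used as an independent fallback.
    """
    cv = latent.cv_tw1_mps if tw == "TW1" else latent.cv_tw2_mps
    if gparams.cv_jitter_frac > 0:
        cv = max(0.1, cv * (1.0 + gparams.cv_jitter_frac * rng.standard_normal()))
    d_fs_fh = record.distance_FS_FH_m
    d_fd_fh = record.distance_FD_FH_m
    if (site == "FS" and d_fs_fh is None) or (site == "FD" and d_fd_fh is None):
        lat = rng.normal(gparams.latency_mean_ms[(site, tw)],
                         gparams.latency_sd_ms[(site, tw)])
    else:
        dist_m = {"FH": 0.0, "FD": d_fd_fh or 0.0, "FS": d_fs_fh or 0.0}[site]
        lat = latent.anchor_latency_ms[tw] + dist_m / cv * 1000.0
    jit_sd = gparams.trial_jitter_sd_ms[tw]
    if jit_sd > 0:
        lat += rng.normal(0.0, jit_sd)
    return lat


def plan_trial(record: ParticipantRecord, latent: ParticipantLatent,
               site: str, trial_index: int, gparams: GroupSimParams,
               rng: np.random.Generator) -> list[PlannedEvent]:
    """Decide, without rendering, which bursts this trial contains."""
    events: list[PlannedEvent] = []
    for tw in TWS:
        if rng.random() >= latent.propensity[(site, tw)]:
            continue
        dur = float(rng.uniform(*gparams.burst_duration_ms[tw]))
        lat = _site_latency(latent, site, tw, gparams, record, rng)
        # onset must stay inside its window; the burst itself only needs to
        # fit the epoch (it may run past the window's upper edge)
        lo = (90.0 if tw == "TW1" else 1000.0) + 5.0
        hi = min((600.0 if tw == "TW1" else 3000.0) - 5.0, 2995.0 - dur)
        lat = float(np.clip(lat, lo, hi))
        amp = gparams.burst_amplitude_uV[tw] * float(
            rng.uniform(*gparams.amplitude_rel_range))
        n_ph = int(rng.integers(gparams.n_phases_range[0],
                                gparams.n_phases_range[1] + 1))
        coact = rng.random() < gparams.coactivation_prob
        if coact:
            muscles = ["TA", "SO"]
        else:
            muscles = ["TA"] if rng.random() < gparams.ta_only_prob else ["SO"]
        for m in muscles:
            m_lat = lat
            if m == "SO" and coact:
                m_lat = lat + float(np.clip(rng.normal(0.0, 15.0), -40.0, 40.0))
            events.append(PlannedEvent(
                participant_id=record.participant_id, site=site,
                trial_index=trial_index, muscle=m, tw=tw, latency_ms=m_lat,
                duration_ms=dur, amplitude_uV=amp, n_phases=n_ph))
    return events


def render_trial(record: ParticipantRecord, latent: ParticipantLatent,
                 site: str, trial_index: int, gparams: GroupSimParams,
                 rng: np.random.Generator,
                 planned: list[PlannedEvent] | None = None
                 ) -> tuple[EMGEpoch, list[PlannedEvent]]:
    """Render one trial: plan bursts (unless given) and add them to noise."""
    if planned is None:
        planned = plan_trial(record, latent, site, trial_index, gparams, rng)
    n = canonical_n_samples()
    chans = {m: _bandlimited_noise(n, CANONICAL_RATE_HZ, gparams.noise_sd_uV,
                                   gparams.noise_band_Hz, rng)
             for m in ("TA", "SO")}
    for ev in planned:
        chans[ev.muscle] = chans[ev.muscle] + simulate_burst(
            ev.latency_ms, ev.duration_ms, ev.amplitude_uV, ev.n_phases, rng,
            n_samples=n)
    energy = float(rng.choice(SITE_ENERGIES_MJ[site]))
    if latent.analgesic_site[site]:
        pain = 0.0
    else:
        pain = float(np.clip(rng.normal(latent.pain_mean[site], 3.0), 0, 100))
    epoch = EMGEpoch(
        participant_id=record.participant_id, trial_index=trial_index,
        site=site, energy_mJ=energy, sampling_rate_Hz=CANONICAL_RATE_HZ,
        t0_offset_ms=CANONICAL_T0_MS, samples_TA=chans["TA"],
        samples_SO=chans["SO"], pain_rating=round(pain, 1))
    return epoch, planned


# alias matching the operation name used throughout the docs
simulate_trial = render_trial


# --------------------------------------------------------------------------
# cohort level
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    seed: int = 0
    n_sci: int = 15
    n_ndc: int = 12
    trials_per_site: int = 60
    sites: tuple[str, ...] = SITES
    sci_params: GroupSimParams = field(default_factory=sci_default_params)
    ndc_params: GroupSimParams = field(default_factory=ndc_default_params)
    clinical: ClinicalSimParams = field(default_factory=ClinicalSimParams)


@dataclass
class CohortResult:
    records: list[ParticipantRecord]
    latents: dict[str, ParticipantLatent]
    epochs: dict[tuple[str, str], list[EMGEpoch]]  # (participant, site)
    planned: pd.DataFrame
    manifest: pd.DataFrame


def _participant_rng(seed: int, group_idx: int, pidx: int,
                     site_idx: int | None = None) -> np.random.Generator:
    key = (group_idx, pidx) if site_idx is None else (group_idx, pidx, site_idx)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_cohort(config: CohortConfig, outdir: str | Path | None = None,
                    render: bool = True) -> CohortResult:
    """Generate a full cohort; optionally write all artifacts to ``outdir``.

    The single seed fans out into one substream per participant and per
    participant x site, so changing cohort size never reshuffles earlier
    participants. With ``render=False`` only the plan layer runs (fast).
    """
    cfg = config
    records: list[ParticipantRecord] = []
    latents: dict[str, ParticipantLatent] = {}
    epochs: dict[tuple[str, str], list[EMGEpoch]] = {}
    planned_rows: list[PlannedEvent] = []
    manifest_rows: list[dict] = []

    groups = [("SCI", cfg.n_sci, cfg.sci_params), ("NDC", cfg.n_ndc, cfg.ndc_params)]
    for gi, (group, n, gparams) in enumerate(groups):
        for p in range(n):
            rng_p = _participant_rng(cfg.seed, gi, p)
            record, latent = simulate_participant(
                group, gparams, cfg.clinical, rng_p, index=p)
            records.append(record)
            latents[record.participant_id] = latent
            for si, site in enumerate(cfg.sites):
                rng_s = _participant_rng(cfg.seed, gi, p, si)
                eps: list[EMGEpoch] = []
                for tr in range(cfg.trials_per_site):
                    isi = int(rng_s.choice(ISI_SET_MS))
                    if render:
                        ep, plan = render_trial(record, latent, site, tr,
                                                gparams, rng_s)
                        eps.append(ep)
                        energy, pain = ep.energy_mJ, ep.pain_rating
                    else:
                        plan = plan_trial(record, latent, site, tr, gparams, rng_s)
                        energy = float(rng_s.choice(SITE_ENERGIES_MJ[site]))
                        pain = None
                    planned_rows.extend(plan)
                    manifest_rows.append({
                        "participant_id": record.participant_id, "site": site,
                        "trial_index": tr, "energy_mJ": energy, "ISI_ms": isi,
                        "pain_rating": pain, "valid": 1})
                if render:
                    epochs[(record.participant_id, site)] = eps

    if planned_rows:
        planned = pd.DataFrame([asdict(e) for e in planned_rows])
    else:
        planned = pd.DataFrame(
            columns=list(PlannedEvent.__dataclass_fields__))
    manifest = pd.DataFrame(manifest_rows)
    result = CohortResult(records=records, latents=latents, epochs=epochs,
                          planned=planned, manifest=manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_clinical_table(records, outdir / "clinical.tsv")
        write_manifest(manifest, outdir / "manifest.tsv")
        planned.to_csv(outdir / "planted_truth.tsv", sep="\t", index=False,
                       float_format="%.6g")
        for (pid, site), eps in epochs.items():
            write_epochs(eps, outdir / f"epochs_{pid}_{site}.tsv")
    return result


def cohort_response_rates(result: CohortResult,
                          trials_per_site: int) -> pd.DataFrame:
    """Planted (ground-truth) response rates per participant x site x window.

    A trial counts as a response in a window when at least one burst was
    planted there, regardless of muscle.
    """
    rows = []
    planned = result.planned
    for rec in result.records:
        for site in SITES:
            for tw in TWS:
                if len(planned):
                    sub = planned[(planned.participant_id == rec.participant_id)
                                  & (planned.site == site) & (planned.tw == tw)]
                    n_resp = sub.trial_index.nunique()
                else:
                    n_resp = 0
                rows.append({
                    "participant_id": rec.participant_id, "group": rec.group,
                    "site": site, "window": tw,
                    "response_rate_pct": 100.0 * n_resp / trials_per_site})
    return pd.DataFrame(rows)
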