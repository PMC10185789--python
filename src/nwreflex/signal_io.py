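"""Domain types and on-disk formats for laser-evoked withdrawal-reflex data.

Everything the pipeline reads or writes lives here: stimulus-locked EMG
epochs (two channels, tibialis anterior TA and soleus SO), trial manifests,
clinical cohort tables, and detection outputs.

Conventions
-----------
* Time is in milliseconds relative to laser onset (onset = 0); sample ``i``
  of an epoch sits at ``t0_offset_ms + i * 1000 / sampling_rate_Hz``.
* Every named window is half-open ``[a, b)`` unless stated otherwise.
* The canonical epoch geometry is -500 ... +3000 ms at 1000 Hz
  (3501 samples per channel).
* All on-disk artifacts are tab-separated text; metadata lines start
  with ``#``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SITES = ("FS", "FD", "FH")
MUSCLES = ("TA", "SO")
GROUPS = ("SCI", "NDC")
AIS_GRADES = ("A", "B", "C", "D", "E")

#: tokens that map to a missing value when reading clinical tables
MISSING_TOKENS = {"", "n.a.", "na", "n/a", "MD", "md", "nan", "NaN", "None"}

CANONICAL_RATE_HZ = 1000.0
CANONICAL_T0_MS = -500.0
CANONICAL_POST_MS = 3000.0


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected layout."""


class InvariantError(ValueError):
    """Raised when parsed data violates a domain-type invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class EMGEpoch:
    """One stimulus-locked two-channel EMG trace — the unit of detection."""

    participant_id: str
    trial_index: int
    site: str
    energy_mJ: float
    sampling_rate_Hz: float
    t0_offset_ms: float
    samples_TA: np.ndarray  # µV
    samples_SO: np.ndarray  # µV
    pain_rating: float | None = None  # per-stimulus NRS 0–100
    valid: bool = True

    def __post_init__(self) -> None:
        self.samples_TA = np.asarray(self.samples_TA, dtype=float)
        self.samples_SO = np.asarray(self.samples_SO, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.site not in SITES:
            raise InvariantError(f"unknown site {self.site!r}")
        if len(self.samples_TA) != len(self.samples_SO):
            raise InvariantError(
                f"trial {self.participant_id}/{self.site}/{self.trial_index}: "
                f"channel lengths differ (TA {len(self.samples_TA)}, "
                f"SO {len(self.samples_SO)})"
            )
        if not self.sampling_rate_Hz > 2 * 450:
            raise InvariantError(
                f"sampling rate {self.sampling_rate_Hz} Hz is below twice the "
                "450 Hz band edge"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples_TA)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_Hz

    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(self.n_samples) * self.dt_ms

    def channel(self, muscle: str) -> np.ndarray:
        if muscle == "TA":
            return self.samples_TA
        if muscle == "SO":
            return self.samples_SO
        raise KeyError(muscle)

    def index_of(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms``."""
        return int(math.ceil((t_ms - self.t0_offset_ms) / self.dt_ms - 1e-9))


def canonical_n_samples(rate_hz: float = CANONICAL_RATE_HZ,
                        t0_ms: float = CANONICAL_T0_MS,
                        post_ms: float = CANONICAL_POST_MS) -> int:
    """Sample count of one epoch: (post − t0)/1000 · fs + 1 (3501 canonically)."""
    return int(round((post_ms - t0_ms) / 1000.0 * rate_hz)) + 1


@dataclass
class ParticipantRecord:
    """Clinical scores, site distances and group label for one participant."""

    participant_id: str
    group: str  # SCI | NDC
    age_years: float | None = None
    sex: str | None = None
    AIS: str | None = None
    NLI: str | None = None
    TSI_years: float | None = None
    SCIPI_score: int | None = None  # 0–7 neuropathic-pain screen
    CPG_neuropathic: bool | None = None  # clinical pain grading, final call
    NocP: bool | None = None
    NRS_spontaneous: int | None = None  # 0–10
    MAS_joint_scores: tuple[float, ...] = ()
    SCAT_joint_scores: tuple[float, ...] = ()
    MAS_mean: float | None = None
    SCAT_mean: float | None = None
    distance_FS_FH_m: float | None = None
    distance_FD_FH_m: float | None = 0.40

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvariantError(f"unknown group {self.group!r}")
        if self.AIS is not None and self.AIS not in AIS_GRADES:
            raise InvariantError(
                f"participant {self.participant_id}: unknown AIS grade {self.AIS!r}"
            )
        if self.MAS_joint_scores and self.MAS_mean is None:
            self.MAS_mean = float(np.mean(self.MAS_joint_scores))
        if self.SCAT_joint_scores and self.SCAT_mean is None:
            self.SCAT_mean = float(np.mean(self.SCAT_joint_scores))
        if (self.MAS_joint_scores and self.MAS_mean is not None
                and abs(self.MAS_mean - float(np.mean(self.MAS_joint_scores))) > 0.01):
            raise InvariantError(
                f"participant {self.participant_id}: MAS_mean inconsistent with joints"
            )
        if self.group == "NDC" and any(
                v is not None for v in (self.AIS, self.NLI, self.TSI_years)):
            raise InvariantError(
                f"participant {self.participant_id}: NDC records must not carry "
                "AIS/NLI/TSI"
            )


@dataclass
class DetectionConfig:
    """Tunables of the threshold/burst/time-window detector.

    The reflex definition is EMG activity exceeding the background mean by
    ``threshold_sd_multiplier`` standard deviations of the rectified
    pre-stimulus window, with a polyphasic shape (>= ``min_phases`` phases).
    TW1 (~A-delta latencies) and TW2 (C-fiber latencies) are disjoint
    half-open / closed windows.
    """

    noise_window_ms: tuple[float, float] = (-500.0, 0.0)
    threshold_sd_multiplier: float = 2.0
    min_burst_ms: float = 6.0
    offset_hold_ms: float = 50.0
    merge_gap_ms: float = 50.0
    min_phases: int = 3
    phase_amplitude_fraction: float = 0.5
    tw1_ms: tuple[float, float] = (90.0, 600.0)   # half-open [90, 600)
    tw2_ms: tuple[float, float] = (1000.0, 3000.0)  # closed [1000, 3000]
    artifact_sigma_max_uV: float = 30.0
    coactivation_max_dt_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.threshold_sd_multiplier <= 0:
            raise InvariantError("threshold multiplier must be > 0")
        if not self.noise_window_ms[0] < self.noise_window_ms[1] <= 0:
            raise InvariantError("noise window must precede stimulus onset")
        if self.tw1_ms[1] > self.tw2_ms[0]:
            raise InvariantError("TW1 and TW2 must be disjoint")


# --------------------------------------------------------------------------
# epoch TSV
# --------------------------------------------------------------------------

_EPOCH_COLS = ("time_ms", "TA_uV", "SO_uV")


def write_epochs(epochs: Sequence[EMGEpoch], path: str | Path) -> Path:
    """Write epochs as a TSV block file.

    Layout: ``#``-prefixed file metadata, then per trial a
    ``# trial`` metadata line followed by one row per sample
    (columns time_ms, TA_uV, SO_uV). Values keep 6 significant digits.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("# nwreflex epochs v1\n")
    if epochs:
        e0 = epochs[0]
        buf.write(f"# participant: {e0.participant_id}\n")
        buf.write(f"# site: {e0.site}\n")
        buf.write(f"# sampling_rate_Hz: {e0.sampling_rate_Hz:g}\n")
        buf.write(f"# t0_offset_ms: {e0.t0_offset_ms:g}\n")
    buf.write("\t".join(_EPOCH_COLS) + "\n")
    for ep in epochs:
        pain = "" if ep.pain_rating is None else f"{ep.pain_rating:g}"
        buf.write(
            f"# trial\t{ep.trial_index}\tparticipant={ep.participant_id}"
            f"\tsite={ep.site}\tenergy_mJ={ep.energy_mJ:g}"
            f"\tpain_rating={pain}\tvalid={int(ep.valid)}\n"
        )
        t = ep.times_ms()
        for i in range(ep.n_samples):
            buf.write(f"{t[i]:.6g}\t{ep.samples_TA[i]:.6g}\t{ep.samples_SO[i]:.6g}\n")
    path.write_text(buf.getvalue())
    return path


def read_epochs(path: str | Path) -> list[EMGEpoch]:
    """Read an epoch TSV written by :func:`write_epochs`."""
    path = Path(path)
    rate = CANONICAL_RATE_HZ
    t0 = CANONICAL_T0_MS
    participant = "unknown"
    site = "FS"
    epochs: list[EMGEpoch] = []
    cur_meta: dict | None = None
    ta: list[float] = []
    so: list[float] = []

    def flush() -> None:
        nonlocal cur_meta, ta, so
        if cur_meta is None:
            return
        epochs.append(EMGEpoch(
            participant_id=cur_meta["participant"],
            trial_index=cur_meta["trial_index"],
            site=cur_meta["site"],
            energy_mJ=cur_meta["energy_mJ"],
            sampling_rate_Hz=rate,
            t0_offset_ms=t0,
            samples_TA=np.array(ta),
            samples_SO=np.array(so),
            pain_rating=cur_meta["pain_rating"],
            valid=cur_meta["valid"],
        ))
        cur_meta, ta, so = None, [], []

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("# trial"):
                flush()
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: malformed trial header")
                meta = {"participant": participant, "site": site,
                        "energy_mJ": float("nan"), "pain_rating": None,
                        "valid": True, "trial_index": int(parts[1])}
                for kv in parts[2:]:
                    if "=" not in kv:
                        raise FormatError(
                            f"{path}:{lineno}: malformed trial metadata {kv!r}")
                    k, v = kv.split("=", 1)
                    if k == "participant":
                        meta["participant"] = v
                    elif k == "site":
                        meta["site"] = v
                    elif k == "energy_mJ":
                        meta["energy_mJ"] = float(v)
                    elif k == "pain_rating":
                        meta["pain_rating"] = float(v) if v else None
                    elif k == "valid":
                        meta["valid"] = bool(int(v))
                cur_meta = meta
            elif line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("participant:"):
                    participant = body.split(":", 1)[1].strip()
                elif body.startswith("site:"):
                    site = body.split(":", 1)[1].strip()
                elif body.startswith("sampling_rate_Hz:"):
                    rate = float(body.split(":", 1)[1])
                elif body.startswith("t0_offset_ms:"):
                    t0 = float(body.split(":", 1)[1])
            elif line.startswith("time_ms"):
                if line.split("\t") != list(_EPOCH_COLS):
                    raise FormatError(
                        f"{path}:{lineno}: unexpected column header {line!r}")
            else:
                if cur_meta is None:
                    raise FormatError(
                        f"{path}:{lineno}: sample row outside any trial block")
                fields = line.split("\t")
                if len(fields) != 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
                ta.append(float(fields[1]))
                so.append(float(fields[2]))
    flush()
    return epochs


# --------------------------------------------------------------------------
# trial manifest
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = ("participant_id", "site", "trial_index",
                    "energy_mJ", "ISI_ms", "pain_rating", "valid")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"participant_id": str, "site": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# clinical table
# --------------------------------------------------------------------------

def _missing(tok) -> bool:
    if tok is None:
        return True
    if isinstance(tok, float) and math.isnan(tok):
        return True
    return str(tok).strip() in MISSING_TOKENS


def _opt_float(tok) -> float | None:
    return None if _missing(tok) else float(tok)


def _opt_int(tok) -> int | None:
    return None if _missing(tok) else int(float(tok))


def _opt_bool(tok, row: str, col: str) -> bool | None:
    if _missing(tok):
        return None
    s = str(tok).strip().upper()
    if s in {"Y", "YES", "1", "TRUE"}:
        return True
    if s in {"N", "NO", "0", "FALSE"}:
        return False
    raise FormatError(f"row {row}, column {col}: cannot parse yes/no value {tok!r}")


def read_clinical_table(path: str | Path) -> list[ParticipantRecord]:
    """Read a clinical cohort TSV (columns ID, Age, Gender, AIS, NLI, TSI,
    SCIPI, CPG, NocP, NRS, MAS, SCAT, optional Group and site distances).

    ``n.a.``, ``MD`` and empty cells all map to missing. Rows without an AIS
    grade and without an explicit Group column are treated as NDC.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     skip_blank_lines=True)
    if df.empty and "ID" not in df.columns:
        return []
    records: list[ParticipantRecord] = []
    for _, row in df.iterrows():
        pid = str(row.get("ID", "")).strip()
        ais_tok = row.get("AIS")
        ais = None if _missing(ais_tok) else str(ais_tok).strip()
        if "Group" in df.columns and not _missing(row.get("Group")):
            group = str(row["Group"]).strip()
        else:
            group = "SCI" if ais is not None else "NDC"
        if group not in GROUPS:
            raise FormatError(f"row {pid}, column Group: unknown group {group!r}")
        if ais is not None and ais not in AIS_GRADES:
            raise FormatError(f"row {pid}, column AIS: unknown grade {ais!r}")
        nli_tok = row.get("NLI")
        records.append(ParticipantRecord(
            participant_id=pid,
            group=group,
            age_years=_opt_float(row.get("Age")),
            sex=None if _missing(row.get("Gender")) else str(row["Gender"]).strip(),
            AIS=ais,
            NLI=None if _missing(nli_tok) else str(nli_tok).strip(),
            TSI_years=_opt_float(row.get("TSI")),
            SCIPI_score=_opt_int(row.get("SCIPI")),
            CPG_neuropathic=_opt_bool(row.get("CPG"), pid, "CPG"),
            NocP=_opt_bool(row.get("NocP"), pid, "NocP"),
            NRS_spontaneous=_opt_int(row.get("NRS")),
            MAS_mean=_opt_float(row.get("MAS")),
            SCAT_mean=_opt_float(row.get("SCAT")),
            distance_FS_FH_m=_opt_float(row.get("distance_FS_FH_m")),
            distance_FD_FH_m=(
                0.40 if _missing(row.get("distance_FD_FH_m"))
                else float(row["distance_FD_FH_m"])),
        ))
    return records


def write_clinical_table(records: Iterable[ParticipantRecord],
                         path: str | Path) -> Path:
    rows = []
    for r in records:
        rows.append({
            "ID": r.participant_id, "Group": r.group,
            "Age": r.age_years, "Gender": r.sex,
            "AIS": r.AIS or "n.a.", "NLI": r.NLI or "n.a.",
            "TSI": "n.a." if r.TSI_years is None else f"{r.TSI_years:.1f}",
            "SCIPI": "n.a." if r.SCIPI_score is None else r.SCIPI_score,
            "CPG": {True: "Y", False: "N", None: "n.a."}[r.CPG_neuropathic],
            "NocP": {True: "Y", False: "N", None: "n.a."}[r.NocP],
            "NRS": "n.a." if r.NRS_spontaneous is None else r.NRS_spontaneous,
            "MAS": "MD" if r.MAS_mean is None else f"{r.MAS_mean:.2f}",
            "SCAT": "MD" if r.SCAT_mean is None else f"{r.SCAT_mean:.2f}",
            "distance_FS_FH_m": (
                "" if r.distance_FS_FH_m is None else f"{r.distance_FS_FH_m:.3f}"),
            "distance_FD_FH_m": (
                "" if r.distance_FD_FH_m is None else f"{r.distance_FD_FH_m:.3f}"),
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def load_reference_cohort() -> list[ParticipantRecord]:
    """The packaged 15-participant chronic-SCI reference clinical table."""
    with resources.as_file(
            resources.files("nwreflex.data") / "sci_reference_cohort.tsv") as p:
        return read_clinical_table(p)


# --------------------------------------------------------------------------
# detection output
# --------------------------------------------------------------------------

EVENT_COLUMNS = ("participant_id", "site", "trial_index", "muscle",
                 "onset_ms", "offset_ms", "peak_uV", "auc_uVs",
                 "n_phases", "window", "coactivated", "valid")


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"participant_id": str, "site": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"events file {path} lacks columns {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# optional BrainVision adapter
# --------------------------------------------------------------------------

def read_brainvision_epochs(vhdr_path: str | Path,
                            ta_channel: str, so_channel: str,
                            participant_id: str, site: str,
                            stimulus_marker: str = "Stimulus",
                            energy_mJ: float = float("nan")) -> list[EMGEpoch]:
    """Convert a BrainVision (.vhdr/.vmrk/.eeg) recording into epochs.

    Optional convenience for hardware-recorded data; the core pipeline never
    requires it. Needs ``mne`` (imported lazily) and cuts canonical
    -500 ... +3000 ms epochs around each matching marker.
    """
    try:
        import mne  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "BrainVision ingestion requires the optional dependency 'mne'"
        ) from exc
    from .preprocess import segment  # local import to avoid a cycle

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    ta = raw.get_data(picks=[ta_channel])[0] * 1e6  # V -> µV
    so = raw.get_data(picks=[so_channel])[0] * 1e6
    ann = raw.annotations
    marker_ms = [1000.0 * on for on, desc in zip(ann.onset, ann.description)
                 if stimulus_marker in desc]
    return segment(ta, so, fs, marker_ms, participant_id=participant_id,
                   site=site, energy_mJ=energy_mJ)
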