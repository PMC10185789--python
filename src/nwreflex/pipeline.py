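"""End-to-end orchestration: simulate -> preprocess -> detect -> summarize
-> statistics, with seeded reproducibility and per-stage artifacts.

Every tunable lives in one :class:`RunConfig`; a resolved copy is written
into each output directory so a run can be reproduced byte-for-byte from
its own artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate, clinstats, detect, preprocess, signal_io, synth

log = logging.getLogger("nwreflex")


@dataclass
class RunConfig:
    seed: int = 0
    n_sci: int = 4
    n_ndc: int = 4
    trials_per_site: int = 20
    sites: tuple[str, ...] = signal_io.SITES
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    detection: signal_io.DetectionConfig = field(
        default_factory=signal_io.DetectionConfig)
    sci_params: synth.GroupSimParams = field(
        default_factory=synth.sci_default_params)
    ndc_params: synth.GroupSimParams = field(
        default_factory=synth.ndc_default_params)
    clinical: synth.ClinicalSimParams = field(
        default_factory=synth.ClinicalSimParams)

    def cohort_config(self) -> synth.CohortConfig:
        return synth.CohortConfig(
            seed=self.seed, n_sci=self.n_sci, n_ndc=self.n_ndc,
            trials_per_site=self.trials_per_site, sites=tuple(self.sites),
            sci_params=self.sci_params, ndc_params=self.ndc_params,
            clinical=self.clinical)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unspecified keys keep their defaults.

    Nested dict keys of the simulator parameter tables are restored from the
    YAML string forms (e.g. ``"('FS', 'TW1')"``) written by save_config.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def tuple_keys(d):
        out = {}
        for k, v in d.items():
            if isinstance(k, str) and k.startswith("("):
                out[tuple(s.strip(" '\"") for s in k.strip("()").split(","))] = v
            else:
                out[k] = v
        return out

    cfg = RunConfig()
    for key in ("seed", "n_sci", "n_ndc", "trials_per_site"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "sites" in raw:
        cfg.sites = tuple(raw["sites"])
    if "preprocess" in raw:
        cfg.preprocess = preprocess.PreprocessConfig(**raw["preprocess"])
    if "detection" in raw:
        d = dict(raw["detection"])
        for k in ("noise_window_ms", "tw1_ms", "tw2_ms"):
            if k in d:
                d[k] = tuple(d[k])
        cfg.detection = signal_io.DetectionConfig(**d)
    for key, factory in (("sci_params", synth.sci_default_params),
                         ("ndc_params", synth.ndc_default_params)):
        if key in raw:
            d = dict(raw[key])
            for fld in ("latency_mean_ms", "latency_sd_ms"):
                if fld in d:
                    d[fld] = tuple_keys(d[fld])
            for fld in ("burst_duration_ms",):
                if fld in d:
                    d[fld] = {k: tuple(v) for k, v in d[fld].items()}
            for fld in ("n_phases_range", "amplitude_rel_range",
                        "noise_band_Hz", "trial_jitter_sd_ms"):
                if fld in d and isinstance(d[fld], list):
                    d[fld] = tuple(d[fld])
            base = dataclasses.asdict(factory())
            base.update(d)
            setattr(cfg, key, synth.GroupSimParams(**{
                k: (tuple_keys(v) if k in ("latency_mean_ms", "latency_sd_ms")
                    and isinstance(v, dict) else v)
                for k, v in base.items()}))
    if "clinical" in raw:
        cfg.clinical = synth.ClinicalSimParams(**raw["clinical"])
    return cfg


def detect_cohort(cohort: synth.CohortResult,
                  pre_cfg: preprocess.PreprocessConfig,
                  det_cfg: signal_io.DetectionConfig
                  ) -> list[detect.TrialDetection]:
    """Filter and run the detector over every rendered epoch."""
    dets: list[detect.TrialDetection] = []
    for (_, _), eps in sorted(cohort.epochs.items()):
        for ep in eps:
            filtered = preprocess.preprocess_epoch(ep, pre_cfg)
            dets.append(detect.detect_trial(filtered, det_cfg))
    return dets


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage, writing epochs, events, summaries, CV estimates, the
    statistics report, the resolved config and a counts log to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")
    counts: dict[str, int | float] = {}

    stage = "simulate"
    try:
        cohort = synth.simulate_cohort(config.cohort_config(), outdir=outdir)
        counts["participants"] = len(cohort.records)
        counts["epochs"] = sum(len(v) for v in cohort.epochs.values())
        counts["planted_events"] = len(cohort.planned)

        stage = "detect"
        dets = detect_cohort(cohort, config.preprocess, config.detection)
        counts["valid_trials"] = sum(d.valid for d in dets)
        counts["invalid_trials"] = sum(not d.valid for d in dets)
        events = detect.detections_to_frame(dets)
        signal_io.write_events(events, outdir / "events.tsv")
        for w in ("TW1", "TW2", "intermediate"):
            counts[f"events_{w}"] = int((events.window == w).sum()) \
                if len(events) else 0

        stage = "summarize"
        summaries = aggregate.summaries_to_frame(
            aggregate.summarize_participant(dets))
        summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False,
                         float_format="%.6g")
        cvs = aggregate.cv_table(dets, cohort.records)
        cvs.to_csv(outdir / "cv.tsv", sep="\t", index=False,
                   float_format="%.6g")
        counts["cv_defined"] = int(cvs.defined.sum()) if len(cvs) else 0

        stage = "stats"
        battery = clinstats.run_battery(summaries, cohort.records)
        battery.to_csv(outdir / "stats.tsv", sep="\t", index=False,
                       float_format="%.6g")
        (outdir / "stats_report.txt").write_text(
            clinstats.battery_report(battery) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (outdir / "counts.json").write_text(json.dumps(counts, indent=2) + "\n")
    log.info("run complete: %s", counts)
    return outdir


def report_figures(outdir: str | Path) -> list[Path]:
    """Grand-average traces per group/site and AUC bar summaries (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    epoch_files = sorted(outdir.glob("epochs_*.tsv"))
    if not epoch_files:
        log.warning("no epoch files in %s; no figures produced", outdir)
        return []
    clinical = signal_io.read_clinical_table(outdir / "clinical.tsv")
    group_of = {r.participant_id: r.group for r in clinical}
    by_group_site: dict[tuple[str, str], list] = {}
    for f in epoch_files:
        eps = signal_io.read_epochs(f)
        if not eps:
            continue
        g = group_of.get(eps[0].participant_id, "SCI")
        by_group_site.setdefault((g, eps[0].site), []).extend(eps)

    written: list[Path] = []
    sites = sorted({s for _, s in by_group_site})
    for site in sites:
        fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
        for ax, group in zip(axes, ("SCI", "NDC")):
            eps = by_group_site.get((group, site), [])
            if eps:
                ga = aggregate.grand_average(eps)
                t = eps[0].times_ms()
                for m, tr in ga.items():
                    ax.plot(t, tr, label=m, lw=0.8)
                ax.legend(loc="upper right")
            ax.axvline(0, color="k", ls="--", lw=0.8)
            ax.set_ylabel(f"{group}\nrectified EMG (uV)")
        axes[-1].set_xlabel("time relative to laser onset (ms)")
        fig.suptitle(f"grand averages, site {site}")
        p = outdir / f"grand_average_{site}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    summ_path = outdir / "summaries.tsv"
    if summ_path.exists():
        s = pd.read_csv(summ_path, sep="\t")
        s = s[s.window == "TW2"]
        if len(s):
            s["group"] = s.participant_id.map(group_of)
            agg = s.groupby(["site", "group"]).auc_mean_uVs.mean().unstack()
            ax = agg.plot.bar(rot=0, figsize=(6, 4), logy=True)
            ax.set_ylabel("mean TW2 AUC (uV*s, log scale)")
            p = outdir / "auc_bars.png"
            ax.figure.savefig(p, dpi=110)
            plt.close(ax.figure)
            written.append(p)
    return written
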