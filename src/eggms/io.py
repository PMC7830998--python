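"""Session serialization, run configuration, and the end-to-end pipeline.

A session directory holds plain-text files: ``signals.csv`` (time_s plus one
µV column per EGG channel), ``gsr.csv``/``hr.csv``, ``events.csv`` (button
presses), ``annotations.json``, ``segments.json``, ``truth.json`` (synthetic
ground truth, optional) and ``acquisition.json``.  The pipeline runs
preprocess -> features (five segments) -> onset detection (driving trial)
-> cohort statistics, logging every exclusion with its reason.
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

from .features import compute_features
from .onset import OnsetConfig, compare_events, compute_envelope, detect_onsets, onset_metrics
from .preprocess import (
    AcquisitionSpec,
    Annotation,
    EGGRecording,
    SegmentMap,
    bandpass_filter,
    edge_guard,
    exclude_artifacts,
    select_channel,
)
from .stats import DEFAULT_ALPHAS, compare_trials, spearman
from .synthetic import ButtonEvents, EpisodeSpec, SessionBundle, SimConfig, WristbandSeries

logger = logging.getLogger("eggms")

__all__ = [
    "RunConfig",
    "read_session",
    "write_session",
    "detect_saturation",
    "run_pipeline",
    "run_cohort",
    "render_report",
]

#: The five analysis segments of the protocol.
FEATURE_SEGMENTS = ("trial1", "trial2", "trial2A", "trial2B", "trial3")


@dataclass(frozen=True)
class RunConfig:
    """Analysis-side knobs for one pipeline run."""

    onset: OnsetConfig = field(default_factory=OnsetConfig)
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    edge_guard_s: float = 60.0
    #: a subject is unusable when more than this fraction of EVERY channel is
    #: annotated or saturated
    exclusion_frac: float = 0.2
    #: minimum rail-run length counted as saturation, seconds
    saturation_min_s: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        onset_cfg = OnsetConfig(**raw.pop("onset", {}))
        if "alphas" in raw:
            raw["alphas"] = tuple(raw["alphas"])
        return cls(onset=onset_cfg, **raw)


# ------------------------------------------------------------- serialization

def write_session(bundle: SessionBundle, out_dir: str | Path) -> Path:
    """Write one session to a directory of CSV/JSON files (full precision)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    egg = bundle.egg
    sig = pd.DataFrame({"time_s": egg.times})
    for ch in range(egg.n_channels):
        sig[f"ch{ch + 1}_uV"] = egg.samples[ch]
    sig.to_csv(out / "signals.csv", index=False, float_format="%.17g")
    pd.DataFrame({"time_s": bundle.gsr.times, "gsr_uS": bundle.gsr.values}).to_csv(
        out / "gsr.csv", index=False, float_format="%.17g")
    pd.DataFrame({"time_s": bundle.hr.times, "hr_bpm": bundle.hr.values}).to_csv(
        out / "hr.csv", index=False, float_format="%.17g")
    pd.DataFrame({"time_s": list(bundle.buttons.timestamps)}).to_csv(
        out / "events.csv", index=False, float_format="%.17g")
    (out / "annotations.json").write_text(json.dumps(
        [dataclasses.asdict(a) for a in egg.annotations], indent=1))
    (out / "segments.json").write_text(json.dumps(
        {k: list(v) for k, v in bundle.segments.named().items()}, indent=1))
    (out / "truth.json").write_text(json.dumps(
        [dataclasses.asdict(e) for e in bundle.truth], indent=1))
    (out / "acquisition.json").write_text(json.dumps(dataclasses.asdict(egg.acq)))
    return out


def _read_csv_checked(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing session file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    t = df["time_s"].to_numpy()
    bad = np.flatnonzero(np.diff(t) < 0)
    if bad.size:
        # offending row is bad[0]+1; +2 more for the header line and 1-based numbering
        raise ValueError(f"{path.name}: time_s not sorted at line {int(bad[0]) + 3}")
    return df


def read_session(session_dir: str | Path) -> SessionBundle:
    """Read and validate a session directory written by :func:`write_session`.

    Raises with a file name (and line number where applicable) on missing
    files, unsorted time columns, or NaN outside annotated intervals.
    """
    d = Path(session_dir)
    acq_raw = json.loads((d / "acquisition.json").read_text())
    acq = AcquisitionSpec(**acq_raw)
    annotations = [Annotation(**a) for a in json.loads((d / "annotations.json").read_text())]

    sig = _read_csv_checked(d / "signals.csv", ["time_s"])
    ch_cols = [c for c in sig.columns if c.startswith("ch")]
    samples = sig[ch_cols].to_numpy().T
    egg = EGGRecording(samples=samples, acq=acq, annotations=annotations,
                       start_time=float(sig["time_s"].iloc[0]))
    for ch in range(egg.n_channels):
        nan_rows = np.flatnonzero(np.isnan(egg.samples[ch]) & ~egg.annotation_mask(ch))
        if nan_rows.size:
            raise ValueError(
                f"signals.csv: NaN outside annotated intervals in {ch_cols[ch]} "
                f"at line {int(nan_rows[0]) + 2}")

    gsr_df = _read_csv_checked(d / "gsr.csv", ["time_s", "gsr_uS"])
    hr_df = _read_csv_checked(d / "hr.csv", ["time_s", "hr_bpm"])
    gsr = WristbandSeries(gsr_df["time_s"].to_numpy(), gsr_df["gsr_uS"].to_numpy(), "uS")
    hr = WristbandSeries(hr_df["time_s"].to_numpy(), hr_df["hr_bpm"].to_numpy(), "bpm")

    ev_df = _read_csv_checked(d / "events.csv", ["time_s"])
    buttons = ButtonEvents(timestamps=tuple(ev_df["time_s"].tolist()))

    seg_raw = json.loads((d / "segments.json").read_text())
    segments = SegmentMap(**{k: tuple(v) for k, v in seg_raw.items()})
    truth_path = d / "truth.json"
    truth = tuple(EpisodeSpec(**e) for e in json.loads(truth_path.read_text())) \
        if truth_path.exists() else ()
    return SessionBundle(egg=egg, gsr=gsr, hr=hr, buttons=buttons,
                         segments=segments, truth=truth)


# ---------------------------------------------------------------- pipeline

def detect_saturation(recording: EGGRecording, min_run_s: float = 1.0) -> EGGRecording:
    """Annotate runs at the quantization rails lasting at least ``min_run_s``."""
    out = recording.copy()
    fs = out.acq.fs
    rail = out.acq.full_scale_uv - out.acq.quant_step_uv
    min_run = max(1, int(round(min_run_s * fs)))
    for ch in range(out.n_channels):
        at_rail = np.abs(out.samples[ch]) >= rail
        for t0, t1 in _bool_runs(at_rail):
            if t1 - t0 >= min_run:
                out.annotations.append(Annotation(
                    out.start_time + t0 / fs, out.start_time + t1 / fs,
                    channel=ch, kind="saturation"))
    return out


def _bool_runs(mask: np.ndarray):
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    return list(zip(starts, ends))


def _usable(recording: EGGRecording, exclusion_frac: float) -> bool:
    """A recording is usable unless more than ``exclusion_frac`` of every
    channel is annotated (artifact or saturation)."""
    n = recording.n_samples
    fracs = [
        recording.annotation_mask(ch, kinds=("artifact", "saturation")).sum() / n
        for ch in range(recording.n_channels)
    ]
    return min(fracs) <= exclusion_frac


def run_pipeline(bundle: SessionBundle, config: RunConfig | None = None,
                 subject: str = "s01") -> dict:
    """Analyze one session: preprocess, per-segment features, onset detection.

    Returns a JSON-able dict with the selected channel, the five feature
    rows, the driving-trial onset summary, and the press/episode comparison.
    Unusable recordings (every channel >20% annotated/saturated by default)
    yield ``{"excluded": True, "reason": ...}``.
    """
    config = config or RunConfig()
    rec = detect_saturation(bundle.egg, config.saturation_min_s)
    if not _usable(rec, config.exclusion_frac):
        logger.warning("subject %s excluded: poor signal quality on every channel", subject)
        return {"subject": subject, "excluded": True,
                "reason": "poor signal quality: every channel exceeds "
                          f"{config.exclusion_frac:.0%} annotated/saturated"}

    filtered = bandpass_filter(rec)
    filtered = edge_guard(filtered, config.edge_guard_s)
    masked, mask_counts = exclude_artifacts(filtered)
    channel = select_channel(masked)
    logger.info("subject %s: channel %d selected (masked samples per channel: %s)",
                subject, channel + 1, mask_counts)
    x = masked.samples[channel]
    seg = bundle.segments

    features = {}
    intervals = dict(seg.named())
    intervals["trial2"] = seg.trial2
    for name in FEATURE_SEGMENTS:
        a, b = intervals[name]
        sl = masked.sample_slice(a, b)
        features[name] = compute_features(x[sl], masked.acq).as_dict()

    # onset detection on the driving trial against the baseline trial
    fs = masked.acq.fs
    sl1 = masked.sample_slice(*seg.trial1)
    sl2 = masked.sample_slice(*seg.trial2)
    base_sig, trial_sig = x[sl1], x[sl2]
    base_env = compute_envelope(base_sig, fs, config.onset, t0=seg.trial1[0])
    trial_env = compute_envelope(trial_sig, fs, config.onset, t0=seg.trial2[0])
    result = detect_onsets(trial_env, base_env, config.onset)
    clean1 = base_sig[np.isfinite(base_sig)]
    baseline_rms = float(np.sqrt(np.mean(clean1**2)))
    duration_s, rel_rms = onset_metrics(result, trial_sig, baseline_rms)
    ev = compare_events(result, bundle.buttons, segments=seg.named())

    return {
        "subject": subject,
        "excluded": False,
        "channel": channel,
        "features": features,
        "onset": {
            "episodes": [list(e) for e in result.episodes],
            "duration_s": duration_s,
            "rel_rms_increase_pct": rel_rms,
            "n_presses": len(bundle.buttons),
            "mean_lead_s": ev.mean_lead_s,
            "sd_lead_s": ev.sd_lead_s,
            "presses_per_segment": ev.presses_per_segment,
        },
        "wristband": {
            name: {
                "gsr_mean_uS": bundle.gsr.segment_stats(a, b)[0],
                "gsr_sd_uS": bundle.gsr.segment_stats(a, b)[1],
                "hr_mean_bpm": bundle.hr.segment_stats(a, b)[0],
                "hr_sd_bpm": bundle.hr.segment_stats(a, b)[1],
            }
            for name, (a, b) in {**seg.named(), "trial2": seg.trial2}.items()
        },
    }


def _feature_table(results: list[dict]) -> pd.DataFrame:
    rows = []
    for r in results:
        if r["excluded"]:
            continue
        for segname, feats in r["features"].items():
            row = {"subject": r["subject"], "segment": segname}
            row.update(feats)
            wb = r["wristband"][segname]
            row.update(wb)
            rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(bundles: list[SessionBundle], config: RunConfig | None = None,
               subjects: list[str] | None = None) -> dict:
    """Full study analysis over a cohort of sessions.

    Per-subject pipelines feed a tidy feature table; the adaptive statistical
    harness compares the three trials and the two driving-trial parts for
    every indicator, and rank correlations link onset metrics to the number
    of nausea reports.  Excluded subjects are reported, never silently
    dropped.
    """
    config = config or RunConfig()
    subjects = subjects or [f"s{i + 1:02d}" for i in range(len(bundles))]
    results = [run_pipeline(b, config, subject=s) for b, s in zip(bundles, subjects)]
    included = [r for r in results if not r["excluded"]]
    excluded = [{"subject": r["subject"], "reason": r["reason"]}
                for r in results if r["excluded"]]

    report: dict = {
        "n_total": len(results),
        "n_included": len(included),
        "excluded": excluded,
        "subjects": results,
    }
    if len(included) >= 3:
        table = _feature_table(results)
        params = tuple(c for c in table.columns if c not in ("subject", "segment"))
        stat = compare_trials(table, parameters=params, alphas=config.alphas)
        report["stats"] = stat.as_dict()
        report["correlations"] = _onset_correlations(included)
    return report


def _onset_correlations(included: list[dict]) -> list[dict]:
    dur = np.array([r["onset"]["duration_s"] for r in included])
    presses = np.array([r["onset"]["n_presses"] for r in included])
    rel = np.array([
        r["onset"]["rel_rms_increase_pct"]
        if r["onset"]["rel_rms_increase_pct"] is not None else np.nan
        for r in included
    ])
    out = []
    for name, x, y in [
        ("duration_vs_presses", dur, presses),
        ("rel_rms_vs_duration", rel, dur),
        ("rel_rms_vs_presses", rel, presses),
    ]:
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
            r, p = spearman(x[ok], y[ok])
            out.append({"pair": name, "n": int(ok.sum()), "r": r, "p": p})
        else:
            out.append({"pair": name, "n": int(ok.sum()), "r": None, "p": None})
    return out


def render_report(report: dict) -> str:
    """Human-readable summary of a cohort report."""
    lines = [
        f"Cohort: {report['n_included']}/{report['n_total']} subjects analyzed",
    ]
    for ex in report.get("excluded", []):
        lines.append(f"  excluded {ex['subject']}: {ex['reason']}")
    stats = report.get("stats")
    if stats:
        lines.append("")
        lines.append(f"Trial comparisons (alpha = {stats['alphas']}):")
        for param, per in stats["outcomes"].items():
            for cname, oc in per.items():
                sig = " *" if oc["significant"].get("0.05") else (
                    " ." if oc["significant"].get("0.1") else "")
                df = ",".join(f"{d:g}" for d in oc["df"])
                lines.append(
                    f"  {param:14s} {cname:7s} {oc['test']:10s}"
                    f" stat={oc['statistic']:8.3f} df=({df}) p={oc['p']:.3f}{sig}")
                for ph in oc["posthoc"]:
                    lines.append(
                        f"      post-hoc {ph['pair'][0]} vs {ph['pair'][1]}: "
                        f"p_corr={ph['p_corrected']:.3f} ({ph['direction']})")
    for corr in report.get("correlations", []):
        if corr["r"] is not None:
            lines.append(
                f"  Spearman {corr['pair']}: r={corr['r']:.2f} p={corr['p']:.3f} (n={corr['n']})")
    return "\n".join(lines)
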