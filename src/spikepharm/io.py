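"""File formats, pipeline configuration and the end-to-end analysis driver.

Spike trains travel as plain-text timestamp files (one float second per line,
``#`` comments) with an optional JSON metadata sidecar (``<file>.meta.json``:
unit id, group, injection time, duration, ground truth).  Voltage traces are
two-column CSV (time_s, value).  A session manifest (TSV/CSV) lists the units
of an experiment; :func:`run_pipeline` takes a manifest plus a
:class:`PipelineConfig` and writes the per-unit classification table, per-group
JSON reports and TSV time courses.  All outputs are deterministic given the
inputs and seeds, so a rerun is byte-identical.
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

from .binning import PSTH_BIN_WIDTH, ACQUISITION_BIN_WIDTH, make_psth
from .classify import ClassifierConfig, ResponseClassification, classify_train
from .detect import DetectionConfig, detect_unit
from .groupstats import GroupResult, response_scatter, summarize_group
from .simulate import (
    DEFAULT_INJECTION_TIME,
    DEFAULT_SESSION_DURATION,
    PYRAMIDAL_RATE_CAP,
    SimulationConfig,
    SpikeTrain,
    VoltageTrace,
)

logger = logging.getLogger("spikepharm")

__all__ = [
    "PipelineConfig",
    "read_spike_times",
    "write_spike_times",
    "read_voltage_csv",
    "write_voltage_csv",
    "read_manifest",
    "write_manifest",
    "run_pipeline",
    "classification_table",
]

MANIFEST_COLUMNS = ["unit_id", "group", "injection_time", "spike_path"]


@dataclass
class PipelineConfig:
    """Declarative analysis settings, defaulting to the study protocol:
    900-s baseline within a 7200-s session, 60-s PSTH bins, a ±2 SD / 3-bin
    response rule, the ≤ 8 spikes/s pyramidal filter and the SNR > 2 unit
    criterion."""

    session_duration: float = DEFAULT_SESSION_DURATION
    injection_time: float = DEFAULT_INJECTION_TIME
    psth_bin_width: float = PSTH_BIN_WIDTH
    acquisition_bin_width: float = ACQUISITION_BIN_WIDTH
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    pyramidal_cap: float = PYRAMIDAL_RATE_CAP
    min_snr: float = 2.0
    seed: int = 0

    @property
    def baseline_duration(self) -> float:
        return self.injection_time

    @property
    def post_duration(self) -> float:
        return self.session_duration - self.injection_time

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "classifier" in d:
            d["classifier"] = ClassifierConfig(**d["classifier"])
        if "detection" in d:
            det = dict(d["detection"])
            if det.get("height_window") is not None:
                det["height_window"] = tuple(det["height_window"])
            d["detection"] = DetectionConfig(**det)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# --------------------------------------------------------------------------
# Spike-time files
# --------------------------------------------------------------------------

def read_spike_times(
    path: str | Path,
    *,
    duration: float | None = None,
    injection_time: float | None = None,
    unit_id: str | None = None,
    group: str | None = None,
) -> SpikeTrain:
    """Read a plain-text timestamp file (one float second per line).

    Lines starting with ``#`` and blank lines are skipped.  Out-of-order times
    are sorted with a warning.  Metadata precedence: explicit arguments, then a
    ``<file>.meta.json`` sidecar, then defaults (session 7200 s, injection
    900 s, unit id from the file stem).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spike-time file not found: {path}")
    meta: dict = {}
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    times: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                value = float(text)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric spike time {text!r}"
                ) from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time {value}")
            times.append(value)
    arr = np.asarray(times, dtype=float)
    if arr.size == 0:
        logger.warning("%s: empty spike-time file", path)
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        logger.warning("%s: spike times out of order; sorting", path)
        arr = np.sort(arr)
    if arr.size > 1:
        arr = np.unique(arr)

    if duration is None:
        duration = float(meta.get("duration", DEFAULT_SESSION_DURATION))
        if arr.size and arr[-1] >= duration:
            duration = float(np.ceil(arr[-1] + 1.0))
    if injection_time is None:
        injection_time = float(meta.get("injection_time", DEFAULT_INJECTION_TIME))
    ground_truth = None
    if "ground_truth" in meta:
        ground_truth = SimulationConfig(**meta["ground_truth"])
    return SpikeTrain(
        times=arr,
        duration=duration,
        injection_time=injection_time,
        unit_id=unit_id or meta.get("unit_id", path.stem),
        group=group or meta.get("group"),
        ground_truth=ground_truth,
    )


def write_spike_times(
    train: SpikeTrain, path: str | Path, *, sidecar: bool = True
) -> Path:
    """Write timestamps (full ``repr`` precision, exact round-trip) plus a
    JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# spike times (s) for unit {train.unit_id}\n")
        for t in train.times:
            fh.write(f"{float(t)!r}\n")
    if sidecar:
        meta = {
            "unit_id": train.unit_id,
            "group": train.group,
            "injection_time": train.injection_time,
            "duration": train.duration,
        }
        if train.ground_truth is not None:
            meta["ground_truth"] = dataclasses.asdict(train.ground_truth)
        sidecar_path = path.with_name(path.name + ".meta.json")
        sidecar_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


# --------------------------------------------------------------------------
# Voltage traces
# --------------------------------------------------------------------------

def write_voltage_csv(trace: VoltageTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": trace.time, "value": trace.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )
    return path


def read_voltage_csv(path: str | Path) -> VoltageTrace:
    """Read a (time_s, value) CSV; the sampling rate is inferred from the
    median time step."""
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value")
    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    if dt <= 0:
        raise ValueError(f"{path}: non-increasing time column")
    return VoltageTrace(samples=df["value"].to_numpy(), sampling_rate=1.0 / dt)


# --------------------------------------------------------------------------
# Manifest and pipeline
# --------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Session manifest: TSV/CSV with columns unit_id, group, injection_time,
    spike_path and optional dose, voltage_path."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def classification_table(
    classifications: list[ResponseClassification],
) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append(
            {
                "unit_id": c.unit_id,
                "group": c.group,
                "label": c.label,
                "onset_min": c.onset_latency_min,
                "percent_change": c.percent_change,
                "baseline_hz": c.baseline.mean_rate,
                "baseline_sd_hz": c.baseline.sd_rate,
                "excluded": c.excluded,
                "reason": c.exclusion_reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "group", "label", "onset_min", "percent_change",
            "baseline_hz", "baseline_sd_hz", "excluded", "reason",
        ],
    )


def _load_unit(row: pd.Series, config: PipelineConfig, manifest_dir: Path):
    """Load one manifest row: detection stage when a voltage trace is listed,
    otherwise the timestamp file directly.  Returns (train, snr or None)."""
    injection = float(row["injection_time"])
    voltage_path = row.get("voltage_path")
    if isinstance(voltage_path, str) and voltage_path:
        vpath = manifest_dir / voltage_path
        if not vpath.exists():
            raise FileNotFoundError(f"voltage file not found: {vpath}")
        trace = read_voltage_csv(vpath)
        train, snr = detect_unit(
            trace,
            config.detection,
            injection_time=injection,
            unit_id=str(row["unit_id"]),
        )
        train.group = str(row["group"])
        return train, snr
    spath = manifest_dir / str(row["spike_path"])
    train = read_spike_times(
        spath,
        duration=config.session_duration,
        injection_time=injection,
        unit_id=str(row["unit_id"]),
        group=str(row["group"]),
    )
    return train, None


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, GroupResult]]:
    """Classify every unit in the manifest and summarise each group.

    Returns the per-unit classification table and a dict of group results;
    when ``out_dir`` is given, writes ``units.tsv``, ``scatter_<group>.tsv``,
    ``group_<group>.json`` and ``timecourse_<group>.tsv``.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        manifest_dir = manifest_path.parent
        manifest = read_manifest(manifest_path)
    else:
        manifest_dir = Path(".")

    trains: list[SpikeTrain] = []
    classifications: list[ResponseClassification] = []
    for _, row in manifest.iterrows():
        train, snr = _load_unit(row, config, manifest_dir)
        cls = classify_train(
            train,
            config.classifier,
            snr=snr,
            min_snr=config.min_snr,
            pyramidal_cap=config.pyramidal_cap,
        )
        trains.append(train)
        classifications.append(cls)
    n_excluded = sum(c.excluded for c in classifications)
    logger.info(
        "classified %d units (%d excluded: %s)",
        len(classifications),
        n_excluded,
        {r: sum(1 for c in classifications if c.exclusion_reason == r)
         for r in {c.exclusion_reason for c in classifications if c.excluded}},
    )

    groups: dict[str, GroupResult] = {}
    for label in pd.unique(manifest["group"]).tolist():
        idx = [i for i, t in enumerate(trains) if t.group == str(label)]
        grp_cls = [classifications[i] for i in idx]
        grp_trains = [trains[i] for i in idx]
        if all(c.excluded for c in grp_cls):
            logger.warning("group %s: all units excluded, no summary", label)
            continue
        groups[str(label)] = summarize_group(grp_cls, grp_trains, label=str(label))

    units = classification_table(classifications)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        units.to_csv(out_dir / "units.tsv", sep="\t", index=False, float_format="%.9g")
        for label, result in groups.items():
            report = {
                "group": result.label,
                "n_neurons": result.n_neurons,
                "n_excluded": result.n_excluded,
                "counts": result.counts,
                "ttest": {
                    "t": None if np.isnan(result.ttest.t) else result.ttest.t,
                    "df": result.ttest.df,
                    "p": None if np.isnan(result.ttest.p) else result.ttest.p,
                    "n": result.ttest.n,
                    "mean_diff_hz": result.ttest.mean_diff,
                    "sem_diff_hz": result.ttest.sem_diff,
                    "degenerate": result.ttest.degenerate,
                },
            }
            (out_dir / f"group_{label}.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )
            result.timecourse.to_csv(
                out_dir / f"timecourse_{label}.tsv",
                sep="\t", index=False, float_format="%.9g",
            )
            idx = [i for i, t in enumerate(trains) if t.group == label]
            response_scatter(
                [trains[i] for i in idx], [classifications[i] for i in idx]
            ).to_csv(
                out_dir / f"scatter_{label}.tsv",
                sep="\t", index=False, float_format="%.9g",
            )
    return units, groups
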