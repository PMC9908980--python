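"""Readers, writers, run configuration and the end-to-end pipeline.

Conventions: CSV is comma-separated UTF-8 with a header row; numbers are
serialized with 17 significant digits so write->read round-trips are exact;
times are seconds, frame indices 0-based, intervals half-open [start, end).
Trace and ECoG files carry a JSON sidecar (``<file>.json``) with their
acquisition metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, spectral, spines, synchrony, synthgen, traces

log = logging.getLogger("painsync")

FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# trace matrices

def write_trace_csv(tm: traces.TraceMatrix, path: str | Path,
                    seed: int | None = None) -> Path:
    """Write a TraceMatrix as time_s + one column per ROI, with sidecar."""
    path = Path(path)
    df = pd.DataFrame(tm.values, columns=tm.roi_ids)
    df.insert(0, "time_s", tm.time_s)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = {"frame_rate_hz": tm.frame_rate_hz, "seed": seed}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace_csv(path: str | Path) -> traces.TraceMatrix:
    """Read and validate a trace CSV (+ JSON sidecar for the frame rate)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if df.shape[1] < 2 or "time_s" not in df.columns:
        raise ValueError(f"{path}: need a time_s column plus >= 1 ROI column")
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 frames")
    t = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"{path}: time_s not strictly increasing at row {row}")
    roi_cols = [c for c in df.columns if c != "time_s"]
    vals = df[roi_cols].to_numpy(dtype=float)
    if np.isnan(vals).any():
        r, c = map(int, np.argwhere(np.isnan(vals))[0])
        raise ValueError(f"{path}: NaN cell at row {r}, ROI {roi_cols[c]!r}")
    if (vals < 0).any():
        r, c = map(int, np.argwhere(vals < 0)[0])
        raise ValueError(f"{path}: negative fluorescence at row {r}, "
                         f"ROI {roi_cols[c]!r}")
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        fr = float(json.loads(sidecar_path.read_text())["frame_rate_hz"])
    else:
        fr = 1.0 / float(np.mean(np.diff(t)))
    return traces.TraceMatrix(values=vals, frame_rate_hz=fr, roi_ids=roi_cols)


def write_dff_csv(dff: traces.DffMatrix, path: str | Path) -> Path:
    """Write ΔF/F0 as time_s + ROI columns plus a baseline-metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(dff.values, columns=dff.roi_ids)
    df.insert(0, "time_s", np.arange(dff.n_frames) / dff.frame_rate_hz)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = {
        "frame_rate_hz": dff.frame_rate_hz,
        "f0_per_roi": dict(zip(dff.roi_ids, map(float, dff.f0_per_roi))),
        "baseline_window_per_roi": {r: list(w) for r, w in
                                    zip(dff.roi_ids,
                                        dff.baseline_window_per_roi)},
        "baseline_sd_per_roi": dict(zip(dff.roi_ids,
                                        map(float, dff.baseline_sd_per_roi))),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_dff_csv(path: str | Path) -> traces.DffMatrix:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(Path(str(path) + ".json").read_text())
    roi_cols = [c for c in df.columns if c != "time_s"]
    return traces.DffMatrix(
        values=df[roi_cols].to_numpy(dtype=float),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        roi_ids=roi_cols,
        f0_per_roi=np.array([meta["f0_per_roi"][r] for r in roi_cols]),
        baseline_window_per_roi=[tuple(meta["baseline_window_per_roi"][r])
                                 for r in roi_cols],
        baseline_sd_per_roi=np.array([meta["baseline_sd_per_roi"][r]
                                      for r in roi_cols]))


def write_activity_csv(activity: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    activity.to_csv(path, float_format=FLOAT_FMT)
    return path


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="roi_id",
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# synchrony outputs

def write_sync(sync: synchrony.SyncResult, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sync.r_matrix, index=sync.roi_ids, columns=sync.roi_ids) \
        .to_csv(outdir / "r_matrix.csv", float_format=FLOAT_FMT)
    sync.pairs.to_csv(outdir / "pairs.csv", index=False,
                      float_format=FLOAT_FMT)
    summary = {"mean_pairwise_r": sync.mean_pairwise_r,
               "significant_fraction": sync.significant_fraction,
               "n_shuffles": sync.n_shuffles, "alpha": sync.alpha,
               "seed": sync.seed, "n_active_rois": len(sync.roi_ids)}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# ECoG

def write_ecog_csv(rec: spectral.EcogRecording, path: str | Path,
                   seed: int | None = None) -> Path:
    path = Path(path)
    pd.DataFrame({"signal": rec.samples}).to_csv(path, index=False,
                                                 float_format=FLOAT_FMT)
    sidecar = {"fs_hz": rec.fs_hz, "epochs": [list(e) for e in rec.epochs],
               "seed": seed}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_ecog_raw(rec: spectral.EcogRecording, path: str | Path,
                   seed: int | None = None) -> Path:
    """float32 little-endian raw samples plus JSON sidecar."""
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    sidecar = {"fs_hz": rec.fs_hz, "epochs": [list(e) for e in rec.epochs],
               "seed": seed, "dtype": "<f4"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_ecog(path: str | Path) -> spectral.EcogRecording:
    """Read a single-column ECoG CSV or float32 raw file (by extension)."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    if path.suffix.lower() == ".csv":
        samples = pd.read_csv(path, float_precision="round_trip")["signal"].to_numpy(dtype=float)
    else:
        samples = np.fromfile(path, dtype=meta.get("dtype", "<f4")) \
            .astype(float)
    epochs = [tuple(e) for e in meta.get("epochs", [])]
    if not epochs:
        epochs = [(0.0, samples.size / float(meta["fs_hz"]))]
    return spectral.EcogRecording(samples=samples, fs_hz=float(meta["fs_hz"]),
                                  epochs=epochs)


def write_psd(psd: spectral.PsdResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"freq_hz": psd.freqs, "rel_power": psd.rel_power,
                  "abs_power": psd.abs_power}) \
        .to_csv(outdir / "psd.csv", index=False, float_format=FLOAT_FMT)
    (outdir / "band_means.json").write_text(json.dumps(
        {"band_means": psd.band_means, "epoch_len_s": psd.epoch_len_s,
         "n_epochs": psd.n_epochs, "total_power": psd.total_power},
        indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# protrusions

def read_protrusion_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in spines.PROTRUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_protrusion_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass
class RunConfig:
    """Parameters for the end-to-end pipeline run.

    Any stage whose input path is None is skipped.  Every parameter is
    validated before any computation starts, and the seed is echoed into
    all stochastic outputs and the manifest.
    """

    traces_csv: str | None = None
    ecog_file: str | None = None
    out_dir: str = "painsync_out"
    seed: int = 0
    # traces
    window_s: float = 2.0
    k: float = 3.0
    duration_s: float = 150.0
    sd_mode: str = "baseline_window"
    # synchrony
    span_s: float = 150.0
    n_shuffles: int = 500
    alpha: float = 0.05
    # spectral
    epoch_s: float = 10.0
    spectral_window: str = "hann"
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha={self.alpha} outside (0, 1]")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        for name in ("window_s", "duration_s", "span_s", "epoch_s", "k"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.sd_mode not in ("baseline_window", "robust"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if self.spectral_window not in ("hann", "boxcar"):
            raise ValueError(f"unknown spectral window "
                             f"{self.spectral_window!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML/JSON key-value file; unknown keys rejected."""
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _param_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a manifest alongside outputs.

    traces_csv -> ΔF/F0 -> activity table -> pairwise synchrony;
    ecog_file -> epoch-averaged relative power spectrum + band means.
    Any stage error aborts with the stage name and offending input.
    Returns the manifest dict.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("painsync")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest: dict = {"painsync_version": version, "seed": config.seed,
                      "param_hash": _param_hash(config),
                      "config": asdict(config), "stages": []}

    if config.traces_csv is not None:
        stage = "traces"
        try:
            log.info("stage=%s input=%s seed=%d", stage, config.traces_csv,
                     config.seed)
            tm = read_trace_csv(config.traces_csv)
            dff = traces.compute_dff(tm, window_s=config.window_s,
                                     sd_mode=config.sd_mode)
            activity = traces.detect_active(dff, k=config.k,
                                            duration_s=config.duration_s)
            write_dff_csv(dff, outdir / "dff.csv")
            write_activity_csv(activity, outdir / "activity.csv")
            manifest["stages"].append(stage)
            stage = "synchrony"
            log.info("stage=%s n_shuffles=%d alpha=%g seed=%d", stage,
                     config.n_shuffles, config.alpha, config.seed)
            sync = synchrony.compute_synchrony(
                dff, activity, span_s=config.span_s,
                n_shuffles=config.n_shuffles, alpha=config.alpha,
                seed=config.seed)
            manifest["synchrony_summary"] = write_sync(sync, outdir / "sync")
            manifest["stages"].append(stage)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed on {config.traces_csv!r}: {exc}"
            ) from exc

    if config.ecog_file is not None:
        stage = "spectral"
        try:
            log.info("stage=%s input=%s epoch_s=%g", stage, config.ecog_file,
                     config.epoch_s)
            rec = read_ecog(config.ecog_file)
            psd = spectral.power_spectrum(rec, epoch_len_s=config.epoch_s,
                                          window=config.spectral_window)
            write_psd(psd, outdir / "spectral")
            manifest["band_means"] = psd.band_means
            manifest["stages"].append(stage)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed on {config.ecog_file!r}: {exc}"
            ) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
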