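"""Record I/O, run configuration, provenance, and the end-to-end pipeline.

Records are exchanged as plain CSV (columns ``time_s,ppg``, comma
separator, UTF-8); ground truth and provenance travel as JSON sidecars.
The pipeline driver chains: baseline removal -> fundamental detection ->
per-harmonic isolation -> Hilbert tracking -> noise split ->
reconstruction -> cardiac metrics -> respiration metrics -> index
collation -> classification, writing every intermediate to disk when an
output directory is configured.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .afclassify import SubjectIndices, Thresholds, classify, compute_indices
from .cardiometrics import CardiacMetrics, compute_cardiac
from .decompose import DecomposeConfig, Decomposition, assemble, hvd_track
from .preprocess import PreprocessConfig, detect_fundamental, isolate_harmonic, remove_baseline
from .reconstruct import Reconstruction, build_reconstruction
from .respmetrics import RespConfig, RespMetrics, compute_resp
from .synthgen import SyntheticRecord
from .waveform import Waveform

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_record",
    "write_record",
    "write_truth_sidecar",
    "analyze_waveform",
    "run_pipeline",
]

log = logging.getLogger("ppgtf")

CSV_TIME_COL = "time_s"
CSV_SIGNAL_COL = "ppg"


@dataclass
class RunConfig:
    """End-to-end run configuration; every key has a CLI flag mirror."""

    input_path: str | Path | None = None
    fmt: str = "csv"
    segment_start_s: float | None = None
    segment_end_s: float | None = None  # default: start + 80 s
    n_harmonics: int = 3
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decompose: DecomposeConfig = field(default_factory=DecomposeConfig)
    resp: RespConfig = field(default_factory=RespConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: str | Path | None = None
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.fmt not in ("csv",):
            raise ValueError(f"unsupported record format {self.fmt!r}")

    def provenance(self) -> dict:
        """All effective parameters plus a stable config hash."""
        cfg = dataclasses.asdict(self)
        cfg = json.loads(json.dumps(cfg, default=str, sort_keys=True))
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"version": __version__, "config": cfg, "config_hash": digest}


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------


def read_record(path: str | Path, fmt: str = "csv") -> tuple[Waveform, dict]:
    """Read a PPG record; returns the waveform and header metadata.

    CSV records need a ``time_s`` column (seconds, uniform) and a ``ppg``
    column.  The sampling rate is inferred from the time column; irregular
    sampling or NaN runs longer than one second are rejected, shorter NaN
    gaps are linearly interpolated.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported record format {fmt!r}")
    path = Path(path)
    df = pd.read_csv(path)
    for col in (CSV_TIME_COL, CSV_SIGNAL_COL):
        if col not in df.columns:
            raise ValueError(
                f"{path.name}: channel/column {col!r} not found "
                f"(has {list(df.columns)})"
            )
    t = df[CSV_TIME_COL].to_numpy(dtype=float)
    x = df[CSV_SIGNAL_COL].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: record too short")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if dt <= 0 or np.max(np.abs(dts - dt)) > 1e-3 * dt + 1e-9:
        raise ValueError(f"{path.name}: irregular sampling in {CSV_TIME_COL}")
    fs = 1.0 / dt
    nan = ~np.isfinite(x)
    if nan.any():
        run = _longest_run(nan)
        if run / fs > 1.0:
            raise ValueError(
                f"{path.name}: NaN gap of {run / fs:.2f} s exceeds 1 s"
            )
        x = x.copy()
        idx = np.arange(x.size)
        x[nan] = np.interp(idx[nan], idx[~nan], x[~nan])
    meta = {"path": str(path), "fs": fs, "n": int(x.size), "t0": float(t[0])}
    return Waveform(x, fs, t0=float(t[0])), meta


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def write_record(wave: Waveform, path: str | Path) -> Path:
    """Write a waveform as the package CSV dialect."""
    path = Path(path)
    pd.DataFrame({CSV_TIME_COL: wave.t, CSV_SIGNAL_COL: wave.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )
    return path


def write_truth_sidecar(record: SyntheticRecord, path: str | Path) -> Path:
    """JSON sidecar with the generative parameters of a synthetic record.

    Stores parameters, label and seed (sufficient to regenerate every
    ground-truth component bit-identically), not the sample arrays.
    """
    path = Path(path)

    def _clean(obj: dict) -> dict:
        return json.loads(json.dumps(obj, default=lambda o: np.asarray(o).tolist()))

    payload = {
        "label": record.label,
        "seed": record.seed,
        "subject_id": record.subject_id,
        "fs": record.ppg.fs,
        "duration_s": record.ppg.n / record.ppg.fs,
        "pulse_spec": _clean(dataclasses.asdict(record.spec)),
        "sdof_config": _clean(dataclasses.asdict(record.sdof)),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    x0: Waveform
    x_b: Waveform
    f0_est: float
    decomposition: Decomposition
    reconstruction: Reconstruction
    cardiac: CardiacMetrics
    resp: RespMetrics
    indices: SubjectIndices
    verdict: str
    votes: dict


def analyze_waveform(
    wave: Waveform,
    cfg: RunConfig | None = None,
    subject_id: str = "",
    label: str | None = None,
) -> PipelineResult:
    """Run the full analysis chain on one (already segmented) waveform."""
    cfg = cfg or RunConfig()
    try:
        x0, x_b = remove_baseline(wave, cfg.preprocess)
    except ValueError as exc:
        raise RuntimeError(f"stage remove_baseline failed: {exc}") from exc
    try:
        f0_est = detect_fundamental(x0)
    except ValueError as exc:
        raise RuntimeError(f"stage detect_fundamental failed: {exc}") from exc
    log.info("fundamental estimate %.3f Hz (%.1f bpm)", f0_est, 60 * f0_est)
    tracks = []
    for i in range(1, cfg.n_harmonics + 1):
        try:
            xi = isolate_harmonic(x0, i, f0_est, cfg.preprocess)
            tracks.append(hvd_track(xi, i, f0_est, cfg.decompose))
        except ValueError as exc:
            raise RuntimeError(f"stage harmonic {i} failed: {exc}") from exc
    decomp = assemble(x0, tracks)
    recon = build_reconstruction(decomp, f0_est)
    cardiac = compute_cardiac(tracks, decomp.x0, f0_est, cfg.resp.resp_band)
    resp = compute_resp(tracks, cfg.resp)
    indices = compute_indices(cardiac, resp, recon, subject_id, label)
    verdict, votes = classify(indices, cfg.thresholds)
    return PipelineResult(
        x0=x0,
        x_b=x_b,
        f0_est=f0_est,
        decomposition=decomp,
        reconstruction=recon,
        cardiac=cardiac,
        resp=resp,
        indices=indices,
        verdict=verdict,
        votes=votes,
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Read, segment, analyze, and (optionally) persist all intermediates."""
    logging.basicConfig()
    log.setLevel(cfg.log_level)
    if cfg.input_path is None:
        raise ValueError("RunConfig.input_path is required")
    wave, meta = read_record(cfg.input_path, cfg.fmt)
    start = cfg.segment_start_s if cfg.segment_start_s is not None else wave.t0
    rec_end = wave.t0 + wave.duration + 0.5 / wave.fs
    # default segment: 80 s, clipped to the record end
    end = cfg.segment_end_s if cfg.segment_end_s is not None else min(start + 80.0, rec_end)
    if end > rec_end:
        raise ValueError(
            f"segment [{start}, {end}) s does not fit the record "
            f"({wave.duration:.1f} s)"
        )
    segment = wave.crop(start, end)
    result = analyze_waveform(segment, cfg, subject_id=Path(str(cfg.input_path)).stem)
    if cfg.outdir is not None:
        _write_outputs(result, cfg, meta)
    return result


def _write_outputs(result: PipelineResult, cfg: RunConfig, meta: dict) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # intermediates on the full segment grid
    pd.DataFrame(
        {
            "time_s": result.x0.t,
            "x0": result.x0.samples,
            "x_b": result.x_b.samples,
        }
    ).to_csv(outdir / "baseline.csv", index=False, float_format="%.9g")
    d = result.decomposition
    frame = {"time_s": d.x0.t, "x0": d.x0.samples, "x_hvd": d.x_hvd.samples,
             "x_noise": d.x_noise.samples, "x_tf": result.reconstruction.x_tf.samples,
             "x_cf": result.reconstruction.x_cf.samples,
             "x_tvsp": result.reconstruction.x_tvsp.samples}
    pd.DataFrame(frame).to_csv(outdir / "reconstruction.csv", index=False,
                               float_format="%.9g")
    for tr in d.tracks:
        pd.DataFrame({"t": tr.t, "A": tr.A, "f": tr.f, "phi0": tr.phi0}).to_csv(
            outdir / f"track_h{tr.order}.csv", index=False, float_format="%.9g"
        )
    payload = {
        "f0_est_hz": result.f0_est,
        "verdict": result.verdict,
        "votes": result.votes,
        "indices": json.loads(
            json.dumps(
                dataclasses.asdict(result.indices),
                default=lambda o: np.asarray(o).tolist(),
            )
        ),
        "record": meta,
        "provenance": cfg.provenance(),
    }
    (outdir / "indices.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
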