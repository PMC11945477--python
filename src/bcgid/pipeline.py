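"""End-to-end orchestration: simulate -> featurize -> sweep -> attribute.

One :func:`run_pipeline` call executes every stage in order, writing all
intermediates (recordings, feature tables, sweep tables, attribution
curves) under an output directory together with a manifest that echoes the
configuration, the per-stage derived seeds and a SHA-256 hash of every file
produced — re-running with the same config and seed reproduces identical
hashes. All randomness flows from ``base_seed`` through named per-stage
seeds.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .attribution import cumulative_mask_scan, detect_peaks, single_peak_scan
from .evaluate import (
    SubjectFeatures,
    probability_bar_report,
    rank_patterns,
    run_pattern,
    sweep_combinations,
)
from .network import TrainConfig, save_model
from .preprocess import (
    detect_motion_segments,
    extract_test_windows,
    extract_training_windows,
    featurize_windows,
)
from .simulate import Recording, SubjectProfile, simulate_recording

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "split_recording", "featurize_recording_pair"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    sampling_rate_hz: float = 100.0
    train_duration_s: float = 120.0
    test_duration_s: float = 60.0
    window_len: int = 1000
    n_train_windows: int = 500
    test_shift_s: float = 1.0
    low_zero_hz: float = 0.5
    high_cut_hz: float = 15.0
    sweep_k: int = 5
    base_seed: int = 0
    exclude_motion: bool = False
    attribution_step_bins: int = 5
    attribution_half_width: int = 3
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        train = d.pop("train", {})
        if isinstance(train, dict):
            train = TrainConfig(**train)
        return cls(**d, train=train)


def stage_seed(base_seed: int, stage: str, item: str = "") -> int:
    """Deterministic per-stage (and per-item) seed below 2^31."""
    tag = zlib.crc32(f"{stage}/{item}".encode())
    ss = np.random.SeedSequence([int(base_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def split_recording(recording: Recording, train_duration_s: float) -> tuple[Recording, Recording]:
    """Split one recording into a training segment and the remaining test segment."""
    cut = int(round(train_duration_s * recording.sampling_rate_hz))
    if not 0 < cut < len(recording):
        raise ValueError("train_duration_s must leave a non-empty test segment")
    return (
        Recording(recording.subject_id, recording.sampling_rate_hz, recording.samples[:cut]),
        Recording(recording.subject_id, recording.sampling_rate_hz, recording.samples[cut:]),
    )


def featurize_recording_pair(
    train_rec: Recording,
    test_rec: Recording,
    config: PipelineConfig,
    seed: int,
) -> SubjectFeatures:
    """Random training windows + strided test windows -> normalised features."""
    exclude = None
    if config.exclude_motion:
        flags = detect_motion_segments(train_rec)
        exclude = flags if flags.segments else None
    train_windows = extract_training_windows(
        train_rec, config.n_train_windows, config.window_len, seed=seed, exclude=exclude
    )
    test_windows = extract_test_windows(test_rec, config.test_shift_s, config.window_len)
    kw = dict(
        sampling_rate_hz=config.sampling_rate_hz,
        low_zero_hz=config.low_zero_hz,
        high_cut_hz=config.high_cut_hz,
    )
    return SubjectFeatures(
        subject_id=train_rec.subject_id,
        train=featurize_windows(train_windows, **kw),
        test=featurize_windows(test_windows, **kw),
    )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    panel: list[SubjectProfile],
    out_dir: str | Path,
) -> dict:
    """Run every stage on a subject panel; returns the manifest dict.

    Output layout: ``recordings/<id>.csv``, ``features/{train,test}.csv``,
    ``sweep/{sweep.csv,summary.json}``, ``attribution/<pattern>_<class>_*.csv``,
    ``models/best_pattern.json`` and ``manifest.json`` at the root.
    """
    out = Path(out_dir)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "files": {},
        "complete": False,
    }
    if len({p.subject_id for p in panel}) != len(panel):
        raise StageError("input: duplicate subject ids in panel")

    def fail(stage: str, exc: Exception) -> StageError:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest(out, manifest)
        return StageError(f"{stage}: {exc}")

    # --- simulate -------------------------------------------------------
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    duration = config.train_duration_s + config.test_duration_s
    recordings: dict[str, Recording] = {}
    try:
        for profile in panel:
            seed = stage_seed(config.base_seed, "simulate", profile.subject_id)
            rec = simulate_recording(profile, duration, config.sampling_rate_hz, seed)
            recordings[profile.subject_id] = rec
            io.write_recording(rec, rec_dir / f"{profile.subject_id}.csv")
        io.write_panel(panel, out / "panel.json")
    except Exception as exc:  # noqa: BLE001 - stage-labelled re-raise
        raise fail("simulate", exc) from exc
    manifest["stages"]["simulate"] = {
        "status": "ok",
        "n_recordings": len(recordings),
        "samples_per_recording": int(round(duration * config.sampling_rate_hz)),
    }

    # --- featurize ------------------------------------------------------
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    features: dict[str, SubjectFeatures] = {}
    try:
        for sid, rec in recordings.items():
            train_rec, test_rec = split_recording(rec, config.train_duration_s)
            seed = stage_seed(config.base_seed, "featurize", sid)
            features[sid] = featurize_recording_pair(train_rec, test_rec, config, seed)
        for role in ("train", "test"):
            sids, starts, mats = [], [], []
            for sid in sorted(features):
                mat = getattr(features[sid], role)
                sids.extend([sid] * len(mat))
                starts.extend(range(len(mat)))
                mats.append(mat)
            io.write_features(sids, starts, np.vstack(mats), feat_dir / f"{role}.csv")
    except Exception as exc:  # noqa: BLE001
        raise fail("featurize", exc) from exc
    n_train = sum(len(f.train) for f in features.values())
    n_test = sum(len(f.test) for f in features.values())
    manifest["stages"]["featurize"] = {
        "status": "ok",
        "n_train_spectra": n_train,
        "n_test_spectra": n_test,
        "bins_per_spectrum": int(features[next(iter(features))].train.shape[1]),
    }

    # --- sweep ----------------------------------------------------------
    sweep_dir = out / "sweep"
    sweep_dir.mkdir(exist_ok=True)
    try:
        sweep = sweep_combinations(
            features, k=config.sweep_k, config=config.train, base_seed=config.base_seed
        )
        io.write_sweep(sweep, sweep_dir / "sweep.csv", sweep_dir / "summary.json")
    except Exception as exc:  # noqa: BLE001
        raise fail("sweep", exc) from exc
    manifest["stages"]["sweep"] = {
        "status": "ok",
        "n_patterns": sweep.n_patterns,
        "n_results": sweep.n_results,
        "epochs_per_pattern": config.train.epochs,
        "train_set_size_per_pattern": config.n_train_windows * config.sweep_k,
    }

    # --- attribute (best pattern) ---------------------------------------
    attr_dir = out / "attribution"
    attr_dir.mkdir(exist_ok=True)
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    try:
        best = rank_patterns(sweep, "best", 1)[0]
        members = tuple(sorted(best.per_class))
        _, predictions, params = run_pattern(features, members, config.train, config.base_seed)
        save_model(params, model_dir / "best_pattern.json", config=config.train)
        io.write_bar_report(
            probability_bar_report(predictions),
            attr_dir / f"{best.pattern_id}_probability_bars.csv",
        )
        for cls in members:
            X = features[cls].test
            for direction in ("low", "high"):
                curve = cumulative_mask_scan(
                    params, X, cls, direction, config.attribution_step_bins
                )
                _write_curve(curve, attr_dir / f"{best.pattern_id}_{cls}_{direction}.csv")
            peaks = detect_peaks(X.mean(axis=0))
            if peaks:
                rows = single_peak_scan(params, X, cls, peaks, config.attribution_half_width)
                _write_peaks(rows, attr_dir / f"{best.pattern_id}_{cls}_peaks.csv")
    except Exception as exc:  # noqa: BLE001
        raise fail("attribute", exc) from exc
    manifest["stages"]["attribute"] = {
        "status": "ok",
        "pattern_id": best.pattern_id,
        "classes": list(members),
    }

    manifest["complete"] = True
    _write_manifest(out, manifest)
    return manifest


def _write_curve(curve, path: Path) -> None:
    lines = ["boundary_hz,mean_own_probability"]
    lines += [
        f"{hz:.1f},{p:.12g}"
        for hz, p in zip(curve.mask_extents_hz, curve.mean_own_probability)
    ]
    path.write_text("\n".join(lines) + "\n")


def _write_peaks(rows, path: Path) -> None:
    from .preprocess import RESOLUTION_HZ

    lines = ["peak_hz,masked_probability,reference_probability"]
    lines += [
        f"{peak * RESOLUTION_HZ:.1f},{masked:.12g},{ref:.12g}"
        for peak, masked, ref in rows
    ]
    path.write_text("\n".join(lines) + "\n")


def _write_manifest(out: Path, manifest: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest["files"] = {
        str(p.relative_to(out)): _hash_file(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p != manifest_path
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
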