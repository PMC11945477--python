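"""File formats: recording CSV, panel manifest JSON, feature and sweep tables.

Recordings are 2-column CSV (``sample_index,voltage``) with ``#``-prefixed
header lines carrying ``subject_id`` and ``sampling_rate_hz``; voltages are
written with ``repr``-level precision so write/read round-trips exactly.
Feature tables are plain CSV with ``subject_id``, ``start_index`` and one
column per bin centre frequency (``f0.0`` ... ``f14.9``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import SweepResult
from .preprocess import N_BINS, RESOLUTION_HZ
from .simulate import HarmonicProfile, Recording, SubjectProfile

__all__ = [
    "write_recording",
    "read_recording",
    "write_panel",
    "read_panel",
    "feature_columns",
    "write_features",
    "read_features",
    "write_sweep",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def write_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# subject_id={recording.subject_id}",
        f"# sampling_rate_hz={recording.sampling_rate_hz!r}",
        "sample_index,voltage",
    ]
    lines.extend(
        f"{i},{v!r}" for i, v in enumerate(recording.samples.tolist())
    )
    path.write_text("\n".join(lines) + "\n")


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    subject_id: str | None = None
    rate: float | None = None
    samples: list[float] = []
    with open(path, newline=None) as fh:  # universal newlines: CRLF == LF
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ParseError(f"{path}:{lineno}: malformed header {line!r}")
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                if key == "subject_id":
                    subject_id = value
                elif key == "sampling_rate_hz":
                    try:
                        rate = float(value)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric sampling rate {value!r}"
                        ) from None
                continue
            if line.startswith("sample_index"):
                continue
            try:
                _, _, voltage = line.partition(",")
                samples.append(float(voltage))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from None
    if subject_id is None:
        raise ParseError(f"{path}: missing '# subject_id=...' header")
    if rate is None:
        raise ParseError(f"{path}: missing '# sampling_rate_hz=...' header")
    return Recording(subject_id, rate, np.asarray(samples))


def _profile_to_dict(p: SubjectProfile) -> dict:
    return {
        "subject_id": p.subject_id,
        "fundamental_hz": p.harmonic.fundamental_hz,
        "harmonic_amplitudes": list(p.harmonic.harmonic_amplitudes),
        "respiration_hz": p.respiration_hz,
        "respiration_depth": p.respiration_depth,
        "hr_jitter": p.hr_jitter,
        "noise_sd": p.noise_sd,
        "artifact_rate_per_min": p.artifact_rate_per_min,
    }


def _profile_from_dict(d: dict) -> SubjectProfile:
    return SubjectProfile(
        subject_id=d["subject_id"],
        harmonic=HarmonicProfile(
            d["fundamental_hz"], tuple(d["harmonic_amplitudes"])
        ),
        respiration_hz=d["respiration_hz"],
        respiration_depth=d["respiration_depth"],
        hr_jitter=d["hr_jitter"],
        noise_sd=d["noise_sd"],
        artifact_rate_per_min=d["artifact_rate_per_min"],
    )


def write_panel(panel: list[SubjectProfile], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([_profile_to_dict(p) for p in panel], indent=1) + "\n"
    )


def read_panel(path: str | Path) -> list[SubjectProfile]:
    return [_profile_from_dict(d) for d in json.loads(Path(path).read_text())]


def feature_columns() -> list[str]:
    return [f"f{i * RESOLUTION_HZ:.1f}" for i in range(N_BINS)]


def write_features(
    subject_ids: list[str],
    start_indices: list[int],
    matrix: np.ndarray,
    path: str | Path,
) -> None:
    df = pd.DataFrame(matrix, columns=feature_columns())
    df.insert(0, "start_index", start_indices)
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "start_index", *feature_columns()} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing feature columns {sorted(missing)[:3]}...")
    return df


def features_by_subject(df: pd.DataFrame) -> dict[str, np.ndarray]:
    cols = feature_columns()
    return {
        str(sid): grp[cols].to_numpy(dtype=np.float64)
        for sid, grp in df.groupby("subject_id", sort=True)
    }


def write_bar_report(report, path: str | Path) -> None:
    """Signed mean-probability matrix as CSV (rows: true class, cols: predicted)."""
    labels = list(report.class_labels)
    df = pd.DataFrame(
        [report.rows[cls] for cls in labels if cls in report.rows],
        index=[cls for cls in labels if cls in report.rows],
        columns=labels,
    )
    df.index.name = "true_class"
    df.to_csv(path, float_format="%.12g")


def write_sweep(sweep: SweepResult, csv_path: str | Path, summary_path: str | Path | None = None) -> None:
    rows = [
        {
            "pattern_id": r.pattern_id,
            "class_id": cls,
            "m_k": int(stats["m_k"]),
            "correct": int(stats["correct"]),
            "rate": stats["rate"],
        }
        for r in sweep.reports
        for cls, stats in sorted(r.per_class.items())
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.12g")
    if summary_path is not None:
        mean_rates = sweep.mean_rates()
        ranking = sorted(mean_rates, key=lambda p: (-mean_rates[p], p))
        summary = {
            "n_patterns": sweep.n_patterns,
            "n_results": sweep.n_results,
            "base_seed": sweep.base_seed,
            "mean_rates": mean_rates,
            "ranking_best_to_worst": ranking,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=1) + "\n")
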