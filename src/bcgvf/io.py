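"""Plain-text readers and writers for recordings, segments, feature
matrices and time-frequency maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .preprocess import SEGMENT_SAMPLES, Segment
from .synth import FS, Extent, RawRecording
from .transform import TimeFreqMap


def write_recording(rec: RawRecording, directory: str | Path, stem: str | None = None) -> tuple[Path, Path]:
    """Write one recording as signal CSV + sidecar annotation CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or rec.subject_id
    sig_path = directory / f"{stem}.csv"
    ann_path = directory / f"{stem}.annotations.csv"
    pd.DataFrame(
        {"sample_index": np.arange(rec.samples.size), "value": rec.samples}
    ).to_csv(sig_path, index=False)
    pd.DataFrame(
        {
            "start": [a.start for a in rec.annotations],
            "end": [a.end for a in rec.annotations],
            "label": [a.label for a in rec.annotations],
            "subject_id": rec.subject_id,
        }
    ).to_csv(ann_path, index=False)
    return sig_path, ann_path


def read_recording(sig_path: str | Path, ann_path: str | Path | None = None) -> RawRecording:
    sig_path = Path(sig_path)
    ann_path = Path(ann_path) if ann_path else sig_path.with_suffix("").with_suffix(".annotations.csv")
    sig = pd.read_csv(sig_path)
    ann = pd.read_csv(ann_path)
    subject_id = str(ann["subject_id"].iloc[0]) if len(ann) else sig_path.stem
    extents = [Extent(int(r.start), int(r.end), str(r.label)) for r in ann.itertuples()]
    return RawRecording(sig["value"].to_numpy(), FS, subject_id, extents)


def write_segments(segments: list[Segment], path: str | Path) -> Path:
    """One row per segment: subject_id, label, t0, s0000..s0874."""
    path = Path(path)
    cols = [f"s{i:04d}" for i in range(SEGMENT_SAMPLES)]
    df = pd.DataFrame([s.samples for s in segments], columns=cols)
    df.insert(0, "subject_id", [s.subject_id for s in segments])
    df.insert(1, "label", [s.label for s in segments])
    df.insert(2, "t0", [s.t0 for s in segments])
    df.to_csv(path, index=False)
    return path


def read_segments(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path)
    cols = [f"s{i:04d}" for i in range(SEGMENT_SAMPLES)]
    return [
        Segment(row[cols].to_numpy(dtype=float), str(row["label"]), str(row["subject_id"]), int(row["t0"]))
        for _, row in df.iterrows()
    ]


def write_features(
    segments: list[Segment], vectors: list[FeatureVector], path: str | Path
) -> Path:
    """Feature matrix CSV: subject_id,label,t0,f01..f22 (bit-exact round-trip)."""
    path = Path(path)
    df = pd.DataFrame(
        np.array([v.values for v in vectors]),
        columns=[f"f{i + 1:02d}" for i in range(len(FEATURE_NAMES))],
    )
    df.insert(0, "subject_id", [s.subject_id for s in segments])
    df.insert(1, "label", [s.label for s in segments])
    df.insert(2, "t0", [s.t0 for s in segments])
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    # round_trip parser: written with %.17g, so values reload bit-exact
    return pd.read_csv(path, float_precision="round_trip")


def feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a feature DataFrame into (X, labels, subject_ids)."""
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return df[fcols].to_numpy(dtype=float), df["label"].to_numpy(), df["subject_id"].to_numpy()


def write_timefreq_map(tfm: TimeFreqMap, path: str | Path) -> Path:
    """Matrix text file, rows = frequencies; grids in comment headers."""
    path = Path(path)
    header = (
        f"hbl={tfm.hbl}\n"
        f"f_grid_hz={','.join(f'{f:.6f}' for f in tfm.f_grid)}\n"
        f"t_grid_samples={','.join(str(int(t)) for t in tfm.t_grid)}"
    )
    np.savetxt(path, tfm.S, header=header)
    return path
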