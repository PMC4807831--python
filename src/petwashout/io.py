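"""File I/O: NIfTI-1 dynamic volumes with frame-timing sidecars, TAC CSVs,
mask volumes and run manifests.

A dynamic series is stored as a 4D NIfTI file plus two sidecars next to
it: ``<stem>_frames.csv`` (frame start/duration table) and
``<stem>_meta.json`` (units, decay-correction flag and provenance).
TACs are single CSV files whose provenance rides in a ``#``-prefixed
JSON header line, so a TAC round-trips with everything the fitters need.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import DynamicImageSeries
from .tac import ROIMask, TimeActivityCurve

__all__ = [
    "save_series",
    "load_series",
    "save_tac",
    "load_tac",
    "save_mask",
    "RunManifest",
    "build_manifest",
]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return (
        path.with_name(stem + "_frames.csv"),
        path.with_name(stem + "_meta.json"),
    )


def save_series(series: DynamicImageSeries, path) -> Path:
    """Write a dynamic series as 4D NIfTI + frame-timing and meta sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*series.voxel_size, 1.0])
    # NIfTI stores (x, y, z, t); the in-memory layout is (t, x, y, z)
    img = nib.Nifti1Image(
        np.moveaxis(series.values, 0, -1).astype(np.float64), affine
    )
    nib.save(img, str(path))

    frames_path, meta_path = _sidecar_paths(path)
    pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "t_start_s": series.frame_starts,
            "duration_s": series.frame_durations,
        }
    ).to_csv(frames_path, index=False)
    meta = {
        "units": series.units,
        "decay_corrected": series.decay_corrected,
        "voxel_size_mm": list(series.voxel_size),
        "meta": series.meta,
    }
    meta_path.write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def load_series(path) -> DynamicImageSeries:
    """Read a dynamic series written by :func:`save_series`."""
    path = Path(path)
    img = nib.load(str(path))
    values = np.moveaxis(np.asarray(img.dataobj, dtype=np.float64), -1, 0)

    frames_path, meta_path = _sidecar_paths(path)
    if not frames_path.exists():
        raise FileNotFoundError(f"frame-timing sidecar missing: {frames_path}")
    frames = pd.read_csv(frames_path)
    expected = set(range(values.shape[0]))
    got = set(int(f) for f in frames["frame"])
    if got != expected:
        missing = sorted(expected - got)
        raise ValueError(
            f"sidecar lists {len(got)} frames but volume has {values.shape[0]}"
            + (f"; missing frame index(es) {missing}" if missing else "")
        )
    frames = frames.sort_values("frame")

    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    voxel_size = tuple(
        meta.get("voxel_size_mm", np.abs(np.diag(img.affine)[:3]).tolist())
    )
    return DynamicImageSeries(
        values=values,
        frame_starts=frames["t_start_s"].to_numpy(),
        frame_durations=frames["duration_s"].to_numpy(),
        voxel_size=voxel_size,
        units=meta.get("units", "counts"),
        decay_corrected=bool(meta.get("decay_corrected", False)),
        meta=meta.get("meta", {}),
    )


def save_mask(mask: ROIMask, voxel_size, path) -> Path:
    """Write an ROI mask as a uint8 NIfTI volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))
    return path


def save_tac(tac: TimeActivityCurve, path) -> Path:
    """Write a TAC as CSV with its provenance in a '#' JSON header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "frame": np.arange(tac.n_frames),
            "t_start_s": tac.frame_starts
            if tac.frame_starts is not None
            else np.full(tac.n_frames, np.nan),
            "t_mid_s": tac.times,
            "duration_s": tac.frame_durations
            if tac.frame_durations is not None
            else np.full(tac.n_frames, np.nan),
            "value": tac.values,
            "decay_corrected": tac.decay_corrected,
        }
    )
    header = "# provenance: " + json.dumps(tac.provenance, default=_json_default)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)
    return path


def load_tac(path) -> TimeActivityCurve:
    """Read a TAC CSV written by :func:`save_tac` (invariants re-validated)."""
    path = Path(path)
    provenance = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = json.loads(first.split(":", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, comment="#")
    starts = df["t_start_s"].to_numpy()
    durations = df["duration_s"].to_numpy()
    return TimeActivityCurve(
        times=df["t_mid_s"].to_numpy(),
        values=df["value"].to_numpy(),
        frame_starts=None if np.all(np.isnan(starts)) else starts,
        frame_durations=None if np.all(np.isnan(durations)) else durations,
        decay_corrected=bool(df["decay_corrected"].iloc[0]),
        provenance=provenance,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Inventory of a pipeline run: version, seed and output checksums."""

    tool_version: str
    timestamp: str
    seed: int
    files: dict[str, str] = field(default_factory=dict)  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "timestamp": self.timestamp,
                "seed": self.seed,
                "files": self.files,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def build_manifest(output_dir, seed: int, version: str) -> RunManifest:
    """Checksum every file under ``output_dir`` into a manifest."""
    output_dir = Path(output_dir)
    files = {}
    for p in sorted(output_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(output_dir))] = _sha256(p)
    return RunManifest(
        tool_version=version,
        timestamp=datetime.now(timezone.utc).isoformat(),
        seed=seed,
        files=files,
    )
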