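"""File I/O: PNG images, label maps with JSON sidecars, CSV timelines,
YAML specs and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import indices
from .datatypes import PlaqueClass, PlaqueLabelMap, SubjectTimeline, UVPhotograph
from .synthetic import SceneSpec, TrialSimSpec

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_label_map",
    "read_label_map",
    "write_timelines",
    "read_timelines",
    "load_scene_spec",
    "load_trial_spec",
    "write_manifest",
]

TIMELINE_COLUMNS = (
    "subject_id",
    "group",
    "hours",
    "visible_abs",
    "visible_rel",
    "nonvisible",
    "total",
)


def write_image(path: str | Path, image: UVPhotograph | np.ndarray) -> None:
    arr = image.pixels if isinstance(image, UVPhotograph) else np.asarray(image)
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_image(path: str | Path, **meta) -> UVPhotograph:
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if present
        arr = arr[..., :3]
    return UVPhotograph(arr, **meta)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)) > 127


def write_label_map(path: str | Path, labels: PlaqueLabelMap) -> None:
    """Write labels as a single-channel PNG plus a JSON class-encoding
    sidecar (``<path>.json``)."""
    path = Path(path)
    iio.imwrite(path, labels.labels.astype(np.uint8))
    sidecar = {cls.name.lower(): int(cls) for cls in PlaqueClass}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_label_map(path: str | Path) -> PlaqueLabelMap:
    return PlaqueLabelMap(iio.imread(Path(path)).astype(np.uint8))


def write_timelines(path: str | Path, timelines: Sequence[SubjectTimeline]) -> None:
    rows = []
    for tl in timelines:
        for hours, rec in tl.records.items():
            rows.append(
                {
                    "subject_id": tl.subject_id,
                    "group": tl.group,
                    "hours": hours,
                    "visible_abs": rec.visible_area_abs,
                    "visible_rel": rec.visible_area_rel,
                    "nonvisible": rec.nonvisible_area,
                    "total": rec.total_area,
                }
            )
    pd.DataFrame(rows, columns=list(TIMELINE_COLUMNS)).to_csv(path, index=False)


def read_timelines(path: str | Path) -> list[SubjectTimeline]:
    """Read a timelines CSV; growth indices are reconstructed from the
    stored areas and elapsed hours."""
    frame = pd.read_csv(path)
    missing = set(TIMELINE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"timelines CSV missing columns: {sorted(missing)}")
    timelines = []
    for (sid, group), sub in frame.groupby(["subject_id", "group"], sort=True):
        sub = sub.sort_values("hours")
        if 0 not in sub["hours"].values:
            raise ValueError(f"subject {sid} lacks the hour-0 baseline record")
        baseline = float(sub.loc[sub["hours"] == 0, "visible_abs"].iloc[0])
        records = {}
        for _, row in sub.iterrows():
            records[float(row["hours"])] = indices.build_index_set(
                visible_abs=float(row["visible_abs"]),
                nonvisible=float(row["nonvisible"]),
                baseline_visible_abs=baseline,
                elapsed_hours=float(row["hours"]),
            )
        timelines.append(SubjectTimeline(subject_id=str(sid), group=str(group), records=records))
    return timelines


def _spec_from_yaml(path: str | Path, cls):
    data = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in {path}: {sorted(unknown)}")
    # YAML has no tuple keys; growth rates come in as "A1": rate etc.
    if cls is TrialSimSpec:
        for key in ("growth_rate_means", "growth_rate_sds"):
            if key in data:
                data[key] = {(k[0], int(k[1])): v for k, v in data[key].items()}
        if "timepoints_hours" in data:
            data["timepoints_hours"] = tuple(data["timepoints_hours"])
    return cls(**data)


def load_scene_spec(path: str | Path) -> SceneSpec:
    return _spec_from_yaml(path, SceneSpec)


def load_trial_spec(path: str | Path) -> TrialSimSpec:
    return _spec_from_yaml(path, TrialSimSpec)


def write_manifest(out_dir: str | Path, seed: int | None, files: Sequence[Path]) -> Path:
    """Write ``manifest.json`` listing every produced file with its
    SHA-256 content hash and the seed used."""
    out_dir = Path(out_dir)
    entries = {}
    for f in sorted(files):
        digest = hashlib.sha256(Path(f).read_bytes()).hexdigest()
        entries[str(Path(f).relative_to(out_dir))] = digest
    manifest = {"seed": seed, "files": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
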