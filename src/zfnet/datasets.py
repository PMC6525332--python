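"""TraceDataset container, on-disk format, and preprocessing.

A dataset is one imaged larva: an ``n_rois x n_frames`` ΔF/F matrix, one
spatial coordinate row per ROI (x, y in μm, imaging-plane index, z in μm),
the frame interval in seconds, and free-form metadata (larva id, age in
days post-fertilization, genotype).

On disk a dataset is a directory of plain-text files:

* ``traces.csv``  — rows = ROIs (indexed by ``roi_id``), columns = frames
* ``coords.csv``  — columns ``roi_id, x_um, y_um, plane, z_um``
* ``meta.json``   — ``frame_interval`` plus larva_id / age_dpf / genotype / notes
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

COORD_COLUMNS = ["roi_id", "x_um", "y_um", "plane", "z_um"]


class DatasetError(ValueError):
    """Malformed or inconsistent dataset."""


@dataclass
class TraceDataset:
    """Per-larva ΔF/F traces plus ROI coordinates and acquisition metadata.

    Parameters
    ----------
    traces : ndarray, shape (n_rois, n_frames)
        ΔF/F values, one row per ROI.  Baseline is 0 by convention.
    coords : DataFrame
        One row per ROI with columns ``roi_id, x_um, y_um, plane, z_um``,
        aligned with the rows of ``traces``.
    frame_interval : float
        Seconds between consecutive frames (> 0).
    meta : dict
        ``larva_id``, ``age_dpf``, ``genotype``, ``notes`` (all optional).
    """

    traces: np.ndarray
    coords: pd.DataFrame
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise DatasetError("traces must be a 2-D (n_rois, n_frames) array")
        if self.traces.shape[1] < 2:
            raise DatasetError("traces must have at least 2 frames")
        if not isinstance(self.coords, pd.DataFrame):
            self.coords = pd.DataFrame(self.coords, columns=COORD_COLUMNS)
        missing = [c for c in COORD_COLUMNS if c not in self.coords.columns]
        if missing:
            raise DatasetError(f"coords missing columns: {missing}")
        self.coords = self.coords.astype(
            {"roi_id": np.int64, "x_um": float, "y_um": float,
             "plane": np.int64, "z_um": float})
        if len(self.coords) != self.traces.shape[0]:
            raise DatasetError(
                f"coords has {len(self.coords)} rows but traces has "
                f"{self.traces.shape[0]} ROIs"
            )
        if not self.frame_interval > 0:
            raise DatasetError("frame_interval must be > 0")

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def larva_id(self) -> str:
        return str(self.meta.get("larva_id", ""))

    def equals(self, other: "TraceDataset") -> bool:
        return (
            np.array_equal(self.traces, other.traces)
            and self.coords.reset_index(drop=True).equals(
                other.coords.reset_index(drop=True))
            and self.frame_interval == other.frame_interval
            and self.meta == other.meta
        )


def write_dataset(dataset: TraceDataset, path: str | Path) -> Path:
    """Write a dataset directory (traces.csv, coords.csv, meta.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    traces = pd.DataFrame(
        dataset.traces,
        index=pd.Index(dataset.coords["roi_id"].to_numpy(), name="roi_id"),
        columns=[f"f{j}" for j in range(dataset.n_frames)],
    )
    traces.to_csv(path / "traces.csv", float_format="%.17g")
    dataset.coords.to_csv(path / "coords.csv", index=False, float_format="%.17g")
    meta = dict(dataset.meta)
    meta["frame_interval"] = dataset.frame_interval
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return path


def read_dataset(path: str | Path) -> TraceDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises
    ------
    DatasetError
        If a file is missing, ``frame_interval`` is absent, or the trace
        and coordinate tables disagree on the ROI count.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset path does not exist: {path}")
    for name in ("traces.csv", "coords.csv", "meta.json"):
        if not (path / name).exists():
            raise DatasetError(f"dataset at {path} is missing {name}")
    traces = pd.read_csv(path / "traces.csv", index_col="roi_id",
                         float_precision="round_trip")
    coords = pd.read_csv(path / "coords.csv", float_precision="round_trip")
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    if "frame_interval" not in meta:
        raise DatasetError(f"meta.json at {path} is missing field 'frame_interval'")
    frame_interval = float(meta.pop("frame_interval"))
    return TraceDataset(
        traces=traces.to_numpy(dtype=float),
        coords=coords,
        frame_interval=frame_interval,
        meta=meta,
    )


def trim_initial(dataset: TraceDataset, trim_seconds: float) -> TraceDataset:
    """Drop the first ``trim_seconds`` of every trace.

    Recordings routinely show a transient fluorescence increase when
    scanning starts, so the first minute is conventionally discarded
    before any correlation is computed.  Removes
    ``floor(trim_seconds / frame_interval)`` frames; coordinates and
    metadata are unchanged.
    """
    if trim_seconds < 0:
        raise DatasetError("trim_seconds must be >= 0")
    n_trim = int(np.floor(trim_seconds / dataset.frame_interval))
    if dataset.n_frames - n_trim < 2:
        raise DatasetError(
            f"trimming {n_trim} frames leaves fewer than 2 of {dataset.n_frames}"
        )
    if n_trim == 0:
        return dataset
    return replace(dataset, traces=dataset.traces[:, n_trim:])


def clean_traces(dataset: TraceDataset) -> tuple[TraceDataset, list]:
    """Drop ROIs whose trace is constant or contains non-finite values.

    Pearson correlation is undefined for zero-variance traces, so they are
    removed (not assigned r = 0).  Returns the cleaned dataset and the list
    of dropped ``roi_id`` values; ROI order is preserved.
    """
    finite = np.isfinite(dataset.traces).all(axis=1)
    with np.errstate(invalid="ignore"):
        varying = np.nanstd(dataset.traces, axis=1) > 0
    keep = finite & varying
    if not keep.any():
        raise DatasetError("all ROIs dropped: no finite, non-constant traces")
    dropped = dataset.coords["roi_id"].to_numpy()[~keep].tolist()
    if not dropped:
        return dataset, []
    return (
        replace(
            dataset,
            traces=dataset.traces[keep],
            coords=dataset.coords.loc[keep].reset_index(drop=True),
        ),
        dropped,
    )


def combine_planes(datasets: Sequence[TraceDataset]) -> TraceDataset:
    """Concatenate single-plane datasets of one larva into one dataset.

    All inputs must share ``frame_interval`` and frame count and carry
    distinct plane indices; each ROI keeps its plane index and z.
    """
    if not datasets:
        raise DatasetError("combine_planes requires at least one dataset")
    if len(datasets) == 1:
        return datasets[0]
    first = datasets[0]
    planes: set = set()
    for ds in datasets:
        if ds.frame_interval != first.frame_interval:
            raise DatasetError("all planes must share frame_interval")
        if ds.n_frames != first.n_frames:
            raise DatasetError(
                f"plane frame counts differ: {ds.n_frames} vs {first.n_frames}"
            )
        p = set(ds.coords["plane"].unique())
        if p & planes:
            raise DatasetError(f"duplicate plane indices: {sorted(p & planes)}")
        planes |= p
    return TraceDataset(
        traces=np.vstack([ds.traces for ds in datasets]),
        coords=pd.concat([ds.coords for ds in datasets], ignore_index=True),
        frame_interval=first.frame_interval,
        meta=dict(first.meta),
    )


@dataclass
class GroupManifest:
    """Index of datasets with group keys (age_dpf, genotype)."""

    entries: list  # of dicts: {"path": str, "age_dpf": int, "genotype": str}

    def __post_init__(self) -> None:
        if not self.entries:
            raise DatasetError("manifest has no entries")
        for e in self.entries:
            for key in ("path", "age_dpf", "genotype"):
                if key not in e:
                    raise DatasetError(f"manifest entry missing field '{key}': {e}")

    @classmethod
    def read(cls, path: str | Path) -> "GroupManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(entries=data["entries"])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"entries": self.entries}, fh, indent=2)

    def group_keys(self) -> list[tuple]:
        return sorted({(e["age_dpf"], e["genotype"]) for e in self.entries})

    def paths_for(self, age_dpf, genotype) -> list[str]:
        return [
            e["path"]
            for e in self.entries
            if e["age_dpf"] == age_dpf and e["genotype"] == genotype
        ]

    def load_group(self, age_dpf, genotype, base: str | Path = ".") -> list[TraceDataset]:
        paths = self.paths_for(age_dpf, genotype)
        if not paths:
            raise DatasetError(f"no manifest entries for group ({age_dpf}, {genotype})")
        out = []
        for p in paths:
            full = Path(base) / p
            if not full.exists():
                raise DatasetError(f"manifest references missing path: {full}")
            out.append(read_dataset(full))
        return out
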