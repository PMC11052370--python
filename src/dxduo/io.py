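"""File I/O and configuration: image stacks, trajectory tables, YAML configs,
run reports.

Stacks are multi-page TIFF or HDF5 3-D unsigned-integer datasets
(frames x rows x cols); trajectories travel as CSV with columns
(trajectory_id, frame, row_px, col_px, intensity); geometry and beam live in
a single YAML file.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .dxt import Spot, SpotTrajectory
from .geometry import (
    BeamSpec,
    ConfigError,
    CrystalPhase,
    DetectorGeometry,
    RingROI,
    build_ring_roi,
)

__all__ = [
    "FormatError",
    "SchemaError",
    "IntegrityError",
    "read_stack",
    "write_stack",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "read_i0_csv",
    "GeometryConfig",
    "load_geometry_config",
    "RunReport",
]

HDF5_DATASET = "frames"


class FormatError(ValueError):
    """File contents do not match the expected format."""


class SchemaError(ValueError):
    """A table is missing required columns."""


class IntegrityError(ValueError):
    """A table violates an integrity constraint (e.g. duplicate keys)."""


def read_stack(path: str | Path, dataset: str | None = None) -> np.ndarray:
    """Load a movie as a (frames, rows, cols) unsigned-integer array.

    TIFF multi-page (.tif/.tiff) or HDF5 (any other suffix; dataset name
    defaults to "frames", else the first 3-D dataset found).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with h5py.File(path, "r") as f:
            name = dataset or (HDF5_DATASET if HDF5_DATASET in f else None)
            if name is None:
                name = next(
                    (k for k in f if isinstance(f[k], h5py.Dataset)
                     and f[k].ndim == 3),
                    None,
                )
            if name is None or name not in f:
                raise FormatError(f"{path}: no 3-D dataset found")
            arr = f[name][...]
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3-D stack (frames, rows, cols), got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: expected integer photon counts, got dtype {arr.dtype}"
        )
    if np.any(arr.reshape(-1)[:: max(1, arr.size // 100000)] < 0):
        raise FormatError(f"{path}: negative counts")
    return arr


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a 3-D integer stack as TIFF or HDF5 by suffix."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim != 3 or not np.issubdtype(stack.dtype, np.integer):
        raise FormatError("stack must be a 3-D integer array")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack)
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset(HDF5_DATASET, data=stack, compression="gzip")


_TRAJ_COLUMNS = ["trajectory_id", "frame", "row_px", "col_px", "intensity"]


def read_trajectories_csv(
    path: str | Path, geom: DetectorGeometry
) -> list[SpotTrajectory]:
    """Load pre-tracked trajectories, grouped by id and frame-sorted.

    Rows may arrive in any order; duplicate (trajectory_id, frame) pairs are
    an integrity error.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["trajectory_id", "frame"])
    if dup.any():
        raise IntegrityError(
            f"{path}: {int(dup.sum())} duplicate (trajectory_id, frame) rows"
        )
    cr, cc = geom.beam_center_px
    out = []
    for tid, g in df.sort_values(["trajectory_id", "frame"]).groupby("trajectory_id"):
        spots = tuple(
            Spot(
                frame=int(r.frame),
                position_px=(float(r.row_px), float(r.col_px)),
                intensity=float(r.intensity),
                radius_px=math.hypot(r.row_px - cr, r.col_px - cc),
                azimuth_deg=math.degrees(math.atan2(r.row_px - cr, r.col_px - cc)),
            )
            for r in g.itertuples()
        )
        out.append(SpotTrajectory(spots=spots, trajectory_id=int(tid)))
    return out


def write_trajectories_csv(
    path: str | Path, trajectories: Sequence[SpotTrajectory]
) -> None:
    rows = [
        {
            "trajectory_id": t.trajectory_id,
            "frame": s.frame,
            "row_px": s.position_px[0],
            "col_px": s.position_px[1],
            "intensity": s.intensity,
            "ring_label": t.ring_label,
        }
        for t in trajectories
        for s in t.spots
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_i0_csv(path: str | Path) -> np.ndarray:
    """Two-column (frame, i0) CSV -> i0 array ordered by frame."""
    df = pd.read_csv(path)
    if "i0" not in df.columns:
        raise SchemaError(f"{path}: missing 'i0' column")
    if "frame" in df.columns:
        df = df.sort_values("frame")
    return df["i0"].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeometryConfig:
    """Everything in the geometry YAML: detector, beam, phases, ring specs."""

    detector: DetectorGeometry
    beam: BeamSpec
    phases: dict[str, CrystalPhase]
    rings: tuple[dict, ...]  # each: {phase, hkl, half_width_px}

    def build_rois(self) -> list[RingROI]:
        rois = []
        for spec in self.rings:
            phase = self.phases[spec["phase"]]
            rois.append(
                build_ring_roi(
                    phase,
                    tuple(spec["hkl"]),
                    self.beam,
                    self.detector,
                    half_width_px=float(spec.get("half_width_px", 2.0)),
                )
            )
        return rois


def load_geometry_config(path: str | Path) -> GeometryConfig:
    """Parse the single-file YAML geometry/beam/ring configuration.

    Expected keys: detector{pitch_mm, rows, cols, center, distance_mm,
    frame_interval_s, masks}, beam{energy_keV, bandwidth, mode},
    phases[{name, system, a, c}], rings[{phase, hkl, half_width_px}].
    """
    with open(path) as f:
        raw = yaml.safe_load(f)
    try:
        det = raw["detector"]
        geom = DetectorGeometry(
            pixel_pitch_mm=float(det["pitch_mm"]),
            n_rows=int(det["rows"]),
            n_cols=int(det["cols"]),
            beam_center_px=tuple(float(x) for x in det["center"]),
            distance_mm=float(det["distance_mm"]),
            frame_interval_s=float(det["frame_interval_s"]),
            mask_rects=tuple(tuple(int(v) for v in m) for m in det.get("masks", [])),
        )
        b = raw["beam"]
        beam = BeamSpec(
            energy_keV=float(b["energy_keV"]),
            bandwidth=float(b.get("bandwidth", 0.0)),
            mode=b.get("mode", "mono"),
        )
        phases = {}
        for p in raw["phases"]:
            phases[p["name"]] = CrystalPhase(
                name=p["name"], system=p["system"], a=float(p["a"]),
                c=float(p["c"]) if p.get("c") is not None else None,
            )
        rings = tuple(raw["rings"])
        for r in rings:
            if r["phase"] not in phases:
                raise ConfigError(f"ring references unknown phase {r['phase']!r}")
    except KeyError as e:
        raise ConfigError(f"{path}: missing config key {e}") from e
    return GeometryConfig(detector=geom, beam=beam, phases=phases, rings=rings)


def _digest(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunReport:
    """Structured per-stage accounting of a pipeline run.

    Every (attempted, accepted, rejected) triple must reconcile:
    accepted + rejected = attempted.
    """

    tool_version: str
    config_echo: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_input(self, name: str, obj: Any) -> None:
        self.input_digests[name] = _digest(obj)

    def add_stage(self, name: str, *, attempted: int, accepted: int,
                  **extra) -> None:
        rejected = attempted - accepted
        if rejected < 0:
            raise ValueError("accepted exceeds attempted")
        self.stage_counts[name] = {
            "attempted": attempted, "accepted": accepted,
            "rejected": rejected, **extra,
        }

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    @property
    def config_digest(self) -> str:
        return _digest(self.config_echo)

    def reconciled(self) -> bool:
        return all(
            c["accepted"] + c["rejected"] == c["attempted"]
            for c in self.stage_counts.values()
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "tool_version": self.tool_version,
            "config_digest": self.config_digest,
            "config_echo": self.config_echo,
            "seeds": self.seeds,
            "input_digests": self.input_digests,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text
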