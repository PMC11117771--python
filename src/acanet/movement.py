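"""Motion-capture preprocessing and a synthetic movement generator.

Input data are marker trajectories: 38 markers × (x, y, z) sampled every
10 ms, each recording labelled with one of five movement classes — gait,
cutting, sitting down, standing up, turning — and, for the non-gait
classes, an annotated "critical area": the frame interval in which the
labelled movement actually happens (the rest of the recording is ordinary
walking).  Recordings are cut into fixed-length sliding windows; a window
inherits the movement label iff it intersects the critical area, otherwise
it counts as gait.  Classes are then balanced by seeded downsampling to
the smallest class.

Real recordings of this kind are rarely shareable, so the module also
ships a seeded synthetic generator producing 38-marker trajectories from
class-specific kinematic templates with matching critical-area structure
(mid-sample for cutting/turning, at onset for sitting down/standing up,
absent for gait).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_COUNT",
    "CLASSES",
    "MovementSample",
    "WindowSegment",
    "read_mocap_table",
    "write_mocap_table",
    "segment_windows",
    "balance_classes",
    "generate_synthetic_dataset",
]

#: Principal joints tracked per frame.
MARKER_COUNT = 38

#: The five movement classes, in canonical label-index order.
CLASSES: tuple[str, ...] = ("gait", "cutting", "sitting down", "standing up", "turning")

_COORDS = ("x", "y", "z")


def marker_columns() -> list[str]:
    """Column names of the flattened layout: m01_x, m01_y, m01_z, m02_x, ..."""
    return [f"m{m + 1:02d}_{c}" for m in range(MARKER_COUNT) for c in _COORDS]


@dataclass
class MovementSample:
    """One recording: (38, 3, F) positions, a class label, and an optional
    critical-area frame interval [start, end] (closed, 0-based)."""

    positions: np.ndarray
    label: str
    critical_area: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[:2] != (MARKER_COUNT, 3):
            raise ValueError(
                f"positions must have shape ({MARKER_COUNT}, 3, F), got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASSES}")
        if self.label == "gait" and self.critical_area is not None:
            raise ValueError("gait samples carry no critical area")
        if self.critical_area is not None:
            s, e = self.critical_area
            if not (0 <= s <= e < self.n_frames):
                raise ValueError(
                    f"critical area [{s}, {e}] outside frame range [0, {self.n_frames})"
                )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[2]

    def flat_features(self) -> np.ndarray:
        """(114, F) marker-major channel layout: m1x, m1y, m1z, m2x, ..."""
        return self.positions.reshape(MARKER_COUNT * 3, self.n_frames)


@dataclass
class WindowSegment:
    """A fixed-length window of flattened features with its class label."""

    features: np.ndarray  # (channels, S)
    label: str
    start: int = 0  # frame offset within the source sample

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be a (channels, S) matrix")


def read_mocap_table(path: str | Path, annotation: Optional[str | Path] = None) -> MovementSample:
    """Load a tabular motion-capture export (CSV) into a MovementSample.

    The CSV must contain a ``frame`` column plus the 114 position columns
    named m01_x .. m38_z; an optional JSON sidecar (``annotation``, or
    ``<path stem>.json`` next to the CSV if present) supplies the class
    label and critical frames, e.g. ``{"label": "turning",
    "critical_area": [139, 159]}``.  Missing or extra marker columns and
    NaN runs are rejected with a descriptive error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = marker_columns()
    cols = [c for c in df.columns if c != "frame"]
    if set(cols) != set(expected):
        raise ValueError(
            f"{path.name}: expected {len(expected)} position columns "
            f"(m01_x..m{MARKER_COUNT}_z), found {len(cols)}"
        )
    values = df[expected].to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        bad = [expected[i] for i in np.unique(np.argwhere(np.isnan(values))[:, 1])][:5]
        raise ValueError(f"{path.name}: NaN values in marker columns {bad}")
    F = values.shape[0]
    positions = values.T.reshape(MARKER_COUNT, 3, F)

    label = "gait"
    critical: Optional[tuple[int, int]] = None
    sidecar = Path(annotation) if annotation is not None else path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", "gait")
        if meta.get("critical_area") is not None:
            s, e = meta["critical_area"]
            critical = (int(s), int(e))
    return MovementSample(positions=positions, label=label, critical_area=critical)


def write_mocap_table(sample: MovementSample, path: str | Path) -> None:
    """Write a sample as CSV + JSON sidecar (the inverse of read_mocap_table)."""
    path = Path(path)
    flat = sample.flat_features()
    df = pd.DataFrame(flat.T, columns=marker_columns())
    df.insert(0, "frame", np.arange(sample.n_frames))
    df.to_csv(path, index=False)
    meta = {
        "label": sample.label,
        "critical_area": list(sample.critical_area) if sample.critical_area else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def segment_windows(sample: MovementSample, S: int, stride: int = 1) -> list[WindowSegment]:
    """Cut a recording into sliding windows of S frames.

    Windows start at 0, stride, 2·stride, ... up to F−S (both ends
    included).  A window [f, f+S−1] gets the sample's movement label iff it
    overlaps the critical area (nonempty closed-interval intersection);
    every other window is gait.
    """
    if S < 1 or stride < 1:
        raise ValueError("S and stride must be positive")
    F = sample.n_frames
    if F < S:
        raise ValueError(f"sample has {F} frames, shorter than window size {S}")
    feats = sample.flat_features()
    out: list[WindowSegment] = []
    for f in range(0, F - S + 1, stride):
        lo, hi = f, f + S - 1
        label = "gait"
        if sample.critical_area is not None:
            cs, ce = sample.critical_area
            if lo <= ce and hi >= cs:
                label = sample.label
        out.append(WindowSegment(features=feats[:, f : f + S], label=label, start=f))
    return out


def balance_classes(segments: Sequence[WindowSegment], seed: int) -> list[WindowSegment]:
    """Downsample every class (seeded, without replacement) to the size of
    the smallest class present."""
    segments = list(segments)
    if not segments:
        return []
    labels = np.array([s.label for s in segments])
    classes, counts = np.unique(labels, return_counts=True)
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        keep.extend(rng.choice(idx, size=n_min, replace=False))
    keep.sort()
    return [segments[i] for i in keep]


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

# Marker-group index ranges within the 38-marker layout.
_GROUPS = {
    "head": range(0, 4),
    "torso": range(4, 10),
    "pelvis": range(10, 14),
    "left_arm": range(14, 20),
    "right_arm": range(20, 26),
    "left_leg": range(26, 32),
    "right_leg": range(32, 38),
}

# Resting heights (m) of each group's centre; lateral spread is added per marker.
_GROUP_Z = {
    "head": 1.65, "torso": 1.30, "pelvis": 0.95,
    "left_arm": 1.05, "right_arm": 1.05,
    "left_leg": 0.45, "right_leg": 0.45,
}
_GROUP_Y = {
    "head": 0.0, "torso": 0.0, "pelvis": 0.0,
    "left_arm": 0.25, "right_arm": -0.25,
    "left_leg": 0.12, "right_leg": -0.12,
}

_GAIT_SPEED = 0.012  # m per 10 ms frame (~1.2 m/s walking speed)
_STEP_PERIOD = 100.0  # frames per gait cycle (~1 s)


def _base_pose(rng: np.random.Generator) -> np.ndarray:
    """(38, 3) resting marker offsets with small per-subject jitter."""
    pose = np.zeros((MARKER_COUNT, 3))
    for name, idx in _GROUPS.items():
        for k, m in enumerate(idx):
            pose[m, 0] = 0.04 * (k - len(idx) / 2)  # anterior-posterior spread
            pose[m, 1] = _GROUP_Y[name] + 0.03 * ((k % 2) - 0.5)
            pose[m, 2] = _GROUP_Z[name] + 0.05 * (k % 3)
    pose += rng.normal(0.0, 0.01, pose.shape)
    return pose


def _gait_motion(F: int, phase: float) -> np.ndarray:
    """(38, 3, F) limb oscillation + forward drift of a steady walk."""
    t = np.arange(F)
    osc = np.sin(2 * np.pi * t / _STEP_PERIOD + phase)
    osc2 = np.sin(4 * np.pi * t / _STEP_PERIOD + phase)
    motion = np.zeros((MARKER_COUNT, 3, F))
    motion[:, 0, :] += _GAIT_SPEED * t  # whole-body forward drift
    for name, idx in _GROUPS.items():
        sgn = -1.0 if name.startswith("left") else 1.0
        for m in idx:
            if "leg" in name:
                motion[m, 0, :] += 0.15 * sgn * osc  # stride swing
                motion[m, 2, :] += 0.04 * np.maximum(sgn * osc, 0.0)  # foot lift
            elif "arm" in name:
                motion[m, 0, :] += 0.10 * (-sgn) * osc  # arm counter-swing
            elif name in ("torso", "head", "pelvis"):
                motion[m, 2, :] += 0.015 * osc2  # vertical bob, twice per cycle
    return motion


def _smoothstep(t: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """0→1 cubic ramp over frames [lo, hi], constant outside."""
    x = np.clip((t - lo) / max(hi - lo, 1), 0.0, 1.0)
    return x * x * (3 - 2 * x)


def generate_synthetic_dataset(
    n_per_class: int,
    F: int = 300,
    seed: int = 0,
    noise_sd: float = 0.005,
) -> list[MovementSample]:
    """Generate ``n_per_class`` recordings of each of the five classes.

    Every recording embeds the labelled movement in ongoing gait, mirroring
    how composite recordings are annotated in practice:

    * gait — steady walking, no critical area;
    * cutting — a sharp lateral side-step (y displacement with a quick
      zig-zag) inside a critical area centred mid-sample;
    * turning — the heading rotates by ~90° across a mid-sample critical
      area, rotating the whole marker cloud about the pelvis;
    * sitting down — pelvis/torso/head drop ~0.45 m across a critical area
      at the onset of the movement, then remain low;
    * standing up — the mirror image, rising at onset.

    ``noise_sd`` is additive white Gaussian marker noise in metres
    (default 5 mm, the order of optical-capture jitter plus soft-tissue
    artefact).  Output is deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if F < 50:
        raise ValueError("F must be >= 50 frames")
    rng = np.random.default_rng(seed)
    t = np.arange(F)
    samples: list[MovementSample] = []
    for label in CLASSES:
        for _ in range(n_per_class):
            pose = _base_pose(rng)
            phase = rng.uniform(0, 2 * np.pi)
            pos = pose[:, :, None] + _gait_motion(F, phase)
            critical: Optional[tuple[int, int]] = None

            if label == "cutting":
                mid = F // 2 + rng.integers(-F // 10, F // 10 + 1)
                half = max(F // 12, 10)
                cs, ce = int(mid - half), int(mid + half)
                critical = (max(cs, 0), min(ce, F - 1))
                ramp = _smoothstep(t, critical[0], critical[1])
                zig = np.sin(2 * np.pi * 3 * _smoothstep(t, critical[0], critical[1]))
                pos[:, 1, :] += 0.55 * ramp + 0.12 * zig  # lateral cut with wobble
                pos[:, 0, :] += -0.25 * ramp  # braking in the plant step
            elif label == "turning":
                mid = F // 2 + rng.integers(-F // 10, F // 10 + 1)
                half = max(F // 10, 12)
                cs, ce = int(mid - half), int(mid + half)
                critical = (max(cs, 0), min(ce, F - 1))
                theta = (np.pi / 2) * _smoothstep(t, critical[0], critical[1])
                pelvis = pos[list(_GROUPS["pelvis"]), :2, :].mean(axis=0)
                dx = pos[:, 0, :] - pelvis[0]
                dy = pos[:, 1, :] - pelvis[1]
                pos[:, 0, :] = pelvis[0] + np.cos(theta) * dx - np.sin(theta) * dy
                pos[:, 1, :] = pelvis[1] + np.sin(theta) * dx + np.cos(theta) * dy
            elif label in ("sitting down", "standing up"):
                onset = int(rng.integers(5, max(F // 10, 6)))
                dur = max(F // 6, 30)
                critical = (onset, min(onset + dur, F - 1))
                ramp = _smoothstep(t, critical[0], critical[1])
                drop = ramp if label == "sitting down" else 1.0 - ramp
                for name in ("head", "torso", "pelvis", "left_arm", "right_arm"):
                    for m in _GROUPS[name]:
                        pos[m, 2, :] -= 0.45 * drop
                for name in ("left_leg", "right_leg"):
                    for m in _GROUPS[name]:
                        pos[m, 0, :] += 0.20 * drop  # knees travel forward when seated
                # seated phase suppresses stride oscillation
                damp = 1.0 - 0.9 * drop
                gait_part = _gait_motion(F, phase)
                pos -= gait_part * (1.0 - damp)[None, None, :]

            pos += rng.normal(0.0, noise_sd, pos.shape)
            samples.append(MovementSample(positions=pos, label=label, critical_area=critical))
    return samples
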