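"""Turn raw x-y cursor trajectories into the normalized angle series the model consumes.

A mouse-tracking trial records the cursor path from a start button at the
bottom-center of the screen toward one of two response labels in the top
corners.  The model does not work on raw pixels: each trajectory is (i)
rescaled to the rectangle [-1, 1] x [0, 1] with the start at the origin,
(ii) time-normalized to a common number of steps by linear interpolation
over the sample index, and (iii) projected to movement angles in [0, pi]
via the four-quadrant inverse tangent, so that the top-left (distractor)
label sits near 3*pi/4 and the top-right (target) label near pi/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "RawTrajectory",
    "NormalizedTrajectory",
    "AngleDataset",
    "rescale_trajectory",
    "time_normalize",
    "to_angles",
    "assemble_dataset",
    "read_trajectories",
    "write_angles",
    "read_angles",
    "START_ANGLE",
]

#: Angle assigned to the degenerate start sample (0, 0): pi/2, i.e. straight
#: up, equidistant from both response labels (no directional commitment).
START_ANGLE = np.pi / 2.0


class DegenerateTrajectoryError(ValueError):
    """Raised for trajectories with fewer than two samples."""


class GeometryError(ValueError):
    """Raised for screen geometries with zero extent."""


class AssemblyError(ValueError):
    """Raised when the subject x trial grid of angle series is incomplete."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Start-button position and screen extent, in screen units.

    ``start_x, start_y`` locate the start button (bottom-center of the
    screen in the standard layout); ``width`` is the full horizontal
    extent and ``height`` the vertical extent from the start button to the
    top of the screen.  The vertical axis is assumed to increase upward;
    flip pixel coordinates before constructing trajectories if needed.
    """

    start_x: float
    start_y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError(
                f"screen extent must be positive, got width={self.width}, "
                f"height={self.height}"
            )


@dataclass(frozen=True)
class RawTrajectory:
    """One trial's ordered cursor samples, in screen or rescaled units."""

    subject_id: str
    trial_id: str
    samples: np.ndarray  # (M, 2) float array of (x, y) pairs

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2 or samples.shape[1] != 2:
            raise ValueError("samples must be an (M, 2) array of (x, y) pairs")
        if samples.shape[0] < 2:
            raise DegenerateTrajectoryError(
                f"trajectory ({self.subject_id}, {self.trial_id}) has "
                f"{samples.shape[0]} sample(s); at least 2 required"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError(
                f"trajectory ({self.subject_id}, {self.trial_id}) contains "
                "non-finite coordinates"
            )


@dataclass(frozen=True)
class NormalizedTrajectory:
    """A trajectory on the common [-1, 1] x [0, 1] plane with N+1 steps."""

    subject_id: str
    trial_id: str
    coords: np.ndarray  # (N+1, 2)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
            raise ValueError("coords must be an (N+1, 2) array with N >= 1")
        if not np.allclose(coords[0], 0.0):
            raise ValueError("first normalized pair must be (0, 0)")

    @property
    def n_steps(self) -> int:
        return self.coords.shape[0] - 1


@dataclass(frozen=True)
class AngleDataset:
    """Dense I x J x (N+1) array of movement angles, in radians.

    This is the model's native input: ``angles[i, j, n]`` is the movement
    angle of subject ``i`` on trial ``j`` at normalized time step ``n``.
    Preprocessed trajectories always fold into [0, pi]; angles anywhere on
    the circle [-pi, pi] are accepted so that exact-model simulations
    (no fold) can flow through the same container.
    """

    angles: np.ndarray
    subject_ids: tuple = field(default=None)
    trial_ids: tuple = field(default=None)

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if angles.ndim != 3:
            raise ValueError("angles must be an I x J x (N+1) array")
        if not np.all(np.isfinite(angles)):
            raise ValueError("angles contain non-finite values")
        if angles.size and (angles.min() < -np.pi - 1e-12 or angles.max() > np.pi + 1e-12):
            raise ValueError("angles must lie in [-pi, pi]")
        I, J, _ = angles.shape
        sids = self.subject_ids or tuple(f"s{i + 1}" for i in range(I))
        tids = self.trial_ids or tuple(f"t{j + 1}" for j in range(J))
        if len(sids) != I or len(tids) != J:
            raise ValueError("subject_ids/trial_ids lengths do not match angles")
        object.__setattr__(self, "subject_ids", tuple(sids))
        object.__setattr__(self, "trial_ids", tuple(tids))

    @property
    def n_subjects(self) -> int:
        return self.angles.shape[0]

    @property
    def n_trials(self) -> int:
        return self.angles.shape[1]

    @property
    def n_steps(self) -> int:
        return self.angles.shape[2] - 1


def rescale_trajectory(raw: RawTrajectory, screen_geometry: ScreenGeometry) -> RawTrajectory:
    """Translate and scale a raw trajectory onto the [-1, 1] x [0, 1] plane.

    The first sample maps to (0, 0); half the screen width maps to one
    horizontal unit (so the top corners sit at x = +/-1) and the full
    height to one vertical unit.  Ordering is preserved; samples that
    stray outside the nominal rectangle (overshoot, small downward
    excursions) are kept as-is and handled downstream by the angle fold.
    """
    samples = raw.samples
    origin = samples[0]
    scale = np.array([screen_geometry.width / 2.0, screen_geometry.height])
    rescaled = (samples - origin) / scale
    return RawTrajectory(raw.subject_id, raw.trial_id, rescaled)


def time_normalize(traj: RawTrajectory, n_steps: int = 101) -> NormalizedTrajectory:
    """Resample a rescaled trajectory to ``n_steps`` equally spaced points.

    The common scale is the cumulative sample index from 0% to 100% (equal
    spacing between recorded coordinate pairs, the Mouse Tracker
    convention); each output point is a linear interpolation between the
    bracketing raw samples and the endpoints are preserved exactly.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    samples = traj.coords if isinstance(traj, NormalizedTrajectory) else traj.samples
    m = samples.shape[0]
    grid = np.linspace(0.0, m - 1.0, n_steps)
    idx = np.arange(m, dtype=float)
    coords = np.column_stack(
        [np.interp(grid, idx, samples[:, 0]), np.interp(grid, idx, samples[:, 1])]
    )
    # exact endpoint preservation against interp rounding
    coords[0] = samples[0]
    coords[-1] = samples[-1]
    return NormalizedTrajectory(traj.subject_id, traj.trial_id, coords)


def to_angles(traj: NormalizedTrajectory) -> np.ndarray:
    """Project a normalized trajectory to movement angles in [0, pi].

    angle_n = |atan2(y_n, x_n)|: the four-quadrant inverse tangent folded
    into the upper half-plane by absolute value, so small downward
    excursions (y < 0) reflect upward while left/right (distractor vs.
    target) information is preserved.  Degenerate pairs at the origin —
    including the start sample — get the neutral angle pi/2.
    """
    coords = traj.coords
    angles = np.abs(np.arctan2(coords[:, 1], coords[:, 0]))
    degenerate = np.all(coords == 0.0, axis=1)
    angles[degenerate] = START_ANGLE
    return angles


def assemble_dataset(
    angle_map: Mapping[tuple, np.ndarray],
    subject_ids: Sequence,
    trial_ids: Sequence,
) -> AngleDataset:
    """Assemble per-(subject, trial) angle sequences into a dense dataset.

    ``angle_map`` maps (subject_id, trial_id) to a length-(N+1) angle
    sequence.  Every cell of the subject x trial grid must be present and
    all sequences must share a common length.
    """
    subject_ids = tuple(subject_ids)
    trial_ids = tuple(trial_ids)
    missing = [
        (s, t) for s in subject_ids for t in trial_ids if (s, t) not in angle_map
    ]
    if missing:
        raise AssemblyError(f"missing (subject, trial) cells: {missing}")
    lengths = {len(np.atleast_1d(v)) for v in angle_map.values()}
    if len(lengths) != 1:
        raise AssemblyError(f"angle sequences have differing lengths: {sorted(lengths)}")
    (n,) = lengths
    arr = np.empty((len(subject_ids), len(trial_ids), n))
    for i, s in enumerate(subject_ids):
        for j, t in enumerate(trial_ids):
            arr[i, j] = np.asarray(angle_map[(s, t)], dtype=float)
    return AngleDataset(arr, subject_ids, trial_ids)


def read_trajectories(path) -> list[RawTrajectory]:
    """Read a `subject,trial,sample,x,y` delimited text file (header required)."""
    df = pd.read_csv(path)
    required = {"subject", "trial", "sample", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file must have columns {sorted(required)}")
    out = []
    for (s, t), g in df.groupby(["subject", "trial"], sort=False):
        g = g.sort_values("sample")
        out.append(RawTrajectory(str(s), str(t), g[["x", "y"]].to_numpy(float)))
    return out


def write_angles(ds: AngleDataset, path) -> None:
    """Write an angle dataset as `subject,trial,step,angle_rad` delimited text."""
    I, J, n = ds.angles.shape
    sub = np.repeat(ds.subject_ids, J * n)
    tri = np.tile(np.repeat(ds.trial_ids, n), I)
    step = np.tile(np.arange(n), I * J)
    pd.DataFrame(
        {"subject": sub, "trial": tri, "step": step, "angle_rad": ds.angles.ravel()}
    ).to_csv(path, index=False)


def read_angles(path) -> AngleDataset:
    """Read an angle dataset written by :func:`write_angles`."""
    df = pd.read_csv(path)
    subjects = list(dict.fromkeys(df["subject"].astype(str)))
    trials = list(dict.fromkeys(df["trial"].astype(str)))
    amap = {
        (str(s), str(t)): g.sort_values("step")["angle_rad"].to_numpy(float)
        for (s, t), g in df.groupby(["subject", "trial"], sort=False)
    }
    return assemble_dataset(amap, subjects, trials)


def trajectories_to_dataset(
    trajectories: Iterable[RawTrajectory],
    screen_geometry: ScreenGeometry,
    n_steps: int = 101,
) -> AngleDataset:
    """Full preprocessing pipeline: rescale, time-normalize, project, assemble."""
    amap: dict[tuple, np.ndarray] = {}
    subjects: list = []
    trials: list = []
    for raw in trajectories:
        norm = time_normalize(rescale_trajectory(raw, screen_geometry), n_steps)
        amap[(raw.subject_id, raw.trial_id)] = to_angles(norm)
        if raw.subject_id not in subjects:
            subjects.append(raw.subject_id)
        if raw.trial_id not in trials:
            trials.append(raw.trial_id)
    return assemble_dataset(amap, subjects, trials)
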