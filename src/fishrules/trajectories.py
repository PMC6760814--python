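"""Reading, cleaning and differentiating multi-individual trajectories.

Trajectories are dense arrays of shape ``[T frames x N individuals x 2]``
(x, y per individual per frame), the layout produced by modern multi-animal
trackers such as idtracker.ai.  All downstream computation works in body
lengths (BL): :func:`normalize_and_mask` translates the arena centre to the
origin and rescales positions by the body length, after which speeds are in
BL/s and the arena radius is expressed in BL.

Every derived quantity is *causal*: smoothing and differentiation use only
the current and past frames, so a value at frame ``t`` can never leak
information about the future the models are asked to predict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrajectorySet",
    "KinematicsSet",
    "SplitIndex",
    "load_trajectories",
    "save_trajectories",
    "interpolate_gaps",
    "normalize_and_mask",
    "smooth_causal",
    "differentiate",
    "shuffle_shift",
    "shuffle_offsets",
    "circular_shift_stats",
    "split",
]

log = logging.getLogger(__name__)


@dataclass
class TrajectorySet:
    """Per-frame positions for all individuals plus recording metadata.

    Parameters
    ----------
    positions : ndarray, shape (T, N, 2)
        x, y position of each individual at each frame.  Entries where
        ``missing_mask`` is True are ignored (and may be NaN).
    fps : float
        Frame rate of the recording (frames per second).
    body_length : float
        Length of one body in the units of ``positions`` (pixels for video
        data; 1.0 once normalized or for simulator output already in BL).
    arena_center : ndarray, shape (2,)
        Centre of the circular arena, same units as ``positions``.
    arena_radius : float
        Arena radius, same units as ``positions``.
    missing_mask : ndarray of bool, shape (T, N)
        True where the individual was not tracked at that frame.
    """

    positions: np.ndarray
    fps: float = 32.0
    body_length: float = 1.0
    arena_center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    arena_radius: float = 1.0
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError(
                f"positions must have shape [T x N x 2], got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise ValueError("need at least T >= 2 frames")
        if self.positions.shape[1] < 1:
            raise ValueError("need at least N >= 1 individuals")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not self.arena_radius > 0:
            raise ValueError("arena_radius must be positive")
        if not self.body_length > 0:
            raise ValueError("body_length must be positive")
        self.arena_center = np.asarray(self.arena_center, dtype=float).reshape(2)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.positions).all(axis=2)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.positions.shape[:2]:
                raise ValueError("missing_mask must have shape [T x N]")
        if not np.isfinite(self.positions[~self.missing_mask]).all():
            raise ValueError("positions must be finite wherever not missing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]

    def copy(self) -> "TrajectorySet":
        return replace(
            self,
            positions=self.positions.copy(),
            arena_center=self.arena_center.copy(),
            missing_mask=self.missing_mask.copy(),
        )


@dataclass
class KinematicsSet:
    """Causal velocities and accelerations derived from a TrajectorySet.

    ``velocity[t]`` and ``acceleration[t]`` depend only on positions at
    frames <= t (backward finite differences); ``valid_mask`` is False for
    the first two frames and wherever the differences touch missing data.
    """

    positions: np.ndarray  # (T, N, 2), BL
    velocity: np.ndarray  # (T, N, 2), BL/s
    acceleration: np.ndarray  # (T, N, 2), BL/s^2
    speed: np.ndarray  # (T, N), BL/s
    valid_mask: np.ndarray  # (T, N) bool
    fps: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[1]


@dataclass
class SplitIndex:
    """Disjoint contiguous frame ranges for train/validation/test.

    ``train`` may consist of up to two contiguous ranges when the
    validation+test block is rotated into the interior of the recording.
    Each range is a half-open ``(start, stop)`` pair.
    """

    train: list[tuple[int, int]]
    validation: tuple[int, int]
    test: tuple[int, int]

    def ranges(self) -> dict[str, list[tuple[int, int]]]:
        return {
            "train": list(self.train),
            "validation": [self.validation],
            "test": [self.test],
        }


# ---------------------------------------------------------------------------
# I/O


_DIALECTS = ("npz", "hdf5", "csv-long")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return "npz"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".csv":
        return "csv-long"
    raise ValueError(
        f"cannot infer dialect from extension {suffix!r}; pass dialect explicitly"
    )


def _read_meta_sidecar(path: Path) -> dict:
    for candidate in (path.with_suffix(".meta.yaml"), Path(str(path) + ".meta.yaml")):
        if candidate.exists():
            with open(candidate) as fh:
                return yaml.safe_load(fh) or {}
    return {}


def load_trajectories(path, dialect: str | None = None, **metadata) -> TrajectorySet:
    """Load a trajectory container (NPZ / HDF5 / long-format CSV).

    NPZ files hold the array under key ``"trajectories"``; HDF5 files under
    dataset ``"/trajectories"``; CSV files are long format with columns
    ``frame, id, x, y`` (frames and ids 0-based).  Metadata (fps,
    body_length, arena_center, arena_radius) is taken from a
    ``<name>.meta.yaml`` sidecar if present, overridden by keyword
    arguments.  Missing points are inferred from NaN (or absent CSV rows).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")

    if dialect == "npz":
        with np.load(path) as data:
            if "trajectories" not in data:
                raise ValueError(f"{path}: NPZ container lacks key 'trajectories'")
            positions = np.asarray(data["trajectories"], dtype=float)
    elif dialect == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            if "trajectories" not in fh:
                raise ValueError(f"{path}: HDF5 container lacks dataset '/trajectories'")
            positions = np.asarray(fh["trajectories"], dtype=float)
            for key in ("fps", "body_length", "arena_radius"):
                if key in fh.attrs and key not in metadata:
                    metadata[key] = float(fh.attrs[key])
            if "arena_center" in fh.attrs and "arena_center" not in metadata:
                metadata["arena_center"] = np.asarray(fh.attrs["arena_center"])
    else:  # csv-long
        frame = pd.read_csv(path)
        if frame.empty or not {"frame", "id", "x", "y"} <= set(frame.columns):
            raise ValueError(
                f"{path}: CSV must be long format with columns frame,id,x,y"
            )
        n_frames = int(frame["frame"].max()) + 1
        n_ind = int(frame["id"].max()) + 1
        positions = np.full((n_frames, n_ind, 2), np.nan)
        positions[frame["frame"].to_numpy(int), frame["id"].to_numpy(int), 0] = (
            frame["x"].to_numpy(float)
        )
        positions[frame["frame"].to_numpy(int), frame["id"].to_numpy(int), 1] = (
            frame["y"].to_numpy(float)
        )

    if positions.ndim != 3 or positions.shape[-1] != 2:
        raise ValueError(
            f"{path}: malformed trajectory array of shape {positions.shape}; "
            "expected [T x N x 2]"
        )
    meta = _read_meta_sidecar(path)
    meta.update(metadata)
    meta.setdefault("arena_radius", _radius_from_positions(positions))
    return TrajectorySet(positions=positions, **meta)


def _radius_from_positions(positions: np.ndarray) -> float:
    finite = positions[np.isfinite(positions).all(axis=2)]
    if finite.size == 0:
        return 1.0
    return float(max(np.linalg.norm(finite, axis=1).max(), 1e-9))


def save_trajectories(ts: TrajectorySet, path, dialect: str | None = None) -> Path:
    """Write a TrajectorySet plus a ``<name>.meta.yaml`` metadata sidecar."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    positions = ts.positions.copy()
    positions[ts.missing_mask] = np.nan
    if dialect == "npz":
        np.savez(path, trajectories=positions)
    elif dialect == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("trajectories", data=positions)
            fh.attrs["fps"] = ts.fps
            fh.attrs["body_length"] = ts.body_length
            fh.attrs["arena_radius"] = ts.arena_radius
            fh.attrs["arena_center"] = ts.arena_center
    elif dialect == "csv-long":
        t_idx, i_idx = np.nonzero(~ts.missing_mask)
        pd.DataFrame(
            {
                "frame": t_idx,
                "id": i_idx,
                "x": positions[t_idx, i_idx, 0],
                "y": positions[t_idx, i_idx, 1],
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = {
        "fps": float(ts.fps),
        "body_length": float(ts.body_length),
        "arena_center": [float(v) for v in ts.arena_center],
        "arena_radius": float(ts.arena_radius),
    }
    with open(path.with_suffix(".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


# ---------------------------------------------------------------------------
# Cleaning and normalization


def interpolate_gaps(ts: TrajectorySet, max_gap: int = 5) -> TrajectorySet:
    """Fill short tracking holes by per-coordinate linear interpolation.

    Runs of missing frames of length <= ``max_gap`` that are bracketed by
    tracked frames are interpolated; longer runs and leading/trailing runs
    are left missing.  The fraction of interpolated points is logged.
    """
    out = ts.copy()
    n_filled = 0
    for i in range(ts.n_individuals):
        missing = ts.missing_mask[:, i]
        if not missing.any():
            continue
        # run-length encode the missing stretches
        edges = np.flatnonzero(np.diff(missing.astype(np.int8)))
        starts = edges[missing[edges + 1]] + 1
        stops = edges[~missing[edges + 1]] + 1  # exclusive
        if missing[0]:
            starts = np.concatenate([[0], starts])
        if missing[-1]:
            stops = np.concatenate([stops, [ts.n_frames]])
        for start, stop in zip(starts, stops):
            length = stop - start
            if start == 0 or stop == ts.n_frames:
                warnings.warn(
                    f"individual {i}: cannot interpolate missing run at the "
                    "recording boundary; left missing",
                    stacklevel=2,
                )
                continue
            if length > max_gap:
                continue
            t = np.arange(start, stop)
            for axis in range(2):
                out.positions[start:stop, i, axis] = np.interp(
                    t,
                    [start - 1, stop],
                    [ts.positions[start - 1, i, axis], ts.positions[stop, i, axis]],
                )
            out.missing_mask[start:stop, i] = False
            n_filled += length
    frac = n_filled / ts.missing_mask.size
    log.info("interpolated %d points (%.4f%% of all points)", n_filled, 100 * frac)
    return out


def normalize_and_mask(
    ts: TrajectorySet, border_fraction: float = 0.8
) -> tuple[TrajectorySet, np.ndarray]:
    """Centre the arena at the origin, rescale to body lengths, mask the border.

    Positions are translated so the arena centre maps to (0, 0) and divided
    by the body length, so all coordinates (and the arena radius) come out
    in BL.  ``border_mask[t, i]`` is True where the individual is further
    from the centre than ``border_fraction`` times the arena radius; such
    points are excluded as *focal* samples downstream but remain available
    as neighbours.  Idempotent on already-normalized data.
    """
    if not ts.arena_radius > 0:
        raise ValueError("arena_radius must be positive")
    out = ts.copy()
    out.positions = (ts.positions - ts.arena_center) / ts.body_length
    out.arena_center = np.zeros(2)
    out.arena_radius = ts.arena_radius / ts.body_length
    out.body_length = 1.0
    dist = np.linalg.norm(np.nan_to_num(out.positions, nan=np.inf), axis=2)
    border_mask = dist > border_fraction * out.arena_radius
    return out, border_mask


def half_gaussian_kernel(kernel_len: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Causal smoothing weights over lags 0..kernel_len-1, normalized to sum 1."""
    k = np.arange(kernel_len, dtype=float)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def smooth_causal(
    ts: TrajectorySet, kernel_len: int = 5, sigma: float = 1.0
) -> TrajectorySet:
    """Smooth each coordinate with a half-Gaussian kernel over past frames only.

    The output at frame ``t`` is a weighted average of frames
    ``t - kernel_len + 1 .. t``; at the start of the recording the kernel is
    truncated and renormalized.  Frames whose window touches a missing point
    stay missing.
    """
    w = half_gaussian_kernel(kernel_len, sigma)
    pos = np.where(ts.missing_mask[..., None], 0.0, ts.positions)
    ok = (~ts.missing_mask).astype(float)
    acc = np.zeros_like(pos)
    norm = np.zeros_like(ok)
    touched_missing = np.zeros_like(ts.missing_mask)
    for k, wk in enumerate(w):
        acc[k:] += wk * pos[: ts.n_frames - k]
        norm[k:] += wk * ok[: ts.n_frames - k]
        touched_missing[k:] |= ts.missing_mask[: ts.n_frames - k]
    out = ts.copy()
    valid = ~touched_missing
    # renormalize: truncation at the start, plus any masked-out weight
    with np.errstate(invalid="ignore", divide="ignore"):
        out.positions = np.where(valid[..., None], acc / norm[..., None], np.nan)
    out.missing_mask = touched_missing
    return out


def differentiate(ts: TrajectorySet) -> KinematicsSet:
    """Backward finite differences: v(t)=(x(t)-x(t-1))*fps, a(t)=(v(t)-v(t-1))*fps."""
    pos = np.where(ts.missing_mask[..., None], np.nan, ts.positions)
    velocity = np.full_like(pos, np.nan)
    velocity[1:] = (pos[1:] - pos[:-1]) * ts.fps
    acceleration = np.full_like(pos, np.nan)
    acceleration[2:] = (velocity[2:] - velocity[1:-1]) * ts.fps
    valid = np.isfinite(acceleration).all(axis=2)
    speed = np.linalg.norm(velocity, axis=2)
    return KinematicsSet(
        positions=pos,
        velocity=velocity,
        acceleration=acceleration,
        speed=speed,
        valid_mask=valid,
        fps=ts.fps,
    )


# ---------------------------------------------------------------------------
# Shuffle control and splitting


def shuffle_offsets(n_frames: int, n_individuals: int) -> np.ndarray:
    """Circular shift applied to individual i: round(i * T / N) frames."""
    if n_individuals > n_frames:
        raise ValueError("need at least as many frames as individuals")
    i = np.arange(n_individuals)
    return np.round(i * n_frames / n_individuals).astype(int)


def circular_shift_stats(
    n_frames: int, n_individuals: int, fps: float = 1.0
) -> tuple[float, float]:
    """(minimum nonzero, mean) circular shift magnitude, in seconds.

    The circular magnitude of a shift ``d`` on a recording of ``T`` frames
    is ``min(d, T - d)``.  For a 10-minute, 100-individual recording this
    gives a minimum nonzero shift of 6 s and a mean shift of 150 s.
    """
    offsets = shuffle_offsets(n_frames, n_individuals)
    mag = np.minimum(offsets, n_frames - offsets)
    nonzero = mag[mag > 0]
    min_shift = float(nonzero.min()) / fps if nonzero.size else 0.0
    return min_shift, float(mag.mean()) / fps


def shuffle_shift(ts: TrajectorySet) -> TrajectorySet:
    """Destroy genuine interactions by circularly time-shifting each individual.

    Individual ``i`` is rolled forward by ``round(i * T / N)`` frames, so
    every pair of individuals ends up relatively shifted by at least ~T/N
    frames while each individual's own kinematic statistics are untouched.
    """
    offsets = shuffle_offsets(ts.n_frames, ts.n_individuals)
    out = ts.copy()
    for i, off in enumerate(offsets):
        out.positions[:, i] = np.roll(ts.positions[:, i], off, axis=0)
        out.missing_mask[:, i] = np.roll(ts.missing_mask[:, i], off, axis=0)
    return out


def split(
    n_frames: int,
    fractions: tuple[float, float, float] = (0.97, 0.02, 0.01),
    rotate: int = 0,
) -> SplitIndex:
    """Contiguous train/validation/test frame ranges.

    ``rotate`` slides the validation+test block to a different contiguous
    region of the recording (0 = at the end), so repeated fits can hold out
    different parts of the recording.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = int(np.floor(fractions[1] * n_frames))
    n_test = int(np.floor(fractions[2] * n_frames))
    n_train = n_frames - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n_frames} frames with fractions {fractions} leaves an "
            "empty part"
        )
    block = n_val + n_test
    n_positions = n_frames // block
    start = (n_positions - 1 - (rotate % n_positions)) * block
    val = (start, start + n_val)
    test = (start + n_val, start + block)
    train = []
    if start > 0:
        train.append((0, start))
    if start + block < n_frames:
        train.append((start + block, n_frames))
    return SplitIndex(train=train, validation=val, test=test)
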