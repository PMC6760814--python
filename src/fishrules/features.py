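"""Focal-frame decision samples: asocial/social variables and turn labels.

Each sample describes one focal individual at one frame: its own kinematics
(the *asocial* vector), the kinematics of its ``n`` nearest neighbours
expressed in the focal's egocentric frame (the *social* vectors), and the
side (left/right) and unsigned angle of the focal's turn after a prediction
horizon.

Egocentric frame convention: origin at the focal, +y along the focal's
velocity, +x to the focal's right.  A body-axis reflection flips the sign
of every x component (and of the relative-heading angle and the normal
acceleration) and swaps the turn label; the turning-decision models are
built to be exactly antisymmetric under this operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectories import KinematicsSet, SplitIndex

__all__ = [
    "ALPHA_CHANNELS",
    "SOCIAL_CHANNELS",
    "WEIGHT_CHANNELS",
    "Sample",
    "SampleSet",
    "DataBundle",
    "Standardizer",
    "focal_frame_transform",
    "focal_frame_inverse",
    "nearest_neighbours",
    "turn_label",
    "reflect",
    "build_dataset",
]

# channel name -> sign under body-axis reflection (-1 flips)
ALPHA_CHANNELS = {"v": +1, "a_perp": -1, "a_par": +1}
SOCIAL_CHANNELS = {"x": -1, "y": +1, "vx": -1, "vy": +1, "v": +1, "theta": -1,
                   "topo": +1}
# weighting-subnetwork channels are reflection-invariant by construction
WEIGHT_CHANNELS = ("v_focal", "v_n", "abs_x", "y", "topo")

DEFAULT_ALPHA = ("v", "a_perp")
DEFAULT_SOCIAL = ("x", "y", "vx", "vy")
DEFAULT_WEIGHT = ("v_focal", "v_n", "abs_x", "y")


def focal_frame_transform(focal_pos, focal_vel, other_pos, other_vel):
    """Express neighbour position/velocity in the focal's egocentric frame.

    Returns ``(x, y, vx, vy)`` with +y along the focal velocity and +x to
    the focal's right.  ``other_*`` may carry leading batch dimensions.
    Raises if the focal speed is zero (frame undefined).
    """
    focal_vel = np.asarray(focal_vel, dtype=float)
    speed = np.linalg.norm(focal_vel)
    if not speed > 0:
        raise ValueError("focal speed is zero; egocentric frame undefined")
    fwd = focal_vel / speed  # +y axis
    right = np.array([fwd[1], -fwd[0]])  # +x axis
    rel = np.asarray(other_pos, dtype=float) - np.asarray(focal_pos, dtype=float)
    vel = np.asarray(other_vel, dtype=float)
    return (
        rel @ right,
        rel @ fwd,
        vel @ right,
        vel @ fwd,
    )


def focal_frame_inverse(focal_pos, focal_vel, x, y, vx, vy):
    """Map egocentric coordinates back to world coordinates (round-trip aid)."""
    focal_vel = np.asarray(focal_vel, dtype=float)
    fwd = focal_vel / np.linalg.norm(focal_vel)
    right = np.array([fwd[1], -fwd[0]])
    pos = np.asarray(focal_pos) + np.multiply.outer(x, right) + np.multiply.outer(y, fwd)
    vel = np.multiply.outer(vx, right) + np.multiply.outer(vy, fwd)
    return pos, vel


def relative_heading(vx, vy):
    """Neighbour heading relative to the focal, in [-pi, pi); 0 = parallel."""
    return np.arctan2(vx, vy)


def nearest_neighbours(positions_t, focal: int, n: int, valid=None) -> np.ndarray:
    """Indices of the n nearest other individuals, by increasing distance.

    Ties are broken by individual index.  ``valid`` optionally marks which
    individuals may serve as neighbours.
    """
    positions_t = np.asarray(positions_t, dtype=float)
    n_ind = positions_t.shape[0]
    dist = np.linalg.norm(positions_t - positions_t[focal], axis=1)
    ok = np.ones(n_ind, dtype=bool) if valid is None else np.asarray(valid, bool).copy()
    ok[focal] = False
    ok &= np.isfinite(dist)
    candidates = np.flatnonzero(ok)
    if candidates.size < n:
        raise ValueError(
            f"only {candidates.size} valid neighbours available, need {n}"
        )
    order = np.lexsort((candidates, dist[candidates]))
    return candidates[order[:n]]


def turn_label(
    kin: KinematicsSet, focal: int, t: int, horizon_frames: int
) -> tuple[str, float]:
    """Side and unsigned angle of the focal's turn after ``horizon_frames``.

    The side is 'right' when the velocity at ``t + horizon`` has a positive
    x component in the egocentric frame at ``t`` (exact zero-angle ties are
    labeled 'right').  The angle is the unsigned angle between the two
    velocities, in degrees.
    """
    t2 = t + horizon_frames
    if t2 >= kin.n_frames:
        raise ValueError("horizon extends past the end of the recording")
    v_now = kin.velocity[t, focal]
    v_fut = kin.velocity[t2, focal]
    s_now = np.linalg.norm(v_now)
    s_fut = np.linalg.norm(v_fut)
    if not (s_now > 0 and s_fut > 0):
        raise ValueError("zero speed at an endpoint; turn undefined")
    cosang = np.clip(np.dot(v_now, v_fut) / (s_now * s_fut), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    cross = v_now[0] * v_fut[1] - v_now[1] * v_fut[0]  # z of v_now x v_fut
    # cross < 0 -> future velocity is clockwise of current -> to the right
    side = "right" if cross <= 0 else "left"
    return side, angle


@dataclass
class Sample:
    """One focal decision instance (convenience view; bulk data lives in arrays)."""

    alpha: np.ndarray  # (A,)
    social: np.ndarray  # (n, D)
    label: str  # 'left' | 'right'
    turn_angle: float  # degrees, [0, 180]
    frame: int
    focal_id: int


@dataclass
class Standardizer:
    """Per-channel location/scale fitted on the training split only.

    Channels that flip sign under body-axis reflection are standardized by
    scale only (no centring), so reflection commutes exactly with
    standardization.
    """

    alpha_names: tuple[str, ...]
    social_names: tuple[str, ...]
    weight_names: tuple[str, ...]
    alpha_mean: np.ndarray = None
    alpha_scale: np.ndarray = None
    social_mean: np.ndarray = None
    social_scale: np.ndarray = None
    weight_mean: np.ndarray = None
    weight_scale: np.ndarray = None

    def fit(self, alpha: np.ndarray, social: np.ndarray, wfeat: np.ndarray) -> "Standardizer":
        def stats(arr, names, signs):
            flat = arr.reshape(-1, arr.shape[-1])
            mean = flat.mean(axis=0)
            scale = flat.std(axis=0)
            scale[scale < 1e-8] = 1.0
            for j, name in enumerate(names):
                if signs.get(name, +1) < 0:
                    mean[j] = 0.0  # keep reflection exact
            return mean, scale

        self.alpha_mean, self.alpha_scale = stats(alpha, self.alpha_names, ALPHA_CHANNELS)
        self.social_mean, self.social_scale = stats(
            social, self.social_names, SOCIAL_CHANNELS
        )
        self.weight_mean, self.weight_scale = stats(wfeat, self.weight_names, {})
        return self

    def transform_alpha(self, alpha):
        return (alpha - self.alpha_mean) / self.alpha_scale

    def transform_social(self, social):
        return (social - self.social_mean) / self.social_scale

    def transform_weight(self, wfeat):
        return (wfeat - self.weight_mean) / self.weight_scale

    @property
    def pi_flip_signs(self) -> np.ndarray:
        """Reflection sign for each column of the pair-subnetwork input."""
        signs = [ALPHA_CHANNELS[n] for n in self.alpha_names]
        signs += [SOCIAL_CHANNELS[n] for n in self.social_names]
        return np.asarray(signs, dtype=np.float32)

    def to_dict(self) -> dict:
        return {
            "alpha_names": list(self.alpha_names),
            "social_names": list(self.social_names),
            "weight_names": list(self.weight_names),
            **{
                k: getattr(self, k).tolist()
                for k in (
                    "alpha_mean",
                    "alpha_scale",
                    "social_mean",
                    "social_scale",
                    "weight_mean",
                    "weight_scale",
                )
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        obj = cls(
            tuple(d["alpha_names"]), tuple(d["social_names"]), tuple(d["weight_names"])
        )
        for k in (
            "alpha_mean",
            "alpha_scale",
            "social_mean",
            "social_scale",
            "weight_mean",
            "weight_scale",
        ):
            setattr(obj, k, np.asarray(d[k], dtype=float))
        return obj


@dataclass
class SampleSet:
    """Column-oriented collection of focal decision samples (raw units)."""

    alpha: np.ndarray  # (S, A)
    social: np.ndarray  # (S, n, D)
    wfeat: np.ndarray  # (S, n, Dw)
    label: np.ndarray  # (S,) int8, 1 = right
    turn_angle: np.ndarray  # (S,) degrees
    frame: np.ndarray  # (S,)
    focal_id: np.ndarray  # (S,)
    alpha_names: tuple[str, ...] = DEFAULT_ALPHA
    social_names: tuple[str, ...] = DEFAULT_SOCIAL
    weight_names: tuple[str, ...] = DEFAULT_WEIGHT

    def __len__(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_neighbours(self) -> int:
        return self.social.shape[1]

    def subset(self, idx) -> "SampleSet":
        return replace(
            self,
            alpha=self.alpha[idx],
            social=self.social[idx],
            wfeat=self.wfeat[idx],
            label=self.label[idx],
            turn_angle=self.turn_angle[idx],
            frame=self.frame[idx],
            focal_id=self.focal_id[idx],
        )

    def pi_features(self, standardizer: Standardizer) -> np.ndarray:
        """Standardized pair-subnetwork input, shape (S, n, A + D)."""
        a = standardizer.transform_alpha(self.alpha)
        s = standardizer.transform_social(self.social)
        a_tiled = np.broadcast_to(a[:, None, :], (len(self), self.n_neighbours, a.shape[1]))
        return np.concatenate([a_tiled, s], axis=2).astype(np.float32)

    def w_features(self, standardizer: Standardizer) -> np.ndarray:
        return standardizer.transform_weight(self.wfeat).astype(np.float32)

    def sample(self, i: int) -> Sample:
        return Sample(
            alpha=self.alpha[i],
            social=self.social[i],
            label="right" if self.label[i] else "left",
            turn_angle=float(self.turn_angle[i]),
            frame=int(self.frame[i]),
            focal_id=int(self.focal_id[i]),
        )

    @staticmethod
    def concatenate(sets: list["SampleSet"]) -> "SampleSet":
        first = sets[0]
        for other in sets[1:]:
            if (
                other.alpha_names != first.alpha_names
                or other.social_names != first.social_names
                or other.weight_names != first.weight_names
            ):
                raise ValueError("cannot concatenate sample sets with different channels")
        return replace(
            first,
            alpha=np.concatenate([s.alpha for s in sets]),
            social=np.concatenate([s.social for s in sets]),
            wfeat=np.concatenate([s.wfeat for s in sets]),
            label=np.concatenate([s.label for s in sets]),
            turn_angle=np.concatenate([s.turn_angle for s in sets]),
            frame=np.concatenate([s.frame for s in sets]),
            focal_id=np.concatenate([s.focal_id for s in sets]),
        )


def reflect(samples: SampleSet) -> SampleSet:
    """Body-axis reflection of every sample: x components flip, labels swap.

    An involution: ``reflect(reflect(s))`` returns the original data.
    Speeds, y components and neighbour distances are unchanged.
    """
    out = replace(
        samples,
        alpha=samples.alpha.copy(),
        social=samples.social.copy(),
        wfeat=samples.wfeat.copy(),
        label=(1 - samples.label).astype(samples.label.dtype),
        turn_angle=samples.turn_angle.copy(),
        frame=samples.frame.copy(),
        focal_id=samples.focal_id.copy(),
    )
    for j, name in enumerate(samples.alpha_names):
        out.alpha[:, j] *= ALPHA_CHANNELS[name]
    for j, name in enumerate(samples.social_names):
        out.social[:, :, j] *= SOCIAL_CHANNELS[name]
    return out


@dataclass
class DataBundle:
    """Train/validation/test SampleSets plus the train-fitted standardizer."""

    train: SampleSet
    validation: SampleSet
    test: SampleSet
    standardizer: Standardizer
    meta: dict = field(default_factory=dict)

    def sets(self) -> dict[str, SampleSet]:
        return {"train": self.train, "validation": self.validation, "test": self.test}


def _social_matrix(names, x, y, vx, vy, topo):
    cols = {
        "x": x,
        "y": y,
        "vx": vx,
        "vy": vy,
        "v": np.hypot(vx, vy),
        "theta": relative_heading(vx, vy),
        "topo": topo,
    }
    return np.stack([cols[n] for n in names], axis=-1)


def _weight_matrix(names, v_focal, x, y, vx, vy, topo):
    cols = {
        "v_focal": np.broadcast_to(v_focal[:, None], x.shape),
        "v_n": np.hypot(vx, vy),
        "abs_x": np.abs(x),
        "y": y,
        "topo": topo,
    }
    return np.stack([cols[n] for n in names], axis=-1)


def build_dataset(
    kin: KinematicsSet,
    split_index: SplitIndex,
    n_neighbours: int = 25,
    horizon: int = 32,
    border_mask: np.ndarray | None = None,
    alpha_vars: tuple[str, ...] = DEFAULT_ALPHA,
    social_vars: tuple[str, ...] = DEFAULT_SOCIAL,
    weight_vars: tuple[str, ...] = DEFAULT_WEIGHT,
    include_topo: bool = False,
    frame_stride: int = 1,
    min_turn_angle: float = 0.0,
) -> DataBundle:
    """Build egocentric decision samples for every valid (focal, frame).

    A focal contributes a sample at frame ``t`` when its kinematics are
    valid at ``t`` and ``t + horizon``, its speed is positive at both, it is
    not border-masked at ``t``, and at least ``n_neighbours`` other
    individuals have valid kinematics at ``t``.  Neighbours are ordered by
    increasing distance (ties by index).  ``include_topo`` appends each
    neighbour's 1-based distance rank to both the social and weighting
    variables.  Standardization statistics are fitted on the training split
    only.

    ``min_turn_angle`` (degrees) drops samples whose turn is at or below
    the threshold; used with noise-free synthetic trajectories to remove
    exact zero-turn ties (no update event within the horizon), which carry
    no decision signal.
    """
    # the topological index feeds the pair subnetwork; the weighting
    # subnetwork keeps its reflection-invariant default set (pass 'topo' in
    # weight_vars explicitly to let the aggregation see the rank as well)
    if include_topo and "topo" not in social_vars:
        social_vars = tuple(social_vars) + ("topo",)
    n_ind = kin.n_individuals
    if n_ind - 1 < n_neighbours:
        raise ValueError(
            f"{n_ind} individuals cannot supply {n_neighbours} neighbours"
        )
    if border_mask is None:
        border_mask = np.zeros(kin.valid_mask.shape, dtype=bool)

    speed_ok = np.nan_to_num(kin.speed) > 0
    focal_ok = kin.valid_mask & speed_ok & ~border_mask
    # the label needs a well-defined heading at t + horizon
    future_ok = np.zeros_like(focal_ok)
    future_ok[: kin.n_frames - horizon] = (
        kin.valid_mask[horizon:] & speed_ok[horizon:]
    )
    neighbour_ok = kin.valid_mask  # border-masked individuals stay usable here

    parts: dict[str, list] = {"train": [], "validation": [], "test": []}
    for part, ranges in split_index.ranges().items():
        rows = {k: [] for k in ("alpha", "x", "y", "vx", "vy", "label",
                                "angle", "frame", "focal")}
        for start, stop in ranges:
            stop = min(stop, kin.n_frames - horizon)
            for t in range(start, stop, frame_stride):
                cand = np.flatnonzero(neighbour_ok[t])
                if cand.size < n_neighbours + 1:
                    continue
                focals = np.flatnonzero(focal_ok[t] & future_ok[t])
                if focals.size == 0:
                    continue
                pos_t = kin.positions[t]
                vel_t = kin.velocity[t]
                for f in focals:
                    others = cand[cand != f]
                    if others.size < n_neighbours:
                        continue
                    rel = pos_t[others] - pos_t[f]
                    dist = np.linalg.norm(rel, axis=1)
                    order = np.lexsort((others, dist))[:n_neighbours]
                    nb = others[order]
                    fwd = vel_t[f] / kin.speed[t, f]
                    right = np.array([fwd[1], -fwd[0]])
                    rel_nb = rel[order]
                    vel_nb = vel_t[nb]
                    rows["x"].append(rel_nb @ right)
                    rows["y"].append(rel_nb @ fwd)
                    rows["vx"].append(vel_nb @ right)
                    rows["vy"].append(vel_nb @ fwd)
                    acc = kin.acceleration[t, f]
                    alpha_cols = {
                        "v": kin.speed[t, f],
                        "a_perp": acc @ right,
                        "a_par": acc @ fwd,
                    }
                    rows["alpha"].append([alpha_cols[n] for n in alpha_vars])
                    v_fut = kin.velocity[t + horizon, f]
                    cosang = np.clip(
                        np.dot(fwd, v_fut) / np.linalg.norm(v_fut), -1.0, 1.0
                    )
                    angle = np.degrees(np.arccos(cosang))
                    if min_turn_angle > 0 and angle <= min_turn_angle:
                        for key in ("x", "y", "vx", "vy", "alpha"):
                            rows[key].pop()
                        continue
                    rows["angle"].append(angle)
                    rows["label"].append(1 if v_fut @ right >= 0 else 0)
                    rows["frame"].append(t)
                    rows["focal"].append(f)
        if rows["alpha"]:
            x = np.asarray(rows["x"])
            y = np.asarray(rows["y"])
            vx = np.asarray(rows["vx"])
            vy = np.asarray(rows["vy"])
            topo = np.broadcast_to(
                np.arange(1, n_neighbours + 1, dtype=float), x.shape
            )
            alpha = np.asarray(rows["alpha"], dtype=float)
            v_focal = alpha[:, list(alpha_vars).index("v")] if "v" in alpha_vars else (
                np.linalg.norm(kin.velocity[rows["frame"], rows["focal"]], axis=1)
            )
            parts[part].append(
                SampleSet(
                    alpha=alpha,
                    social=_social_matrix(social_vars, x, y, vx, vy, topo),
                    wfeat=_weight_matrix(weight_vars, v_focal, x, y, vx, vy, topo),
                    label=np.asarray(rows["label"], dtype=np.int8),
                    turn_angle=np.asarray(rows["angle"], dtype=float),
                    frame=np.asarray(rows["frame"], dtype=np.int64),
                    focal_id=np.asarray(rows["focal"], dtype=np.int64),
                    alpha_names=tuple(alpha_vars),
                    social_names=tuple(social_vars),
                    weight_names=tuple(weight_vars),
                )
            )

    empty = [p for p, lst in parts.items() if not lst]
    if empty:
        raise ValueError(f"no samples in split part(s): {', '.join(empty)}")
    sets = {p: SampleSet.concatenate(lst) for p, lst in parts.items()}
    standardizer = Standardizer(
        tuple(alpha_vars), tuple(social_vars), tuple(weight_vars)
    ).fit(sets["train"].alpha, sets["train"].social, sets["train"].wfeat)
    return DataBundle(
        train=sets["train"],
        validation=sets["validation"],
        test=sets["test"],
        standardizer=standardizer,
        meta={
            "n_neighbours": n_neighbours,
            "horizon": horizon,
            "frame_stride": frame_stride,
            "alpha_vars": tuple(alpha_vars),
            "social_vars": tuple(social_vars),
            "weight_vars": tuple(weight_vars),
            "fps": kin.fps,
        },
    )
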