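"""Zonal (repulsion / orientation / attraction) agent-based simulator.

Agents move at constant speed in a circular arena and, on stochastic update
events, steer toward a desired direction determined by Couzin-style zonal
rules: neighbours inside the repulsion zone override everything (the agent
turns directly away from them); otherwise the agent aligns with
orientation-zone neighbours and moves toward attraction-zone neighbours.
Zones are annular regions in the agent's egocentric frame and can be
displaced forward, squashed into ellipses, or clipped by a rear blind
angle; an optional topological cap restricts interactions to the nearest
``k`` visible neighbours regardless of distance.

Because the rules are known, the simulator also records, per frame and per
agent, the *true* number of interacting neighbours (the repulsion-zone
occupancy when that zone is occupied, the orientation+attraction occupancy
otherwise) — the ground truth against which the attention model's
effective-neighbour estimates are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectories import TrajectorySet

__all__ = [
    "Zone",
    "ZonalConfig",
    "GroundTruthCounts",
    "SimState",
    "PRESETS",
    "preset_config",
    "desired_direction",
    "step",
    "simulate",
]


@dataclass(frozen=True)
class Zone:
    """Annular region in the agent frame (+y forward).

    Membership: with the relative position (x, y) in the agent frame, the
    elliptical radius is ``rho = hypot(x / axis_ratio, y - offset)`` and the
    neighbour is inside when ``r_inner <= rho < r_outer``.
    """

    r_inner: float
    r_outer: float
    offset: float = 0.0  # forward displacement of the zone centre, BL
    axis_ratio: float = 1.0  # lateral (x) semi-axis relative to the y semi-axis

    def __post_init__(self) -> None:
        if self.r_inner < 0 or self.r_outer < self.r_inner:
            raise ValueError("zone radii must satisfy 0 <= r_inner <= r_outer")
        if self.axis_ratio <= 0:
            raise ValueError("axis_ratio must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        rho = np.hypot(x / self.axis_ratio, y - self.offset)
        return (rho >= self.r_inner) & (rho < self.r_outer)


@dataclass
class ZonalConfig:
    """Simulation parameters; defaults match the published simulation setup.

    50 agents at a constant 3 BL/s in a circular arena of radius 25 BL,
    updating direction with probability 1/3 per 1/32 s step, turning at
    most ``turning_rate`` per update plus Gaussian heading noise.
    """

    n_agents: int = 50
    speed: float = 3.0  # BL/s
    dt: float = 1.0 / 32.0  # s
    p_keep: float = 2.0 / 3.0  # probability of not updating direction
    turning_rate: float = 0.2  # rad per update event
    noise_sd: float = 0.2  # rad, heading noise on update events
    arena_radius: float = 25.0  # BL
    repulsion: Zone = field(default_factory=lambda: Zone(0.0, 2.0))
    orientation: Zone = field(default_factory=lambda: Zone(2.0, 6.0))
    attraction: Zone = field(default_factory=lambda: Zone(6.0, 10.0))
    blind_half_angle: float = 0.0  # rad, rear cone half-width (0 = no blind zone)
    topological_cap: int | None = None  # max neighbours considered, None = all
    noise_mode: str = "desired"  # 'desired': error rotates the target direction
    #                              before the rate-limited turn; 'heading':
    #                              additive heading noise after the turn

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_keep <= 1.0:
            raise ValueError("p_keep must lie in [0, 1]")
        if self.dt <= 0 or self.speed <= 0 or self.arena_radius <= 0:
            raise ValueError("dt, speed and arena_radius must be positive")
        if self.noise_mode not in ("desired", "heading"):
            raise ValueError("noise_mode must be 'desired' or 'heading'")

    @property
    def fps(self) -> float:
        return 1.0 / self.dt


# Geometry variants exercised in the ground-truth recovery experiments.
PRESETS: dict[str, dict] = {
    "circular": {},
    "large-repulsion": {
        "repulsion": Zone(0.0, 3.0),
        "orientation": Zone(3.0, 6.0),
    },
    "displaced": {"orientation": Zone(2.0, 6.0, offset=2.0)},
    "elliptical": {"orientation": Zone(2.0, 6.0, axis_ratio=1.6)},
    "blind-angle": {"blind_half_angle": np.pi / 4},
}


def preset_config(name: str, **overrides) -> ZonalConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return ZonalConfig(**{**PRESETS[name], **overrides})


@dataclass
class SimState:
    positions: np.ndarray  # (N, 2) BL
    headings: np.ndarray  # (N,) rad, velocity = speed * (cos h, sin h)

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.headings.copy())


@dataclass
class GroundTruthCounts:
    """Per (frame, agent) true interacting-neighbour bookkeeping."""

    counts: np.ndarray  # (T, N) int
    repulsion_active: np.ndarray  # (T, N) bool


def _neighbour_sets(state: SimState, config: ZonalConfig):
    """Zone membership masks (N, N) after blind-angle and topological filters."""
    n = config.n_agents
    rel = state.positions[None, :, :] - state.positions[:, None, :]  # i -> j
    dist = np.linalg.norm(rel, axis=2)
    np.fill_diagonal(dist, np.inf)

    cos_h = np.cos(state.headings)
    sin_h = np.sin(state.headings)
    # agent frame of i: +y forward, +x right
    x = rel[..., 0] * sin_h[:, None] - rel[..., 1] * cos_h[:, None]
    y = rel[..., 0] * cos_h[:, None] + rel[..., 1] * sin_h[:, None]

    visible = ~np.eye(n, dtype=bool)
    if config.blind_half_angle > 0:
        # rear bearing: angle from the backward direction
        bearing = np.arctan2(x, y)  # 0 = dead ahead, +/-pi = behind
        visible &= np.abs(bearing) < (np.pi - config.blind_half_angle)

    if config.topological_cap is not None and config.topological_cap < n - 1:
        d = np.where(visible, dist, np.inf)
        order = np.argsort(d, axis=1, kind="stable")[:, : config.topological_cap]
        capped = np.zeros_like(visible)
        rows = np.repeat(np.arange(n), config.topological_cap)
        capped[rows, order.ravel()] = True
        visible &= capped

    rep = visible & config.repulsion.contains(x, y)
    ori = visible & config.orientation.contains(x, y)
    att = visible & config.attraction.contains(x, y)
    return rel, dist, rep, ori, att


def desired_direction(state: SimState, config: ZonalConfig):
    """Zonal-rule steering for every agent.

    Returns unit desired-direction vectors (falling back to the current
    heading when no neighbour is in any zone or the rule sum cancels), the
    true interacting-neighbour count, and the repulsion-override flag.
    """
    rel, dist, rep, ori, att = _neighbour_sets(state, config)
    with np.errstate(invalid="ignore"):
        rhat = rel / dist[..., None]
    rhat = np.nan_to_num(rhat)

    heading_vec = np.stack(
        [np.cos(state.headings), np.sin(state.headings)], axis=1
    )
    rep_any = rep.any(axis=1)
    d_rep = -(rhat * rep[..., None]).sum(axis=1)
    d_soc = (heading_vec[None, :, :] * ori[..., None]).sum(axis=1) + (
        rhat * att[..., None]
    ).sum(axis=1)

    desired = np.where(rep_any[:, None], d_rep, d_soc)
    norm = np.linalg.norm(desired, axis=1)
    fallback = norm < 1e-12
    desired = np.where(
        fallback[:, None], heading_vec, desired / np.where(fallback, 1.0, norm)[:, None]
    )

    counts = np.where(rep_any, rep.sum(axis=1), (ori | att).sum(axis=1))
    return desired, counts.astype(np.int32), rep_any


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def step(
    state: SimState, config: ZonalConfig, rng: np.random.Generator
) -> tuple[SimState, np.ndarray, np.ndarray]:
    """Advance one time step; returns (new state, true counts, repulsion flags).

    Counts describe the state *entering* the step.  Each agent keeps its
    heading with probability ``p_keep``; otherwise it turns toward the
    zonal desired direction by at most ``turning_rate``, with the Gaussian
    "error" applied as a rotation of the desired direction before the
    rate-limited turn (``noise_mode='desired'``, the zonal-model reference
    behaviour) or as additive heading noise after it
    (``noise_mode='heading'``).  At the arena border the radial velocity
    component is reversed.
    """
    desired, counts, rep_any = desired_direction(state, config)
    n = config.n_agents
    update = rng.random(n) >= config.p_keep
    noise = rng.normal(0.0, config.noise_sd, size=n)

    headings = state.headings.copy()
    want = np.arctan2(desired[:, 1], desired[:, 0])
    if config.noise_mode == "desired":
        delta = _wrap_angle(want + noise - headings)
        delta = np.clip(delta, -config.turning_rate, config.turning_rate)
        headings[update] = headings[update] + delta[update]
    else:
        delta = _wrap_angle(want - headings)
        delta = np.clip(delta, -config.turning_rate, config.turning_rate)
        headings[update] = headings[update] + delta[update] + noise[update]
    headings = _wrap_angle(headings)

    vel = config.speed * np.stack([np.cos(headings), np.sin(headings)], axis=1)
    proposed = state.positions + vel * config.dt
    outside = np.linalg.norm(proposed, axis=1) > config.arena_radius
    if outside.any():
        idx = np.flatnonzero(outside)
        p = state.positions[idx]
        r = np.linalg.norm(p, axis=1, keepdims=True)
        radial = np.where(r > 1e-12, p / r, 0.0)
        v = vel[idx]
        v_rad = (v * radial).sum(axis=1, keepdims=True)
        v = v - 2.0 * np.maximum(v_rad, 0.0) * radial  # reverse outward component
        headings[idx] = np.arctan2(v[:, 1], v[:, 0])
        proposed[idx] = p + v * config.dt
        # residual overshoot (tangential motion at the wall): project inside
        rr = np.linalg.norm(proposed[idx], axis=1)
        over = rr > config.arena_radius
        if over.any():
            j = idx[over]
            proposed[j] *= (config.arena_radius / rr[over])[:, None]

    return SimState(proposed, headings), counts, rep_any


def simulate(
    config: ZonalConfig,
    n_frames: int,
    seed: int = 0,
    burn_in: int = 256,
) -> tuple[TrajectorySet, GroundTruthCounts]:
    """Run the zonal model; returns trajectories (BL units) and ground truth.

    Deterministic given ``seed``.  Agents start at uniform random positions
    in the inner half of the arena with random headings; ``burn_in`` steps
    are discarded so the recorded portion starts from developed schooling.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    n = config.n_agents
    r = config.arena_radius * 0.5 * np.sqrt(rng.random(n))
    phi = rng.uniform(-np.pi, np.pi, size=n)
    state = SimState(
        positions=np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1),
        headings=rng.uniform(-np.pi, np.pi, size=n),
    )
    for _ in range(burn_in):
        state, _, _ = step(state, config, rng)

    positions = np.empty((n_frames, n, 2))
    counts = np.empty((n_frames, n), dtype=np.int32)
    rep_flags = np.empty((n_frames, n), dtype=bool)
    for t in range(n_frames):
        positions[t] = state.positions
        state, counts[t], rep_flags[t] = step(state, config, rng)

    ts = TrajectorySet(
        positions=positions,
        fps=config.fps,
        body_length=1.0,
        arena_center=np.zeros(2),
        arena_radius=config.arena_radius,
    )
    return ts, GroundTruthCounts(counts=counts, repulsion_active=rep_flags)
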