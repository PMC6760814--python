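"""Grid evaluation of the pair-interaction logit and its classification.

The trained attention model's pair subnetwork Pi_A is a low-dimensional
function of (focal speed, focal normal acceleration, neighbour position,
neighbour velocity), so it can be understood by evaluating it on grids.
For each spatial cell (x, y) the logit is swept over the neighbour's
relative heading theta; the cell is an *orientation* (alignment or
anti-alignment) region when the logit changes sign with theta, and an
attraction or repulsion region otherwise, judged by the sign of the
theta-averaged logit times sign(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairLogitMap",
    "RegionMap",
    "REGION_CODES",
    "default_grid",
    "pair_logit_map",
    "weight_map",
    "attraction_repulsion_score",
    "alignment_score",
    "classify_regions",
]

REGION_CODES = {
    "alignment": 0,
    "anti-alignment": 1,
    "attraction": 2,
    "repulsion": 3,
}
_CODE_NAMES = {v: k for k, v in REGION_CODES.items()}

# Fig-2-style default spatial grid: 8 x 8 cells at odd BL coordinates.
FIG2_COORDS = np.array([-7.0, -5.0, -3.0, -1.0, 1.0, 3.0, 5.0, 7.0])


def default_grid(
    x=None, y=None, n_theta: int = 64, neighbour_speeds=(1.0, 2.0, 4.0, 8.0)
) -> dict:
    """Grid specification: spatial cells, theta sweep and speed slices."""
    return {
        "x": FIG2_COORDS.copy() if x is None else np.asarray(x, dtype=float),
        "y": FIG2_COORDS.copy() if y is None else np.asarray(y, dtype=float),
        "theta": np.linspace(-np.pi, np.pi, n_theta, endpoint=False),
        "neighbour_speeds": np.asarray(neighbour_speeds, dtype=float),
    }


@dataclass
class PairLogitMap:
    """Antisymmetrized pair logit on a (speed, x, y, theta) grid."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    neighbour_speeds: np.ndarray
    focal_speed: float
    a_perp: float
    z: np.ndarray  # (n_speeds, n_x, n_y, n_theta)


@dataclass
class RegionMap:
    """Per-cell interaction class and scores derived from a PairLogitMap."""

    x: np.ndarray
    y: np.ndarray
    neighbour_speeds: np.ndarray
    region: np.ndarray  # (n_speeds, n_x, n_y) int codes, see REGION_CODES
    alignment: np.ndarray  # score; NaN outside orientation cells
    attraction_repulsion: np.ndarray  # score, all cells
    low_confidence: np.ndarray  # bool, |z| below the noise floor everywhere

    def region_name(self, code: int) -> str:
        return _CODE_NAMES[code]


def _grid_features(model, grid: dict, focal_speed: float, a_perp: float,
                   topo_rank: float):
    """Raw-unit alpha/social/weight feature rows for every grid point."""
    std = model.standardizer
    x, y, theta, speeds = (
        grid["x"], grid["y"], grid["theta"], grid["neighbour_speeds"],
    )
    V, X, Y, TH = np.meshgrid(speeds, x, y, theta, indexing="ij")
    vx = V * np.sin(TH)
    vy = V * np.cos(TH)
    alpha_cols = {"v": focal_speed, "a_perp": a_perp, "a_par": 0.0}
    alpha = np.array([[alpha_cols[n] for n in std.alpha_names]], dtype=float)
    social_cols = {
        "x": X, "y": Y, "vx": vx, "vy": vy, "v": V,
        "theta": np.arctan2(vx, vy), "topo": np.full_like(X, topo_rank),
    }
    social = np.stack([social_cols[n].ravel() for n in std.social_names], axis=-1)
    weight_cols = {
        "v_focal": np.full_like(X, focal_speed), "v_n": V, "abs_x": np.abs(X),
        "y": Y, "topo": np.full_like(X, topo_rank),
    }
    wfeat = np.stack([weight_cols[n].ravel() for n in std.weight_names], axis=-1)
    shape = V.shape
    return alpha, social, wfeat, shape


def pair_logit_map(
    model,
    focal_speed: float = 3.04,
    a_perp: float = 0.0,
    grid: dict | None = None,
    topo_rank: float = 1.0,
) -> PairLogitMap:
    """Evaluate the antisymmetrized pair subnetwork on a grid (weights ignored).

    ``model`` is a trained :class:`~fishrules.networks.AttentionNetwork`.
    The neighbour velocity is composed from its speed and relative heading
    theta (0 = parallel to the focal, positive toward the focal's right).
    If the model was trained with the topological-index input, the map is
    evaluated at the fixed rank ``topo_rank``.
    """
    grid = default_grid() if grid is None else grid
    std = model.standardizer
    alpha, social, wfeat, shape = _grid_features(
        model, grid, focal_speed, a_perp, topo_rank
    )
    pi_in = np.concatenate(
        [
            np.broadcast_to(std.transform_alpha(alpha), (social.shape[0], alpha.shape[1])),
            std.transform_social(social),
        ],
        axis=1,
    )
    z = model.pair_logit(pi_in).reshape(shape)
    return PairLogitMap(
        x=grid["x"], y=grid["y"], theta=grid["theta"],
        neighbour_speeds=grid["neighbour_speeds"],
        focal_speed=focal_speed, a_perp=a_perp, z=z,
    )


def weight_map(
    model,
    focal_speed: float = 3.04,
    grid: dict | None = None,
    topo_rank: float = 1.0,
) -> np.ndarray:
    """Aggregation weight W on the same grid, shape (n_speeds, n_x, n_y)."""
    grid = default_grid() if grid is None else grid
    std = model.standardizer
    _, _, wfeat, shape = _grid_features(model, grid, focal_speed, 0.0, topo_rank)
    w = model.weight_value(std.transform_weight(wfeat)).reshape(shape)
    return w[..., 0]  # W does not depend on theta


def attraction_repulsion_score(z_theta: np.ndarray, x) -> np.ndarray:
    """sign(x) times the theta-average of the logit (last axis).

    Positive means attraction (the focal turns toward the neighbour's side
    on average), negative repulsion.  ``x = 0`` yields 0 by the sign
    convention.
    """
    return np.sign(x) * np.asarray(z_theta).mean(axis=-1)


def alignment_score(z_theta: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """max_theta(z sign(theta)) - max_theta(-z sign(theta)) over the last axis.

    Positive when the focal turns toward the side the neighbour is turning
    to (alignment); negative for the reversed pattern (anti-alignment); a
    theta-independent logit scores 0.
    """
    s = np.sign(theta)
    zs = np.asarray(z_theta) * s
    return zs.max(axis=-1) - (-zs).max(axis=-1)


def classify_regions(pmap: PairLogitMap, noise_floor_frac: float = 0.01) -> RegionMap:
    """Label every spatial cell as alignment / anti-alignment / attraction / repulsion.

    A cell is an orientation area when the logit crosses the noise floor in
    both directions across theta; there the alignment score decides
    alignment vs anti-alignment.  Elsewhere the sign of the
    attraction-repulsion score decides.  Cells whose |z| stays below the
    noise floor for every theta are still labeled by score sign but flagged
    low-confidence.
    """
    z = pmap.z
    eps = noise_floor_frac * np.abs(z).max()
    has_pos = (z > eps).any(axis=-1)
    has_neg = (z < -eps).any(axis=-1)
    orientation = has_pos & has_neg
    low_conf = ~(has_pos | has_neg)

    align = alignment_score(z, pmap.theta)
    ar = attraction_repulsion_score(z, pmap.x[None, :, None])

    region = np.where(ar >= 0, REGION_CODES["attraction"], REGION_CODES["repulsion"])
    region = np.where(
        orientation,
        np.where(align >= 0, REGION_CODES["alignment"], REGION_CODES["anti-alignment"]),
        region,
    )
    align_out = np.where(orientation, align, np.nan)
    return RegionMap(
        x=pmap.x, y=pmap.y, neighbour_speeds=pmap.neighbour_speeds,
        region=region, alignment=align_out, attraction_repulsion=ar,
        low_confidence=low_conf,
    )
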