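"""Turning-side models: interaction network, attention network, focal baseline.

All three models output the logit ``z`` of the focal turning right after the
prediction horizon, ``p = 1 / (1 + exp(-z))``, and are built to be exactly
antisymmetric under body-axis reflection: ``z(mirrored scene) = -z(scene)``.

* The **interaction network** embeds each (focal, neighbour) pair with a
  shared subnetwork Pi_I (3 hidden layers x 128 ReLU units, 128-unit linear
  readout), sums the embeddings over neighbours, rectifies, and maps the sum
  to a logit with a second subnetwork Gamma (one 128-unit hidden layer).
  The whole function is antisymmetrized: ``z = I(s) - I(s*)``.

* The **attention network** gives each neighbour a scalar logit
  contribution Pi_A (same stack as Pi_I with a 1-unit readout,
  antisymmetrized per neighbour) and a strictly positive weight
  ``W_i = exp(u_i)`` from a weighting subnetwork whose inputs are a
  reflection-invariant subset of the variables; the logit is the
  weight-normalized average ``z = sum_i Pi_i W_i / sum_j W_j``.

* The **focal baseline** sees only the asocial variables.

Training minimizes the cross-entropy of the realized turn side with Adam,
annealing the learning rate geometrically across epochs, and early-stops
when the validation loss has not improved for ``patience`` epochs *and* has
risen ``rise_factor`` times above its minimum.  Parameters at the epoch of
minimum validation loss are returned.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .features import DataBundle, SampleSet, Standardizer
from .nnet import MLP, Adam

__all__ = [
    "TrainConfig",
    "AttentionNetwork",
    "InteractionNetwork",
    "FocalNetwork",
    "make_network",
    "logit_to_probability",
    "cross_entropy_loss",
    "train",
    "evaluate_accuracy",
    "save_checkpoint",
    "load_checkpoint",
]

_KIND_DEFAULTS = {
    # model_kind: (batch_size, lr_start, lr_end)
    "attention": (500, 1e-4, 1e-5),
    "interaction": (200, 5e-5, 1e-5),
    "focal_only": (500, 1e-4, 1e-5),
}


@dataclass
class TrainConfig:
    """Optimization schedule for one model fit.

    Defaults follow the published protocol: Adam, batch size 500 and
    learning rate 1e-4 -> 1e-5 for the attention model (200 and
    5e-5 -> 1e-5 for the interaction model), at most ``max_epochs`` epochs,
    stopping early once the validation loss has not reached a new minimum
    for ``patience`` epochs and sits ``rise_factor`` above that minimum.
    """

    model_kind: str = "attention"
    batch_size: int | None = None
    lr_start: float | None = None
    lr_end: float | None = None
    max_epochs: int = 100
    patience: int = 10
    rise_factor: float = 1.25
    seed: int = 0
    hidden: int = 128
    n_hidden: int = 3

    def __post_init__(self) -> None:
        if self.model_kind not in _KIND_DEFAULTS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        defaults = _KIND_DEFAULTS[self.model_kind]
        if self.batch_size is None:
            self.batch_size = defaults[0]
        if self.lr_start is None:
            self.lr_start = defaults[1]
        if self.lr_end is None:
            self.lr_end = defaults[2]
        if min(self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("batch_size, max_epochs and patience must be positive")
        if not (self.lr_start > 0 and self.lr_end > 0 and self.lr_end <= self.lr_start):
            raise ValueError("learning-rate schedule must be positive and decreasing")

    def learning_rate(self, epoch: int) -> float:
        """Geometric annealing from lr_start to lr_end across max_epochs."""
        if self.max_epochs == 1:
            return self.lr_start
        frac = epoch / (self.max_epochs - 1)
        return self.lr_start * (self.lr_end / self.lr_start) ** frac


def logit_to_probability(z):
    """Logistic map p = 1 / (1 + exp(-z)), computed stably."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def cross_entropy_loss(p_right, labels) -> float:
    """Mean negative log of the probability assigned to the realized side."""
    p_right = np.asarray(p_right, dtype=float)
    labels = np.asarray(labels)
    if p_right.size < 1:
        raise ValueError("need at least one prediction")
    p_star = np.where(labels == 1, p_right, 1.0 - p_right)
    return float(-np.mean(np.log(np.clip(p_star, 1e-12, None))))


def _logit_loss(z: np.ndarray, y: np.ndarray) -> float:
    # cross entropy straight from logits: log(1 + e^z) - y z
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


class _TurnModel:
    """Shared plumbing: manifest checks, batched logit prediction, params."""

    kind: str

    def __init__(self, standardizer: Standardizer, hidden: int, n_hidden: int):
        self.standardizer = standardizer
        self.hidden = hidden
        self.n_hidden = n_hidden

    # -- interface each subclass provides -------------------------------
    def _forward_batch(self, feats: tuple, cache: bool = False):
        raise NotImplementedError

    def _features(self, samples: SampleSet) -> tuple:
        raise NotImplementedError

    def networks(self) -> list[MLP]:
        raise NotImplementedError

    # --------------------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for net in self.networks() for p in net.params]

    def set_params(self, params: list[np.ndarray]) -> None:
        i = 0
        for net in self.networks():
            k = len(net.params)
            net.set_params(params[i : i + k])
            i += k

    def n_params(self) -> int:
        return sum(net.n_params() for net in self.networks())

    def check_manifest(self, samples: SampleSet) -> None:
        want = (
            self.standardizer.alpha_names,
            self.standardizer.social_names,
            self.standardizer.weight_names,
        )
        have = (samples.alpha_names, samples.social_names, samples.weight_names)
        if want != have:
            raise ValueError(
                f"variable manifest mismatch: model trained on {want}, data has {have}"
            )

    def predict_logits(self, samples: SampleSet, batch: int = 4096) -> np.ndarray:
        self.check_manifest(samples)
        feats = self._features(samples)
        out = np.empty(len(samples), dtype=np.float64)
        for start in range(0, len(samples), batch):
            sl = slice(start, start + batch)
            out[sl] = self._forward_batch(tuple(f[sl] for f in feats))[0]
        return out

    def predict_proba(self, samples: SampleSet, batch: int = 4096) -> np.ndarray:
        return logit_to_probability(self.predict_logits(samples, batch))


class AttentionNetwork(_TurnModel):
    """Attention model: per-neighbour logit x normalized positive weight."""

    kind = "attention"

    def __init__(
        self,
        standardizer: Standardizer,
        rng: np.random.Generator,
        hidden: int = 128,
        n_hidden: int = 3,
    ):
        super().__init__(standardizer, hidden, n_hidden)
        d_pi = len(standardizer.alpha_names) + len(standardizer.social_names)
        d_w = len(standardizer.weight_names)
        sizes = [hidden] * n_hidden
        self.pi_net = MLP([d_pi, *sizes, 1], rng)
        self.w_net = MLP([d_w, *sizes, 1], rng)
        self.flip = standardizer.pi_flip_signs

    def networks(self) -> list[MLP]:
        return [self.pi_net, self.w_net]

    def _features(self, samples: SampleSet) -> tuple:
        return (
            samples.pi_features(self.standardizer),
            samples.w_features(self.standardizer),
        )

    def _forward_batch(self, feats: tuple, cache: bool = False):
        P, Wf = feats
        B, n, d = P.shape
        rows = P.reshape(B * n, d)
        stacked = np.concatenate([rows, rows * self.flip], axis=0)
        cache_pi: list | None = [] if cache else None
        pi_out = self.pi_net.forward(stacked, cache_pi)[:, 0]
        pi = (pi_out[: B * n] - pi_out[B * n :]).reshape(B, n)
        cache_w: list | None = [] if cache else None
        u = self.w_net.forward(Wf.reshape(B * n, -1), cache_w)[:, 0].reshape(B, n)
        u_max = u.max(axis=1, keepdims=True)
        e = np.exp(u - u_max)
        omega = e / e.sum(axis=1, keepdims=True)
        z = np.einsum("bn,bn->b", pi.astype(np.float64), omega.astype(np.float64))
        extras = {"pi": pi, "omega": omega, "u": u,
                  "cache_pi": cache_pi, "cache_w": cache_w}
        return z, extras

    def _backward_batch(self, dz: np.ndarray, extras: dict) -> list[np.ndarray]:
        pi, omega, z = extras["pi"], extras["omega"], extras["z"]
        B, n = pi.shape
        d_pi = (dz[:, None] * omega).astype(np.float32).reshape(B * n, 1)
        du = (dz[:, None] * omega * (pi - z[:, None])).astype(np.float32)
        g_pi, _ = self.pi_net.backward(
            extras["cache_pi"], np.concatenate([d_pi, -d_pi], axis=0)
        )
        g_w, _ = self.w_net.backward(extras["cache_w"], du.reshape(B * n, 1))
        return g_pi + g_w

    # -- analysis hooks ---------------------------------------------------
    def attention_logit(self, samples: SampleSet):
        """Logit plus per-neighbour weights W_i and contributions Pi_i."""
        self.check_manifest(samples)
        z, extras = self._forward_batch(self._features(samples))
        weights = np.exp(extras["u"].astype(np.float64))
        return z, weights, extras["pi"].astype(np.float64)

    def neighbour_weights(self, samples: SampleSet, batch: int = 4096) -> np.ndarray:
        """Normalized attention weights omega_i, shape (S, n)."""
        self.check_manifest(samples)
        feats = self._features(samples)
        out = np.empty((len(samples), samples.n_neighbours))
        for start in range(0, len(samples), batch):
            sl = slice(start, start + batch)
            _, extras = self._forward_batch(tuple(f[sl] for f in feats))
            out[sl] = extras["omega"]
        return out

    def pair_logit(self, pi_features: np.ndarray) -> np.ndarray:
        """Antisymmetrized pair contribution Pi_A on standardized inputs (R, d)."""
        rows = pi_features.astype(np.float32)
        stacked = np.concatenate([rows, rows * self.flip], axis=0)
        out = self.pi_net.forward(stacked)[:, 0]
        k = rows.shape[0]
        return (out[:k].astype(np.float64) - out[k:].astype(np.float64))

    def weight_value(self, w_features: np.ndarray) -> np.ndarray:
        """Unnormalized positive weight W on standardized inputs (R, d_w)."""
        u = self.w_net.forward(w_features.astype(np.float32))[:, 0]
        return np.exp(u.astype(np.float64))


class InteractionNetwork(_TurnModel):
    """Deep interaction model: summed pair embeddings -> ReLU -> Gamma."""

    kind = "interaction"

    def __init__(
        self,
        standardizer: Standardizer,
        rng: np.random.Generator,
        hidden: int = 128,
        n_hidden: int = 3,
    ):
        super().__init__(standardizer, hidden, n_hidden)
        d_pi = len(standardizer.alpha_names) + len(standardizer.social_names)
        sizes = [hidden] * n_hidden
        self.pi_net = MLP([d_pi, *sizes, hidden], rng)
        self.gamma_net = MLP([hidden, hidden, 1], rng)
        self.flip = standardizer.pi_flip_signs

    def networks(self) -> list[MLP]:
        return [self.pi_net, self.gamma_net]

    def _features(self, samples: SampleSet) -> tuple:
        return (samples.pi_features(self.standardizer),)

    def _forward_batch(self, feats: tuple, cache: bool = False):
        (P,) = feats
        B, n, d = P.shape
        rows = P.reshape(B * n, d)
        stacked = np.concatenate([rows, rows * self.flip], axis=0)
        cache_pi: list | None = [] if cache else None
        emb = self.pi_net.forward(stacked, cache_pi)
        summed = emb.reshape(2 * B, n, -1).sum(axis=1)
        h = np.maximum(summed, 0.0)
        cache_g: list | None = [] if cache else None
        out = self.gamma_net.forward(h, cache_g)[:, 0]
        z = out[:B].astype(np.float64) - out[B:].astype(np.float64)
        extras = {"summed": summed, "n": n, "cache_pi": cache_pi, "cache_g": cache_g}
        return z, extras

    def _backward_batch(self, dz: np.ndarray, extras: dict) -> list[np.ndarray]:
        B = dz.shape[0]
        n = extras["n"]
        d_out = np.concatenate([dz, -dz]).astype(np.float32)[:, None]
        g_gamma, dh = self.gamma_net.backward(extras["cache_g"], d_out, need_dx=True)
        d_sum = dh * (extras["summed"] > 0)
        d_emb = np.repeat(d_sum, n, axis=0)
        g_pi, _ = self.pi_net.backward(extras["cache_pi"], d_emb)
        return g_pi + g_gamma


class FocalNetwork(_TurnModel):
    """Baseline seeing only the focal's own kinematics (antisymmetrized)."""

    kind = "focal_only"

    def __init__(
        self,
        standardizer: Standardizer,
        rng: np.random.Generator,
        hidden: int = 128,
        n_hidden: int = 3,
    ):
        super().__init__(standardizer, hidden, n_hidden)
        d_a = len(standardizer.alpha_names)
        sizes = [hidden] * n_hidden
        self.net = MLP([d_a, *sizes, 1], rng)
        from .features import ALPHA_CHANNELS

        self.flip = np.asarray(
            [ALPHA_CHANNELS[n] for n in standardizer.alpha_names], dtype=np.float32
        )

    def networks(self) -> list[MLP]:
        return [self.net]

    def _features(self, samples: SampleSet) -> tuple:
        return (self.standardizer.transform_alpha(samples.alpha).astype(np.float32),)

    def _forward_batch(self, feats: tuple, cache: bool = False):
        (A,) = feats
        B = A.shape[0]
        stacked = np.concatenate([A, A * self.flip], axis=0)
        cache_f: list | None = [] if cache else None
        out = self.net.forward(stacked, cache_f)[:, 0]
        z = out[:B].astype(np.float64) - out[B:].astype(np.float64)
        return z, {"cache_f": cache_f}

    def _backward_batch(self, dz: np.ndarray, extras: dict) -> list[np.ndarray]:
        d = dz.astype(np.float32)[:, None]
        grads, _ = self.net.backward(extras["cache_f"], np.concatenate([d, -d], axis=0))
        return grads


_MODEL_CLASSES = {
    "attention": AttentionNetwork,
    "interaction": InteractionNetwork,
    "focal_only": FocalNetwork,
}


def make_network(
    kind: str,
    standardizer: Standardizer,
    seed: int = 0,
    hidden: int = 128,
    n_hidden: int = 3,
) -> _TurnModel:
    """Build an untrained model of the requested kind with seeded init."""
    if kind not in _MODEL_CLASSES:
        raise ValueError(f"unknown model kind {kind!r}")
    rng = np.random.default_rng(seed)
    return _MODEL_CLASSES[kind](standardizer, rng, hidden=hidden, n_hidden=n_hidden)


def train(model: _TurnModel, bundle: DataBundle, config: TrainConfig) -> dict:
    """Fit a model on the bundle's training split; returns the history.

    The model ends at the parameters of the epoch with minimum validation
    loss.  Deterministic given ``config.seed`` (which drives minibatch
    shuffling; build the model with a seeded :func:`make_network`).
    """
    model.check_manifest(bundle.train)
    feats_train = model._features(bundle.train)
    y_train = bundle.train.label.astype(np.float32)
    feats_val = model._features(bundle.validation)
    y_val = bundle.validation.label.astype(np.float64)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7261696E]))
    opt = Adam(model.params)
    n_train = len(bundle.train)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_epoch = -1
    best_params: list[np.ndarray] | None = None

    for epoch in range(config.max_epochs):
        lr = config.learning_rate(epoch)
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = tuple(f[idx] for f in feats_train)
            z, extras = model._forward_batch(batch, cache=True)
            extras["z"] = z
            y = y_train[idx]
            loss = _logit_loss(z, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss {loss}"
                )
            losses.append(loss)
            dz = (logit_to_probability(z) - y) / len(idx)
            grads = model._backward_batch(dz, extras)
            opt.step(model.params, grads, lr)
        val_z = _predict_features(model, feats_val)
        val_loss = _logit_loss(val_z, y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = [p.copy() for p in model.params]
        if (
            epoch - best_epoch >= config.patience
            and val_loss >= config.rise_factor * best_val
        ):
            break

    if best_params is not None:
        model.set_params(best_params)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    history["n_epochs"] = len(history["val_loss"])
    return history


def _predict_features(model: _TurnModel, feats: tuple, batch: int = 4096) -> np.ndarray:
    n = feats[0].shape[0]
    out = np.empty(n, dtype=np.float64)
    for start in range(0, n, batch):
        sl = slice(start, start + batch)
        out[sl] = model._forward_batch(tuple(f[sl] for f in feats))[0]
    return out


def evaluate_accuracy(
    model: _TurnModel, samples: SampleSet, angle_range: tuple[float, float] = (0, 180)
) -> float:
    """Fraction of correct side predictions for turns inside the closed range."""
    lo, hi = angle_range
    keep = (samples.turn_angle >= lo) & (samples.turn_angle <= hi)
    if not keep.any():
        raise ValueError(f"no samples with turn angle in [{lo}, {hi}]")
    subset = samples.subset(keep)
    z = model.predict_logits(subset)
    pred = (z >= 0).astype(np.int8)  # ties predicted 'right'
    return float(np.mean(pred == subset.label))


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: _TurnModel, config: TrainConfig | None, path) -> Path:
    """Portable NPZ checkpoint with the variable manifest embedded."""
    path = Path(path)
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    manifest = {
        "kind": model.kind,
        "hidden": model.hidden,
        "n_hidden": model.n_hidden,
        "standardizer": model.standardizer.to_dict(),
        "config": asdict(config) if config is not None else None,
    }
    np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path) -> tuple[_TurnModel, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        params = [
            data[f"param_{i}"] for i in range(sum(1 for k in data if k.startswith("param_")))
        ]
    std = Standardizer.from_dict(manifest["standardizer"])
    model = make_network(
        manifest["kind"], std, seed=0,
        hidden=manifest["hidden"], n_hidden=manifest["n_hidden"],
    )
    model.set_params(params)
    return model, manifest
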