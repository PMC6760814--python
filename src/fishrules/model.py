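"""High-level modelling interface: build from data, fit, inspect results.

:class:`CollectiveTurnModel` wraps the full workflow — preprocessing,
sample construction, network training — behind a fit interface, and
:class:`CollectiveTurnResults` carries the trained network together with
its training history, accuracy diagnostics and the analysis products
(pair-interaction maps, region classification, effective neighbour
counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import aggregation, maps_scores, networks, pipeline
from .features import DataBundle
from .trajectories import TrajectorySet

__all__ = ["CollectiveTurnModel", "CollectiveTurnResults"]


class CollectiveTurnModel:
    """Turning-side model of an individual in a collective.

    Parameters
    ----------
    data : DataBundle
        Train/validation/test decision samples (see
        :func:`fishrules.features.build_dataset`).
    kind : {'attention', 'interaction', 'focal_only'}
        Model family: the analyzable attention network (default), the
        higher-capacity interaction network, or the asocial baseline.
    config : TrainConfig, optional
        Optimization schedule; defaults follow the published protocol.

    Examples
    --------
    >>> from fishrules import simulator, pipeline
    >>> ts, _ = simulator.simulate(simulator.ZonalConfig(), 1200, seed=0)
    >>> model = CollectiveTurnModel.from_trajectories(ts, horizon=4,
    ...     split_fractions=(0.8, 0.1, 0.1))
    >>> results = model.fit(seed=0)          # doctest: +SKIP
    >>> print(results.summary())             # doctest: +SKIP
    """

    def __init__(
        self,
        data: DataBundle,
        kind: str = "attention",
        config: networks.TrainConfig | None = None,
    ):
        if kind not in ("attention", "interaction", "focal_only"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.data = data
        self.kind = kind
        self.config = config

    @classmethod
    def from_trajectories(
        cls,
        ts: TrajectorySet,
        horizon: int | None = None,
        n_neighbours: int = 25,
        kind: str = "attention",
        include_topo: bool = False,
        config: networks.TrainConfig | None = None,
        **prepare_kwargs,
    ) -> "CollectiveTurnModel":
        """Build directly from a recording (preprocess + sample construction)."""
        if horizon is None:
            horizon = int(round(ts.fps))  # 1 s ahead by default
        bundle = pipeline.prepare_bundle(
            ts, horizon=horizon, n_neighbours=n_neighbours,
            include_topo=include_topo, **prepare_kwargs,
        )
        return cls(bundle, kind=kind, config=config)

    def fit(self, seed: int = 0, **config_overrides) -> "CollectiveTurnResults":
        """Train the network; returns a results object.

        Deterministic given ``seed``, which drives both parameter
        initialization and minibatch shuffling.
        """
        config = self.config
        if config is None or config_overrides:
            base = {} if config is None else {
                k: getattr(config, k)
                for k in ("batch_size", "lr_start", "lr_end", "max_epochs",
                          "patience", "rise_factor", "hidden", "n_hidden")
            }
            base.update(config_overrides)
            config = networks.TrainConfig(model_kind=self.kind, seed=seed, **base)
        net = networks.make_network(
            self.kind, self.data.standardizer, seed=seed,
            hidden=config.hidden, n_hidden=config.n_hidden,
        )
        history = networks.train(net, self.data, config)
        return CollectiveTurnResults(self, net, history, config)


@dataclass
class CollectiveTurnResults:
    """Fitted turning-side model with diagnostics and analysis products."""

    model: CollectiveTurnModel
    network: networks._TurnModel
    history: dict
    config: networks.TrainConfig
    _cache: dict = field(default_factory=dict, repr=False)

    # -- diagnostics ------------------------------------------------------
    def accuracy(
        self, angle_range: tuple[float, float] = (0, 180), part: str = "test"
    ) -> float:
        """Turn-side accuracy on a data part, filtered by turn angle (degrees)."""
        samples = self.model.data.sets()[part]
        return networks.evaluate_accuracy(self.network, samples, angle_range)

    def predict_proba(self, samples=None) -> np.ndarray:
        """P(turn right) for the given samples (default: the test split)."""
        if samples is None:
            samples = self.model.data.test
        return self.network.predict_proba(samples)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        data = self.model.data
        lines = [
            "Collective turning-side model",
            "=" * 46,
            f"{'Model kind:':<28}{self.network.kind}",
            f"{'Parameters:':<28}{self.network.n_params():,}",
            f"{'Neighbours per sample:':<28}{data.train.n_neighbours}",
            f"{'Train/val/test samples:':<28}"
            f"{len(data.train)}/{len(data.validation)}/{len(data.test)}",
            f"{'Epochs run (best):':<28}"
            f"{self.history['n_epochs']} ({self.history['best_epoch']})",
            f"{'Best validation loss:':<28}{self.history['best_val_loss']:.4f}",
            f"{'Test accuracy (all):':<28}{self.accuracy():.3f}",
        ]
        try:
            lines.append(
                f"{'Test accuracy (20-160 deg):':<28}"
                f"{self.accuracy((20, 160)):.3f}"
            )
        except ValueError:
            pass
        if self.network.kind == "attention":
            ntot, nimp = self.neighbour_counts()
            lines += [
                f"{'Mean N_total:':<28}{ntot.mean():.2f}",
                f"{'Mean N_important:':<28}{nimp.mean():.2f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- analysis products (attention model) ------------------------------
    def _require_attention(self) -> None:
        if self.network.kind != "attention":
            raise ValueError("map and weight analyses need the attention model")

    def pair_logit_map(self, **kwargs) -> maps_scores.PairLogitMap:
        self._require_attention()
        return maps_scores.pair_logit_map(self.network, **kwargs)

    def region_map(self, **kwargs) -> maps_scores.RegionMap:
        self._require_attention()
        return maps_scores.classify_regions(self.pair_logit_map(**kwargs))

    def weight_map(self, **kwargs) -> np.ndarray:
        self._require_attention()
        return maps_scores.weight_map(self.network, **kwargs)

    def neighbour_weights(self, part: str = "test") -> np.ndarray:
        self._require_attention()
        key = f"omega_{part}"
        if key not in self._cache:
            samples = self.model.data.sets()[part]
            self._cache[key] = self.network.neighbour_weights(samples)
        return self._cache[key]

    def neighbour_counts(self, part: str = "test") -> tuple[np.ndarray, np.ndarray]:
        """(N_total, N_important) per sample of the requested part."""
        omega = self.neighbour_weights(part)
        return aggregation.n_total(omega), aggregation.n_important(omega)

    def count_series(self, part: str = "test") -> dict:
        self._require_attention()
        return aggregation.neighbour_count_series(
            self.network, self.model.data.sets()[part]
        )

    def save(self, path) -> None:
        networks.save_checkpoint(self.network, self.config, path)
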