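"""Attention-weight analysis: effective and important neighbour counts.

The attention model assigns each neighbour a positive weight ``W_i``;
normalized weights ``omega_i = W_i / sum_j W_j`` sum to one and measure each
neighbour's share of the focal's decision.  The *effective number of
interacting neighbours* is the perplexity of that distribution,
``N_total = exp(-sum_i omega_i log omega_i) = 1 / omega_t`` with ``omega_t``
the typical weight; it equals ``n`` for uniform weights and 1 when a single
neighbour dominates.  ``N_important`` counts the neighbours whose weight is
at least the typical weight.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "normalized_weights",
    "n_total",
    "n_important",
    "neighbour_count_series",
    "power_spectrum",
]


def normalized_weights(weights: np.ndarray) -> np.ndarray:
    """omega_i = W_i / sum_j W_j along the last axis; requires W_i > 0."""
    weights = np.asarray(weights, dtype=float)
    if (weights <= 0).any():
        raise ValueError("aggregation weights must be strictly positive")
    return weights / weights.sum(axis=-1, keepdims=True)


def n_total(omega: np.ndarray) -> np.ndarray:
    """Effective neighbour count: exp of the Shannon entropy (natural log).

    Accepts normalized weights along the last axis; zero entries contribute
    0 * log 0 = 0.
    """
    omega = np.asarray(omega, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(omega > 0, omega * np.log(omega), 0.0)
    return np.exp(-terms.sum(axis=-1))


def n_important(omega: np.ndarray, strict_below: bool = False) -> np.ndarray:
    """Count of neighbours with weight at least the typical weight 1/N_total.

    ``strict_below`` selects the complementary strict-< count instead
    (the literal reading of "weight smaller than the typical weight").
    The comparison carries a tiny relative tolerance so exactly-uniform
    weights count as typical despite floating-point round-off.
    """
    omega = np.asarray(omega, dtype=float)
    omega_t = (1.0 / n_total(omega))[..., None] * (1.0 - 1e-9)
    if strict_below:
        return (omega < omega_t).sum(axis=-1)
    return (omega >= omega_t).sum(axis=-1)


def neighbour_count_series(model, samples) -> dict[int, dict[str, np.ndarray]]:
    """Per-focal time series of (N_total, N_important) from attention weights.

    ``model`` is a trained attention network; ``samples`` a SampleSet with
    frame/focal provenance.  Returns, per focal id, frame-sorted arrays
    plus segment boundaries where the frame sequence has gaps.
    """
    omega = model.neighbour_weights(samples)
    ntot = n_total(omega)
    nimp = n_important(omega)
    out: dict[int, dict[str, np.ndarray]] = {}
    for focal in np.unique(samples.focal_id):
        idx = np.flatnonzero(samples.focal_id == focal)
        idx = idx[np.argsort(samples.frame[idx], kind="stable")]
        frames = samples.frame[idx]
        gaps = np.flatnonzero(np.diff(frames) > 1) + 1
        out[int(focal)] = {
            "frames": frames,
            "n_total": ntot[idx],
            "n_important": nimp[idx],
            "segment_starts": np.concatenate([[0], gaps]),
        }
    return out


def power_spectrum(
    series: np.ndarray, fps: float, nperseg: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram (Welch) power spectral density of a count series.

    Segments of ``nperseg`` frames with 50% overlap; if the series is
    shorter than one segment a single periodogram is returned (with a
    warning from the estimator).  Frequencies run up to fps/2.
    """
    series = np.asarray(series, dtype=float)
    nperseg = min(nperseg, series.size)
    freqs, psd = signal.welch(
        series - series.mean(), fs=fps, nperseg=nperseg, noverlap=nperseg // 2,
        detrend=False,
    )
    return freqs, psd
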