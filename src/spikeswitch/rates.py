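"""Sliding-window firing-rate series.

The analysis epoch is the last 500 ms before the saccade. The rate series
r(t) uses a 100 ms window slid in 20 ms steps, one window per step across
the epoch: 500/20 = 25 bins, centered at -490, -470, ..., -10 ms. Each
window spans center ± 50 ms, half-open [c-50, c+50), so the earliest window
reaches back to -540 ms and the latest draws spikes up to +40 ms after the
saccade; the denominator is a constant 100 ms. (Truncating to fully
interior windows would yield 21 bins; this package keeps one bin per step
so the bin count matches the epoch/step ratio.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import Session, SpikeTrain

__all__ = [
    "RateSeries",
    "compute_rate_series",
    "mean_rate_in_window",
    "rate_matrix",
    "DEFAULT_WINDOW_MS",
    "DEFAULT_STEP_MS",
    "DEFAULT_EPOCH",
]

DEFAULT_WINDOW_MS = 100.0
DEFAULT_STEP_MS = 20.0
DEFAULT_EPOCH = (-500.0, 0.0)


@dataclass
class RateSeries:
    """Windowed firing-rate series of one neuron on one trial."""

    neuron_id: int
    trial_id: int
    bin_centers_ms: np.ndarray
    rate_hz: np.ndarray


def _bin_centers(window_ms: float, step_ms: float,
                 epoch: tuple[float, float]) -> np.ndarray:
    span = epoch[1] - epoch[0]
    n_bins = span / step_ms
    if abs(n_bins - round(n_bins)) > 1e-9 or round(n_bins) < 1:
        raise ValueError(
            f"epoch span {span} ms is not an integer multiple of "
            f"step {step_ms} ms")
    n_bins = int(round(n_bins))
    return epoch[0] + step_ms / 2.0 + step_ms * np.arange(n_bins)


def _window_counts(spike_ms: np.ndarray, centers: np.ndarray,
                   window_ms: float) -> np.ndarray:
    t = np.asarray(spike_ms, dtype=float)
    half = window_ms / 2.0
    lo = np.searchsorted(t, centers - half, side="left")
    hi = np.searchsorted(t, centers + half, side="left")  # half-open [a, b)
    return (hi - lo).astype(float)


def compute_rate_series(spikes: SpikeTrain,
                        window_ms: float = DEFAULT_WINDOW_MS,
                        step_ms: float = DEFAULT_STEP_MS,
                        epoch: tuple[float, float] = DEFAULT_EPOCH
                        ) -> RateSeries:
    """Windowed rate series for one spike train (defaults: 25 bins)."""
    centers = _bin_centers(window_ms, step_ms, epoch)
    counts = _window_counts(spikes.spike_ms, centers, window_ms)
    return RateSeries(spikes.neuron_id, spikes.trial_id, centers,
                      counts / (window_ms / 1000.0))


def mean_rate_in_window(spikes: SpikeTrain,
                        window: tuple[float, float]) -> float:
    """Mean firing rate (Hz) in a half-open window [a, b)."""
    a, b = window
    if b <= a:
        raise ValueError(f"empty window ({a}, {b})")
    t = np.asarray(spikes.spike_ms, dtype=float)
    n = np.searchsorted(t, b, side="left") - np.searchsorted(t, a, side="left")
    return float(n) / ((b - a) / 1000.0)


def rate_matrix(session: Session, neuron_id: int,
                trial_ids: list[int] | None = None,
                window_ms: float = DEFAULT_WINDOW_MS,
                step_ms: float = DEFAULT_STEP_MS,
                epoch: tuple[float, float] = DEFAULT_EPOCH
                ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Stack one neuron's rate series into an (n_trials, n_bins) matrix.

    Trials with no recorded spike train contribute all-zero rows (a valid
    observation: the neuron fired no spikes). Returns (rates, bin_centers,
    trial_ids) with rows ordered as ``trial_ids``.
    """
    if trial_ids is None:
        trial_ids = session.trial_ids
    centers = _bin_centers(window_ms, step_ms, epoch)
    by_trial = session.spikes_for(neuron_id)
    mat = np.zeros((len(trial_ids), centers.size))
    for i, tid in enumerate(trial_ids):
        if tid in by_trial:
            mat[i] = _window_counts(by_trial[tid].spike_ms, centers,
                                    window_ms) / (window_ms / 1000.0)
    return mat, centers, list(trial_ids)
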