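"""Mechanism tests for difficulty-coding neurons and class bookkeeping.

Once a neuron is known to encode trial difficulty (via the bin-wise linear
models) and its single-trial switches are reliably decoded, three
mechanisms are adjudicated:

* **switch-time code** — the per-trial switch time correlates with |TRO|
  (Kendall tau-b over correct switching trials, both response sides
  pooled);
* **rate code** — the per-trial mean rate from t90 to the end of the
  encoding window correlates with |TRO|;
* **binary code** — the per-trial mean rate in the encoding window is
  better described by an equal-weight two-Gaussian mixture (ΔBIC test),
  for at least one response side ("binary any side") or both.

Each test family is corrected across the population with
Benjamini-Hochberg FDR (default Q = 0.05). |TRO| operationalizes
difficulty (larger |TRO| = easier); tests are two-sided, so either sign of
dependence can reach significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .hmm import NeuronSwitchAnalysis
from .linear import bh_fdr
from .mixture import MixtureComparison
from .rates import mean_rate_in_window
from .session import Session

__all__ = [
    "CorrelationResult",
    "NeuronClassification",
    "kendall_tau",
    "switch_time_coding_test",
    "rate_coding_test",
    "encoding_window_span_ms",
    "classify_population",
]


@dataclass
class CorrelationResult:
    """Kendall tau-b with a two-sided p-value."""

    statistic: float
    p_value: float
    n: int
    variable: str = ""


@dataclass
class NeuronClassification:
    neuron_id: int
    flags: set[str] = field(default_factory=set)


def kendall_tau(x, y, variable: str = "") -> CorrelationResult:
    """Tie-corrected Kendall tau-b; all-tied data return (0, 1) by contract."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.kendalltau(x, y)
    tau, p = float(res.statistic), float(res.pvalue)
    if np.isnan(tau):  # zero-variance input: every pair tied
        tau, p = 0.0, 1.0
    return CorrelationResult(statistic=tau, p_value=max(min(p, 1.0), 1e-300),
                             n=int(x.size), variable=variable)


def switch_time_coding_test(analysis: NeuronSwitchAnalysis,
                            session: Session) -> CorrelationResult:
    """Kendall correlation of per-trial switch time with |TRO|.

    Uses correct switching trials, both response sides pooled. The decoded
    profile must be reliable.
    """
    if not analysis.reliable:
        raise ValueError("switch profile is not reliable")
    xs, ys = [], []
    for prof in analysis.profiles.values():
        for tid, t_sw in prof.switch_ms.items():
            trial = session.trials[tid]
            if t_sw is not None and trial.correct:
                xs.append(abs(trial.tro_deg))
                ys.append(t_sw)
    return kendall_tau(xs, ys, variable="switch_time_ms ~ |TRO|")


def encoding_window_span_ms(window_bins: tuple[int, int],
                            bin_centers: np.ndarray,
                            window_ms: float = 100.0
                            ) -> tuple[float, float]:
    """Time span [start, end) covered by an inclusive bin-index interval."""
    b0, b1 = window_bins
    return (float(bin_centers[b0] - window_ms / 2),
            float(bin_centers[b1] + window_ms / 2))


def rate_coding_test(analysis: NeuronSwitchAnalysis, session: Session,
                     windows_by_side: dict[str, tuple[float, float]]
                     ) -> CorrelationResult:
    """Kendall correlation of post-switch mean rate with |TRO|.

    For each response side with an encoding window, the per-trial mean rate
    is computed from that side's t90 to the end of the window (ms span from
    ``windows_by_side``); correct trials of both sides are pooled. Sides
    whose t90 falls at or beyond the window end are skipped.
    """
    if not analysis.reliable:
        raise ValueError("switch profile is not reliable")
    by_trial = {s.trial_id: s for s in session.spikes
                if s.neuron_id == analysis.neuron_id}
    xs, ys = [], []
    for side, prof in analysis.profiles.items():
        if side not in windows_by_side or prof.t90_ms is None:
            continue
        _, end_ms = windows_by_side[side]
        if prof.t90_ms >= end_ms:
            continue
        for tid in prof.paths:
            trial = session.trials[tid]
            if not trial.correct or tid not in by_trial:
                continue
            xs.append(abs(trial.tro_deg))
            ys.append(mean_rate_in_window(by_trial[tid],
                                          (prof.t90_ms, end_ms)))
    if len(xs) < 3:
        raise ValueError("no response side with a usable rate window")
    return kendall_tau(xs, ys, variable="post_switch_rate_hz ~ |TRO|")


def classify_population(
    mt_flagged: set[int],
    difficulty_sides: dict[int, set[str]],
    hmm_reliable: dict[int, bool],
    switch_tests: dict[int, CorrelationResult],
    rate_tests: dict[int, CorrelationResult],
    binary_tests: dict[tuple[int, str], MixtureComparison],
    q: float = 0.05,
) -> tuple[dict[int, NeuronClassification], dict[str, int]]:
    """Assign coding-mechanism flags and tally class intersections.

    Each test family (switch-time, rate, ΔBIC) is BH-FDR corrected across
    its own population at level ``q``. Returns (classifications keyed by
    neuron, intersection counts).
    """
    neurons = (set(mt_flagged) | set(difficulty_sides) | set(hmm_reliable)
               | set(switch_tests) | set(rate_tests)
               | {nid for nid, _ in binary_tests})
    cls = {nid: NeuronClassification(nid) for nid in sorted(neurons)}

    for nid in mt_flagged:
        cls[nid].flags.add("mt_code")
    for nid, sides in difficulty_sides.items():
        if sides:
            cls[nid].flags.add("difficulty_any_side")
        if len(sides) >= 2:
            cls[nid].flags.add("difficulty_both_sides")
    for nid, ok in hmm_reliable.items():
        if ok:
            cls[nid].flags.add("hmm_reliable")

    def _family(tests: dict[int, CorrelationResult], flag: str) -> None:
        nids = sorted(tests)
        if not nids:
            return
        rej = bh_fdr([tests[n].p_value for n in nids], q)
        for nid, r in zip(nids, rej):
            if r and hmm_reliable.get(nid, False):
                cls[nid].flags.add(flag)

    _family(switch_tests, "switch_time_code")
    _family(rate_tests, "rate_code")

    keys = sorted(k for k, c in binary_tests.items() if c.p_value is not None)
    if keys:
        rej = bh_fdr([binary_tests[k].p_value for k in keys], q)
        by_neuron: dict[int, int] = {}
        for (nid, _side), r in zip(keys, rej):
            if r:
                by_neuron[nid] = by_neuron.get(nid, 0) + 1
        for nid, n_sides in by_neuron.items():
            cls[nid].flags.add("binary_any_side")
            if n_sides >= 2:
                cls[nid].flags.add("binary_both_sides")

    def count(*flags: str) -> int:
        return sum(1 for c in cls.values()
                   if all(f in c.flags for f in flags))

    counts = {
        "mt_code": count("mt_code"),
        "difficulty_any_side": count("difficulty_any_side"),
        "difficulty_both_sides": count("difficulty_both_sides"),
        "hmm_reliable": count("hmm_reliable"),
        "switch_time_code": count("switch_time_code"),
        "rate_code": count("rate_code"),
        "binary_any_side": count("binary_any_side"),
        "binary_both_sides": count("binary_both_sides"),
        "switch_and_rate": count("switch_time_code", "rate_code"),
        "switch_and_binary": count("switch_time_code", "binary_any_side"),
        "rate_and_binary": count("rate_code", "binary_any_side"),
        "switch_and_rate_and_binary": count(
            "switch_time_code", "rate_code", "binary_any_side"),
        "mt_and_difficulty": count("mt_code", "difficulty_any_side"),
    }
    return cls, counts
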