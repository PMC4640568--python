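"""Synthetic session generator with known ground truth.

Emulates a two-interval, two-alternative orientation-discrimination task:
a logistic psychometric curve over test relative orientations (TRO) of
±1..±4 degrees, movement times (MT) that decrease with trial ease on
correct trials and increase on error trials (the X-shaped chronometric
pattern), and spike trains produced by each of the coding mechanisms the
analysis is designed to detect:

``mt_code``
    constant within-trial rate modulated linearly by the trial's MT;
``switch_time``
    a low->high rate step whose timing advances with trial ease;
``rate_code``
    a step at a fixed mean time to a level that grows with trial ease;
``binary``
    a step that occurs only with probability increasing in trial ease;
``null``
    homogeneous Poisson firing.

Spike trains are inhomogeneous Poisson with piecewise-constant rates,
sampled exactly (per-segment Poisson counts + uniform placement); no
refractoriness or spike-history effects. Each neuron draws from its own
random substream keyed by (master seed, neuron_id), so removing a neuron
never perturbs another's spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .session import Session, SpikeTrain, TrialRecord

__all__ = [
    "BehaviorParams",
    "NeuronSpec",
    "generate_behavior",
    "sample_piecewise_poisson",
    "generate_neuron",
    "generate_session",
    "demo_neuron_specs",
]

MECHANISMS = ("mt_code", "switch_time", "rate_code", "binary", "null")

#: recorded epoch emitted by the generator, ms relative to saccade onset
DEFAULT_EPOCH_MS = (-1000.0, 100.0)


@dataclass
class BehaviorParams:
    """Task and behavior parameters.

    ``beta`` is the psychometric slope (1/deg): P(choice=left | TRO) =
    1 / (1 + exp(beta * TRO)). ``mt_base``/``mt_gain``/``mt_sd`` shape the
    chronometric X-pattern: on correct trials MT = mt_base - mt_gain*|TRO|
    + noise, on error trials mt_base + mt_gain*|TRO| + noise, truncated to
    (0, 1200] ms.
    """

    beta: float = 1.1
    mt_base: float = 300.0
    mt_gain: float = 10.0
    mt_sd: float = 50.0
    tro_levels: tuple[float, ...] = (-4, -3, -2, -1, 1, 2, 3, 4)
    trials_per_level: int = 40

    def validate(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.mt_sd < 0:
            raise ValueError("mt_sd must be >= 0")
        if 0 in self.tro_levels:
            raise ValueError("tro_levels must not contain 0")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one simulated neuron.

    Rates in Hz, times in ms. ``switch_anchor`` is the mean switch time
    (relative to saccade) at |TRO| = 0; ``switch_gain`` advances the switch
    by that many ms per degree of |TRO| (easier -> earlier). ``p0``/``p1``
    give the binary mechanism's switch probability clip(p0 + p1*|TRO|, 0, 1).
    ``mt_gain_hz`` is the mt_code rate change per ms of (MT - mt_base).
    """

    neuron_id: int
    mechanism: str
    lambda_low: float = 5.0
    lambda_high: float = 30.0
    switch_anchor: float = -250.0
    switch_gain: float = 25.0
    switch_jitter_sd: float = 20.0
    rate_gain: float = 2.0
    p0: float = 0.2
    p1: float = 0.15
    mt_gain_hz: float = 0.1
    mt_base: float = 300.0

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.lambda_low < 0 or self.lambda_high < 0:
            raise ValueError("rates must be >= 0")


def generate_behavior(params: BehaviorParams, seed=None,
                      rng: Optional[np.random.Generator] = None
                      ) -> list[TrialRecord]:
    """Draw one session's worth of behavioral trials."""
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    tid = 0
    for tro in params.tro_levels:
        p_left = 1.0 / (1.0 + math.exp(params.beta * tro))
        for _ in range(params.trials_per_level):
            choice = "left" if rng.random() < p_left else "right"
            correct = (tro < 0) == (choice == "left")
            sign = -1.0 if correct else 1.0
            mt = params.mt_base + sign * params.mt_gain * abs(tro)
            mt += rng.normal(0.0, params.mt_sd) if params.mt_sd > 0 else 0.0
            mt = min(max(mt, 1e-3), 1200.0)
            trials.append(TrialRecord(
                trial_id=tid, s1_deg=0.0, s2_deg=float(tro),
                tro_deg=float(tro), choice=choice, correct=correct,
                mt_ms=float(mt)))
            tid += 1
    return trials


def sample_piecewise_poisson(segments: Sequence[tuple[float, float, float]],
                             seed=None,
                             rng: Optional[np.random.Generator] = None
                             ) -> np.ndarray:
    """Exact draw from a piecewise-constant-rate Poisson process.

    ``segments`` is an ordered, non-overlapping sequence of
    (t_start_ms, t_end_ms, rate_hz) triples. Returns sorted spike times (ms).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    prev_end = -np.inf
    times: list[np.ndarray] = []
    for t0, t1, rate in segments:
        if t1 <= t0:
            raise ValueError(f"segment ({t0}, {t1}) has non-positive duration")
        if t0 < prev_end:
            raise ValueError("segments overlap or are out of order")
        if rate < 0:
            raise ValueError("rates must be >= 0")
        prev_end = t1
        n = rng.poisson(rate * (t1 - t0) / 1000.0)
        if n:
            times.append(np.sort(rng.uniform(t0, t1, size=n)))
    if not times:
        return np.empty(0)
    return np.concatenate(times)


def _neuron_rng(master_seed: int, neuron_id: int) -> np.random.Generator:
    # keyed by neuron_id so substreams are independent of the neuron roster
    return np.random.default_rng([int(master_seed) % (2**31), 1000003, int(neuron_id)])


def generate_neuron(spec: NeuronSpec, trials: Sequence[TrialRecord],
                    epoch_ms: tuple[float, float] = DEFAULT_EPOCH_MS,
                    seed=None, rng: Optional[np.random.Generator] = None
                    ) -> tuple[list[SpikeTrain], dict[int, Optional[float]]]:
    """Simulate one neuron across all trials.

    Returns the spike trains and a per-trial map of true switch times
    (None on trials with no switch or for non-switching mechanisms).
    """
    spec.validate()
    if not trials:
        raise ValueError("trials must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    t0, t1 = epoch_ms
    trains: list[SpikeTrain] = []
    switch_ms: dict[int, Optional[float]] = {}
    for trial in trials:
        atro = abs(trial.tro_deg)
        t_sw: Optional[float] = None
        if spec.mechanism == "null":
            segs = [(t0, t1, spec.lambda_low)]
        elif spec.mechanism == "mt_code":
            rate = max(spec.lambda_low
                       + spec.mt_gain_hz * (trial.mt_ms - spec.mt_base), 0.0)
            segs = [(t0, t1, rate)]
        else:
            jitter = (rng.normal(0.0, spec.switch_jitter_sd)
                      if spec.switch_jitter_sd > 0 else 0.0)
            if spec.mechanism == "switch_time":
                t_sw = spec.switch_anchor - spec.switch_gain * atro + jitter
                high = spec.lambda_high
            elif spec.mechanism == "rate_code":
                t_sw = spec.switch_anchor + jitter
                high = spec.lambda_high + spec.rate_gain * atro
            else:  # binary
                p_switch = min(max(spec.p0 + spec.p1 * atro, 0.0), 1.0)
                if rng.random() < p_switch:
                    t_sw = spec.switch_anchor + jitter
                    high = spec.lambda_high
                else:
                    t_sw = None
                    high = spec.lambda_low
            if t_sw is None:
                segs = [(t0, t1, spec.lambda_low)]
            else:
                t_cut = min(max(t_sw, t0 + 1e-9), t1 - 1e-9)
                segs = [(t0, t_cut, spec.lambda_low), (t_cut, t1, high)]
        spikes = sample_piecewise_poisson(segs, rng=rng)
        trains.append(SpikeTrain(spec.neuron_id, trial.trial_id, spikes))
        switch_ms[trial.trial_id] = t_sw
    return trains, switch_ms


def generate_session(behavior: BehaviorParams,
                     neurons: Sequence[NeuronSpec],
                     seed: int,
                     epoch_ms: tuple[float, float] = DEFAULT_EPOCH_MS
                     ) -> Session:
    """Generate a full session; fully deterministic given the master seed."""
    ids = [n.neuron_id for n in neurons]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate neuron_id in specs")
    behavior_rng = np.random.default_rng([int(seed) % (2**31), 7])
    trials = generate_behavior(behavior, rng=behavior_rng)
    all_spikes: list[SpikeTrain] = []
    ground_truth: dict[int, dict] = {}
    for spec in neurons:
        rng = _neuron_rng(seed, spec.neuron_id)
        trains, switch_ms = generate_neuron(spec, trials, epoch_ms, rng=rng)
        all_spikes.extend(trains)
        params = {k: v for k, v in vars(spec).items()
                  if k not in ("neuron_id", "mechanism")}
        params["switch_ms"] = switch_ms
        ground_truth[spec.neuron_id] = {
            "mechanism": spec.mechanism, "params": params}
    return Session(
        trials={t.trial_id: t for t in trials},
        spikes=all_spikes,
        epoch_ms=epoch_ms,
        ground_truth=ground_truth if neurons else None,
        meta={"generator_seed": int(seed)},
    )


def demo_neuron_specs(n_per_mechanism: int = 5, n_null: int = 5,
                      **overrides) -> list[NeuronSpec]:
    """Default demo roster: n_per_mechanism of each coding mechanism plus
    n_null homogeneous-Poisson neurons.  mt_code/null neurons fire at a
    20 Hz baseline; switching neurons step from 5 to 30 Hz.
    """
    specs: list[NeuronSpec] = []
    nid = 0
    for mech in ("mt_code", "switch_time", "rate_code", "binary"):
        for _ in range(n_per_mechanism):
            kw = dict(overrides)
            if mech == "mt_code":
                kw.setdefault("lambda_low", 20.0)
            specs.append(NeuronSpec(neuron_id=nid, mechanism=mech, **kw))
            nid += 1
    for _ in range(n_null):
        kw = dict(overrides)
        kw.setdefault("lambda_low", 20.0)
        specs.append(NeuronSpec(neuron_id=nid, mechanism="null", **kw))
        nid += 1
    return specs
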