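"""Two-state hidden Markov model for single-trial activity switches.

Within each trial a neuron is assumed to occupy one of Q hidden firing-rate
states (Q = 2 by default: low and high). In state q the neuron fires as a
Poisson process of intensity λ_q, which at a 2 ms bin width defines the
per-bin spike probability E_q = 1 − exp(−λ_q · 0.002); bins with more than
one spike are clipped to 1, so emissions are Bernoulli. The chain is
time-homogeneous with transition matrix A (A_ij = P(q_{t+1}=j | q_t=i)).

Parameters are estimated by Baum-Welch (EM) on a seeded random 80% of the
trials of one response side; the Viterbi algorithm then decodes the most
likely state path of every trial of that side. States are relabeled so
emission probability increases with state index (state 0 = low). A decoded
population is only trusted when (a) the mean dwell time of every visited
state is at least 25 ms, (b) no trial switches state more than three
times, and (c) at least five trials of each response side contain a
switch. The summary statistic t90 is the time by which 90% of switching
trials have entered the high state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .session import Session, SpikeTrain

__all__ = [
    "HmmSpec",
    "HmmFit",
    "SwitchProfile",
    "NeuronSwitchAnalysis",
    "binarize_spikes",
    "fit_hmm",
    "viterbi_decode",
    "extract_switch_times",
    "reliability_check",
    "t90_switch_time",
    "compare_state_counts",
    "analyze_neuron_switches",
    "BernoulliSwitchHMM",
]

_PROB_FLOOR = 1e-6
HMM_EPOCH = (-500.0, 0.0)


@dataclass
class HmmSpec:
    """HMM hyperparameters."""

    n_states: int = 2
    bin_ms: float = 2.0
    train_fraction: float = 0.8
    max_iter: int = 300
    tol: float = 1e-6
    n_restarts: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")


@dataclass
class HmmFit:
    """Fitted HMM parameters (states ordered by increasing emission)."""

    transition: np.ndarray     # (Q, Q), rows sum to 1
    emission: np.ndarray       # (Q,) P(spike in one bin | state)
    initial: np.ndarray        # (Q,)
    log_likelihood: float      # training log-likelihood at convergence
    ll_history: np.ndarray     # per-iteration training log-likelihood
    degenerate: bool = False   # all-empty training data

    @property
    def n_states(self) -> int:
        return self.emission.size

    def rate_hz(self, bin_ms: float = 2.0) -> np.ndarray:
        """Per-state Poisson intensity implied by the emissions."""
        return -np.log1p(-self.emission) / (bin_ms / 1000.0)


def binarize_spikes(spikes: SpikeTrain | np.ndarray,
                    epoch: tuple[float, float] = HMM_EPOCH,
                    bin_ms: float = 2.0) -> np.ndarray:
    """Binary observation sequence: 1 iff >= 1 spike in each half-open bin."""
    t = spikes.spike_ms if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    span = epoch[1] - epoch[0]
    n_bins = span / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"epoch span {span} not divisible by bin_ms {bin_ms}")
    n_bins = int(round(n_bins))
    t = t[(t >= epoch[0]) & (t < epoch[1])]
    idx = np.floor((t - epoch[0]) / bin_ms).astype(int)
    obs = np.zeros(n_bins, dtype=np.uint8)
    obs[idx] = 1
    return obs


def _emission_probs(obs: np.ndarray, e: np.ndarray) -> np.ndarray:
    # obs (T, L) -> per-bin state likelihoods (T, L, Q)
    return np.where(obs[..., None] == 1, e, 1.0 - e)


def _forward_backward_np(obs: np.ndarray, a: np.ndarray, e: np.ndarray,
                         pi: np.ndarray):
    """Scaled forward-backward over a stack of equal-length sequences.

    Returns (loglik, gamma (T,L,Q), xi_sum (Q,Q))."""
    T, L = obs.shape
    Q = e.size
    B = _emission_probs(obs, e)
    alpha = np.empty((T, L, Q))
    c = np.empty((T, L))
    a_ = alpha[:, 0] = pi[None, :] * B[:, 0]
    c[:, 0] = a_.sum(axis=1)
    alpha[:, 0] /= c[:, 0, None]
    for t in range(1, L):
        a_ = (alpha[:, t - 1] @ a) * B[:, t]
        c[:, t] = a_.sum(axis=1)
        alpha[:, t] = a_ / c[:, t, None]
    loglik = float(np.log(c).sum())

    beta = np.empty((T, L, Q))
    beta[:, L - 1] = 1.0
    xi_sum = np.zeros((Q, Q))
    for t in range(L - 2, -1, -1):
        nb = B[:, t + 1] * beta[:, t + 1]           # (T, Q)
        beta[:, t] = (nb @ a.T) / c[:, t + 1, None]
        xi_sum += a * (alpha[:, t].T @ (nb / c[:, t + 1, None]))
    gamma = alpha * beta
    return loglik, gamma, xi_sum


def _em_stats_np(obs, a, e, pi):
    """EM sufficient statistics via the numpy forward-backward.

    Returns (loglik, gamma0_sum, occ, gamma_sum, gamma_obs_sum, xi_sum)
    where occ = sum of gamma over all but the last bin (transition
    occupancy) and gamma_obs_sum weights gamma by the binary observations.
    """
    loglik, gamma, xi_sum = _forward_backward_np(obs, a, e, pi)
    gamma0 = gamma[:, 0].sum(axis=0)
    occ = gamma[:, :-1].sum(axis=(0, 1))
    gsum = gamma.sum(axis=(0, 1))
    gobs = (gamma * obs[..., None]).sum(axis=(0, 1))
    return loglik, gamma0, occ, gsum, gobs, xi_sum


try:  # compiled inner loop; the numpy path above is the reference fallback
    from numba import njit

    @njit(cache=False)
    def _em_stats_jit(obs, a, e, pi):  # pragma: no cover - compiled
        T, L = obs.shape
        Q = e.size
        alpha = np.empty((L, Q))
        c = np.empty(L)
        gamma0 = np.zeros(Q)
        occ = np.zeros(Q)
        gsum = np.zeros(Q)
        gobs = np.zeros(Q)
        xi_sum = np.zeros((Q, Q))
        loglik = 0.0
        for n in range(T):
            o = obs[n]
            s = 0.0
            for q in range(Q):
                b = e[q] if o[0] == 1 else 1.0 - e[q]
                alpha[0, q] = pi[q] * b
                s += alpha[0, q]
            c[0] = s
            for q in range(Q):
                alpha[0, q] /= s
            for t in range(1, L):
                s = 0.0
                for q in range(Q):
                    acc = 0.0
                    for r in range(Q):
                        acc += alpha[t - 1, r] * a[r, q]
                    b = e[q] if o[t] == 1 else 1.0 - e[q]
                    alpha[t, q] = acc * b
                    s += acc * b
                c[t] = s
                for q in range(Q):
                    alpha[t, q] /= s
            for t in range(L):
                loglik += np.log(c[t])
            # backward pass accumulating statistics on the fly
            beta_next = np.ones(Q)
            nb = np.empty(Q)
            beta_t = np.empty(Q)
            for q in range(Q):
                g = alpha[L - 1, q]
                gsum[q] += g
                if o[L - 1] == 1:
                    gobs[q] += g
            for t in range(L - 2, -1, -1):
                for q in range(Q):
                    b = e[q] if o[t + 1] == 1 else 1.0 - e[q]
                    nb[q] = b * beta_next[q] / c[t + 1]
                for q in range(Q):
                    acc = 0.0
                    for r in range(Q):
                        acc += a[q, r] * nb[r]
                        xi_sum[q, r] += alpha[t, q] * a[q, r] * nb[r]
                    beta_t[q] = acc
                    g = alpha[t, q] * acc
                    gsum[q] += g
                    occ[q] += g
                    if o[t] == 1:
                        gobs[q] += g
                    if t == 0:
                        gamma0[q] += g
                for q in range(Q):
                    beta_next[q] = beta_t[q]
        return loglik, gamma0, occ, gsum, gobs, xi_sum

    def _em_stats(obs, a, e, pi):
        out = _em_stats_jit(np.ascontiguousarray(obs, dtype=np.uint8),
                            np.ascontiguousarray(a),
                            np.ascontiguousarray(e),
                            np.ascontiguousarray(pi))
        return (float(out[0]),) + out[1:]

except Exception:  # pragma: no cover - numba unavailable
    _em_stats = _em_stats_np


def _run_em(obs: np.ndarray, a: np.ndarray, e: np.ndarray, pi: np.ndarray,
            max_iter: int, tol: float) -> HmmFit:
    lls: list[float] = []
    for _ in range(max_iter):
        loglik, gamma0, occ, gsum, gobs, xi_sum = _em_stats(obs, a, e, pi)
        lls.append(loglik)
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol:
            break
        pi = gamma0 / obs.shape[0]
        a = xi_sum / np.maximum(occ[:, None], 1e-300)
        a = np.clip(a, 1e-8, None)
        a /= a.sum(axis=1, keepdims=True)
        e = gobs / np.maximum(gsum, 1e-300)
        e = np.clip(e, _PROB_FLOOR, 1 - _PROB_FLOOR)
        pi = np.clip(pi, 1e-8, None)
        pi /= pi.sum()
    return HmmFit(transition=a, emission=e, initial=pi,
                  log_likelihood=lls[-1], ll_history=np.asarray(lls))


def _relabel(fit: HmmFit) -> HmmFit:
    order = np.argsort(fit.emission, kind="stable")
    return replace(fit,
                   transition=fit.transition[np.ix_(order, order)],
                   emission=fit.emission[order],
                   initial=fit.initial[order])


def fit_hmm(observations: Sequence[np.ndarray] | np.ndarray,
            spec: HmmSpec) -> HmmFit:
    """Baum-Welch fit on a training subset of the observation sequences.

    Initialization: emissions spread around the pooled spike probability
    (0.5x to 1.5x across states), transition diagonal 0.98, uniform initial
    distribution, multiplied by seeded jitter; ``spec.n_restarts`` restarts
    keep the best training likelihood. States come back relabeled with
    emission increasing.
    """
    spec.validate()
    obs = np.asarray(observations, dtype=np.uint8)
    if obs.ndim == 1:
        obs = obs[None, :]
    if obs.shape[0] < 1:
        raise ValueError("need at least one observation sequence")
    rng = np.random.default_rng(spec.seed)
    n_train = max(1, int(round(spec.train_fraction * obs.shape[0])))
    train = obs[rng.permutation(obs.shape[0])[:n_train]]

    Q = spec.n_states
    p_pool = float(train.mean())
    degenerate = p_pool == 0.0
    base_e = np.clip(np.linspace(0.5, 1.5, Q) * max(p_pool, _PROB_FLOOR),
                     _PROB_FLOOR, 1 - _PROB_FLOOR)
    best: Optional[HmmFit] = None
    for _ in range(spec.n_restarts):
        e0 = np.clip(base_e * np.exp(rng.normal(0, 0.1, Q)),
                     _PROB_FLOOR, 1 - _PROB_FLOOR)
        if Q == 1:
            a0 = np.ones((1, 1))
        else:
            a0 = np.full((Q, Q), 0.02 / (Q - 1))
            np.fill_diagonal(a0, 0.98)
        pi0 = np.full(Q, 1.0 / Q)
        fit = _run_em(train, a0, e0, pi0, spec.max_iter, spec.tol)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    best.degenerate = degenerate
    return _relabel(best)


def score_sequences(observations: Sequence[np.ndarray] | np.ndarray,
                    fit: HmmFit) -> float:
    """Total log-likelihood of sequences under a fitted model."""
    obs = np.asarray(observations, dtype=np.uint8)
    if obs.ndim == 1:
        obs = obs[None, :]
    return _em_stats(obs, fit.transition, fit.emission, fit.initial)[0]


def viterbi_decode(observation: np.ndarray, fit: HmmFit) -> np.ndarray:
    """Most likely state path; ties break toward the lower-index state."""
    obs = np.asarray(observation, dtype=np.uint8)
    with np.errstate(divide="ignore"):
        log_a = np.log(fit.transition)
        log_pi = np.log(fit.initial)
        log_b = np.log(_emission_probs(obs[None, :], fit.emission)[0])
    L, Q = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((L, Q), dtype=int)
    for t in range(1, L):
        scores = delta[:, None] + log_a            # (from, to)
        back[t] = np.argmax(scores, axis=0)        # first max -> lower state
        delta = scores[back[t], np.arange(Q)] + log_b[t]
    path = np.empty(L, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def extract_switch_times(path: np.ndarray,
                         epoch: tuple[float, float] = HMM_EPOCH,
                         bin_ms: float = 2.0
                         ) -> tuple[Optional[float], int]:
    """First low->high transition time (start of the first high bin after a
    low bin) and the total number of state changes in either direction."""
    path = np.asarray(path, dtype=int)
    changes = np.flatnonzero(np.diff(path) != 0) + 1
    n_switches = changes.size
    switch_ms: Optional[float] = None
    for k in changes:
        if path[k - 1] == 0 and path[k] > 0:
            switch_ms = epoch[0] + k * bin_ms
            break
    return switch_ms, n_switches


def _dwell_runs(path: np.ndarray) -> list[tuple[int, int]]:
    """(state, run length in bins) for each visit."""
    runs = []
    start = 0
    for k in range(1, len(path) + 1):
        if k == len(path) or path[k] != path[start]:
            runs.append((int(path[start]), k - start))
            start = k
    return runs


def reliability_check(paths_by_side: dict[str, list[np.ndarray]],
                      bin_ms: float = 2.0,
                      min_dwell_ms: float = 25.0,
                      max_switches: int = 3,
                      min_switching_trials: int = 5
                      ) -> tuple[bool, list[str]]:
    """Apply the three reliability criteria to a decoded neuron.

    (a) mean dwell duration of every visited state, pooled over visits and
    trials of both sides, >= ``min_dwell_ms``; (b) every trial has at most
    ``max_switches`` state changes; (c) at least ``min_switching_trials``
    trials of each response side contain a state change.
    """
    failed: list[str] = []
    dwell: dict[int, list[int]] = {}
    any_over = False
    switching = {side: 0 for side in paths_by_side}
    for side, paths in paths_by_side.items():
        for p in paths:
            runs = _dwell_runs(np.asarray(p))
            for s, ln in runs:
                dwell.setdefault(s, []).append(ln)
            n_sw = len(runs) - 1
            if n_sw > max_switches:
                any_over = True
            if n_sw >= 1:
                switching[side] += 1
    if any(np.mean(v) * bin_ms < min_dwell_ms for v in dwell.values()):
        failed.append("a")
    if any_over:
        failed.append("b")
    if any(n < min_switching_trials for n in switching.values()):
        failed.append("c")
    return not failed, failed


def t90_switch_time(switch_times: Sequence[float]) -> float:
    """Time by which 90% of switching trials have switched: the
    ceil(0.9 n)-th order statistic."""
    times = np.sort(np.asarray([t for t in switch_times if t is not None],
                               dtype=float))
    if times.size < 5:
        raise ValueError("need at least 5 switching trials for t90")
    k = math.ceil(0.9 * times.size)
    return float(times[k - 1])


def compare_state_counts(observations: Sequence[np.ndarray] | np.ndarray,
                         spec: HmmSpec,
                         state_counts: Sequence[int] = (2, 3)) -> dict:
    """Fit HMMs with different state counts and compare by BIC.

    BIC = -2 lnL + p ln(T_obs) with p = Q^2 - 1 + Q free parameters
    (Q(Q-1) transition, Q-1 initial, Q emission) and T_obs the total number
    of observed bins across all sequences. Lower BIC wins; ties go to the
    smaller model.
    """
    obs = np.asarray(observations, dtype=np.uint8)
    if obs.ndim == 1:
        obs = obs[None, :]
    t_obs = obs.size
    out: dict = {"per_model": {}}
    for q in state_counts:
        fit = fit_hmm(obs, replace(spec, n_states=q))
        ll = score_sequences(obs, fit)
        p = q * q - 1 + q
        out["per_model"][q] = {
            "fit": fit, "log_likelihood": ll, "n_params": p,
            "bic": -2.0 * ll + p * math.log(t_obs)}
    out["selected"] = min(sorted(out["per_model"]),
                          key=lambda q: (out["per_model"][q]["bic"], q))
    return out


@dataclass
class SwitchProfile:
    """Decoded switch behavior of one neuron on one response side."""

    neuron_id: int
    side: str
    fit: HmmFit
    paths: dict[int, np.ndarray]
    switch_ms: dict[int, Optional[float]]
    n_switches: dict[int, int]
    t90_ms: Optional[float]


@dataclass
class NeuronSwitchAnalysis:
    """Per-side switch profiles plus the neuron-level reliability verdict."""

    neuron_id: int
    profiles: dict[str, SwitchProfile]
    reliable: bool
    failed_criteria: list[str] = field(default_factory=list)

    def pooled_switch_times(self, trial_filter=None
                            ) -> dict[int, Optional[float]]:
        out: dict[int, Optional[float]] = {}
        for prof in self.profiles.values():
            for tid, t in prof.switch_ms.items():
                if trial_filter is None or trial_filter(tid):
                    out[tid] = t
        return out


def analyze_neuron_switches(session: Session, neuron_id: int,
                            spec: Optional[HmmSpec] = None,
                            epoch: tuple[float, float] = HMM_EPOCH
                            ) -> NeuronSwitchAnalysis:
    """Fit per-response-side HMMs for one neuron and decode every trial.

    Trials are split by the behavioral response (choice); each side gets
    its own model fit on a seeded 80% of its trials and decoded on all of
    them. Reliability pools both sides.
    """
    if spec is None:
        spec = HmmSpec()
    by_trial = session.spikes_for(neuron_id)
    profiles: dict[str, SwitchProfile] = {}
    paths_by_side: dict[str, list[np.ndarray]] = {}
    for side_idx, side in enumerate(("left", "right")):
        tids = [tid for tid in session.trial_ids
                if session.trials[tid].choice == side]
        if not tids:
            continue
        obs = np.stack([
            binarize_spikes(by_trial[tid], epoch, spec.bin_ms)
            if tid in by_trial
            else np.zeros(int(round((epoch[1] - epoch[0]) / spec.bin_ms)),
                          dtype=np.uint8)
            for tid in tids])
        side_seed = (int(spec.seed) % (2**31), 47, int(neuron_id), side_idx)
        side_spec = replace(spec, seed=side_seed)
        fit = fit_hmm(obs, side_spec)
        paths = {tid: viterbi_decode(obs[i], fit)
                 for i, tid in enumerate(tids)}
        switch_ms: dict[int, Optional[float]] = {}
        n_switches: dict[int, int] = {}
        for tid, p in paths.items():
            s, n = extract_switch_times(p, epoch, spec.bin_ms)
            switch_ms[tid] = s
            n_switches[tid] = n
        times = [t for t in switch_ms.values() if t is not None]
        t90 = t90_switch_time(times) if len(times) >= 5 else None
        profiles[side] = SwitchProfile(neuron_id, side, fit, paths,
                                       switch_ms, n_switches, t90)
        paths_by_side[side] = list(paths.values())
    reliable, failed = reliability_check(paths_by_side, spec.bin_ms)
    if len(profiles) < 2:
        reliable, failed = False, sorted(set(failed) | {"c"})
    return NeuronSwitchAnalysis(neuron_id, profiles, reliable, failed)


class BernoulliSwitchHMM:
    """Model-object wrapper around :func:`fit_hmm` (statsmodels-style)."""

    def __init__(self, observations: Sequence[np.ndarray] | np.ndarray,
                 spec: Optional[HmmSpec] = None):
        self.observations = np.asarray(observations, dtype=np.uint8)
        if self.observations.ndim == 1:
            self.observations = self.observations[None, :]
        self.spec = spec or HmmSpec()

    def fit(self) -> "SwitchHMMResults":
        return SwitchHMMResults(self, fit_hmm(self.observations, self.spec))


@dataclass
class SwitchHMMResults:
    model: BernoulliSwitchHMM
    params: HmmFit

    def decode(self, observation: Optional[np.ndarray] = None):
        if observation is not None:
            return viterbi_decode(observation, self.params)
        return [viterbi_decode(o, self.params) for o in self.model.observations]

    def summary(self) -> str:
        f = self.params
        rates = f.rate_hz(self.model.spec.bin_ms)
        lines = [
            f"Bernoulli-emission HMM, Q={f.n_states}"
            + ("  [degenerate]" if f.degenerate else ""),
            "state  E(spike/bin)   rate(Hz)   A(stay)",
        ]
        for q in range(f.n_states):
            lines.append(f"{q:>5}  {f.emission[q]:>12.5f} {rates[q]:>10.2f} "
                         f"{f.transition[q, q]:>9.5f}")
        lines.append(f"training log-likelihood: {f.log_likelihood:.3f} "
                     f"({f.ll_history.size} EM iterations)")
        return "\n".join(lines)
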