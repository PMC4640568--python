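"""Bin-wise linear models with Monte-Carlo permutation nulls.

Three linear models relate the windowed rate series r(t) to a per-trial
scalar regressor, independently at each of the 25 time bins:

* ``lm_mt``      r(t) = d1(t) * MT  + d2(t)   on all completed trials;
* ``lm_tro_pos`` r(t) = d1(t) * TRO + d2(t)   on correct trials, TRO > 0;
* ``lm_tro_neg`` likewise on correct trials with TRO < 0;
* ``lm_diff``    r(t) = d1(t) * |TRO| + d2(t) on all correct trials.

Significance is assessed non-parametrically: the regressor labels are
permuted across trials (one permutation per surrogate, shared by all bins
so the temporal correlation of r(t) is preserved under the null), every
bin is refit, and a bin is significant when the observed slope leaves the
central 95% of its bin's null (two-sided) or the observed R² exceeds the
null's 95th percentile (one-sided). Because neighboring bins share spikes,
a run-length criterion guards against spurious runs: the longest run of
consecutive significant bins is compared with the null distribution of
longest runs obtained by scoring each surrogate against the pooled
surrogate null. Neuron-level p-values are corrected across the population
with Benjamini-Hochberg FDR; a neuron counts as encoding the regressor
only when both the slope and R² run-length p-values survive FDR and the
two significance masks overlap in a common interval (the encoding window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .rates import (DEFAULT_EPOCH, DEFAULT_STEP_MS, DEFAULT_WINDOW_MS,
                    _bin_centers, _window_counts)
from .session import Session, TrialRecord

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "BinwiseModelResult",
    "fit_bin_regression",
    "build_permutation_null",
    "per_bin_significance",
    "max_run_length",
    "run_length_pvalue",
    "bh_fdr",
    "run_linear_model",
    "encoding_window",
    "BinwiseLinearModel",
    "BinwiseLinearResults",
]

MODEL_NAMES = ("lm_mt", "lm_tro_pos", "lm_tro_neg", "lm_diff")


@dataclass
class ModelSpec:
    """Which regressor and which trials a linear model uses."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")

    def select(self, trials: Sequence[TrialRecord]
               ) -> tuple[list[int], np.ndarray]:
        """Trial ids entering the model and their regressor values."""
        if self.name == "lm_mt":
            keep = [(t.trial_id, t.mt_ms) for t in trials]
        elif self.name == "lm_tro_pos":
            keep = [(t.trial_id, t.tro_deg) for t in trials
                    if t.correct and t.tro_deg > 0]
        elif self.name == "lm_tro_neg":
            keep = [(t.trial_id, t.tro_deg) for t in trials
                    if t.correct and t.tro_deg < 0]
        else:  # lm_diff
            keep = [(t.trial_id, abs(t.tro_deg)) for t in trials if t.correct]
        ids = [k for k, _ in keep]
        return ids, np.asarray([v for _, v in keep], dtype=float)


@dataclass
class BinwiseModelResult:
    """Per-bin fits and run-length statistics for one neuron, one model."""

    neuron_id: int
    model: str
    slope: np.ndarray          # d1(t), 25 values
    intercept: np.ndarray      # d2(t)
    r2: np.ndarray
    slope_sig: np.ndarray      # booleans
    r2_sig: np.ndarray
    max_run_slope: int
    max_run_r2: int
    p_run_slope: float
    p_run_r2: float
    n_surrogates: int
    n_trials: int


def fit_bin_regression(x: np.ndarray, y: np.ndarray
                       ) -> tuple[float, float, float]:
    """Ordinary least squares of one bin: returns (slope, intercept, r2).

    Constant y returns (0, mean(y), 0) by contract; constant x raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("need at least 2 trials")
    xc = x - x.mean()
    varx = float(xc @ xc)
    if varx == 0:
        raise ValueError("all regressor values identical")
    yc = y - y.mean()
    vary = float(yc @ yc)
    if vary == 0:
        return 0.0, float(y.mean()), 0.0
    slope = float(xc @ yc) / varx
    intercept = float(y.mean() - slope * x.mean())
    r2 = float(xc @ yc) ** 2 / (varx * vary)
    return slope, intercept, r2


def _batch_ols(Xc: np.ndarray, Yc: np.ndarray, varx: np.ndarray,
               vary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simple OLS: Xc (S, n) centered regressors, Yc (n, B)
    centered responses; returns slopes and r2 of shape (S, B)."""
    cross = Xc @ Yc                                    # (S, B)
    slopes = cross / varx[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(vary[None, :] > 0,
                      cross**2 / (varx[:, None] * vary[None, :]), 0.0)
    return slopes, r2


def build_permutation_null(rates: np.ndarray, x: np.ndarray,
                           n_surrogates: int = 100, seed=None,
                           rng: Optional[np.random.Generator] = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null for all bins at once.

    One label permutation per surrogate is shared by every bin. Returns
    (null_slope, null_r2), each (n_surrogates, n_bins).
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    Y = np.asarray(rates, float)
    n = x.size
    perms = np.stack([rng.permutation(n) for _ in range(n_surrogates)])
    Xp = x[perms]                       # (S, n)
    Xc = Xp - Xp.mean(axis=1, keepdims=True)
    varx = np.einsum("ij,ij->i", Xc, Xc)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    vary = np.einsum("ij,ij->j", Yc, Yc)
    return _batch_ols(Xc, Yc, varx, vary)


def per_bin_significance(observed: np.ndarray, null: np.ndarray,
                         statistic_kind: str, alpha: float = 0.05
                         ) -> np.ndarray:
    """Mark bins whose observed statistic leaves the null envelope.

    ``statistic_kind``: "slope" (two-sided, central 1-alpha band) or
    "r2" (upper one-sided, 1-alpha percentile).
    """
    observed = np.asarray(observed, float)
    null = np.asarray(null, float)
    if null.shape[1] != observed.size:
        raise ValueError("null and observed bin counts differ")
    if statistic_kind == "slope":
        lo = np.quantile(null, alpha / 2, axis=0)
        hi = np.quantile(null, 1 - alpha / 2, axis=0)
        return (observed < lo) | (observed > hi)
    if statistic_kind == "r2":
        hi = np.quantile(null, 1 - alpha, axis=0)
        return observed > hi
    raise ValueError(f"unknown statistic_kind {statistic_kind!r}")


def max_run_length(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = run = 0
    for v in np.asarray(mask, bool):
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def _max_runs_rows(masks: np.ndarray) -> np.ndarray:
    """Longest True-run per row of a 2-D boolean array (vectorized)."""
    m = np.asarray(masks, bool)
    runs = np.zeros(m.shape[0], dtype=int)
    cur = np.zeros(m.shape[0], dtype=int)
    for j in range(m.shape[1]):
        cur = np.where(m[:, j], cur + 1, 0)
        runs = np.maximum(runs, cur)
    return runs


def run_length_pvalue(observed_run: int, null_runs: Sequence[int]) -> float:
    """Add-one Monte-Carlo p-value: P(null longest run >= observed)."""
    null_runs = np.asarray(null_runs)
    if null_runs.size < 1:
        raise ValueError("need at least one null run")
    return (1 + int(np.sum(null_runs >= observed_run))) / (null_runs.size + 1)


def bh_fdr(pvalues: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level q."""
    p = np.asarray(pvalues, float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _analyze_neuron(Y: np.ndarray, x: np.ndarray, alpha: float,
                    n_surrogates: int, rng: np.random.Generator,
                    neuron_id: int, model: str) -> BinwiseModelResult:
    n, n_bins = Y.shape
    xc = x - x.mean()
    varx = float(xc @ xc)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    vary = np.einsum("ij,ij->j", Yc, Yc)
    cross = xc @ Yc
    slope = cross / varx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(vary > 0, cross**2 / (varx * vary), 0.0)
    intercept = Y.mean(axis=0) - slope * x.mean()

    null_slope, null_r2 = build_permutation_null(Y, x, n_surrogates, rng=rng)
    slope_sig = per_bin_significance(slope, null_slope, "slope", alpha)
    r2_sig = per_bin_significance(r2, null_r2, "r2", alpha)
    obs_run_slope = max_run_length(slope_sig)
    obs_run_r2 = max_run_length(r2_sig)

    # score every surrogate against the pooled null to build the run-length null
    lo = np.quantile(null_slope, alpha / 2, axis=0)
    hi = np.quantile(null_slope, 1 - alpha / 2, axis=0)
    null_slope_masks = (null_slope < lo) | (null_slope > hi)
    hi_r2 = np.quantile(null_r2, 1 - alpha, axis=0)
    null_r2_masks = null_r2 > hi_r2
    null_runs_slope = _max_runs_rows(null_slope_masks)
    null_runs_r2 = _max_runs_rows(null_r2_masks)

    return BinwiseModelResult(
        neuron_id=neuron_id, model=model,
        slope=slope, intercept=intercept, r2=r2,
        slope_sig=slope_sig, r2_sig=r2_sig,
        max_run_slope=obs_run_slope, max_run_r2=obs_run_r2,
        p_run_slope=run_length_pvalue(obs_run_slope, null_runs_slope),
        p_run_r2=run_length_pvalue(obs_run_r2, null_runs_r2),
        n_surrogates=n_surrogates, n_trials=n)


def run_linear_model(session: Session, model: ModelSpec | str,
                     alpha: float = 0.05, n_surrogates: int = 100,
                     seed: int = 0,
                     neuron_ids: Optional[Sequence[int]] = None,
                     window_ms: float = DEFAULT_WINDOW_MS,
                     step_ms: float = DEFAULT_STEP_MS,
                     epoch: tuple[float, float] = DEFAULT_EPOCH,
                     ) -> tuple[dict[int, BinwiseModelResult], dict[int, str]]:
    """Fit one linear model for every neuron of a session.

    Returns (results by neuron_id, skipped neurons with reasons).
    """
    if isinstance(model, str):
        model = ModelSpec(model)
    trials = [session.trials[k] for k in session.trial_ids]
    trial_ids, x = model.select(trials)
    results: dict[int, BinwiseModelResult] = {}
    skipped: dict[int, str] = {}
    ids = list(neuron_ids) if neuron_ids is not None else session.neuron_ids
    # one pass over the spike table instead of a scan per neuron
    centers = _bin_centers(window_ms, step_ms, epoch)
    by_neuron: dict[int, dict[int, np.ndarray]] = {}
    for s in session.spikes:
        by_neuron.setdefault(s.neuron_id, {})[s.trial_id] = s.spike_ms
    for nid in ids:
        if x.size < 2 or np.unique(x).size < 2:
            skipped[nid] = "fewer than 2 distinct regressor values"
            continue
        trains = by_neuron.get(nid, {})
        Y = np.zeros((len(trial_ids), centers.size))
        for i, tid in enumerate(trial_ids):
            if tid in trains:
                Y[i] = _window_counts(trains[tid], centers,
                                      window_ms) / (window_ms / 1000.0)
        rng = np.random.default_rng([int(seed) % (2**31), 31, int(nid)])
        results[nid] = _analyze_neuron(Y, x, alpha, n_surrogates, rng,
                                       nid, model.name)
    return results, skipped


def _longest_joint_run(res: BinwiseModelResult
                       ) -> Optional[tuple[int, int]]:
    mask = res.slope_sig & res.r2_sig
    best: Optional[tuple[int, int]] = None
    start = None
    for j, v in enumerate(np.append(mask, False)):
        if v and start is None:
            start = j
        elif not v and start is not None:
            if best is None or (j - start) > (best[1] - best[0] + 1):
                best = (start, j - 1)
            start = None
    return best


def encoding_window(result_a: BinwiseModelResult,
                    result_b: Optional[BinwiseModelResult] = None
                    ) -> Optional[tuple[int, int]]:
    """Largest run of bins where both slope and R² are significant.

    With two model results (e.g. the TRO and |TRO| models for one response
    side) the longer interval wins; ties break toward the earlier interval.
    Returns inclusive (start_bin, end_bin) or None.
    """
    wins = [w for w in (_longest_joint_run(result_a),
                        _longest_joint_run(result_b) if result_b else None)
            if w is not None]
    if not wins:
        return None
    return max(wins, key=lambda w: (w[1] - w[0] + 1, -w[0]))


class BinwiseLinearModel:
    """Population-level bin-wise linear model (statsmodels-style).

    Parameters
    ----------
    session : Session
    model : str or ModelSpec
        One of "lm_mt", "lm_tro_pos", "lm_tro_neg", "lm_diff".
    """

    def __init__(self, session: Session, model: ModelSpec | str, *,
                 window_ms: float = DEFAULT_WINDOW_MS,
                 step_ms: float = DEFAULT_STEP_MS,
                 epoch: tuple[float, float] = DEFAULT_EPOCH):
        self.session = session
        self.model = ModelSpec(model) if isinstance(model, str) else model
        self.window_ms = window_ms
        self.step_ms = step_ms
        self.epoch = epoch

    def fit(self, alpha: float = 0.05, n_surrogates: int = 100,
            seed: int = 0,
            neuron_ids: Optional[Sequence[int]] = None
            ) -> "BinwiseLinearResults":
        results, skipped = run_linear_model(
            self.session, self.model, alpha, n_surrogates, seed,
            neuron_ids, self.window_ms, self.step_ms, self.epoch)
        return BinwiseLinearResults(self.model.name, results, skipped,
                                    alpha=alpha, n_surrogates=n_surrogates,
                                    seed=seed)


@dataclass
class BinwiseLinearResults:
    """Fit results of :class:`BinwiseLinearModel` across a population."""

    model: str
    results: dict[int, BinwiseModelResult]
    skipped: dict[int, str] = field(default_factory=dict)
    alpha: float = 0.05
    n_surrogates: int = 100
    seed: int = 0

    def flagged(self, q: float) -> list[int]:
        """Neurons whose slope AND R² run-length p-values survive BH-FDR
        at level q and whose significance masks share a common interval."""
        nids = sorted(self.results)
        if not nids:
            return []
        rej_slope = bh_fdr([self.results[n].p_run_slope for n in nids], q)
        rej_r2 = bh_fdr([self.results[n].p_run_r2 for n in nids], q)
        out = []
        for nid, a, b in zip(nids, rej_slope, rej_r2):
            if a and b and encoding_window(self.results[nid]) is not None:
                out.append(nid)
        return out

    def summary(self, q: float = 0.05) -> str:
        flagged = set(self.flagged(q))
        lines = [
            f"Bin-wise linear model: {self.model}",
            f"neurons analyzed: {len(self.results)}  "
            f"skipped: {len(self.skipped)}  surrogates: {self.n_surrogates}",
            f"flagged at BH-FDR q={q}: {len(flagged)}",
            f"{'neuron':>6} {'run_d1':>7} {'p_d1':>8} {'run_R2':>7} "
            f"{'p_R2':>8} {'flag':>5}",
        ]
        for nid in sorted(self.results):
            r = self.results[nid]
            lines.append(
                f"{nid:>6} {r.max_run_slope:>7} {r.p_run_slope:>8.4f} "
                f"{r.max_run_r2:>7} {r.p_run_r2:>8.4f} "
                f"{'*' if nid in flagged else '':>5}")
        return "\n".join(lines)
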