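"""End-to-end analysis pipeline.

Stage order mirrors the analysis logic: behavioral summaries, bin-wise
linear models for movement-time coding (LM_mt, FDR Q = 0.05) and
difficulty coding (LM_tro per response side and LM_|TRO|, Q = 0.1), then
— for the difficulty-encoding neurons only — per-side HMM switch
decoding, the switch-time / rate Kendall tests and the per-side ΔBIC
binary test (each family FDR-corrected at Q = 0.05), and finally the
population class bookkeeping. Every stage draws its randomness from the
single master seed, so a run is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import behavior as behavior_mod
from .hmm import HmmSpec, analyze_neuron_switches
from .linear import BinwiseLinearModel, encoding_window
from .mechanisms import (classify_population, encoding_window_span_ms,
                         rate_coding_test, switch_time_coding_test)
from .mixture import delta_bic_test
from .rates import DEFAULT_EPOCH, DEFAULT_STEP_MS, DEFAULT_WINDOW_MS
from .rates import _bin_centers, mean_rate_in_window
from .session import Session, read_session

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

REPORT_SCHEMA_VERSION = 1

#: sign convention: negative TRO maps to the left target
SIDE_TO_TRO_MODEL = {"left": "lm_tro_neg", "right": "lm_tro_pos"}


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    n_surrogates: int = 100
    q_mt: float = 0.05
    q_difficulty: float = 0.1
    q_mechanism: float = 0.05
    n_resamples: int = 2000
    mixture_restarts: int = 10
    hmm: HmmSpec = field(default_factory=HmmSpec)
    seed: int = 0
    hmm_all_neurons: bool = False  # override: decode every neuron

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _encoding_windows_by_side(nid, tro_results, diff_results, centers):
    """Per-side encoding window (bin interval and ms span) for one neuron.

    Also records the end time of the *last* jointly significant bin across
    the two difficulty models: the post-switch rate test runs from t90 to
    that last significant bin, whereas the binary test averages over the
    largest continuous run (the encoding window proper).
    """
    wins = {}
    for side in ("left", "right"):
        res_tro = tro_results[side].results.get(nid)
        res_diff = diff_results.results.get(nid)
        if res_tro is None and res_diff is None:
            continue
        w = encoding_window(res_tro or res_diff,
                            res_diff if res_tro is not None else None)
        if w is None:
            continue
        last_bin = w[1]
        for res in (res_tro, res_diff):
            if res is not None:
                joint = np.flatnonzero(res.slope_sig & res.r2_sig)
                if joint.size:
                    last_bin = max(last_bin, int(joint[-1]))
        wins[side] = {
            "bins": w,
            "span_ms": encoding_window_span_ms(w, centers),
            "rate_end_ms": float(centers[last_bin] + DEFAULT_WINDOW_MS / 2),
        }
    return wins


def run_pipeline(session: Session | str | Path,
                 config: Optional[PipelineConfig] = None,
                 out_dir: Optional[str | Path] = None) -> dict:
    """Run every stage on a session; returns (and optionally writes) the
    report dictionary."""
    if config is None:
        config = PipelineConfig()
    if not isinstance(session, Session):
        session = read_session(session)
    seed = int(config.seed) % (2**31)
    centers = _bin_centers(DEFAULT_WINDOW_MS, DEFAULT_STEP_MS, DEFAULT_EPOCH)
    stages: dict = {}

    # ---- behavior -------------------------------------------------------
    psych = behavior_mod.psychometric_table(session)
    chrono = behavior_mod.mt_tro_correlations(session)
    stages["behavior"] = {
        "psychometric": psych.to_dict(orient="records"),
        "chronometric": {
            f"{sk}_{ok}": (None if c is None else
                           {"r": c.r, "p_value": c.p_value, "n": c.n})
            for (sk, ok), c in chrono.items()},
    }

    # ---- linear models --------------------------------------------------
    lm_mt = BinwiseLinearModel(session, "lm_mt").fit(
        config.alpha, config.n_surrogates, seed)
    mt_flagged = set(lm_mt.flagged(config.q_mt))

    tro_results = {
        side: BinwiseLinearModel(session, SIDE_TO_TRO_MODEL[side]).fit(
            config.alpha, config.n_surrogates, seed)
        for side in ("left", "right")}
    lm_diff = BinwiseLinearModel(session, "lm_diff").fit(
        config.alpha, config.n_surrogates, seed)
    diff_flagged = {side: set(tro_results[side].flagged(config.q_difficulty))
                    for side in ("left", "right")}
    diff_flagged_any = set(lm_diff.flagged(config.q_difficulty))

    difficulty_sides: dict[int, set[str]] = {}
    windows: dict[int, dict] = {}
    for nid in session.neuron_ids:
        wins = _encoding_windows_by_side(nid, tro_results, lm_diff, centers)
        sides = {side for side in wins
                 if nid in diff_flagged[side] or nid in diff_flagged_any}
        if sides:
            difficulty_sides[nid] = sides
            windows[nid] = {s: wins[s] for s in sides}

    stages["linear_models"] = {
        "lm_mt": {"tested": len(lm_mt.results), "flagged": sorted(mt_flagged),
                  "skipped": lm_mt.skipped},
        "lm_tro_left": {"tested": len(tro_results["left"].results),
                        "flagged": sorted(diff_flagged["left"])},
        "lm_tro_right": {"tested": len(tro_results["right"].results),
                         "flagged": sorted(diff_flagged["right"])},
        "lm_diff": {"tested": len(lm_diff.results),
                    "flagged": sorted(diff_flagged_any)},
        "difficulty_neurons": {str(n): sorted(s)
                               for n, s in difficulty_sides.items()},
    }

    # ---- HMM switch decoding -------------------------------------------
    hmm_spec = dataclasses.replace(config.hmm, seed=seed)
    hmm_targets = (session.neuron_ids if config.hmm_all_neurons
                   else sorted(difficulty_sides))
    analyses = {nid: analyze_neuron_switches(session, nid, hmm_spec)
                for nid in hmm_targets}
    hmm_reliable = {nid: a.reliable for nid, a in analyses.items()}
    stages["hmm"] = {
        "decoded": len(analyses),
        "reliable": sorted(n for n, ok in hmm_reliable.items() if ok),
        "failed_criteria": {str(n): a.failed_criteria
                            for n, a in analyses.items() if not a.reliable},
        "t90_ms": {str(n): {s: p.t90_ms for s, p in a.profiles.items()}
                   for n, a in analyses.items()},
    }

    # ---- mechanism tests ------------------------------------------------
    switch_tests, rate_tests, skipped_mech = {}, {}, {}
    binary_tests = {}
    rng = np.random.default_rng([seed, 97])
    for nid, analysis in analyses.items():
        if nid not in difficulty_sides:
            continue
        if analysis.reliable:
            try:
                switch_tests[nid] = switch_time_coding_test(analysis, session)
            except ValueError as exc:
                skipped_mech[nid] = f"switch test: {exc}"
            spans = {s: (w["span_ms"][0], w["rate_end_ms"])
                     for s, w in windows[nid].items()}
            try:
                rate_tests[nid] = rate_coding_test(analysis, session, spans)
            except ValueError as exc:
                skipped_mech.setdefault(nid, f"rate test: {exc}")
        by_trial = session.spikes_for(nid)
        for side, w in windows[nid].items():
            span = w["span_ms"]
            values = [mean_rate_in_window(by_trial[tid], span)
                      for tid in session.trial_ids
                      if tid in by_trial
                      and session.trials[tid].correct
                      and session.trials[tid].choice == side]
            if len(values) >= 8:
                binary_tests[(nid, side)] = delta_bic_test(
                    np.asarray(values), config.n_resamples,
                    rng=np.random.default_rng([seed, 97, nid,
                                               0 if side == "left" else 1]),
                    n_restarts=config.mixture_restarts)

    # ---- classification -------------------------------------------------
    cls, counts = classify_population(
        mt_flagged, difficulty_sides, hmm_reliable,
        switch_tests, rate_tests, binary_tests, q=config.q_mechanism)
    stages["mechanisms"] = {
        "switch_tests": {str(n): {"tau": t.statistic, "p": t.p_value,
                                  "n": t.n}
                         for n, t in switch_tests.items()},
        "rate_tests": {str(n): {"tau": t.statistic, "p": t.p_value, "n": t.n}
                       for n, t in rate_tests.items()},
        "binary_tests": {f"{n}:{s}": {"delta_bic": c.delta_bic,
                                      "p": c.p_value}
                         for (n, s), c in binary_tests.items()},
        "skipped": {str(n): r for n, r in skipped_mech.items()},
    }
    stages["classification"] = {
        "flags": {str(n): sorted(c.flags) for n, c in cls.items()},
        "intersection_counts": counts,
    }

    if session.ground_truth is not None:
        stages["ground_truth_confusion"] = _confusion(session, cls)

    report = make_report(stages, config)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


_DESIGNATED_FLAG = {"mt_code": "mt_code", "switch_time": "switch_time_code",
                    "rate_code": "rate_code", "binary": "binary_any_side"}


def _confusion(session: Session, cls) -> dict:
    """Per-mechanism recall against generator ground truth."""
    out: dict = {"per_class": {}, "null_false_flag_rate": None}
    mech_flags = {"mt_code", "switch_time_code", "rate_code",
                  "binary_any_side"}
    by_mech: dict[str, list[int]] = {}
    for nid, gt in session.ground_truth.items():
        by_mech.setdefault(gt["mechanism"], []).append(nid)
    for mech, nids in sorted(by_mech.items()):
        if mech == "null":
            hits = sum(1 for n in nids
                       if n in cls and (cls[n].flags & mech_flags))
            out["null_false_flag_rate"] = hits / len(nids)
            out["per_class"]["null"] = {"n": len(nids), "flagged": hits}
            continue
        flag = _DESIGNATED_FLAG[mech]
        hits = sum(1 for n in nids if n in cls and flag in cls[n].flags)
        out["per_class"][mech] = {"n": len(nids), "recall": hits / len(nids)}
    return out


def make_report(stage_outputs: dict,
                config: Optional[PipelineConfig] = None) -> dict:
    """Assemble the versioned machine-readable report."""
    if not stage_outputs:
        raise ValueError("need at least one stage output")
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict() if config is not None else None,
        "stages": stage_outputs,
    }
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
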