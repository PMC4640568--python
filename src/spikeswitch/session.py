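"""On-disk session format and validated in-memory session model.

A *session* is one recording day: a table of completed behavioral trials and
the saccade-aligned spike trains of every simultaneously recorded neuron.
All analysis stages consume this container; synthetic sessions additionally
carry per-neuron ground-truth labels.

Time convention: saccade onset is t = 0 ms; negative times precede the
saccade (the test bar appears near -510 ms). Session files store the raw
session-clock saccade time per trial so that unaligned data can be aligned
on read.

Disk layout (one directory, UTF-8 CSV with header rows, '.' decimals)::

    trials.csv        trial_id, s1_deg, s2_deg, tro_deg, choice, correct,
                      mt_ms, saccade_ms
    spikes.csv        neuron_id, trial_id, spike_ms   (one row per spike)
    meta.json         {"epoch_ms": [start, end], ...}
    ground_truth.csv  neuron_id, mechanism, params    (optional; params is
                      a JSON string)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "SpikeTrain",
    "Session",
    "ValidationReport",
    "read_session",
    "write_session",
    "validate_session",
]

#: duplicate spikes closer than this (ms) are collapsed on construction
SPIKE_DEDUP_MS = 1e-6


@dataclass
class TrialRecord:
    """One completed behavioral trial.

    ``tro_deg`` is the test relative orientation TRO = s2 - s1 (degrees);
    negative TRO maps to the left target under this package's fixed sign
    convention.  ``mt_ms`` is the movement time in (0, 1200] ms.
    """

    trial_id: int
    s1_deg: float
    s2_deg: float
    tro_deg: float
    choice: str  # "left" | "right"
    correct: bool
    mt_ms: float
    saccade_ms: float = 0.0


@dataclass
class SpikeTrain:
    """Saccade-aligned spike times (ms) of one neuron on one trial."""

    neuron_id: int
    trial_id: int
    spike_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_ms, dtype=float)
        t = np.sort(t)
        if t.size > 1:
            keep = np.concatenate([[True], np.diff(t) > SPIKE_DEDUP_MS])
            t = t[keep]
        self.spike_ms = t


@dataclass
class Session:
    """Validated container binding trials, spike trains and metadata.

    ``ground_truth`` maps neuron_id -> {"mechanism": str, "params": dict}
    for synthetic sessions; the params dict may carry per-trial true switch
    times under the key ``"switch_ms"``.
    """

    trials: dict[int, TrialRecord]
    spikes: list[SpikeTrain]
    epoch_ms: tuple[float, float] = (-1000.0, 100.0)
    ground_truth: Optional[dict[int, dict]] = None
    meta: dict = field(default_factory=dict)

    @property
    def neuron_ids(self) -> list[int]:
        return sorted({s.neuron_id for s in self.spikes})

    @property
    def trial_ids(self) -> list[int]:
        return sorted(self.trials)

    def spikes_for(self, neuron_id: int) -> dict[int, SpikeTrain]:
        """Spike trains of one neuron keyed by trial_id."""
        return {s.trial_id: s for s in self.spikes if s.neuron_id == neuron_id}

    def trials_df(self) -> pd.DataFrame:
        rows = [vars(t) for t in (self.trials[k] for k in self.trial_ids)]
        return pd.DataFrame(
            rows,
            columns=[
                "trial_id", "s1_deg", "s2_deg", "tro_deg",
                "choice", "correct", "mt_ms", "saccade_ms",
            ],
        )


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


class SessionFormatError(ValueError):
    """A session directory is missing files or malformed."""


def validate_session(session: Session) -> ValidationReport:
    """Check every session invariant; returns violations, never raises."""
    rep = ValidationReport()
    lo, hi = session.epoch_ms
    if not (lo <= -600.0 and hi >= 50.0):
        rep.add(f"epoch_ms {session.epoch_ms} does not cover [-600, +50]")
    for t in session.trials.values():
        tid = t.trial_id
        if abs(t.tro_deg - (t.s2_deg - t.s1_deg)) > 1e-9:
            rep.add(f"trial {tid}: tro_deg != s2_deg - s1_deg")
        if t.tro_deg == 0:
            rep.add(f"trial {tid}: tro_deg is 0")
        if not (0 < t.mt_ms <= 1200):
            rep.add(f"trial {tid}: mt_ms {t.mt_ms} outside (0, 1200]")
        if t.choice not in ("left", "right"):
            rep.add(f"trial {tid}: choice {t.choice!r} not left/right")
        else:
            expected = (t.tro_deg < 0) == (t.choice == "left")
            if bool(t.correct) != expected:
                rep.add(f"trial {tid}: correct flag inconsistent with "
                        f"TRO/choice sign convention")
    seen: set[tuple[int, int]] = set()
    for s in session.spikes:
        key = (s.neuron_id, s.trial_id)
        if key in seen:
            rep.add(f"duplicate spike train for neuron {s.neuron_id}, "
                    f"trial {s.trial_id}")
        seen.add(key)
        if s.trial_id not in session.trials:
            rep.add(f"spike train for neuron {s.neuron_id} references "
                    f"unknown trial {s.trial_id}")
        if s.spike_ms.size and (s.spike_ms[0] < lo or s.spike_ms[-1] > hi):
            rep.add(f"neuron {s.neuron_id} trial {s.trial_id}: spikes "
                    f"outside declared epoch {session.epoch_ms}")
    return rep


def write_session(session: Session, path: str | Path) -> None:
    """Write the directory layout; lossless round trip for valid sessions."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials_df().to_csv(path / "trials.csv", index=False)
    rows = []
    for s in sorted(session.spikes, key=lambda s: (s.neuron_id, s.trial_id)):
        for t in s.spike_ms:
            rows.append((s.neuron_id, s.trial_id, t))
    pd.DataFrame(rows, columns=["neuron_id", "trial_id", "spike_ms"]).to_csv(
        path / "spikes.csv", index=False, float_format="%.6f")
    meta = dict(session.meta)
    meta["epoch_ms"] = list(session.epoch_ms)
    # record which (neuron, trial) pairs exist so empty trains survive a round trip
    meta["spike_train_keys"] = [
        [s.neuron_id, s.trial_id]
        for s in sorted(session.spikes, key=lambda s: (s.neuron_id, s.trial_id))
    ]
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    if session.ground_truth is not None:
        gt_rows = [
            (nid, d.get("mechanism", ""), json.dumps(d.get("params", {}), sort_keys=True))
            for nid, d in sorted(session.ground_truth.items())
        ]
        pd.DataFrame(gt_rows, columns=["neuron_id", "mechanism", "params"]).to_csv(
            path / "ground_truth.csv", index=False)


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("trials.csv", "spikes.csv", "meta.json"):
        if not (path / fname).exists():
            raise SessionFormatError(f"missing {fname} in {path}")
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    epoch = tuple(float(v) for v in meta.pop("epoch_ms"))
    train_keys = meta.pop("spike_train_keys", None)

    tdf = pd.read_csv(path / "trials.csv")
    trials: dict[int, TrialRecord] = {}
    for row in tdf.itertuples(index=False):
        if row.mt_ms <= 0:
            raise SessionFormatError(
                f"trial {row.trial_id}: non-positive mt_ms {row.mt_ms}")
        trials[int(row.trial_id)] = TrialRecord(
            trial_id=int(row.trial_id), s1_deg=float(row.s1_deg),
            s2_deg=float(row.s2_deg), tro_deg=float(row.tro_deg),
            choice=str(row.choice), correct=bool(row.correct),
            mt_ms=float(row.mt_ms), saccade_ms=float(row.saccade_ms))

    sdf = pd.read_csv(path / "spikes.csv")
    grouped: dict[tuple[int, int], list[float]] = {}
    if train_keys is not None:
        for nid, tid in train_keys:
            grouped[(int(nid), int(tid))] = []
    for row in sdf.itertuples(index=False):
        key = (int(row.neuron_id), int(row.trial_id))
        grouped.setdefault(key, []).append(float(row.spike_ms))
    spikes = []
    for (nid, tid), times in sorted(grouped.items()):
        if tid not in trials:
            raise SessionFormatError(
                f"spike train (neuron {nid}) references unknown trial {tid}")
        spikes.append(SpikeTrain(nid, tid, np.asarray(times)))

    ground_truth = None
    gt_path = path / "ground_truth.csv"
    if gt_path.exists():
        # keep_default_na: the mechanism name "null" is a real label
        gdf = pd.read_csv(gt_path, keep_default_na=False)
        ground_truth = {}
        for row in gdf.itertuples(index=False):
            params = json.loads(row.params)
            # JSON object keys are strings; per-trial switch maps are keyed by id
            if "switch_ms" in params and isinstance(params["switch_ms"], dict):
                params["switch_ms"] = {
                    int(k): v for k, v in params["switch_ms"].items()}
            ground_truth[int(row.neuron_id)] = {
                "mechanism": str(row.mechanism),
                "params": params,
            }
    return Session(trials=trials, spikes=spikes, epoch_ms=epoch,
                   ground_truth=ground_truth, meta=meta)
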