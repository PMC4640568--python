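"""Psychometric and chronometric behavioral summaries.

The psychometric table gives the empirical probability of choosing the
left target at each test relative orientation (TRO). The chronometric
analysis splits trials into four cells, {TRO < 0, TRO > 0} x {correct,
error}, and correlates movement time with signed TRO within each cell
(Pearson). With the X-shaped pattern — MT falling with trial ease on
correct trials and rising on error trials — the expected signs are
(+, -, -, +) for (TRO<0 correct, TRO>0 correct, TRO<0 error, TRO>0 error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session, TrialRecord

__all__ = ["CellCorrelation", "psychometric_table", "mt_tro_correlations",
           "CHRONOMETRIC_CELLS"]

CHRONOMETRIC_CELLS = (
    ("tro_neg", "correct"), ("tro_pos", "correct"),
    ("tro_neg", "error"), ("tro_pos", "error"),
)


@dataclass
class CellCorrelation:
    r: float
    p_value: float
    n: int


def _trials(session_or_trials) -> list[TrialRecord]:
    if isinstance(session_or_trials, Session):
        s = session_or_trials
        return [s.trials[k] for k in s.trial_ids]
    return list(session_or_trials)


def psychometric_table(session_or_trials) -> pd.DataFrame:
    """P(choice = left) by TRO level with binomial standard errors."""
    trials = _trials(session_or_trials)
    rows = []
    for tro in sorted({t.tro_deg for t in trials}):
        sub = [t for t in trials if t.tro_deg == tro]
        n = len(sub)
        p = sum(t.choice == "left" for t in sub) / n
        rows.append((tro, n, p, np.sqrt(p * (1 - p) / n)))
    return pd.DataFrame(rows, columns=["tro_deg", "n_trials", "p_left", "se"])


def mt_tro_correlations(session_or_trials
                        ) -> dict[tuple[str, str], Optional[CellCorrelation]]:
    """Pearson MT ~ signed TRO within each of the four sign/outcome cells.

    Cells with fewer than 3 trials or fewer than 2 distinct TRO values are
    reported as None.
    """
    trials = _trials(session_or_trials)
    out: dict[tuple[str, str], Optional[CellCorrelation]] = {}
    for sign_key, outcome_key in CHRONOMETRIC_CELLS:
        sub = [t for t in trials
               if (t.tro_deg < 0 if sign_key == "tro_neg" else t.tro_deg > 0)
               and (t.correct if outcome_key == "correct" else not t.correct)]
        tro = np.array([t.tro_deg for t in sub])
        mt = np.array([t.mt_ms for t in sub])
        if tro.size < 3 or np.unique(tro).size < 2 or np.unique(mt).size < 2:
            out[(sign_key, outcome_key)] = None
            continue
        r, p = stats.pearsonr(tro, mt)
        out[(sign_key, outcome_key)] = CellCorrelation(float(r), float(p),
                                                       int(tro.size))
    return out
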