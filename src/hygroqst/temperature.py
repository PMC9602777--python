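"""Weighted mean skin temperature and session-window summaries.

Whole-body mean skin temperature (mean Tsk) is estimated from six local
thermistors with fixed regional weights::

    mean Tsk = 0.14 cheek + 0.19 chest + 0.11 forearm
             + 0.05 hand  + 0.32 thigh + 0.19 back

Because the weighting is linear, averaging mean Tsk per sample over a
window equals weighting the per-channel window averages; this module
computes it per sample.  Sessions last 50 min; the sensory test occupies
the final 15 min, so the default analysis window is [2100, 3000) s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (SKIN_CHANNELS, DataError, Group, Participant,
                         Session, TemperatureSample)

logger = logging.getLogger(__name__)

__all__ = ["TSK_WEIGHTS", "MissingChannelError", "SessionWindowSummary",
           "mean_tsk", "window_average", "summarize_sessions",
           "session_group_summary", "DEFAULT_WINDOW_S"]

#: Regional weights of the six-site mean skin temperature equation.
TSK_WEIGHTS: Dict[str, float] = {
    "cheek": 0.14,
    "chest": 0.19,
    "forearm": 0.11,
    "hand": 0.05,
    "thigh": 0.32,
    "back": 0.19,
}
assert abs(sum(TSK_WEIGHTS.values()) - 1.0) < 1e-12

#: Final 15 min of a 50-min session, [start, end) in seconds.
DEFAULT_WINDOW_S: Tuple[float, float] = (2100.0, 3000.0)


class MissingChannelError(DataError):
    pass


@dataclass
class SessionWindowSummary:
    participant_id: str
    session: Session
    mean_tsk: float    # degC, window average of the weighted mean
    mean_trec: float   # degC, window average of rectal temperature
    n_samples: int
    window: Tuple[float, float]


def mean_tsk(sample, weights: Optional[Mapping[str, float]] = None) -> float:
    """Weighted mean skin temperature of one sample (degC).

    ``sample`` is a :class:`TemperatureSample` or a mapping of the six
    channel names to temperatures.  The result is a convex combination,
    hence always within [min, max] of the channels.
    """
    if weights is None:
        weights = TSK_WEIGHTS
    channels = sample.channels() if isinstance(sample, TemperatureSample) else sample
    total = 0.0
    for name in SKIN_CHANNELS:
        if name not in channels or channels[name] is None:
            raise MissingChannelError(f"missing skin channel {name!r}")
        total += weights[name] * channels[name]
    return total


def window_average(series: Sequence[TemperatureSample],
                   window: Tuple[float, float] = DEFAULT_WINDOW_S,
                   weights: Optional[Mapping[str, float]] = None) -> SessionWindowSummary:
    """Average mean Tsk and rectal temperature over [start, end).

    Missing samples are not interpolated; gaps simply reduce ``n_samples``.
    """
    start, end = window
    inside = [s for s in series if start <= s.time < end]
    if not inside:
        raise DataError(f"no samples inside window [{start}, {end})")
    pid = inside[0].participant_id
    session = inside[0].session
    tsk = float(np.mean([mean_tsk(s, weights) for s in inside]))
    trec = float(np.mean([s.rectal for s in inside]))
    return SessionWindowSummary(participant_id=pid, session=session,
                                mean_tsk=tsk, mean_trec=trec,
                                n_samples=len(inside), window=(start, end))


def summarize_sessions(temperatures: Iterable[TemperatureSample],
                       window: Tuple[float, float] = DEFAULT_WINDOW_S) -> pd.DataFrame:
    """One row per (participant, session) with window-averaged mean Tsk / Trec."""
    by_key: Dict[tuple, list] = {}
    for t in temperatures:
        by_key.setdefault((t.participant_id, t.session), []).append(t)
    rows = []
    for (pid, session), series in sorted(by_key.items(), key=lambda kv: (kv[0][0], kv[0][1].name)):
        s = window_average(series, window)
        rows.append({"participant_id": pid, "session": str(session),
                     "mean_tsk_c": s.mean_tsk, "mean_trec_c": s.mean_trec,
                     "n_samples": s.n_samples})
    return pd.DataFrame(rows)


def session_group_summary(summaries: pd.DataFrame,
                          participants: Sequence[Participant],
                          response: str = "mean_tsk_c",
                          conf: float = 0.95):
    """Group x session means/SDs plus paired session contrasts.

    ``summaries`` is the frame from :func:`summarize_sessions`.  Contrasts
    are within-participant session differences pooled across groups, with
    a t-based confidence interval on n-1 degrees of freedom.  Participants
    missing a session are excluded from the paired contrasts with a
    logged warning.

    Returns ``(group_session_frame, contrasts_frame)``.
    """
    group_of = {p.id: str(p.group) for p in participants}
    df = summaries.copy()
    df["group"] = df["participant_id"].map(group_of)
    if df["group"].isna().any():
        unknown = df.loc[df["group"].isna(), "participant_id"].unique()
        raise DataError(f"summaries reference unknown participants {list(unknown)}")

    cells = (df.groupby(["group", "session"])[response]
               .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
               .reset_index())
    if (cells["n"] < 2).any():
        raise DataError("need >= 2 participants per (group, session) cell")

    wide = df.pivot(index="participant_id", columns="session", values=response)
    complete = wide.dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        logger.warning("excluding participants missing a session from paired contrasts: %s",
                       sorted(dropped))

    pairs = [("HEAT", "NEUTRAL"), ("COLD", "NEUTRAL"), ("HEAT", "COLD")]
    rows = []
    for a, b in pairs:
        if a not in complete.columns or b not in complete.columns:
            continue
        d = (complete[a] - complete[b]).to_numpy(dtype=float)
        n = d.size
        mean = d.mean()
        if n > 1 and d.std(ddof=1) > 0:
            se = d.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + conf / 2.0, n - 1)
            lo, hi = mean - tcrit * se, mean + tcrit * se
        else:
            lo = hi = mean
        rows.append({"comparison": f"{a} - {b}", "mean_difference": mean,
                     "ci_low": lo, "ci_high": hi, "n": n})
    return cells, pd.DataFrame(rows)
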