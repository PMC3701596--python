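"""Behavioural sleep scoring from beam-break activity.

Sleep is scored by the continuous-inactivity rule used with infrared
locomotor monitoring in mice: an epoch is asleep iff it belongs to a
maximal run of zero-count epochs spanning at least 40 s (inclusive).  Runs
truncated by the trace boundary count only their observed duration — no
extrapolation beyond the data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .study import ActivityTrace


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class SleepSeries:
    epoch_s: int
    is_sleep: np.ndarray

    def __post_init__(self):
        self.is_sleep = np.asarray(self.is_sleep, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return len(self.is_sleep)

    def total_sleep_s(self) -> int:
        return int(self.is_sleep.sum()) * self.epoch_s


def _zero_runs(counts: np.ndarray):
    """Yield (start, stop) index pairs of maximal zero runs."""
    zero = np.asarray(counts) == 0
    if not zero.any():
        return []
    padded = np.concatenate([[False], zero, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def score_sleep(trace: ActivityTrace, min_inactivity_s: int = 40) -> SleepSeries:
    """Score each epoch as sleep/wake by the continuous-inactivity rule.

    An epoch is sleep iff it lies in a maximal run of zero-count epochs
    whose total duration is ``>= min_inactivity_s`` (default 40 s).
    ``min_inactivity_s`` must be a positive multiple of the epoch length;
    anything else is a configuration error — there is no silent rounding.
    """
    if min_inactivity_s <= 0 or min_inactivity_s % trace.epoch_s != 0:
        raise ConfigError(
            f"min_inactivity_s={min_inactivity_s} must be a positive multiple "
            f"of epoch_s={trace.epoch_s}"
        )
    min_epochs = min_inactivity_s // trace.epoch_s
    is_sleep = np.zeros(trace.n_epochs, dtype=bool)
    for start, stop in _zero_runs(trace.counts):
        if stop - start >= min_epochs:
            is_sleep[start:stop] = True
    return SleepSeries(epoch_s=trace.epoch_s, is_sleep=is_sleep)


def percent_sleep(series: SleepSeries, window_h: float) -> pd.DataFrame:
    """Percentage of each consecutive window spent asleep.

    Returns one row per window with ``window_start_h``, ``percent_sleep``
    (0-100) and ``complete``; a partial trailing window is reported with
    ``complete=False`` rather than silently dropped.
    """
    if window_h <= 0:
        raise ConfigError("window_h must be positive")
    win_epochs_f = window_h * 3600.0 / series.epoch_s
    win_epochs = int(round(win_epochs_f))
    if abs(win_epochs_f - win_epochs) > 1e-9 or win_epochs == 0:
        raise ConfigError(
            f"window of {window_h} h is not a whole number of "
            f"{series.epoch_s}-s epochs"
        )
    rows = []
    for start in range(0, series.n_epochs, win_epochs):
        chunk = series.is_sleep[start:start + win_epochs]
        rows.append({
            "window_start_h": start * series.epoch_s / 3600.0,
            "percent_sleep": 100.0 * float(chunk.mean()),
            "complete": len(chunk) == win_epochs,
        })
    return pd.DataFrame(rows)
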