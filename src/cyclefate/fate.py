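"""CDK2 activity and proliferation/quiescence fate calls.

CDK2 activity is the cytoplasm/nucleus ratio of the DHB sensor signal.  The
binary rule calls a daughter quiescent when the smoothed ratio stays below a
threshold (default 0.8) for a contiguous interval longer than a minimum
window (default 10 h); otherwise the cell is proliferating.  The three-state
scheme additionally distinguishes G1 arrest: the ratio shows a sustained
increase but the Cdt1 reporter never completes its G1 peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .phases import rolling_slope, smooth_trace

NUC_FLOOR = 1e-6


@dataclass
class FateParams:
    ratio_threshold: float = 0.8
    min_window: float = 10.0  # hours
    cdt1_peak_fraction: float = 0.9
    smooth_window: int = 5
    #: minimum duration (h) of a positive rolling slope counting as a
    #: "sustained increase" of CDK2 activity
    rise_window: float = 2.0
    #: slope floor (ratio units per hour) below which a trend is noise
    slope_eps: float = 0.01
    #: "interval": longest contiguous sub-threshold interval (default);
    #: "global": mean over the whole track compared to the threshold
    mean_mode: str = "interval"

    def __post_init__(self):
        if self.ratio_threshold <= 0 or self.min_window <= 0:
            raise ValueError("ratio_threshold and min_window must be positive")
        if not 0 < self.cdt1_peak_fraction <= 1:
            raise ValueError("cdt1_peak_fraction must be in (0, 1]")
        if self.mean_mode not in ("interval", "global"):
            raise ValueError("mean_mode must be 'interval' or 'global'")


@dataclass
class FateCall:
    cell_id: str
    binary: str  # quiescent | proliferative | indeterminate
    three_state: str  # quiescent | G1_arrest | proliferative | indeterminate
    longest_subthreshold_h: float
    reached_cdt1_peak: Optional[bool]
    censored: bool = False
    flags: list = None

    def __post_init__(self):
        if self.flags is None:
            self.flags = []


def cdk2_activity(nuc_trace, cyt_trace, floor: float = NUC_FLOOR):
    """Elementwise Cyt/Nuc sensor ratio; near-zero nuclear frames are masked."""
    nuc = np.asarray(nuc_trace, dtype=float)
    cyt = np.asarray(cyt_trace, dtype=float)
    if nuc.shape != cyt.shape:
        raise ValueError("nuclear and cytoplasmic traces differ in length")
    ratio = np.full(nuc.shape, np.nan)
    ok = nuc > floor
    ratio[ok] = cyt[ok] / nuc[ok]
    return ratio


def _longest_true_run_hours(mask, times):
    """Duration (h) spanned by the longest contiguous True run."""
    best = 0.0
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            best = max(best, times[i - 1] - times[start])
            start = None
    if start is not None:
        best = max(best, times[-1] - times[start])
    return float(best)


def _cdt1_reached_peak(cdt1, times, fraction, reference=None):
    """Whether Cdt1 completed its G1 apex.

    With an external ``reference`` level the trace maximum is compared to
    ``fraction * reference``.  Without one, a completed peak is recognised as
    an interior maximum followed by a sustained decline (the rise-then-fall
    of a finished G1), since a per-cell maximum alone is trivially attained.
    """
    cdt1 = np.asarray(cdt1, dtype=float)
    if reference is not None:
        return bool(np.max(cdt1) >= fraction * reference)
    sm = smooth_trace(cdt1, 5)
    i = int(np.argmax(sm))
    if i >= len(sm) - 2:
        return False
    return bool(np.min(sm[i:]) < sm[i] * (1.0 - (1.0 - fraction)))


def classify_fate(
    ratio_trace,
    times,
    cdt1_trace=None,
    params: FateParams | None = None,
    cdt1_reference: Optional[float] = None,
    cell_id: str = "",
) -> FateCall:
    """Binary and three-state fate call from a CDK2 ratio trace.

    The trace is evaluated from cell birth (first sample).  Tracks spanning
    less than ``min_window`` are returned indeterminate.
    """
    params = params or FateParams()
    ratio = np.asarray(ratio_trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(ratio) != len(times):
        raise ValueError("ratio and time vectors differ in length")
    span = times[-1] - times[0] if len(times) else 0.0
    if span < params.min_window:
        return FateCall(
            cell_id,
            "indeterminate",
            "indeterminate",
            np.nan,
            None,
            censored=True,
            flags=["track shorter than min_window"],
        )

    ok = np.isfinite(ratio)
    sm = np.full(len(ratio), np.nan)
    if ok.any():
        sm[ok] = smooth_trace(ratio[ok], params.smooth_window)

    if params.mean_mode == "global":
        quiescent = bool(np.nanmean(sm) < params.ratio_threshold)
        longest = span if quiescent else 0.0
    else:
        below = ok & (sm < params.ratio_threshold)
        longest = _longest_true_run_hours(below, times)
        quiescent = longest > params.min_window

    # sustained increase of the smoothed ratio (rolling slope positive for
    # >= rise_window hours)
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    w = max(int(round(params.rise_window / dt)) | 1, 3)
    slopes = rolling_slope(np.nan_to_num(sm, nan=np.nanmean(sm)), times, w)
    rising = _longest_true_run_hours(slopes > params.slope_eps, times) >= (
        params.rise_window - dt / 2
    )

    reached = (
        _cdt1_reached_peak(cdt1_trace, times, params.cdt1_peak_fraction, cdt1_reference)
        if cdt1_trace is not None
        else None
    )

    if quiescent:
        three = "quiescent" if not rising else "G1_arrest"
    else:
        if reached is False:
            three = "G1_arrest"
        else:
            three = "proliferative"

    binary = "quiescent" if quiescent else "proliferative"
    censored = False
    return FateCall(cell_id, binary, three, longest, reached, censored)


def cohort_fate_fractions(calls, grouping=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group quiescent fraction with a binomial confidence interval.

    ``grouping`` maps cell_id -> group label (or None for a single pooled
    group).  Indeterminate calls are excluded; empty groups are omitted with
    a warning.
    """
    calls = list(calls)
    groups: dict[str, list] = {}
    for c in calls:
        if c.binary == "indeterminate":
            continue
        g = grouping.get(c.cell_id, "all") if grouping else "all"
        groups.setdefault(g, []).append(c)
    if grouping:
        for g in set(grouping.values()) - set(groups):
            warnings.warn(f"group {g!r} empty after excluding indeterminate calls",
                          stacklevel=2)
    rows = []
    for g in sorted(groups):
        cs = groups[g]
        n = len(cs)
        k = sum(1 for c in cs if c.binary == "quiescent")
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=1 - alpha)
        rows.append(
            {
                "group": g,
                "n": n,
                "n_quiescent": k,
                "frac_quiescent": k / n,
                "frac_proliferative": (n - k) / n,
                "ci_low": ci.low,
                "ci_high": ci.high,
            }
        )
    return pd.DataFrame(rows)
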