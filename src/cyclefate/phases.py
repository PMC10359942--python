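"""Per-frame cell-cycle phase labels and phase durations from Fucci4 traces.

The segmentation rules follow the reporter logic of the four-color Fucci
system: G1 shows high or rising Cdt1 with low Geminin; the G1/S transition
coincides with the Cdt1 apex and the onset of Geminin accumulation; S ends at
the SLBP peak; G2 spans SLBP peak to the Geminin peak / mitotic entry; M is
marked by an abrupt change in the histone (H1) reporter pattern and ends at
division.  Intervals are half-open [start, end): a boundary frame belongs to
the later phase.  Phases cut by the observation window are flagged truncated
and excluded from duration summaries (untruncated G1 requires an observed
birth, untruncated M an observed division).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import ReporterTrack

PHASE_ORDER = ("G1", "S", "G2", "M")
UNDETERMINED = "undetermined"

#: robust per-cell maximum: resists single-frame spikes
ROBUST_MAX_PERCENTILE = 98.0
#: "low Geminin" threshold as a fraction of the cell's Geminin maximum
LOW_GEMININ_FRACTION = 0.20
#: H1 mitotic signature: raw level above this multiple of the pre-mitotic
#: median marks chromatin condensation
H1_SIGNATURE_FACTOR = 1.4


def smooth_trace(values, window: int = 5):
    """Centered moving average; ends handled by shrinking the window."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot smooth an empty trace")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return values.copy()
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def detect_peak(values, times, smooth_window: int = 1):
    """Time and value of the global maximum (ties -> earliest).

    Returns ``(peak_time, peak_value, flag)`` with ``flag`` "ok" or
    "no peak" for an all-equal trace.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 samples to detect a peak")
    sm = smooth_trace(values, smooth_window)
    if np.ptp(sm) == 0:
        return times[0], float(sm[0]), "no peak"
    i = int(np.argmax(sm))
    return float(times[i]), float(sm[i]), "ok"


def _robust_norm(values):
    m = np.percentile(values, ROBUST_MAX_PERCENTILE)
    if m <= 0:
        return np.zeros_like(values), 0.0
    return values / m, m


def _interior_peak(sm, idx, margin, decline=0.10):
    """True if the argmax is away from the trace ends and followed by a
    sustained decline (a real apex rather than a monotone rise cut short)."""
    n = len(sm)
    if idx < margin or idx >= n - margin:
        return False
    peak = sm[idx]
    return np.min(sm[idx:]) < peak * (1.0 - decline)


def rolling_slope(values, times, window: int = 5):
    """Least-squares slope of ``values`` vs ``times`` over a centered rolling
    window (shrunk at the ends)."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half, n - 1) + 1
        t = times[lo:hi]
        v = values[lo:hi]
        tc = t - t.mean()
        denom = (tc**2).sum()
        out[i] = (tc * v).sum() / denom if denom > 0 else 0.0
    return out


@dataclass
class PhaseAnnotation:
    """Per-frame phase labels, boundary times and per-phase durations."""

    cell_id: str
    times: np.ndarray
    labels: np.ndarray
    boundaries: dict = field(default_factory=dict)  # t_G1S, t_SG2, t_G2M, t_div
    durations: dict = field(default_factory=dict)  # d_G1 .. d_M (NaN if unknown)
    truncated: dict = field(default_factory=dict)  # per-phase flags
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "time_h": self.times, "phase": self.labels}
        )


def _all_g1_annotation(track, cdt1_norm, gem_norm, flags):
    """Fallback: no resolvable boundaries; frames with G1-like reporter state
    are labelled G1, everything downstream is truncated."""
    labels = np.full(len(track.times), UNDETERMINED, dtype=object)
    g1_like = (gem_norm < LOW_GEMININ_FRACTION) | (np.ptp(gem_norm) == 0)
    labels[g1_like] = "G1"
    return PhaseAnnotation(
        track.cell_id,
        track.times,
        labels,
        boundaries={"t_G1S": np.nan, "t_SG2": np.nan, "t_G2M": np.nan, "t_div": np.nan},
        durations={p: np.nan for p in ("d_G1", "d_S", "d_G2", "d_M")},
        truncated={p: True for p in PHASE_ORDER},
        flags=flags,
    )


def call_phases(
    track: ReporterTrack,
    division_time: Optional[float] = None,
    observation_end: Optional[float] = None,
    smooth_window: int = 5,
    birth_observed: bool = True,
) -> PhaseAnnotation:
    """Segment one track into G1/S/G2/M.

    ``division_time`` (e.g. from a lineage table) is authoritative when
    given; otherwise division is inferred from the H1 mitotic signature at
    the end of a track that stops before ``observation_end``.
    """
    for ch in ("Cdt1", "Geminin", "SLBP", "H1"):
        if ch not in track.channels:
            raise ValueError(f"track {track.cell_id}: missing channel {ch!r}")
    times = track.times
    if len(times) < 8:
        raise ValueError(f"track {track.cell_id}: need >= 8 frames")
    dt = float(times[1] - times[0])
    flags: list = []

    cdt1_n, _ = _robust_norm(np.asarray(track.channels["Cdt1"], dtype=float))
    gem_n, gem_max = _robust_norm(np.asarray(track.channels["Geminin"], dtype=float))
    slbp_n, _ = _robust_norm(np.asarray(track.channels["SLBP"], dtype=float))
    h1 = np.asarray(track.channels["H1"], dtype=float)

    cdt1_s = smooth_trace(cdt1_n, smooth_window)
    gem_s = smooth_trace(gem_n, smooth_window)
    slbp_s = smooth_trace(slbp_n, smooth_window)

    margin = max(smooth_window // 2, 1)

    # Geminin dynamic range: a silent Geminin channel means the cell never
    # left G1 within the observation window.
    gem_active = np.ptp(gem_s) > 0 and np.max(gem_s) > 4 * np.median(
        np.abs(np.diff(gem_s))
    ) and np.max(gem_s) > 2.5 * np.min(gem_s)
    i_cdt1 = int(np.argmax(cdt1_s))
    if i_cdt1 == 0 and _interior_peak(cdt1_n, int(np.argmax(cdt1_n)), 1):
        # a 1-2 frame G1: the shrinking-window average at the track edge can
        # overtake a genuine apex right after birth; fall back to the raw trace
        i_cdt1 = int(np.argmax(cdt1_n))
    # margin 1, not the smoothing half-window: a short G1 (a few frames) still
    # produces a genuine apex right after birth
    if not gem_active or not _interior_peak(cdt1_s, i_cdt1, 1) and not (
        i_cdt1 == int(np.argmax(cdt1_n)) and _interior_peak(cdt1_n, i_cdt1, 1)
    ):
        flags.append("no G1/S transition detected")
        return _all_g1_annotation(track, cdt1_n, gem_n, flags)

    t_g1s = float(times[i_cdt1])

    # S/G2 boundary: SLBP peak after the G1/S transition
    i_slbp = int(np.argmax(slbp_s))
    if not _interior_peak(slbp_s, i_slbp, margin) or times[i_slbp] <= t_g1s:
        flags.append("unresolvable ordering: SLBP peak not after Cdt1 peak")
        return _all_g1_annotation(track, cdt1_n, gem_n, flags)
    t_sg2 = float(times[i_slbp])

    # G2/M boundary: histone signature preferred, Geminin peak as fallback.
    pre = h1[times < t_sg2]
    h1_med = np.median(pre) if len(pre) else np.median(h1)
    sig = (h1 > H1_SIGNATURE_FACTOR * h1_med) & (times > t_sg2)
    t_g2m_h1 = float(times[np.argmax(sig)]) if sig.any() else np.nan
    i_gem = int(np.argmax(gem_s))
    t_g2m_gem = (
        float(times[i_gem])
        if _interior_peak(gem_s, i_gem, margin) and times[i_gem] > t_sg2
        else np.nan
    )
    t_g2m = t_g2m_h1 if np.isfinite(t_g2m_h1) else t_g2m_gem

    # division: recorded event > end-of-track H1 signature
    if division_time is not None:
        t_div = float(division_time)
        m_truncated = False
    elif np.isfinite(t_g2m) and sig[-1] and (
        observation_end is None or times[-1] < observation_end - dt / 2
    ):
        # track ends mid-signature before the window closes -> cell divided
        t_div = float(times[-1] + dt)
        m_truncated = False
        flags.append("division inferred from H1 signature")
    else:
        t_div = np.nan
        m_truncated = True
        flags.append("no recorded division; M (and later) truncated")

    if not np.isfinite(t_g2m):
        flags.append("no G2/M boundary (no H1 signature or Geminin peak)")
        t_g2m = np.nan

    order = [t_g1s, t_sg2, t_g2m, t_div]
    finite = [b for b in order if np.isfinite(b)]
    if any(b2 < b1 - 1e-9 for b1, b2 in zip(finite, finite[1:])):
        flags.append("unresolvable boundary ordering")
        return _all_g1_annotation(track, cdt1_n, gem_n, flags)

    labels = np.full(len(times), UNDETERMINED, dtype=object)
    labels[times < t_g1s] = "G1"
    labels[(times >= t_g1s) & (times < t_sg2)] = "S"
    if np.isfinite(t_g2m):
        labels[(times >= t_sg2) & (times < t_g2m)] = "G2"
        m_end = t_div if np.isfinite(t_div) else times[-1] + dt
        labels[(times >= t_g2m) & (times < m_end)] = "M"
    else:
        labels[times >= t_sg2] = "G2"

    birth = float(times[0])
    truncated = {
        "G1": not birth_observed,
        "S": False,
        "G2": not np.isfinite(t_g2m),
        "M": m_truncated or not np.isfinite(t_g2m),
    }
    durations = {
        "d_G1": t_g1s - birth if not truncated["G1"] else np.nan,
        "d_S": t_sg2 - t_g1s,
        "d_G2": t_g2m - t_sg2 if np.isfinite(t_g2m) else np.nan,
        "d_M": t_div - t_g2m
        if np.isfinite(t_div) and np.isfinite(t_g2m)
        else np.nan,
    }
    boundaries = {
        "t_G1S": t_g1s,
        "t_SG2": t_sg2,
        "t_G2M": t_g2m,
        "t_G2M_h1": t_g2m_h1,
        "t_G2M_geminin": t_g2m_gem,
        "t_div": t_div,
    }
    return PhaseAnnotation(
        track.cell_id, times, labels, boundaries, durations, truncated, flags
    )


def phase_duration_summary(annotations) -> pd.DataFrame:
    """Mean, SD and n of untruncated phase durations across a cohort."""
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotations supplied")
    rows = []
    for phase in PHASE_ORDER:
        key = f"d_{phase}"
        vals = np.array(
            [
                a.durations.get(key, np.nan)
                for a in annotations
                if not a.truncated.get(phase, True)
            ]
        )
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows.append(
                {
                    "phase": phase,
                    "mean_h": np.nan,
                    "sd_h": np.nan,
                    "n": 0,
                    "note": "no untruncated durations",
                }
            )
        else:
            rows.append(
                {
                    "phase": phase,
                    "mean_h": float(np.mean(vals)),
                    "sd_h": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "n": int(len(vals)),
                    "note": "",
                }
            )
    return pd.DataFrame(rows)
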