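"""Mitosis-anchored alignment and lineage-level statistics.

Includes mother-daughter p21 window-mean correlation (5-h windows on either
side of mitosis), the sibling p21 discrepancy statistic

    D = 2 * sum_i (x_i - y_i)^2 / (sum_i (x_i - xbar)^2 + sum_i (y_i - ybar)^2)

over a non-ordered sibling pair (0 for identical siblings; the complement
1 - D is reported as the resemblance R^2), sibling fate concordance counts,
and the binned relationship between a mother's time to mitosis and the
percentage of proliferating daughters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LineageParams:
    anchor_window_pre: float = 5.0  # hours before mitosis (mother side)
    anchor_window_post: float = 5.0  # hours after mitosis (daughter side)
    bin_width: float = 1.3  # hours, for time-to-mitosis binning

    def __post_init__(self):
        if min(self.anchor_window_pre, self.anchor_window_post, self.bin_width) <= 0:
            raise ValueError("all window/bin parameters must be positive")


@dataclass
class AnchoredTrack:
    cell_id: str
    role: str  # mother | daughter
    rel_times: np.ndarray  # 0 at the first division
    channels: dict


@dataclass
class SiblingPair:
    pair_id: str
    cell_a: str
    cell_b: str
    x: np.ndarray  # p21 series of sibling A over the common post-mitosis window
    y: np.ndarray
    fate_a: str = ""
    fate_b: str = ""
    group: str = ""

    @property
    def concordance(self) -> str:
        if "indeterminate" in (self.fate_a, self.fate_b):
            return "indeterminate"
        return "concordant" if self.fate_a == self.fate_b else "discordant"


def align_to_mitosis(tracks, lineage: pd.DataFrame):
    """Shift every track's time axis so the first division sits at 0.

    Mothers occupy negative time, daughters positive.  A mother's division
    time is taken from its daughters' lineage rows; cells without a recorded
    division are excluded and returned separately.
    """
    div_of_mother = (
        lineage.groupby("parent_id")["division_time_h"].first().to_dict()
        if len(lineage)
        else {}
    )
    birth_of_daughter = dict(zip(lineage["cell_id"], lineage["division_time_h"]))
    anchored, excluded = [], []
    for t in tracks:
        if t.cell_id in birth_of_daughter:
            anchor, role = birth_of_daughter[t.cell_id], "daughter"
        elif t.cell_id in div_of_mother:
            anchor, role = div_of_mother[t.cell_id], "mother"
        else:
            excluded.append(t.cell_id)
            continue
        anchored.append(
            AnchoredTrack(t.cell_id, role, t.times - anchor, dict(t.channels))
        )
    return anchored, excluded


def window_mean(rel_times, values, side: str, width: float) -> float:
    """Mean of samples in the pre-mitosis window [-width, 0) or the
    post-mitosis window (0, +width].  NaN when the window holds no sample."""
    rel_times = np.asarray(rel_times, dtype=float)
    values = np.asarray(values, dtype=float)
    if side == "pre":
        mask = (rel_times >= -width) & (rel_times < 0)
    elif side == "post":
        mask = (rel_times > 0) & (rel_times <= width)
    else:
        raise ValueError("side must be 'pre' or 'post'")
    mask &= np.isfinite(values)
    if not mask.any():
        return np.nan
    return float(values[mask].mean())


def mother_daughter_correlation(pre_means, post_means):
    """Pearson r (two-sided p) between mother pre- and daughter post-mitosis
    window means.  Pairs with a missing value are dropped."""
    x = np.asarray(pre_means, dtype=float)
    y = np.asarray(post_means, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "p": np.nan, "n": n, "flag": "zero variance"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": n, "flag": ""}


def sibling_discrepancy(x, y):
    """Sibling discrepancy D and its complement R2 = 1 - D.

    D is symmetric in (x, y) and invariant to a common additive shift and a
    common positive rescaling of both series.  Undefined (ValueError) when
    both series are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples per sibling")
    denom = np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)
    if denom == 0:
        raise ValueError("both series constant: discrepancy undefined")
    d = 2.0 * np.sum((x - y) ** 2) / denom
    return float(d), float(1.0 - d)


def pooled_sibling_discrepancy(pairs):
    """Group-level D/R2 obtained by concatenating all pair series."""
    xs = np.concatenate([np.asarray(p.x, dtype=float) for p in pairs])
    ys = np.concatenate([np.asarray(p.y, dtype=float) for p in pairs])
    return sibling_discrepancy(xs, ys)


def concordance_table(pairs) -> pd.DataFrame:
    """Concordant/discordant sibling-pair counts per mother-stage group.

    Pairs with an indeterminate fate are excluded and counted separately.
    """
    rows: dict[str, dict] = {}
    for p in pairs:
        g = p.group or "all"
        row = rows.setdefault(
            g, {"group": g, "concordant": 0, "discordant": 0, "excluded": 0}
        )
        c = p.concordance
        if c == "indeterminate":
            row["excluded"] += 1
        else:
            row[c] += 1
    out = pd.DataFrame(sorted(rows.values(), key=lambda r: r["group"]))
    if len(out):
        out["n_pairs"] = out["concordant"] + out["discordant"]
    return out


def proliferation_vs_time(
    time_to_mitosis,
    daughter_proliferative,
    bin_width: float = 1.3,
    min_mothers_per_bin: int = 2,
):
    """Percentage of proliferating daughters vs the mother's time to mitosis.

    Mothers are binned by time-to-first-mitosis into right-open bins of
    ``bin_width`` hours starting at 0; per bin the percentage of
    proliferating daughters is computed, and a Pearson correlation across
    bin centers is reported with its sign.  Bins with fewer than
    ``min_mothers_per_bin`` mothers are dropped from the correlation.

    Parameters are parallel sequences: one entry per daughter, carrying the
    mother's time to mitosis and whether that daughter proliferated.
    """
    ttm = np.asarray(time_to_mitosis, dtype=float)
    prolif = np.asarray(daughter_proliferative, dtype=bool)
    if len(ttm) != len(prolif):
        raise ValueError("inputs differ in length")
    idx = np.floor(ttm / bin_width).astype(int)
    rows = []
    for b in sorted(set(idx)):
        sel = idx == b
        n_mothers = len(np.unique(ttm[sel]))
        rows.append(
            {
                "bin_center_h": (b + 0.5) * bin_width,
                "n_daughters": int(sel.sum()),
                "n_mothers": n_mothers,
                "pct_proliferating": 100.0 * prolif[sel].mean(),
            }
        )
    table = pd.DataFrame(rows)
    usable = table[table["n_mothers"] >= min_mothers_per_bin]
    if len(usable) < 2 or np.ptp(usable["pct_proliferating"].to_numpy()) == 0:
        return table, {"r": np.nan, "p": np.nan, "n_bins": len(usable),
                       "flag": "correlation undefined"}
    r, p = stats.pearsonr(usable["bin_center_h"], usable["pct_proliferating"])
    return table, {"r": float(r), "p": float(p), "n_bins": len(usable), "flag": ""}


# ---------------------------------------------------------------------------
# cohort-level assembly helpers


def sibling_pairs_from_cohort(
    cohort,
    fate_by_cell: Optional[dict] = None,
    params: LineageParams | None = None,
    channel: str = "p21",
):
    """Build :class:`SiblingPair` records with post-mitosis window series.

    ``fate_by_cell`` maps cell_id -> binary fate; when omitted the
    simulator's ground-truth fate is used.
    """
    params = params or LineageParams()
    by_id = {t.cell_id: t for t in cohort.tracks}
    pairs = []
    for parent, grp in cohort.lineage.groupby("parent_id"):
        ids = sorted(grp["cell_id"])
        if len(ids) != 2:
            continue
        a, b = (by_id[i] for i in ids)
        div = float(grp["division_time_h"].iloc[0])
        series = []
        for t in (a, b):
            rel = t.times - div
            mask = (rel > 0) & (rel <= params.anchor_window_post)
            series.append(np.asarray(t.channels[channel], dtype=float)[mask])
        n = min(len(series[0]), len(series[1]))
        if n < 2:
            continue
        if fate_by_cell is not None:
            fa = fate_by_cell.get(a.cell_id, "indeterminate")
            fb = fate_by_cell.get(b.cell_id, "indeterminate")
        else:
            fa, fb = a.truth.get("fate", ""), b.truth.get("fate", "")
        pairs.append(
            SiblingPair(
                pair_id=parent,
                cell_a=a.cell_id,
                cell_b=b.cell_id,
                x=series[0][:n],
                y=series[1][:n],
                fate_a=fa,
                fate_b=fb,
                group=str(a.truth.get("stage_at_treatment", "")),
            )
        )
    return pairs


def mother_daughter_window_means(cohort, params: LineageParams | None = None,
                                 channel: str = "p21") -> pd.DataFrame:
    """One row per (mother, daughter) pair: pre- and post-mitosis window
    means of ``channel`` plus the mother-stage group."""
    params = params or LineageParams()
    by_id = {t.cell_id: t for t in cohort.tracks}
    rows = []
    for _, row in cohort.lineage.iterrows():
        mother = by_id.get(row["parent_id"])
        daughter = by_id.get(row["cell_id"])
        if mother is None or daughter is None:
            continue
        div = float(row["division_time_h"])
        pre = window_mean(
            mother.times - div, mother.channels[channel], "pre",
            params.anchor_window_pre,
        )
        post = window_mean(
            daughter.times - div, daughter.channels[channel], "post",
            params.anchor_window_post,
        )
        rows.append(
            {
                "mother_id": mother.cell_id,
                "daughter_id": daughter.cell_id,
                "group": mother.truth.get("stage_at_treatment", ""),
                "pre_mean": pre,
                "post_mean": post,
            }
        )
    return pd.DataFrame(rows)
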