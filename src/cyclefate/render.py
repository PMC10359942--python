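"""Synthetic fluorescence-field rendering for the image-quantification chain.

Each cell is drawn as a nuclear disk carrying the nuclear channel values
(H1, Cdt1, Geminin, SLBP, CDK2 nuclear signal, p21) surrounded by a
cytoplasmic annulus carrying the cytoplasmic CDK2 sensor signal, composited
over a smoothly varying illumination-bias surface and a constant background
level.  Ground-truth centers and per-channel means are recorded per frame so
the quantification chain can be validated pixel-for-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

NUCLEAR_CHANNELS = ("Cdt1", "Geminin", "SLBP", "H1", "p21")


@dataclass
class RenderParams:
    shape: tuple = (256, 256)
    nuclear_radius: int = 5
    cyto_width: int = 4  # annulus width of rendered cytoplasm (px)
    background_level: float = 10.0
    bias_amplitude: float = 0.0  # 0 disables the illumination bias
    noise_sigma: float = 0.0  # additive Gaussian, a.u.
    drift_sigma: float = 0.0  # random-walk step SD (px per frame)
    margin: int = 16
    rng_seed: int = 0


def bias_field(params: RenderParams) -> np.ndarray:
    """Unit-mean smooth illumination surface (tilted plane + vignette)."""
    h, w = params.shape
    yy, xx = np.mgrid[0:h, 0:w]
    a = params.bias_amplitude
    if a == 0:
        return np.ones(params.shape)
    plane = (xx / w - 0.5) * 0.6 + (yy / h - 0.5) * 0.4
    r2 = ((xx / w - 0.5) ** 2 + (yy / h - 0.5) ** 2) / 0.5
    surf = 1.0 + a * plane - 0.5 * a * r2
    return surf / surf.mean()


def _grid_positions(n: int, params: RenderParams, spacing: int):
    h, w = params.shape
    m = params.margin
    xs = np.arange(m, w - m, spacing)
    ys = np.arange(m, h - m, spacing)
    slots = [(y, x) for y in ys for x in xs]
    if n > len(slots):
        raise ValueError(
            f"field {params.shape} too small for {n} cells at spacing {spacing}"
        )
    return slots[:n]


class FieldRenderer:
    """Renders a cohort of tracks into per-frame multi-channel images.

    Mothers occupy grid slots; at division the two daughters appear offset
    on either side of the mother's last position.  An optional per-frame
    random-walk drift (below the linking search radius) exercises the
    tracker.
    """

    def __init__(self, tracks, params: Optional[RenderParams] = None):
        self.params = params or RenderParams()
        self.tracks = list(tracks)
        p = self.params
        self.rng = np.random.default_rng(p.rng_seed)
        self.bias = bias_field(p)
        r_cell = p.nuclear_radius + p.cyto_width
        spacing = 4 * r_cell
        mothers = [t for t in self.tracks if t.parent_id is None]
        slots = _grid_positions(len(mothers), p, spacing)
        self._base_pos = {}
        off = p.nuclear_radius + 2
        for t, slot in zip(mothers, slots):
            self._base_pos[t.cell_id] = np.asarray(slot, dtype=float)
        # per-cell per-frame drift (precomputed, seeded)
        self._drift = {}
        for t in self.tracks:
            if p.drift_sigma > 0:
                steps = self.rng.normal(0, p.drift_sigma, size=(len(t.times), 2))
                self._drift[t.cell_id] = np.cumsum(steps, axis=0)
            else:
                self._drift[t.cell_id] = np.zeros((len(t.times), 2))
        # daughters appear on either side of the mother's final (drifted)
        # position; tracks are ordered parent-before-daughter
        for t in self.tracks:
            if t.parent_id is not None:
                sign = 1 if t.cell_id.endswith("0") else -1
                parent_end = (
                    self._base_pos[t.parent_id] + self._drift[t.parent_id][-1]
                )
                self._base_pos[t.cell_id] = parent_end + np.array([sign * off, 0.0])

    # -- geometry -------------------------------------------------------

    def position(self, track, local_index: int):
        pos = self._base_pos[track.cell_id] + self._drift[track.cell_id][local_index]
        h, w = self.params.shape
        m = self.params.nuclear_radius + self.params.cyto_width + 1
        return np.clip(pos, m, [h - m - 1, w - m - 1])

    def _alive(self, time_h: float):
        out = []
        for t in self.tracks:
            dt = t.times[1] - t.times[0] if len(t.times) > 1 else 0.25
            k = int(round((time_h - t.times[0]) / dt))
            if 0 <= k < len(t.times) and abs(t.times[k] - time_h) < dt / 2:
                out.append((t, k))
        return out

    # -- rendering ------------------------------------------------------

    def render_frame(self, time_h: float, frame_index: int = 0):
        """Render one multi-channel frame.

        Returns ``(images, truth)`` where ``images`` maps channel name ->
        2-D array (channels: the nuclear reporters plus a single "CDK2"
        channel carrying the nuclear signal in the disk and the cytoplasmic
        signal in the annulus) and ``truth`` is a DataFrame of ground-truth
        centers and channel values.
        """
        p = self.params
        h, w = p.shape
        yy, xx = np.mgrid[0:h, 0:w]
        channels = {c: np.zeros((h, w)) for c in NUCLEAR_CHANNELS + ("CDK2",)}
        rows = []
        alive = self._alive(time_h)
        for track, k in alive:
            cy, cx = np.round(self.position(track, k)).astype(int)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            disk = d2 <= p.nuclear_radius**2
            cyto = (d2 > p.nuclear_radius**2) & (
                d2 <= (p.nuclear_radius + p.cyto_width) ** 2
            )
            row = {"frame": frame_index, "time_h": time_h, "cell_id": track.cell_id,
                   "y": cy, "x": cx}
            for c in NUCLEAR_CHANNELS:
                v = float(track.channels[c][k])
                channels[c][disk] += v
                row[c] = v
            v_nuc = float(track.channels["cdk2_nuc"][k])
            v_cyt = float(track.channels["cdk2_cyt"][k])
            channels["CDK2"][disk] += v_nuc
            channels["CDK2"][cyto] += v_cyt
            row["cdk2_nuc"] = v_nuc
            row["cdk2_cyt"] = v_cyt
            rows.append(row)
        for c in channels:
            img = self.bias * (p.background_level + channels[c])
            if p.noise_sigma > 0:
                img = img + self.rng.normal(0, p.noise_sigma, img.shape)
            channels[c] = np.clip(img, 0.0, None)
        return channels, pd.DataFrame(rows)

    def render_movie(self, times):
        """Render a sequence of frames; returns (stacks, truth table)."""
        stacks = None
        truths = []
        for i, t in enumerate(times):
            imgs, tr = self.render_frame(t, frame_index=i)
            if stacks is None:
                stacks = {c: [] for c in imgs}
            for c, im in imgs.items():
                stacks[c].append(im)
            truths.append(tr)
        stacks = {c: np.stack(v) for c, v in stacks.items()}
        return stacks, pd.concat(truths, ignore_index=True)


def render_field(tracks, frame_index: int, image_params: Optional[RenderParams] = None,
                 sampling_interval: float = 0.25, t0: float = 0.0):
    """Render the cohort at global frame ``frame_index`` (time t0 + k*dt)."""
    params = image_params or RenderParams()
    renderer = FieldRenderer(tracks, params)
    time_h = t0 + frame_index * sampling_interval
    return renderer.render_frame(time_h, frame_index)
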