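"""Image quantification: background flattening, LoG nuclear detection,
disk/ring intensity measurement, and frame-to-frame linking.

The measurement geometry mirrors a standard live-imaging chain: each nucleus
is represented by a fixed-radius disk (default 5 px at 0.55 um/px) found by
Laplacian-of-Gaussian filtering on the histone channel; the cytoplasmic
signal is measured in an annulus of fixed width (default 2 px) immediately
outside the disk, so the CDK2 activity readout is ring mean / disk mean of
the sensor channel.  Tracking is greedy mutual-nearest-neighbour linking
with division detection — a deliberate simplification of LAP-style trackers,
adequate at the densities the synthetic renderer produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import interpolate, ndimage, spatial
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu


@dataclass
class ImageParams:
    pixel_size: float = 0.55  # um per pixel
    nuclear_radius: int = 5  # px
    ring_width: int = 2  # px
    log_sigma: Optional[float] = None  # defaults to nuclear_radius / sqrt(2)
    background_tile: int = 32  # px

    def __post_init__(self):
        if self.nuclear_radius < 1 or self.ring_width < 1:
            raise ValueError("nuclear_radius and ring_width must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.log_sigma is None:
            self.log_sigma = self.nuclear_radius / np.sqrt(2.0)


@dataclass
class CellMeasurement:
    frame: int
    center: tuple  # (row, col)
    nuclear_means: dict
    cyt_cdk2_mean: float = np.nan
    cdk2_ratio: float = np.nan
    background_corrected: bool = False
    flags: list = field(default_factory=list)


def _disk_offsets(radius: int):
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    return yy[d2 <= r * r], xx[d2 <= r * r]


def _ring_offsets(radius: int, width: int):
    r_out = int(radius + width)
    yy, xx = np.mgrid[-r_out : r_out + 1, -r_out : r_out + 1]
    d2 = yy**2 + xx**2
    sel = (d2 > radius * radius) & (d2 <= r_out * r_out)
    return yy[sel], xx[sel]


def flatten_background(image, params: ImageParams):
    """Divide out a smooth illumination bias and subtract the global
    background.

    The bias surface is estimated from the darkest pixels of each tile
    (cells occupy a minority of pixels, so low-order statistics of a tile
    sample the background), smoothed across the tile grid and upsampled;
    the image is divided by the unit-mean bias and the median background of
    non-cell pixels subtracted.  The result is clamped at 0.

    Returns ``(corrected, bias)``.
    """
    img = np.asarray(image, dtype=float)
    tile = int(params.background_tile)
    if min(img.shape) <= tile:
        raise ValueError("image must be larger than background_tile")
    ny, nx = img.shape[0] // tile, img.shape[1] // tile
    grid = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            t = img[i * tile : (i + 1) * tile, j * tile : (j + 1) * tile]
            # cells cover a minority of any tile; the 25th percentile samples
            # background even when a whole cell falls inside the tile
            grid[i, j] = np.percentile(t, 25)
    if not np.any(grid > 0):
        warnings.warn("no background signal detected; correction skipped",
                      stacklevel=2)
        return img.copy(), np.ones_like(img)
    # interpolate from tile centers with a low-order spline; the grid is
    # padded by one linearly-extrapolated ring so image borders (where a
    # plane/vignette bias is strongest) are interpolated, not extrapolated
    gp = np.pad(grid, 1, mode="reflect", reflect_type="odd")
    yc = np.concatenate(([-0.5], np.arange(ny) + 0.5, [ny + 0.5])) * tile
    xc = np.concatenate(([-0.5], np.arange(nx) + 0.5, [nx + 0.5])) * tile
    k = min(2, len(yc) - 1, len(xc) - 1)
    spline = interpolate.RectBivariateSpline(yc, xc, gp, ky=k, kx=k)
    bias = spline(np.arange(img.shape[0]), np.arange(img.shape[1]))
    bias /= bias.mean()
    bias = np.maximum(bias, 1e-3)
    flat = img / bias
    # global background: median of non-cell pixels (Otsu split; fall back to
    # the global median when the image is featureless)
    try:
        thr = threshold_otsu(flat)
        bg_pix = flat[flat < thr]
        bg = np.median(bg_pix) if bg_pix.size else np.median(flat)
    except ValueError:
        bg = np.median(flat)
    out = np.clip(flat - bg, 0.0, None)
    return out, bias


def detect_nuclei(h1_channel, params: ImageParams):
    """Nuclear centers by LoG blob detection on the histone channel.

    Scale-matched LoG (sigma = nuclear_radius / sqrt(2)), local maxima above
    an Otsu-derived threshold, minimum separation twice the nuclear radius.
    Returns an (n, 2) array of (row, col) centers.
    """
    img = np.asarray(h1_channel, dtype=float)
    if img.size == 0 or np.ptp(img) == 0:
        return np.empty((0, 2), dtype=int)
    sigma = params.log_sigma
    resp = -(sigma**2) * ndimage.gaussian_laplace(img, sigma)
    pos = resp[resp > 0]
    if pos.size < 2 or np.ptp(pos) == 0:
        return np.empty((0, 2), dtype=int)
    thr = threshold_otsu(resp)
    peaks = peak_local_max(
        resp,
        min_distance=2 * params.nuclear_radius,
        threshold_abs=max(thr, 0.0),
        exclude_border=False,
    )
    return peaks


def measure_cell(
    images: dict,
    center,
    params: ImageParams,
    frame: int = 0,
    cdk2_channel: str = "CDK2",
    other_centers=None,
    background_corrected: bool = False,
) -> CellMeasurement:
    """Nuclear disk means per channel plus the cytoplasmic-ring CDK2 mean.

    The disk and the ring are disjoint pixel sets by construction.  Cells
    closer to the image edge than ``nuclear_radius + ring_width`` are
    flagged and their ring mean omitted; a neighbouring center whose disk
    could overlap the ring flags the measurement as contaminated.
    """
    r, w = params.nuclear_radius, params.ring_width
    cy, cx = int(round(center[0])), int(round(center[1]))
    any_img = next(iter(images.values()))
    h_, w_ = np.asarray(any_img).shape
    flags = []
    edge_ok = (r + w <= cy < h_ - (r + w)) and (r + w <= cx < w_ - (r + w))
    disk_ok = (r <= cy < h_ - r) and (r <= cx < w_ - r)
    if not disk_ok:
        raise ValueError("center too close to the image edge for the nuclear disk")
    dy, dx = _disk_offsets(r)
    nuclear = {
        name: float(np.mean(np.asarray(img, dtype=float)[cy + dy, cx + dx]))
        for name, img in images.items()
    }
    meas = CellMeasurement(
        frame=frame,
        center=(cy, cx),
        nuclear_means=nuclear,
        background_corrected=background_corrected,
        flags=flags,
    )
    if not edge_ok:
        flags.append("edge-clipped: ring mean omitted")
        return meas
    if other_centers is not None:
        for oc in np.atleast_2d(np.asarray(other_centers, dtype=float)):
            if len(oc) != 2:
                continue
            d = np.hypot(oc[0] - cy, oc[1] - cx)
            if 0 < d < 2 * r + w:
                flags.append("contaminated: neighbour overlaps the ring")
                break
    if cdk2_channel in images:
        ry, rx = _ring_offsets(r, w)
        ring_mean = float(
            np.mean(np.asarray(images[cdk2_channel], dtype=float)[cy + ry, cx + rx])
        )
        meas.cyt_cdk2_mean = ring_mean
        nuc = nuclear.get(cdk2_channel, np.nan)
        meas.cdk2_ratio = ring_mean / nuc if nuc and np.isfinite(nuc) else np.nan
    return meas


# ---------------------------------------------------------------------------
# linking


@dataclass
class LinkedTrack:
    track_id: int
    parent_id: Optional[int]
    frames: list
    coords: list  # (row, col) per frame

    @property
    def start_frame(self):
        return self.frames[0]

    @property
    def end_frame(self):
        return self.frames[-1]


def link_tracks(detections_per_frame, max_disp: float):
    """Greedy mutual-nearest-neighbour linking across consecutive frames.

    Unlinked detections start new tracks.  A division is recorded when a
    track's endpoint has two near neighbours in the next frame (its mutual
    nearest neighbour plus one otherwise-unmatched detection within
    ``max_disp``): the parent track ends and two child tracks begin.
    """
    frames = [np.atleast_2d(np.asarray(d, dtype=float)) for d in detections_per_frame]
    frames = [f if f.size else np.empty((0, 2)) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to link")

    tracks: list[LinkedTrack] = []
    next_id = 0
    # active[i] = track index currently ending at detection i of current frame
    active = []
    for i in range(len(frames[0])):
        tracks.append(LinkedTrack(next_id, None, [0], [tuple(frames[0][i])]))
        active.append(next_id)
        next_id += 1

    for f in range(1, len(frames)):
        prev, cur = frames[f - 1], frames[f]
        links = {}  # cur index -> prev index
        if len(prev) and len(cur):
            t_prev = spatial.cKDTree(prev)
            t_cur = spatial.cKDTree(cur)
            d1, nn_of_prev = t_cur.query(prev)
            d2, nn_of_cur = t_prev.query(cur)
            for j in range(len(cur)):
                i = nn_of_cur[j]
                if nn_of_prev[i] == j and d2[j] <= max_disp:
                    links[j] = i
            # division candidates: unmatched current detections near a prev
            # detection that already has a mutual link
            linked_prev = {}
            for j, i in links.items():
                linked_prev.setdefault(i, []).append(j)
            for j in range(len(cur)):
                if j in links:
                    continue
                i = nn_of_cur[j]
                if d2[j] <= max_disp and i in linked_prev and len(linked_prev[i]) == 1:
                    linked_prev[i].append(j)
            divisions = {i: js for i, js in linked_prev.items() if len(js) == 2}
        else:
            divisions = {}

        new_active = [None] * len(cur)
        consumed = set()
        for i, js in divisions.items():
            parent = active[i]
            for j in sorted(js):
                tracks.append(
                    LinkedTrack(next_id, parent, [f], [tuple(cur[j])])
                )
                new_active[j] = next_id
                next_id += 1
                consumed.add(j)
        for j, i in links.items():
            if j in consumed:
                continue
            tid = active[i]
            tracks[tid].frames.append(f)
            tracks[tid].coords.append(tuple(cur[j]))
            new_active[j] = tid
        for j in range(len(cur)):
            if new_active[j] is None:
                tracks.append(LinkedTrack(next_id, None, [f], [tuple(cur[j])]))
                new_active[j] = next_id
                next_id += 1
        active = new_active
    return tracks
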