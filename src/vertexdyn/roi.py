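"""Vertex intensity ratios from distance-transform ROIs.

Vertex enrichment of a junctional marker is quantified as (V - B)/(J - B)
where V, J and B are mean intensities over three disjoint ROIs built from
Euclidean distance transforms inside a 41 x 41 px neighborhood of the
vertex: the vertex disk (within 3 px of the vertex, 29 pixels), the
interface band (within 3 px of the skeleton, minus the vertex disk), and the
local background (at least 7 px from the skeleton, leaving a 3 px buffer).
The local background and interface normalization absorb non-uniform
illumination and per-junction expression differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VertexROISet",
    "build_rois",
    "intensity_ratio",
    "measure_tracked",
    "trajectory_variability",
    "ratio_distribution_over_time",
    "most_contracted_frame",
    "normalize_trace",
]


@dataclass
class VertexROISet:
    """Boolean ROI masks inside the window, plus the window slices."""

    window: tuple[slice, slice]
    vertex: np.ndarray
    junction: np.ndarray
    background: np.ndarray
    valid: bool


def build_rois(
    skeleton: np.ndarray,
    vertex_yx: tuple[float, float],
    window: int = 41,
    vertex_radius: float = 3.0,
    background_distance: float = 7.0,
    d_line: np.ndarray | None = None,
) -> VertexROISet:
    """ROI masks for one vertex on one frame.

    ``skeleton`` is the boolean watershed-line image; ``d_line`` may carry
    its precomputed Euclidean distance transform (shared across vertices of a
    frame). Vertices closer than ``window // 2`` px to the image border are
    marked invalid and excluded from measurement.
    """
    half = window // 2
    H, W = skeleton.shape
    iy, ix = int(round(vertex_yx[0])), int(round(vertex_yx[1]))
    win = (slice(iy - half, iy + half + 1), slice(ix - half, ix + half + 1))
    if iy - half < 0 or ix - half < 0 or iy + half + 1 > H or ix + half + 1 > W:
        empty = np.zeros((window, window), dtype=bool)
        return VertexROISet(win, empty, empty, empty, valid=False)
    if d_line is None:
        d_line = ndimage.distance_transform_edt(~skeleton)
    dl = d_line[win]
    yy, xx = np.mgrid[0:window, 0:window].astype(float)
    dv = np.hypot(yy - half + (iy - vertex_yx[0]), xx - half + (ix - vertex_yx[1]))
    vertex = dv <= vertex_radius
    junction = (dl <= vertex_radius) & ~vertex
    background = dl >= background_distance
    valid = bool(junction.any() and background.any())
    return VertexROISet(win, vertex, junction, background, valid=valid)


def intensity_ratio(image: np.ndarray, rois: VertexROISet,
                    eps: float | None = None) -> dict:
    """Mean V/J/B intensities and the ratio (V-B)/(J-B) for one vertex.

    The ratio is invalid (NaN) when J - B falls below ``eps`` (default: 1% of
    the image's robust intensity range), signalling vanishing junctional
    contrast rather than raising.
    """
    if eps is None:
        lo, hi = np.percentile(image, (1, 99))
        eps = 0.01 * max(hi - lo, 1e-12)
    if not rois.valid:
        return dict(V=np.nan, J=np.nan, B=np.nan, ratio=np.nan, valid=False)
    sub = np.asarray(image, dtype=float)[rois.window]
    V = float(sub[rois.vertex].mean())
    J = float(sub[rois.junction].mean())
    B = float(sub[rois.background].mean())
    if J - B <= eps:
        return dict(V=V, J=J, B=B, ratio=np.nan, valid=False)
    return dict(V=V, J=J, B=B, ratio=(V - B) / (J - B), valid=True)


def measure_tracked(stack: np.ndarray, tracked, channel: int = 1,
                    window: int = 41) -> pd.DataFrame:
    """Intensity traces for every tracked vertex.

    ``stack`` is (T, C, H, W); ``tracked`` a TrackedTissue. Returns one row
    per vertex per frame with V, J, B, ratio and validity.
    """
    rows = []
    for f in range(tracked.n_frames):
        img = stack[f, channel]
        lo, hi = np.percentile(img, (1, 99))
        eps = 0.01 * max(hi - lo, 1e-12)
        skel = tracked.labels[f] == 0
        d_line = ndimage.distance_transform_edt(~skel)
        vtab = tracked.vertices[tracked.vertices.frame == f]
        for row in vtab.itertuples():
            rois = build_rois(skel, (row.y, row.x), window=window, d_line=d_line)
            m = intensity_ratio(img, rois, eps=eps)
            rows.append(dict(frame=f, vertex=int(row.vertex), **m))
    return pd.DataFrame(rows)


def trajectory_variability(traces: pd.DataFrame, min_frames: int = 5):
    """Per-vertex sd of the intensity-ratio trajectory, and its population
    summary (mean +- sem over vertices).

    Vertices with fewer than ``min_frames`` valid frames are excluded.
    Population (n) convention is used for the sd throughout the package.
    """
    per_vertex = {}
    for vid, grp in traces.groupby("vertex"):
        r = grp.loc[grp.valid.astype(bool), "ratio"].to_numpy(dtype=float)
        r = r[np.isfinite(r)]
        if len(r) < min_frames:
            continue
        per_vertex[int(vid)] = float(np.std(r))
    sds = np.array(list(per_vertex.values()))
    if len(sds) == 0:
        return per_vertex, (np.nan, np.nan)
    sem = float(np.std(sds) / np.sqrt(len(sds))) if len(sds) > 1 else np.nan
    return per_vertex, (float(np.mean(sds)), sem)


def most_contracted_frame(tracked) -> int:
    """Alignment reference: frame minimizing total vertical-interface length.

    Falls back (with a warning) to the movie midpoint when the movie has no
    vertical interfaces.
    """
    import warnings

    iface = tracked.interfaces
    vertical = [t for t, m in tracked.interface_meta.items() if m.cls == "vertical"]
    if not vertical:
        warnings.warn("no vertical interfaces; aligning at movie midpoint", stacklevel=2)
        return tracked.n_frames // 2
    sel = iface[iface.interface.isin(vertical)]
    tot = sel.groupby("frame").length_px.sum()
    return int(tot.idxmin())


def ratio_distribution_over_time(
    movies: list[pd.DataFrame],
    alignments: list[int],
    time_bin_frames: int = 5,
    ratio_bins: np.ndarray | None = None,
):
    """Per-time-bin normalized histograms of ratios over movies aligned at
    their most-contracted frame (aligned time 0)."""
    if ratio_bins is None:
        ratio_bins = np.linspace(0.0, 4.0, 41)
    recs = []
    for traces, a0 in zip(movies, alignments):
        ok = traces[traces.valid.astype(bool)]
        recs.append(pd.DataFrame(dict(t=ok.frame - a0, ratio=ok.ratio)))
    allrec = pd.concat(recs, ignore_index=True)
    allrec["tbin"] = np.floor(allrec.t / time_bin_frames).astype(int)
    out = {}
    for tb, grp in allrec.groupby("tbin"):
        h, _ = np.histogram(grp.ratio, bins=ratio_bins, density=True)
        out[int(tb)] = h
    return out, ratio_bins


def normalize_trace(series: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd (population convention) normalization.

    Raises on zero variance; callers exclude such traces.
    """
    x = np.asarray(series, dtype=float)
    sd = np.std(x)
    if sd == 0:
        raise ValueError("cannot normalize a constant trace (sd = 0)")
    return (x - np.mean(x)) / sd
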