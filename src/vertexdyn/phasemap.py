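"""Gaussian-weighted interpolation of covariates into area-phase space.

Oscillation cycles vary in length, so time averaging across cells blurs
cycle structure; remapping covariates from time to the instantaneous-phase
domain aligns cycles exactly. Samples (phase coordinates, value) are
interpolated onto a regular grid by Gaussian-weighted averaging, with
samples replicated at +-360 deg along every phase axis so the grid wraps
(the node at -180 equals the node at +180). Grids can be 1D (phase), 2D
(vertex angle x phase) or 3D (three cell phases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase import PhaseTrace, segment_cycles

__all__ = [
    "PhaseGrid",
    "interp_to_grid",
    "phase_bin_mean",
    "cycle_shifted_samples",
    "length_vs_phase",
    "fractional_length_vs_phase",
    "shape_metric_vs_phase",
    "vertex_angle",
    "intensity_angle_phase_map",
    "tangential_rate_3phase_map",
    "variance_attribution",
]


@dataclass
class PhaseGrid:
    """Interpolated values on a (wrapped) phase grid."""

    axes: list[np.ndarray]          # node coordinates per axis, deg
    values: np.ndarray              # NaN where masked
    weights: np.ndarray             # effective sample count per node
    bandwidth: float                # kernel sd, deg

    @property
    def ndim(self) -> int:
        return len(self.axes)


def _axis_nodes(spacing: float) -> np.ndarray:
    return np.arange(-180.0, 180.0 + spacing / 2, spacing)


def interp_to_grid(
    coords: np.ndarray,
    values: np.ndarray,
    spacing: float | None = None,
    bandwidth: float = 15.0,
    min_weight: float = 5.0,
    wrap: bool | tuple = True,
) -> PhaseGrid:
    """Gaussian-weighted average of samples onto a phase grid.

    Node value = sum(w_i v_i)/sum(w_i) with w_i = exp(-d^2 / 2h^2), d the
    Euclidean distance in grid coordinates after replicating each sample at
    +-360 deg along every wrapped axis. Nodes with total weight below
    ``min_weight`` effective samples are masked (NaN). Empty input gives a
    fully masked grid.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1 and coords.shape[1] > 1 and np.ndim(values) == 1 \
            and len(values) == coords.shape[1]:
        coords = coords.T
    values = np.asarray(values, dtype=float)
    d = coords.shape[1] if coords.size else 1
    if spacing is None:
        spacing = 5.0 if d < 3 else 15.0
    wrap = (wrap,) * d if isinstance(wrap, bool) else tuple(wrap)
    axes = [_axis_nodes(spacing) for _ in range(d)]
    shape = tuple(len(a) for a in axes)
    ok = np.all(np.isfinite(coords), axis=1) & np.isfinite(values)
    coords, values = coords[ok], values[ok]
    if len(values) == 0:
        nan = np.full(shape, np.nan)
        return PhaseGrid(axes, nan, np.zeros(shape), bandwidth)
    # per-axis weight matrices (nodes x samples), summed over +-360 replicas
    mats = []
    for k in range(d):
        diff = axes[k][:, None] - coords[None, :, k]
        w = np.exp(-diff ** 2 / (2 * bandwidth ** 2))
        if wrap[k]:
            for shift in (-360.0, 360.0):
                w += np.exp(-(diff + shift) ** 2 / (2 * bandwidth ** 2))
        mats.append(w)
    if d == 1:
        wsum = mats[0].sum(axis=1)
        vsum = mats[0] @ values
    elif d == 2:
        wsum = np.einsum("ai,bi->ab", mats[0], mats[1])
        vsum = np.einsum("ai,bi,i->ab", mats[0], mats[1], values)
    elif d == 3:
        wsum = np.einsum("ai,bi,ci->abc", mats[0], mats[1], mats[2])
        vsum = np.einsum("ai,bi,ci,i->abc", mats[0], mats[1], mats[2], values)
    else:
        raise ValueError("grids above 3D are not supported")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = vsum / wsum
    out[wsum < min_weight] = np.nan
    return PhaseGrid(axes, out, wsum, bandwidth)


def phase_bin_mean(phases: np.ndarray, values: np.ndarray, center: float,
                   width: float = 10.0) -> float:
    """Mean value inside a phase bin of ``width`` deg centered at ``center``,
    with wrap-around (so the bin at 180 includes phases near -180)."""
    phases = np.asarray(phases, dtype=float)
    values = np.asarray(values, dtype=float)
    d = np.abs((phases - center + 180.0) % 360.0 - 180.0)
    sel = (d <= width / 2.0) & np.isfinite(values)
    return float(values[sel].mean()) if sel.any() else np.nan


def cycle_shifted_samples(series: pd.Series, trace: PhaseTrace):
    """(phase, value - value_at_cycle_start) samples pooled over complete
    cycles; the reset to zero at each cycle start makes negative values
    within-cycle net contraction and positive values net growth."""
    cycles, _ = segment_cycles(trace)
    ph, val = [], []
    x = series.to_numpy(dtype=float) if isinstance(series, pd.Series) else np.asarray(series, float)
    for a, b in cycles:
        if b > len(x):
            continue
        seg = x[a:b]
        if not np.isfinite(seg).all():
            continue
        ph.append(trace.phase_deg[a:b])
        val.append(seg - seg[0])
    if not ph:
        return np.empty(0), np.empty(0)
    return np.concatenate(ph), np.concatenate(val)


def length_vs_phase(
    lengths: list, flank_traces: list,
    bandwidth: float = 15.0, spacing: float = 5.0,
):
    """Interface length change vs flanking-cell area phase.

    ``lengths``: per interface, its length series; ``flank_traces``: per
    interface, the list of PhaseTraces of its flanking cells (both cell A
    and cell B mappings are pooled). Returns (PhaseGrid, bins dict) with
    10-deg bin means at 0 deg (post-contraction length change) and at
    175 deg (full-cycle change); their difference is the change over the
    expansion half-cycle alone.
    """
    ph_all, v_all = [], []
    for L, traces in zip(lengths, flank_traces):
        for tr in traces:
            ph, v = cycle_shifted_samples(L, tr)
            ph_all.append(ph)
            v_all.append(v)
    ph = np.concatenate(ph_all) if ph_all else np.empty(0)
    v = np.concatenate(v_all) if v_all else np.empty(0)
    grid = interp_to_grid(ph[:, None], v, spacing=spacing, bandwidth=bandwidth)
    b0 = phase_bin_mean(ph, v, 0.0)
    b175 = phase_bin_mean(ph, v, 175.0)
    return grid, {"bin_0": b0, "bin_175": b175, "expansion_change": b175 - b0}


def fractional_length_vs_phase(lengths: list, perimeters: list, flank_traces: list,
                               **kw):
    """Same machinery on fractional length L/P (interface length over owning
    cell perimeter), which is invariant under isotropic area change."""
    fracs = []
    traces = []
    for L, Ps, trs in zip(lengths, perimeters, flank_traces):
        for P, tr in zip(Ps, trs):
            fracs.append(L / P)
            traces.append([tr])
    return length_vs_phase(fracs, traces, **kw)


def shape_metric_vs_phase(metric: list, euclid_traces: list,
                          bandwidth: float = 15.0, spacing: float = 5.0):
    """Cell shape metric (contour / Euclidean area) vs the phase of the
    Euclidean area. Reports 10-deg bin means at -180, -90, 0, 90, 180."""
    ph_all, v_all = [], []
    for m, tr in zip(metric, euclid_traces):
        x = m.to_numpy(dtype=float) if isinstance(m, pd.Series) else np.asarray(m, float)
        n = min(len(x), len(tr.phase_deg))
        ph_all.append(tr.phase_deg[:n])
        v_all.append(x[:n])
    ph = np.concatenate(ph_all)
    v = np.concatenate(v_all)
    grid = interp_to_grid(ph[:, None], v, spacing=spacing, bandwidth=bandwidth)
    bins = {c: phase_bin_mean(ph, v, c) for c in (-180.0, -90.0, 0.0, 90.0, 180.0)}
    return grid, bins


def vertex_angle(rel_xy: np.ndarray, ventral_angle: float = 90.0) -> np.ndarray:
    """Angle of the centroid-to-vertex vector relative to the ventral
    direction, wrapped to (-180, 180]; 0 = due ventral, +-180 = due dorsal.
    Frames with the vertex on the centroid are NaN."""
    rel = np.asarray(rel_xy, dtype=float)
    r = np.hypot(rel[:, 0], rel[:, 1])
    ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) - ventral_angle
    ang = (ang + 180.0) % 360.0 - 180.0
    return np.where(r > 0, ang, np.nan)


def intensity_angle_phase_map(
    angles: np.ndarray, phases: np.ndarray, norm_intensity: np.ndarray,
    bandwidth: float = 15.0, spacing: float = 5.0, band_half_angle: float = 45.0,
):
    """2D map of normalized vertex intensity over (vertex angle, cell phase).

    Also returns band-mean curves vs phase for the T1-associated sector
    (angle within ``band_half_angle`` of +-90 deg, where vertices of
    contracting vertical interfaces sit) and the non-contracting sector
    (around 0/180 deg).
    """
    coords = np.column_stack([angles, phases])
    grid = interp_to_grid(coords, norm_intensity, spacing=spacing, bandwidth=bandwidth)
    d90 = np.abs(np.abs((angles + 180.0) % 360.0 - 180.0) - 90.0)
    t1_band = d90 <= band_half_angle
    curves = {}
    for name, sel in (("t1_band", t1_band), ("noncontracting_band", ~t1_band)):
        g = interp_to_grid(phases[sel][:, None], norm_intensity[sel],
                           spacing=spacing, bandwidth=bandwidth)
        curves[name] = g
    return grid, curves


def tangential_rate_3phase_map(
    phases_abc: np.ndarray, rates: np.ndarray,
    bandwidth: float = 20.0, spacing: float = 15.0, min_weight: float = 5.0,
):
    """3D map of tangential vertex displacement rate over the phases of the
    three cells of the vertex (A, B, and C or D). Returns the grid plus the
    2D slice-average maps vs (phiA, phiB) and (phiA, phiC)."""
    import warnings

    grid = interp_to_grid(phases_abc, rates, spacing=spacing,
                          bandwidth=bandwidth, min_weight=min_weight)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-masked lines
        ab = np.nanmean(grid.values, axis=2)
        ac = np.nanmean(grid.values, axis=1)
    return grid, {"phiA_phiB": ab, "phiA_phiC": ac}


def variance_attribution(grid: PhaseGrid) -> np.ndarray:
    """Fraction of map structure attributable to each phase axis.

    For each axis the marginal profile (mean over the other axes) is
    computed; attribution = variance of that profile / sum over axes. The
    axis of the cell actually driving the rate carries most of the variance.
    """
    import warnings

    v = grid.values
    out = []
    for k in range(v.ndim):
        other = tuple(i for i in range(v.ndim) if i != k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof = np.nanmean(v, axis=other)
        out.append(np.nanvar(prof))
    out = np.asarray(out)
    s = out.sum()
    return out / s if s > 0 else out
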