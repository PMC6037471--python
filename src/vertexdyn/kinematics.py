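"""Drift-removed vertex kinematics.

Vertex motion is separated from tissue translation by measuring positions
relative to the centroid of a reference cell; in that cell-centric frame the
motion decomposes into a radial component (area oscillation) and a
tangential component Delta_s = r * Delta_theta (sliding along the cell
periphery). By convention tangential displacement toward the opposing
vertex of the vertical (T1) interface is negative, so interface-contracting
motion is negative and elongating motion positive.

The module also quantifies motion coupling of vertex pairs within a cell
(zero-lag correlation of rates of approach along the pair axis) and the
length budget of contracting-interface triplets (vertex sliding conserves
the sum of a contracting interface and its two transverse interfaces;
interface shrinkage without sliding removes that length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VertexMotion",
    "PairCoupling",
    "cell_centric_positions",
    "tangential_radial",
    "displacement_rate",
    "pair_coupling",
    "pair_category",
    "triplet_conservation",
    "triplet_flatness",
]


@dataclass
class VertexMotion:
    r: np.ndarray               # radius (um)
    theta_deg: np.ndarray       # unwrapped polar angle
    ds: np.ndarray              # tangential displacement per frame (um), signed
    dr: np.ndarray              # radial displacement per frame (um)
    sign_convention: int        # +1 if increasing theta elongates the interface


@dataclass
class PairCoupling:
    correlation: float
    n_frames: int
    category: str


def cell_centric_positions(v_xy: np.ndarray, c_xy: np.ndarray) -> np.ndarray:
    """Vertex positions relative to the reference cell centroid.

    Both inputs are (T, 2); frames with a missing centroid propagate NaN.
    Rigid translation of cell + vertex cancels exactly.
    """
    return np.asarray(v_xy, dtype=float) - np.asarray(c_xy, dtype=float)


def tangential_radial(rel_xy: np.ndarray,
                      opposing_rel_xy: np.ndarray | None = None) -> VertexMotion:
    """Decompose cell-centric motion into radial and tangential parts.

    ``rel_xy`` is the (T, 2) cell-centric vertex trajectory. If
    ``opposing_rel_xy`` (trajectory of the opposing vertex of the vertical
    interface, same frame base) is given, the tangential sign is flipped so
    that motion toward the opposing vertex (interface contraction) is
    negative; otherwise increasing polar angle counts positive.

    Frames where the vertex sits on the centroid (r = 0) are masked NaN.
    """
    rel = np.asarray(rel_xy, dtype=float)
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    theta = np.degrees(np.unwrap(np.radians(theta)))
    bad = r <= 0
    sign = 1
    if opposing_rel_xy is not None:
        opp = np.asarray(opposing_rel_xy, dtype=float)
        th_o = np.degrees(np.arctan2(opp[:, 1], opp[:, 0]))
        d = (th_o - (theta % 360.0) + 180.0) % 360.0 - 180.0
        # if the opposing vertex lies at larger theta, increasing theta
        # contracts the interface => flip so contraction is negative
        sign = -1 if np.nanmedian(d) > 0 else 1
    dtheta = np.diff(theta, prepend=theta[0])
    r_mid = r.copy()
    ds = sign * r_mid * np.radians(dtheta)
    dr = np.diff(r, prepend=r[0])
    ds[bad] = np.nan
    dr[bad] = np.nan
    theta = np.where(bad, np.nan, theta)
    return VertexMotion(r=r, theta_deg=theta, ds=ds, dr=dr, sign_convention=sign)


def displacement_rate(series: np.ndarray, frame_interval: float,
                      window_s: float = 25.0, per_minute: bool = True) -> np.ndarray:
    """Finite-difference rate over ~``window_s`` (default 25 s).

    rate(t) = (x(t + D) - x(t)) / D with D the nearest frame count to the
    window; the long baseline avoids correlating localization error.
    Output units are per minute when ``per_minute`` (positions in um give
    um/min), else per second. Trailing frames without a forward sample are
    NaN, as is any rate computed from a NaN position.
    """
    x = np.asarray(series, dtype=float)
    nd = max(int(round(window_s / frame_interval)), 1)
    out = np.full(x.shape, np.nan)
    dt = nd * frame_interval
    out[:-nd] = (x[nd:] - x[:-nd]) / dt
    if per_minute:
        out = out * 60.0
    return out


def pair_category(k: int, n_vertices: int = 6) -> str:
    """Pair category from the cyclic separation of two vertices on a cell.

    With six vertices: separation 1 = adjacent, 2 = diagonal, 3 = opposed.
    """
    k = min(k % n_vertices, (n_vertices - k) % n_vertices)
    return {1: "adjacent", 2: "diagonal", 3: "opposed"}.get(k, f"sep{k}")


def pair_coupling(p1_xy: np.ndarray, p2_xy: np.ndarray, frame_interval: float,
                  window_s: float = 25.0, category: str = "",
                  min_frames: int = 10) -> PairCoupling:
    """Zero-lag correlation of two vertices' rates of approach.

    Each frame displacement is projected on the average vertex-to-vertex
    axis before and after the displacement (positive toward the other
    vertex); the cumulative parallel positions are differentiated over
    ~25 s and Pearson-correlated at zero lag. Mutual approach/withdrawal
    gives positive correlation; common translation gives negative.
    """
    p1 = np.asarray(p1_xy, dtype=float)
    p2 = np.asarray(p2_xy, dtype=float)
    if len(p1) < min_frames:
        raise ValueError(f"common interval shorter than {min_frames} frames")
    sep = p2 - p1
    if np.nanmin(np.hypot(sep[:, 0], sep[:, 1])) <= 0:
        raise ValueError("coincident vertices")
    d1 = np.diff(p1, axis=0)
    d2 = np.diff(p2, axis=0)
    axis = sep[:-1] + sep[1:]
    axis = axis / np.linalg.norm(axis, axis=1, keepdims=True)
    a1 = np.einsum("ij,ij->i", d1, axis)          # toward vertex 2
    a2 = np.einsum("ij,ij->i", d2, -axis)         # toward vertex 1
    s1 = np.concatenate([[0.0], np.cumsum(a1)])
    s2 = np.concatenate([[0.0], np.cumsum(a2)])
    r1 = displacement_rate(s1, frame_interval, window_s)
    r2 = displacement_rate(s2, frame_interval, window_s)
    ok = np.isfinite(r1) & np.isfinite(r2)
    if ok.sum() < min_frames:
        raise ValueError("too few valid rate samples")
    c = np.corrcoef(r1[ok], r2[ok])[0, 1]
    return PairCoupling(correlation=float(c), n_frames=int(ok.sum()), category=category)


def triplet_conservation(
    l1: pd.Series,
    transverse: tuple[pd.Series, pd.Series],
    frame_interval: float,
    min_lifetime_s: float = 300.0,
    window_s: float = 300.0,
) -> pd.DataFrame | None:
    """Aligned length curves for one contracting-interface triplet.

    ``l1`` is the contracting interface's length series (um) indexed by
    frame; ``transverse`` the two transverse interfaces on one cell side.
    Tracks shorter than ``min_lifetime_s`` are excluded (returns None); the
    last ``window_s`` (5 min) before the contraction endpoint are kept and
    re-indexed so the last time point is T = 0 (seconds, negative into the
    past). Frames missing any member are dropped.
    """
    if len(l1) * frame_interval < min_lifetime_s:
        return None
    frames = l1.index
    nwin = int(round(window_s / frame_interval))
    frames = frames[-(nwin + 1):]
    df = pd.DataFrame(dict(L1=l1.reindex(frames),
                           T1=transverse[0].reindex(frames),
                           T2=transverse[1].reindex(frames)))
    df = df.dropna()
    if df.empty:
        return None
    t_end = df.index.max()
    out = pd.DataFrame(dict(
        t_s=(df.index - t_end) * frame_interval,
        L1=df.L1.to_numpy(),
        transverse_sum=(df.T1 + df.T2).to_numpy(),
    ))
    out["total"] = out.L1 + out.transverse_sum
    return out.reset_index(drop=True)


def triplet_flatness(curves: pd.DataFrame) -> float:
    """Relative net change of the triplet total over the window.

    ~0 for pure sliding (length conserved); approaches the relative L1 loss
    when contraction removes length without transverse compensation.
    """
    tot = curves.total.to_numpy(dtype=float)
    return float((tot[0] - tot[-1]) / tot[0])
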