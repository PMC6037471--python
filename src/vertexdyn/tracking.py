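"""Tracking of cells, tricellular vertices, and interfaces through time.

Cell identity is propagated by maximal label overlap between consecutive
frames (the frame interval is short relative to cell deformation, so no
motion model is needed). Vertices are identified by the frozenset of their
adjacent tracked cell ids, interfaces by their flanking cell pair; any
topology change (neighbor exchange) therefore terminates the affected
vertex/interface tracks and starts new ones. An interface track whose
length falls below ``length_zero_tol_px`` at a termination that is not the
movie end is flagged ``fully_contracting`` (a completed T1 contraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .segmentation import TissueGraph, _neighbor_label_sets

__all__ = [
    "TrackConfig",
    "TrackedTissue",
    "track",
    "cell_geometry",
    "classify_interface",
]


@dataclass
class TrackConfig:
    pixel_size: float = 0.2          # um / px
    frame_interval: float = 3.0      # s
    ventral_angle: float = 90.0      # image-frame angle of the ventral (DV) axis, deg
    vertical_half_angle: float = 30.0
    length_zero_tol_px: float = 2.0  # final length below this => full contraction
    min_track_frames: int = 5


@dataclass
class InterfaceTrackMeta:
    track: int
    cells: tuple[int, int]
    first_frame: int
    last_frame: int
    cls: str
    fully_contracting: bool
    end_cells: tuple[int | None, int | None]  # (C top, D bottom) at track start


@dataclass
class TrackedTissue:
    """Tracked tissue: per-frame tables keyed by stable track ids."""

    config: TrackConfig
    graphs: list[TissueGraph]
    labels: list[np.ndarray]                 # remapped to persistent cell ids
    cells: pd.DataFrame                      # frame, cell, y, x, area_px, border
    vertices: pd.DataFrame                   # frame, vertex, y, x, cells
    interfaces: pd.DataFrame                 # frame, interface, v0, v1, length_px, ...
    vertex_cells: dict[int, frozenset] = field(default_factory=dict)
    interface_meta: dict[int, InterfaceTrackMeta] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.graphs)

    def cell_series(self, cell: int, col: str) -> pd.Series:
        df = self.cells[self.cells.cell == cell].set_index("frame").sort_index()
        return df[col]

    def vertex_positions(self, vertex: int) -> pd.DataFrame:
        df = self.vertices[self.vertices.vertex == vertex]
        return df.set_index("frame").sort_index()[["y", "x"]]

    def interface_lengths_um(self, iface: int) -> pd.Series:
        df = self.interfaces[self.interfaces.interface == iface]
        return df.set_index("frame").sort_index()["length_px"] * self.config.pixel_size


def classify_interface(orientation_deg: float, ventral_angle: float = 90.0,
                       half_angle: float = 30.0) -> str:
    """'vertical' (DV-aligned, T1-type), 'transverse' (AP-aligned), or 'other'."""
    if not np.isfinite(orientation_deg):
        return "other"
    d_dv = abs((orientation_deg - ventral_angle + 90.0) % 180.0 - 90.0)
    d_ap = abs((orientation_deg - ventral_angle) % 180.0 - 90.0)
    if d_dv <= half_angle:
        return "vertical"
    if d_ap <= half_angle:
        return "transverse"
    return "other"


def _relabel_by_overlap(prev: np.ndarray, cur: np.ndarray, next_id: int):
    """Map current labels to persistent ids by maximal overlap with ``prev``
    (already persistent). Ties break to the smallest persistent id."""
    mapping: dict[int, int] = {}
    cur_ids = np.unique(cur)
    cur_ids = cur_ids[cur_ids != 0]
    # overlap counts
    mask = (cur > 0) & (prev > 0)
    pairs, counts = np.unique(
        np.stack([cur[mask], prev[mask]]), axis=1, return_counts=True
    )
    best: dict[int, tuple[int, int]] = {}  # cur -> (count, prev_id)
    for (c, p), n in zip(pairs.T, counts):
        c, p = int(c), int(p)
        cand = (int(n), -p)
        if c not in best or cand > (best[c][0], -best[c][1]):
            best[c] = (int(n), p)
    claimed: dict[int, tuple[int, int]] = {}  # prev_id -> (count, cur)
    for c in sorted(best):
        n, p = best[c]
        if p not in claimed or n > claimed[p][0]:
            claimed[p] = (n, c)
    for c in cur_ids:
        c = int(c)
        if c in best and claimed.get(best[c][1], (None, None))[1] == c:
            mapping[c] = best[c][1]
        else:
            mapping[c] = next_id
            next_id += 1
    out = np.zeros_like(cur)
    for c, pid in mapping.items():
        out[cur == c] = pid
    return out, next_id


def track(graphs: list[TissueGraph], config: TrackConfig | None = None) -> TrackedTissue:
    """Track a sequence of tissue graphs into cell/vertex/interface tables."""
    if len(graphs) < 2:
        raise ValueError("tracking requires at least two frames")
    config = config or TrackConfig()
    # --- persistent cell ids ---------------------------------------------
    labels = [graphs[0].labels.astype(np.int32)]
    next_id = int(labels[0].max()) + 1
    for g in graphs[1:]:
        lab, next_id = _relabel_by_overlap(labels[-1], g.labels, next_id)
        labels.append(lab)

    cell_rows, vert_rows, iface_rows = [], [], []
    vertex_track_of: dict[frozenset, tuple[int, int]] = {}  # key -> (track, last_frame)
    iface_track_of: dict[frozenset, tuple[int, int]] = {}
    vertex_cells: dict[int, frozenset] = {}
    iface_info: dict[int, dict] = {}
    next_v, next_e = 0, 0

    for f, (g, lab) in enumerate(zip(graphs, labels)):
        border = set()
        edge = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        border = set(int(v) for v in np.unique(edge) if v != 0)
        for rp in regionprops(lab):
            cell_rows.append(dict(frame=f, cell=int(rp.label), y=rp.centroid[0],
                                  x=rp.centroid[1], area_px=int(rp.area),
                                  border=int(rp.label) in border))
        # remap graph cell ids to persistent ids via one representative pixel
        remap = {}
        for old in np.unique(g.labels):
            if old == 0:
                continue
            ys, xs = np.nonzero(g.labels == old)
            remap[int(old)] = int(lab[ys[0], xs[0]])
        vpos = {}
        vtrack_frame = {}
        for v in g.vertices:
            key = frozenset(remap[c] for c in v.cells)
            if len(key) < 3:
                continue
            prev = vertex_track_of.get(key)
            if prev is not None and prev[1] == f - 1:
                tid = prev[0]
            else:
                tid = next_v
                next_v += 1
                vertex_cells[tid] = key
            vertex_track_of[key] = (tid, f)
            vert_rows.append(dict(frame=f, vertex=tid, y=v.y, x=v.x,
                                  cells="|".join(map(str, sorted(key)))))
            vpos[v.id] = (v.y, v.x, tid)
            vtrack_frame[key] = tid
        for e in g.interfaces:
            key = frozenset(remap[c] for c in e.cells)
            if len(key) != 2:
                continue
            if e.v0 not in vpos or e.v1 not in vpos:
                continue
            y0, x0, t0 = vpos[e.v0]
            y1, x1, t1 = vpos[e.v1]
            prev = iface_track_of.get(key)
            if prev is not None and prev[1] == f - 1:
                tid = prev[0]
            else:
                tid = next_e
                next_e += 1
                a, b = sorted(key)
                # end cells: other cells at each endpoint vertex (C = top)
                ends = []
                for vid in (e.v0, e.v1):
                    vx = next(v for v in g.vertices if v.id == vid)
                    others = sorted(frozenset(remap[c] for c in vx.cells) - key)
                    ends.append((vpos[vid][0], others[0] if others else None))
                ends.sort(key=lambda t: t[0])
                iface_info[tid] = dict(cells=(a, b),
                                       end_cells=(ends[0][1], ends[-1][1]))
            iface_track_of[key] = (tid, f)
            length = float(np.hypot(y1 - y0, x1 - x0))
            ori = float(np.degrees(np.arctan2(y1 - y0, x1 - x0)) % 180.0)
            iface_rows.append(dict(frame=f, interface=tid, v0=t0, v1=t1,
                                   length_px=length, orientation=ori,
                                   cell_a=sorted(key)[0], cell_b=sorted(key)[1]))

    cells = pd.DataFrame(cell_rows)
    vertices = pd.DataFrame(vert_rows)
    interfaces = pd.DataFrame(iface_rows)

    meta: dict[int, InterfaceTrackMeta] = {}
    n_frames = len(graphs)
    # vertex cell-sets present per frame, for merged-vertex detection
    verts_by_frame: dict[int, list[frozenset]] = {}
    for row in vertices.itertuples():
        verts_by_frame.setdefault(int(row.frame), []).append(vertex_cells[int(row.vertex)])
    flagged_pairs: set[tuple[int, int]] = set()
    if len(interfaces):
        order = sorted(interfaces.groupby("interface"),
                       key=lambda kv: int(kv[1].frame.min()))
        for tid, grp in order:
            grp = grp.sort_values("frame")
            first, last = int(grp.frame.iloc[0]), int(grp.frame.iloc[-1])
            cls = classify_interface(float(grp.orientation.iloc[0]),
                                     config.ventral_angle, config.vertical_half_angle)
            pair = iface_info[tid]["cells"]
            # full contraction: early termination of a sufficiently long and
            # initially resolvable track, ending either below the length
            # tolerance or in a merged (>= 4-fold) vertex spanning both cells
            fully = (
                last < n_frames - 1
                and len(grp) >= config.min_track_frames
                and float(grp.length_px.max()) >= 2 * config.length_zero_tol_px
                and pair not in flagged_pairs
            )
            if fully:
                ends_small = float(grp.length_px.iloc[-1]) <= config.length_zero_tol_px
                merged = any(frozenset(pair) <= s
                             for s in verts_by_frame.get(last + 1, []))
                fully = ends_small or merged
            if fully:
                flagged_pairs.add(pair)
            meta[tid] = InterfaceTrackMeta(
                track=tid, cells=pair, first_frame=first,
                last_frame=last, cls=cls, fully_contracting=fully,
                end_cells=iface_info[tid]["end_cells"],
            )

    return TrackedTissue(config=config, graphs=graphs, labels=labels,
                         cells=cells, vertices=vertices, interfaces=interfaces,
                         vertex_cells=vertex_cells, interface_meta=meta)


def cell_geometry(tracked: TrackedTissue) -> pd.DataFrame:
    """Per-cell per-frame geometry in physical units.

    pixel area     : label pixel count x pixel area
    perimeter      : contour perimeter of the label region
    contour area   : pixel area + half the area of the bounding skeleton pixels
    Euclidean area : shoelace area of the polygon of detected vertices
    shape metric   : contour area / Euclidean area (> 1 = outward bulging);
                     missing when fewer than three vertices are detected.
    """
    cfg = tracked.config
    px2 = cfg.pixel_size ** 2
    rows = []
    for f, lab in enumerate(tracked.labels):
        pix, sets = _neighbor_label_sets(lab)
        bcount: dict[int, int] = {}
        for s in sets:
            for c in s:
                bcount[c] = bcount.get(c, 0) + 1
        vtab = tracked.vertices[tracked.vertices.frame == f]
        vcells = {row.vertex: tracked.vertex_cells[row.vertex] for row in vtab.itertuples()}
        for rp in regionprops(lab):
            cell = int(rp.label)
            area_um2 = rp.area * px2
            # half-pixel Minkowski offset: the region boundary sits half a
            # boundary pixel inside the mid-membrane contour
            perim_um = (rp.perimeter + np.pi) * cfg.pixel_size
            contour_um2 = (rp.area + 0.5 * bcount.get(cell, 0)) * px2
            vsel = vtab[[cell in vcells[v] for v in vtab.vertex]]
            if len(vsel) >= 3:
                pts = vsel[["x", "y"]].to_numpy(dtype=float)
                c0 = pts.mean(axis=0)
                ang = np.arctan2(pts[:, 1] - c0[1], pts[:, 0] - c0[0])
                pts = pts[np.argsort(ang)]
                x, y = pts[:, 0], pts[:, 1]
                euclid = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) * px2
                shape = contour_um2 / euclid if euclid > 0 else np.nan
            else:
                euclid, shape = np.nan, np.nan
            rows.append(dict(frame=f, cell=cell, area_um2=area_um2,
                             perimeter_um=perim_um, contour_area_um2=contour_um2,
                             euclid_area_um2=euclid, shape_metric=shape))
    return pd.DataFrame(rows)
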