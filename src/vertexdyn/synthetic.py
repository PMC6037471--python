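"""Ground-truthed synthetic epithelium movies.

A polygonal tissue (hexagonal lattice) is animated with prescribed per-cell
apical-area oscillations, optional vertex-sliding / line-tension interface
events, and rigid drift, then rendered into a two-channel fluorescence movie
(channel 1: membrane marker with mild vertex enrichment; channel 2: second
junctional marker whose vertex enrichment may lead channel 1 in time).

The generator is the pipeline's test bed: every analysis stage downstream is
validated against the analytic ground truth stored alongside the rendered
images (true polygon coordinates, areas, oscillation phases, interface
lengths, and vertex intensity programs).

Geometry is kinematic, not mechanical: per-frame vertex positions are
obtained by a sparse Gauss-Newton solve that drives every cell's polygon
area to its prescribed sinusoid (and, during interface events, drives the
five involved interface lengths to their prescribed targets) while a weak
tether to the previous frame keeps the mesh conforming and suppresses
null-space drift.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

__all__ = [
    "SimSpec",
    "SlideEvent",
    "GroundTruth",
    "build_lattice",
    "animate",
    "render",
    "export_ground_truth",
    "simulate",
    "make_oscillating_areas",
]


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------

@dataclass
class SlideEvent:
    """A prescribed interface-shortening event.

    mode 'sliding'      : the donor interface loses ``delta_um`` while each of
                          the four transverse interfaces gains ``delta_um/2``
                          (total junctional length conserved on both cell
                          sides -- pure vertex sliding).
    mode 'line_tension' : the donor loses ``delta_um`` while all transverse
                          lengths are held fixed (membrane is removed).
    """

    interface: int
    t_start_s: float
    duration_s: float
    delta_um: float
    mode: str = "sliding"


@dataclass
class SimSpec:
    """Study conditions for one synthetic movie."""

    grid_shape: tuple[int, int] = (5, 5)
    hex_side_um: float = 2.4
    pixel_size: float = 0.2          # um / px
    frame_interval: float = 3.0      # s
    n_frames: int = 100
    # area oscillation
    osc_period_s: float = 150.0
    osc_amplitude: float = 0.10      # fractional area, A = A0*(1 - a*cos(phase))
    osc_phase_offset_deg: float = -180.0  # phase at t=0 (-180 = area maximum)
    period_spread: float = 0.0       # fractional per-cell period randomization
    random_phase: bool = False       # per-cell uniform random phase offsets
    # interface events
    sliding_events: list[SlideEvent] = field(default_factory=list)
    mode: str = "isotropic"          # 'isotropic' | 'ratchet'
    ratchet_rate_um_per_cycle: float = 0.5
    # marker model (intensity ratios at tricellular vertices)
    marker_base_ratio: float = 1.6
    marker_gain: float = 0.5         # ratio modulation amplitude vs cell phase
    marker_lead_s: float = 0.0       # channel-2 temporal lead over channel 1
    background_level: float = 10.0
    junction_level: float = 100.0
    # rendering / noise
    membrane_sigma_px: float = 1.3   # structural membrane line width
    punctum_sigma_px: float = 1.8
    psf_sigma_px: float = 0.7
    read_noise_sd: float = 1.5
    poisson_scale: float = 0.5       # photons-per-count scaling; 0 disables
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # um/s, (vx, vy)
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        if r < 3 or c < 3:
            raise ValueError(f"grid_shape must be at least 3x3, got {r}x{c}")
        if self.osc_period_s <= 2 * self.frame_interval:
            raise ValueError("oscillation period must exceed 2x frame interval")
        if not 0.0 <= self.osc_amplitude < 0.5:
            raise ValueError("osc_amplitude must lie in [0, 0.5)")
        if self.mode not in ("isotropic", "ratchet"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimSpec":
        d = json.loads(text)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["drift_velocity"] = tuple(d["drift_velocity"])
        d["sliding_events"] = [SlideEvent(**e) for e in d.get("sliding_events", [])]
        return cls(**d)


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic tissue state: geometry, programs, and derived tables.

    positions are in micrometres, image convention (x rightward, y downward,
    origin at the top-left of the lattice bounding box before margins).
    """

    spec: SimSpec
    cell_ids: np.ndarray                 # (C,) 1-based ids
    cell_vertices: list[np.ndarray]      # per cell, ordered vertex indices
    vertex_cells: list[frozenset]        # per vertex, adjacent cell ids
    interfaces: np.ndarray               # (E, 2) vertex index pairs
    interface_cells: list[tuple]         # per interface, (cell_a, cell_b|None)
    positions: np.ndarray                # (T, V, 2) um, columns (x, y)
    # filled by animate()
    periods: np.ndarray | None = None    # (C,) s
    amplitudes: np.ndarray | None = None
    phase0: np.ndarray | None = None     # (C,) deg
    target_areas: np.ndarray | None = None   # (T, C) um^2
    true_phase: np.ndarray | None = None     # (T, C) deg in (-180, 180]
    intensity_ratio: np.ndarray | None = None  # (T, V, 2) prescribed ratios

    # -- basic geometry -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_cells)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def polygon(self, cell: int, frame: int = 0) -> np.ndarray:
        """(k, 2) polygon coordinates of ``cell`` (1-based id) at ``frame``."""
        idx = self.cell_vertices[cell - 1]
        return self.positions[frame, idx]

    def cell_areas(self, frame: int) -> np.ndarray:
        return np.array(
            [abs(_shoelace(self.positions[frame, vidx]))
             for vidx in self.cell_vertices]
        )

    def cell_centroids(self, frame: int) -> np.ndarray:
        return np.array(
            [self.positions[frame, vidx].mean(axis=0)
             for vidx in self.cell_vertices]
        )

    def interface_lengths(self, frame: int) -> np.ndarray:
        p = self.positions[frame]
        d = p[self.interfaces[:, 0]] - p[self.interfaces[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def interface_orientations(self, frame: int = 0) -> np.ndarray:
        """Orientation in degrees in [0, 180), measured from +x."""
        p = self.positions[frame]
        d = p[self.interfaces[:, 1]] - p[self.interfaces[:, 0]]
        return np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0

    def interior_cells(self) -> np.ndarray:
        """Cells all of whose vertices are tricellular (not on tissue rim)."""
        keep = []
        for cid, vidx in zip(self.cell_ids, self.cell_vertices):
            if all(len(self.vertex_cells[v]) == 3 for v in vidx):
                keep.append(cid)
        return np.array(keep, dtype=int)

    def interior_vertices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.vertex_cells) if len(s) == 3],
            dtype=int,
        )

    def vertical_interfaces(self, half_angle: float = 30.0,
                            ventral_angle: float = 90.0) -> np.ndarray:
        ori = self.interface_orientations(0)
        d = np.abs((ori - ventral_angle + 90.0) % 180.0 - 90.0)
        return np.flatnonzero(d <= half_angle)

    def transverse_partners(self, iface: int) -> dict:
        """Transverse interfaces of ``iface`` keyed by (vertex index, cell id).

        For each endpoint vertex and each flanking cell, the other interface
        of that cell's polygon incident at the vertex.
        """
        v0, v1 = self.interfaces[iface]
        ca, cb = self.interface_cells[iface]
        edge_lookup = {}
        for e, (a, b) in enumerate(self.interfaces):
            edge_lookup[frozenset((int(a), int(b)))] = e
        out = {}
        for v in (int(v0), int(v1)):
            for cell in (ca, cb):
                if cell is None:
                    continue
                vidx = self.cell_vertices[cell - 1]
                k = int(np.flatnonzero(vidx == v)[0])
                nb = {int(vidx[(k - 1) % len(vidx)]), int(vidx[(k + 1) % len(vidx)])}
                for other in nb:
                    e = edge_lookup.get(frozenset((v, other)))
                    if e is not None and e != iface:
                        out.setdefault((v, cell), []).append(e)
        return {k: v[0] for k, v in out.items() if v}


def _shoelace(p: np.ndarray) -> float:
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# --------------------------------------------------------------------------
# lattice construction
# --------------------------------------------------------------------------

def build_lattice(spec: SimSpec) -> GroundTruth:
    """Frame-0 hexagonal tiling (pointy-top, so left/right edges run along y).

    Every interior vertex has exactly three incident cells and the planar
    graph satisfies Euler's relation V - E + F = 2 (outer face included).
    """
    rows, cols = spec.grid_shape
    s = spec.hex_side_um
    dx, dy = np.sqrt(3.0) * s, 1.5 * s
    angles = np.radians([90.0, 150.0, 210.0, 270.0, 330.0, 30.0])
    offsets = np.column_stack([s * np.cos(angles), s * np.sin(angles)])

    vert_index: dict[tuple[int, int], int] = {}
    coords: list[np.ndarray] = []
    cell_vertices: list[np.ndarray] = []
    vertex_cells: list[set] = []

    def vid_of(p: np.ndarray) -> int:
        key = (round(p[0] * 1e6), round(p[1] * 1e6))
        if key not in vert_index:
            vert_index[key] = len(coords)
            coords.append(p.copy())
            vertex_cells.append(set())
        return vert_index[key]

    cid = 0
    for i in range(rows):
        for j in range(cols):
            cid += 1
            c = np.array([j * dx + (i % 2) * dx / 2.0, i * dy])
            vids = np.array([vid_of(c + off) for off in offsets])
            cell_vertices.append(vids)
            for v in vids:
                vertex_cells[v].add(cid)

    interfaces: dict[frozenset, list] = {}
    for cell, vids in enumerate(cell_vertices, start=1):
        for k in range(len(vids)):
            key = frozenset((int(vids[k]), int(vids[(k + 1) % len(vids)])))
            interfaces.setdefault(key, []).append(cell)
    iface_pairs = []
    iface_cells = []
    for key, cells in sorted(interfaces.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        iface_pairs.append((a, b))
        cells = sorted(cells)
        iface_cells.append((cells[0], cells[1] if len(cells) > 1 else None))

    pos = np.asarray(coords)
    pos -= pos.min(axis=0)
    return GroundTruth(
        spec=spec,
        cell_ids=np.arange(1, cid + 1),
        cell_vertices=cell_vertices,
        vertex_cells=[frozenset(s) for s in vertex_cells],
        interfaces=np.asarray(iface_pairs, dtype=int),
        interface_cells=iface_cells,
        positions=pos[None, :, :],
    )


# --------------------------------------------------------------------------
# animation
# --------------------------------------------------------------------------

def _true_phase_deg(spec: SimSpec, periods, phase0, t) -> np.ndarray:
    """Analysis-convention phase: 0 deg at area minimum, +-180 at maximum."""
    theta = 360.0 * np.asarray(t)[:, None] / periods[None, :] + phase0[None, :]
    return (theta + 180.0) % 360.0 - 180.0


class _FrameSolver:
    """Sparse Gauss-Newton solve of per-frame vertex positions."""

    def __init__(self, gt: GroundTruth, w_area=1.0, w_len=30.0, w_tether=1e-3):
        self.gt = gt
        self.wA, self.wL, self.wR = w_area, w_len, w_tether
        self.A0 = gt.cell_areas(0)
        self.sign0 = np.array(
            [np.sign(_shoelace(gt.positions[0, vidx])) or 1.0
             for vidx in gt.cell_vertices]
        )
        self.scale = gt.spec.hex_side_um

        # static structure: all cells share the same polygon arity on a
        # hexagonal lattice, enabling vectorized residuals/jacobians
        self.vidx = np.array([np.asarray(v) for v in gt.cell_vertices])
        C, K = self.vidx.shape
        self.knext = np.roll(np.arange(K), -1)
        self.kprev = np.roll(np.arange(K), 1)
        rows = np.repeat(np.arange(C), 2 * K)
        cols = np.empty((C, K, 2), dtype=int)
        cols[..., 0] = 2 * self.vidx
        cols[..., 1] = 2 * self.vidx + 1
        self.area_rows = rows
        self.area_cols = cols.reshape(-1)

    def solve(self, x0, area_targets, length_targets, tether_to,
              max_iter=40, tol=1e-9):
        gt = self.gt
        x = x0.reshape(-1).astype(float).copy()
        t0 = tether_to.reshape(-1)
        nv = gt.n_vertices
        C, K = self.vidx.shape
        nL = len(length_targets)
        if nL:
            ij = np.array([t[0] for t in length_targets], dtype=int)
            ltar = np.array([t[1] for t in length_targets], dtype=float)
        lam = 1e-12
        for _ in range(max_iter):
            p = x.reshape(nv, 2)
            poly = p[self.vidx]                                   # (C, K, 2)
            area = 0.5 * np.sum(poly[:, :, 0] * poly[:, self.knext, 1]
                                - poly[:, self.knext, 0] * poly[:, :, 1], axis=1)
            area = self.sign0 * area
            res_a = self.wA * (area - area_targets) / self.A0
            gA = np.empty((C, K, 2))
            gA[..., 0] = 0.5 * (poly[:, self.knext, 1] - poly[:, self.kprev, 1])
            gA[..., 1] = 0.5 * (poly[:, self.kprev, 0] - poly[:, self.knext, 0])
            gA *= (self.wA * self.sign0 / self.A0)[:, None, None]
            rows = [self.area_rows]
            cols = [self.area_cols]
            vals = [gA.reshape(-1)]
            ri = C
            if nL:
                d = p[ij[:, 0]] - p[ij[:, 1]]
                L = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)
                res_l = self.wL * (L - ltar) / self.scale
                u = (self.wL / self.scale) * d / L[:, None]
                rows.append(np.repeat(np.arange(ri, ri + nL), 4))
                cols.append(np.column_stack([2 * ij[:, 0], 2 * ij[:, 0] + 1,
                                             2 * ij[:, 1], 2 * ij[:, 1] + 1]).reshape(-1))
                vals.append(np.column_stack([u, -u]).reshape(-1))
                ri += nL
            else:
                res_l = np.empty(0)
            tet = self.wR * (x - t0)
            rows.append(np.arange(ri, ri + 2 * nv))
            cols.append(np.arange(2 * nv))
            vals.append(np.full(2 * nv, self.wR))
            res = np.concatenate([res_a, res_l, tet])
            J = sp.csr_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(ri + 2 * nv, 2 * nv))
            g = J.T @ res
            H = (J.T @ J + lam * sp.eye(2 * nv)).tocsc()
            x += spla.spsolve(H, -g)
            if np.max(np.abs(res[:ri])) < tol:
                break
        return x.reshape(nv, 2)


def _event_schedule(gt: GroundTruth, spec: SimSpec):
    """Per-frame interface-length offsets: dict frame -> list of (iface, delta, mode)."""
    T = spec.n_frames
    t = spec.times
    deltas = {}  # iface -> (delta array over frames, mode)
    for ev in spec.sliding_events:
        frac = np.clip((t - ev.t_start_s) / max(ev.duration_s, 1e-9), 0.0, 1.0)
        d = ev.delta_um * frac
        if ev.interface in deltas:
            raise ValueError("multiple events on one interface are not supported")
        L0 = gt.interface_lengths(0)[ev.interface]
        if ev.delta_um >= L0:
            raise ValueError(
                f"slide length {ev.delta_um} um exceeds donor interface length {L0:.3f} um"
            )
        deltas[ev.interface] = (d, ev.mode)
    if spec.mode == "ratchet":
        dt = spec.frame_interval
        vert = gt.vertical_interfaces()
        L0 = gt.interface_lengths(0)
        for e in vert:
            ca = gt.interface_cells[e][0]
            phase = gt.true_phase[:, ca - 1]
            contracting = (phase < 0.0).astype(float)
            half_period = gt.periods[ca - 1] / 2.0
            d = spec.ratchet_rate_um_per_cycle * np.cumsum(contracting * dt) / half_period
            d = np.minimum(d, 0.6 * L0[e])
            if e not in deltas:
                deltas[e] = (d, "sliding")
    return deltas


def animate(gt: GroundTruth, spec: SimSpec | None = None) -> GroundTruth:
    """Animate frame-0 geometry through all frames of the spec.

    Per frame the solver drives every cell's polygon area to
    ``A0 * (1 - amplitude * cos(phase))`` and, for active interface events,
    the five involved interface lengths to their prescribed targets; drift is
    then added as a rigid translation.
    """
    spec = spec or gt.spec
    rng = np.random.default_rng(spec.seed)
    C, T = gt.n_cells, spec.n_frames
    periods = np.full(C, float(spec.osc_period_s))
    if spec.period_spread > 0:
        periods *= 1.0 + spec.period_spread * rng.uniform(-1, 1, size=C)
    phase0 = np.full(C, float(spec.osc_phase_offset_deg))
    if spec.random_phase:
        phase0 = rng.uniform(-180.0, 180.0, size=C)
    amps = np.full(C, float(spec.osc_amplitude))

    gt.periods, gt.phase0, gt.amplitudes = periods, phase0, amps
    gt.true_phase = _true_phase_deg(spec, periods, phase0, spec.times)
    A0 = gt.cell_areas(0)
    gt.target_areas = A0[None, :] * (1.0 - amps[None, :] * np.cos(np.radians(gt.true_phase)))

    deltas = _event_schedule(gt, spec)
    solver = _FrameSolver(gt)
    V = gt.n_vertices
    pos = np.empty((T, V, 2))
    pos[0] = gt.positions[0]
    # isotropy-preserving predictor: scale frame-0 positions about the tissue
    # center with a per-vertex local factor (mean sqrt area ratio of the
    # adjacent cells). For spatially uniform phases this is an exact global
    # scaling -- every length scales with sqrt(area), so fractional lengths
    # are constant by construction -- and the Gauss-Newton solve only has to
    # polish residual area errors for non-uniform phase fields.
    p0 = gt.positions[0]
    ctr = p0.mean(axis=0)
    counts = np.zeros(V)
    for vidx in gt.cell_vertices:
        counts[vidx] += 1
    offset = np.zeros((V, 2))
    for f in range(T):
        targets = gt.target_areas[f]
        scale = np.sqrt(targets / A0)
        s_v = np.zeros(V)
        for c, vidx in enumerate(gt.cell_vertices):
            s_v[vidx] += scale[c]
        s_v /= counts
        pred = ctr + s_v[:, None] * (p0 - ctr)
        x_free = solver.solve(pred, targets, [], tether_to=pred)
        if deltas:
            # baseline (event-free) lengths at this frame define event targets
            lt = []
            pfree = x_free
            for e, (d, mode) in deltas.items():
                if d[f] <= 0:
                    continue
                i, j = map(int, gt.interfaces[e])
                base = float(np.hypot(*(pfree[i] - pfree[j])))
                lt.append(((i, j), max(base - d[f], 0.05)))
                for (v, cell), te in gt.transverse_partners(e).items():
                    ti, tj = map(int, gt.interfaces[te])
                    tbase = float(np.hypot(*(pfree[ti] - pfree[tj])))
                    gain = d[f] / 2.0 if mode == "sliding" else 0.0
                    lt.append(((ti, tj), tbase + gain))
            # carry the event displacement field on top of the isotropic state
            start = x_free + offset
            x_full = solver.solve(start, targets, lt, tether_to=start)
            offset = x_full - x_free
            pos[f] = x_full
        else:
            pos[f] = x_free
    drift = np.asarray(spec.drift_velocity)[None, None, :] * spec.times[:, None, None]
    gt.positions = pos + drift

    # vertex intensity programs (prescribed ratios, both channels)
    ratios = np.full((T, V, 2), 1.0)
    interior = gt.interior_vertices()
    for v in interior:
        cell = min(gt.vertex_cells[v])
        for ch, lead in enumerate((0.0, spec.marker_lead_s)):
            ph = _true_phase_deg(spec, periods[[cell - 1]], phase0[[cell - 1]],
                                 spec.times + lead)[:, 0]
            ratios[:, v, ch] = spec.marker_base_ratio + spec.marker_gain * np.cos(np.radians(ph))
    gt.intensity_ratio = ratios
    return gt


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _roi_masks_local(skel: np.ndarray, vertex_yx: tuple[int, int]):
    """Vertex / junction / background masks for render calibration.

    Mirrors the measurement definition: vertex = within 3 px of the vertex
    pixel, junction = within 3 px of the skeleton minus the vertex disk,
    background = at least 7 px from the skeleton.
    """
    d_line = ndimage.distance_transform_edt(~skel)
    vm = np.zeros_like(skel)
    vm[vertex_yx] = True
    d_vert = ndimage.distance_transform_edt(~vm)
    vertex = d_vert <= 3.0
    junction = (d_line <= 3.0) & ~vertex
    background = d_line >= 7.0
    return vertex, junction, background


def _punctum_field(shape, centers, sigma):
    """Sum of unit-amplitude puncta; sigma 0 collapses to single pixels."""
    out = np.zeros(shape)
    if sigma <= 0:
        for cy, cx in centers:
            out[int(round(cy)), int(round(cx))] += 1.0
        return out
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    for cy, cx in centers:
        out += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return out


def _render_calibration(spec: SimSpec):
    """Linear intensity-response coefficients on a lattice-like junction patch.

    The patch reproduces the local geometry of a tricellular vertex in the
    hexagonal tissue (three edges of the actual pixel edge length; neighbor
    vertices carry their own puncta) so that the measured junction ROI
    includes the same neighbor-punctum spill as in a rendered movie.

    Returns (fJ, fVm, fVp, fJp): junction-/vertex-ROI means of a unit
    membrane profile and of unit-amplitude puncta (center + neighbors), all
    after PSF blurring. Punctum amplitudes can then be solved per vertex so
    that the distance-transform ROI measurement recovers the prescribed
    intensity ratio.
    """
    from skimage.draw import line as draw_line

    s_px = spec.hex_side_um / spec.pixel_size
    n = int(2 * (s_px + 48)) | 1
    c = n // 2
    skel = np.zeros((n, n), dtype=bool)
    centers = [(float(c), float(c))]
    for ang in (90.0, 210.0, 330.0):
        ex = c + s_px * np.cos(np.radians(ang))
        ey = c + s_px * np.sin(np.radians(ang))
        rr, cc = draw_line(c, c, int(round(ey)), int(round(ex)))
        skel[rr, cc] = True
        centers.append((ey, ex))
        for branch in (ang + 120.0, ang - 120.0):
            bx = ex + s_px * np.cos(np.radians(branch))
            by = ey + s_px * np.sin(np.radians(branch))
            rr, cc = draw_line(int(round(ey)), int(round(ex)),
                               int(round(by)), int(round(bx)))
            skel[rr, cc] = True
    d_line = ndimage.distance_transform_edt(~skel)
    if spec.membrane_sigma_px > 0:
        mem = np.exp(-d_line ** 2 / (2 * spec.membrane_sigma_px ** 2))
    else:
        mem = skel.astype(float)
    punct = _punctum_field((n, n), centers, spec.punctum_sigma_px)
    if spec.psf_sigma_px > 0:
        mem = ndimage.gaussian_filter(mem, spec.psf_sigma_px)
        punct = ndimage.gaussian_filter(punct, spec.psf_sigma_px)
    # restrict ROIs to the 41x41 neighborhood of the central vertex
    win = (slice(c - 20, c + 21), slice(c - 20, c + 21))
    vm, jm, _ = _roi_masks_local(skel, (c, c))
    vm, jm = vm[win], jm[win]
    mem_w, punct_w = mem[win], punct[win]
    return (float(mem_w[jm].mean()), float(mem_w[vm].mean()),
            float(punct_w[vm].mean()), float(punct_w[jm].mean()))


def render(gt: GroundTruth, spec: SimSpec | None = None,
           margin_px: int | None = None) -> np.ndarray:
    """Render the animated tissue into a (T, 2, H, W) float32 stack.

    Channel intensities are calibrated so that, for an ideal straight-edged
    junction, the measured junction-ROI mean equals ``junction_level`` and
    the vertex-ROI mean equals ``background + (junction - background) *
    prescribed_ratio`` -- i.e. the prescribed intensity ratio is recovered by
    the distance-transform ROI measurement up to geometry and noise.
    """
    from skimage.draw import line as draw_line

    spec = spec or gt.spec
    if gt.true_phase is None:
        raise ValueError("render requires an animated ground truth (call animate first)")
    if margin_px is None:
        margin_px = int(np.ceil(24 + 4 * spec.psf_sigma_px))
    px = gt.positions / spec.pixel_size
    origin = px.min(axis=(0, 1)) - margin_px
    px = px - origin
    H = int(np.ceil(px[..., 1].max())) + margin_px + 1
    W = int(np.ceil(px[..., 0].max())) + margin_px + 1
    if H < 41 or W < 41:
        raise ValueError("image too small to contain lattice plus PSF/ROI margin")

    fJ, fVm, fVp, fJp = _render_calibration(spec)
    B, J = spec.background_level, spec.junction_level
    mem_amp = (J - B) / fJ
    rng = np.random.default_rng(spec.seed + 1)
    interior = gt.interior_vertices()
    out = np.empty((spec.n_frames, 2, H, W), dtype=np.float32)
    yy, xx = np.mgrid[0:13, 0:13].astype(float)  # punctum stamp window
    for f in range(spec.n_frames):
        skel = np.zeros((H, W), dtype=bool)
        p = px[f]
        for i, j in gt.interfaces:
            x0, y0 = np.round(p[i]).astype(int)
            x1, y1 = np.round(p[j]).astype(int)
            rr, cc = draw_line(y0, x0, y1, x1)
            skel[rr, cc] = True
        if spec.membrane_sigma_px > 0:
            d_line = ndimage.distance_transform_edt(~skel)
            mem = np.exp(-d_line ** 2 / (2 * spec.membrane_sigma_px ** 2))
        else:
            mem = skel.astype(float)
        for ch in range(2):
            img = B + mem_amp * mem
            for v in interior:
                ratio = gt.intensity_ratio[f, v, ch]
                amp = mem_amp * (ratio * fJ - fVm) / (fVp - ratio * fJp)
                cxv, cyv = p[v]
                iy, ix = int(round(cyv)) - 6, int(round(cxv)) - 6
                if iy < 0 or ix < 0 or iy + 13 > H or ix + 13 > W:
                    continue
                if spec.punctum_sigma_px > 0:
                    g = np.exp(-((yy + iy - cyv) ** 2 + (xx + ix - cxv) ** 2)
                               / (2 * spec.punctum_sigma_px ** 2))
                    img[iy:iy + 13, ix:ix + 13] += amp * g
                else:
                    img[int(round(cyv)), int(round(cxv))] += amp
            if spec.psf_sigma_px > 0:
                img = ndimage.gaussian_filter(img, spec.psf_sigma_px)
            if spec.poisson_scale > 0:
                img = rng.poisson(np.clip(img, 0, None) / spec.poisson_scale) * spec.poisson_scale
            if spec.read_noise_sd > 0:
                img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
            out[f, ch] = np.clip(img, 0, None)
    return out


def pixel_positions(gt: GroundTruth, spec: SimSpec | None = None,
                    margin_px: int | None = None) -> np.ndarray:
    """Vertex positions in pixel coordinates of the rendered stack."""
    spec = spec or gt.spec
    if margin_px is None:
        margin_px = int(np.ceil(24 + 4 * spec.psf_sigma_px))
    px = gt.positions / spec.pixel_size
    origin = px.min(axis=(0, 1)) - margin_px
    return px - origin


# --------------------------------------------------------------------------
# export / convenience
# --------------------------------------------------------------------------

def export_ground_truth(gt: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write per-frame cell/vertex/interface truth tables as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    T = gt.n_frames
    rows = []
    for f in range(T):
        cent = gt.cell_centroids(f)
        areas = gt.cell_areas(f)
        for c in range(gt.n_cells):
            rows.append(dict(frame=f, cell=int(gt.cell_ids[c]),
                             x=cent[c, 0], y=cent[c, 1], area=areas[c],
                             phase=(gt.true_phase[f, c] if gt.true_phase is not None else np.nan),
                             period=(gt.periods[c] if gt.periods is not None else np.nan)))
    cells = pd.DataFrame(rows)
    rows = []
    for f in range(T):
        for v in range(gt.n_vertices):
            r = gt.intensity_ratio[f, v] if gt.intensity_ratio is not None else (np.nan, np.nan)
            rows.append(dict(frame=f, vertex=v,
                             x=gt.positions[f, v, 0], y=gt.positions[f, v, 1],
                             n_cells=len(gt.vertex_cells[v]),
                             cells="|".join(map(str, sorted(gt.vertex_cells[v]))),
                             ratio_ch1=r[0], ratio_ch2=r[1]))
    vertices = pd.DataFrame(rows)
    rows = []
    for f in range(T):
        L = gt.interface_lengths(f)
        ori = gt.interface_orientations(f)
        for e in range(len(gt.interfaces)):
            a, b = gt.interface_cells[e]
            rows.append(dict(frame=f, interface=e,
                             v0=int(gt.interfaces[e, 0]), v1=int(gt.interfaces[e, 1]),
                             cell_a=a, cell_b=(b if b is not None else -1),
                             length=L[e], orientation=ori[e]))
    ifaces = pd.DataFrame(rows)
    paths = {}
    for name, df in (("cells", cells), ("vertices", vertices), ("interfaces", ifaces)):
        p = outdir / f"truth_{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    (outdir / "simspec.json").write_text(gt.spec.to_json())
    return paths


def simulate(spec: SimSpec, outdir: str | Path | None = None):
    """Build, animate, and render a movie; optionally write TIFF + truth CSVs.

    Returns (ground truth, image stack).
    """
    gt = animate(build_lattice(spec), spec)
    stack = render(gt, spec)
    if outdir is not None:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        T, _, H, W = stack.shape
        tifffile.imwrite(outdir / "movie.tif", stack.reshape(T * 2, H, W))
        export_ground_truth(gt, outdir)
    return gt, stack


def make_marker_traces(n_vertices: int, duration_s: float, frame_interval: float,
                       lead_s: float = 3.0, period_range_s=(100.0, 300.0),
                       base_ratio: float = 1.6, gain: float = 0.5,
                       stochastic_sd: float = 0.3, stochastic_corr_s: float = 8.0,
                       noise_sd: float = 0.05, seed: int = 0):
    """Paired two-channel vertex intensity-ratio programs.

    Each vertex's enrichment is a slow phase-locked component (maximal at
    area phase 0, the end of contraction) plus a shared broadband stochastic
    component with correlation time ``stochastic_corr_s`` (transient
    recruitment fluctuations seen by both markers). Channel 2 evaluates the
    common signal ``lead_s`` seconds ahead of channel 1, i.e. channel 2
    leads in time; independent white measurement noise is added per channel.
    Returns (t, ch1, ch2) with trace arrays of shape (n_vertices, T).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, frame_interval)
    fine = min(frame_interval, 0.5)
    tt = np.arange(0.0, duration_s + abs(lead_s) + 20.0, fine)
    periods = rng.uniform(*period_range_s, size=n_vertices)
    phase0 = rng.uniform(-180.0, 180.0, size=n_vertices)
    ch1 = np.empty((n_vertices, len(t)))
    ch2 = np.empty((n_vertices, len(t)))
    for v in range(n_vertices):
        w = ndimage.gaussian_filter1d(rng.normal(0.0, 1.0, len(tt)),
                                      stochastic_corr_s / fine)
        sd = np.std(w)
        sto = w / sd * stochastic_sd if sd > 0 else w

        def signal(ts):
            ph = np.radians(360.0 * ts / periods[v] + phase0[v])
            return base_ratio + gain * np.cos(ph) + np.interp(ts, tt, sto)

        ch1[v] = signal(t)
        ch2[v] = signal(t + lead_s)
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, ch1.shape)
        ch2 = ch2 + rng.normal(0.0, noise_sd, ch2.shape)
    return t, ch1, ch2


def central_vertical_interface(gt: GroundTruth) -> int:
    """A vertical interface near the tissue center flanked by interior cells
    (the canonical site for injecting a T1 contraction)."""
    interior = set(gt.interior_cells())
    center = gt.positions[0].mean(axis=0)
    best, best_d = None, np.inf
    for e in gt.vertical_interfaces():
        a, b = gt.interface_cells[e]
        if b is None or a not in interior or b not in interior:
            continue
        mid = gt.positions[0, gt.interfaces[e]].mean(axis=0)
        d = float(np.hypot(*(mid - center)))
        if d < best_d:
            best, best_d = int(e), d
    if best is None:
        raise ValueError("no interior vertical interface available")
    return best


def add_t1_event(spec: SimSpec, t_start_s: float = 60.0,
                 duration_s: float = 150.0,
                 final_length_um: float = 0.15) -> SimSpec:
    """Inject one full T1 contraction (sliding mode) on a central vertical
    interface; the donor shrinks to ``final_length_um`` and holds there."""
    gt = build_lattice(spec)
    e = central_vertical_interface(gt)
    L0 = float(gt.interface_lengths(0)[e])
    spec.sliding_events = list(spec.sliding_events) + [
        SlideEvent(interface=e, t_start_s=t_start_s, duration_s=duration_s,
                   delta_um=L0 - final_length_um)
    ]
    return spec


def make_oscillating_areas(n_cells: int, duration_s: float, frame_interval: float,
                           period_range_s=(100.0, 300.0), mean_area_um2: float = 35.0,
                           amplitude: float = 0.10, snr: float = 5.0,
                           seed: int = 0):
    """Analytic per-cell area series for phase-recovery benchmarks.

    Each cell's area is ``A0 * (1 - a * cos(phase(t)))`` with a random period
    and phase offset, plus white Gaussian noise of sd ``a*A0/snr`` (snr = 0 or
    inf disables noise). Returns (times, areas (n, T), true phase deg (n, T)).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, frame_interval)
    periods = rng.uniform(*period_range_s, size=n_cells)
    phase0 = rng.uniform(-180.0, 180.0, size=n_cells)
    phase = (360.0 * t[None, :] / periods[:, None] + phase0[:, None] + 180.0) % 360.0 - 180.0
    a = amplitude * mean_area_um2
    areas = mean_area_um2 - a * np.cos(np.radians(phase))
    if snr and np.isfinite(snr) and snr > 0:
        areas = areas + rng.normal(0.0, a / snr, size=areas.shape)
    return t, areas, phase
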