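"""Seeded-watershed segmentation and tissue-graph extraction.

A membrane-channel frame is segmented into cells by a seeded watershed
(seeds = regional minima of the Gaussian-smoothed image after h-minima
suppression), producing an integer label image whose zero-valued pixels form
the one-pixel watershed skeleton. The skeleton directly yields the tissue
graph: tricellular vertices (clusters of skeleton pixels whose 8-neighborhood
touches >= 3 distinct cell labels) and interfaces (skeleton segments flanked
by exactly two labels, bounded by two vertices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_minima
from skimage.segmentation import watershed

__all__ = [
    "DegenerateSegmentationError",
    "Vertex",
    "Interface",
    "TissueGraph",
    "segment_frame",
    "extract_tissue_graph",
]


class DegenerateSegmentationError(ValueError):
    """Raised when segmentation collapses to fewer than two regions."""


@dataclass
class Vertex:
    id: int
    y: float
    x: float
    cells: frozenset


@dataclass
class Interface:
    id: int
    v0: int
    v1: int
    cells: frozenset
    pixels: np.ndarray  # (N, 2) y,x skeleton pixels of the contour


@dataclass
class TissueGraph:
    """Per-frame skeletonized segmentation and connectivity."""

    labels: np.ndarray
    vertices: list[Vertex] = field(default_factory=list)
    interfaces: list[Interface] = field(default_factory=list)

    @property
    def skeleton(self) -> np.ndarray:
        return self.labels == 0

    def border_cells(self) -> set[int]:
        lab = self.labels
        edge = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        return set(int(v) for v in np.unique(edge) if v != 0)

    def cell_vertices(self, cell: int) -> list[Vertex]:
        return [v for v in self.vertices if cell in v.cells]

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def interface_by_cells(self, a: int, b: int) -> Interface | None:
        key = frozenset((a, b))
        for e in self.interfaces:
            if e.cells == key:
                return e
        return None


def segment_frame(
    image: np.ndarray,
    sigma: float = 1.5,
    h: float | None = None,
    min_cell_area: int = 40,
) -> np.ndarray:
    """Seeded-watershed labels with 1-px boundary lines (label 0).

    Seeds are the regional minima of the Gaussian-smoothed membrane image
    after h-minima suppression (``h`` defaults to 10% of the robust intensity
    range). Regions smaller than ``min_cell_area`` pixels lose their seed and
    are re-flooded by their neighbors.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single-channel 2D image")
    sm = ndimage.gaussian_filter(img, sigma)
    lo, hi = np.percentile(sm, (1, 99))
    if hi - lo <= 0:
        warnings.warn("flat image: single degenerate region", stacklevel=2)
        return np.ones_like(img, dtype=np.int32)
    if h is None:
        h = 0.10 * (hi - lo)
    minima = h_minima(sm, h)
    markers, n = ndimage.label(minima)
    if n < 2:
        warnings.warn("fewer than two seeds: single degenerate region", stacklevel=2)
        return np.ones_like(img, dtype=np.int32)
    for _ in range(3):
        labels = watershed(sm, markers, watershed_line=True)
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = set(ids[counts < min_cell_area])
        if not small:
            break
        keep = ~np.isin(markers, list(small))
        markers = markers * keep
        if len(np.unique(markers)) <= 2:  # background + at most one seed
            raise DegenerateSegmentationError(
                "all regions below min_cell_area; segmentation degenerate"
            )
    return labels.astype(np.int32)


_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_label_sets(labels: np.ndarray):
    """For each skeleton pixel, the set of distinct nonzero labels among its
    8-neighbors. Returns (pixel coords (N,2), list of frozensets)."""
    skel = labels == 0
    ys, xs = np.nonzero(skel)
    H, W = labels.shape
    stacked = np.zeros((len(_SHIFTS), len(ys)), dtype=labels.dtype)
    for k, (dy, dx) in enumerate(_SHIFTS):
        yy = np.clip(ys + dy, 0, H - 1)
        xx = np.clip(xs + dx, 0, W - 1)
        stacked[k] = labels[yy, xx]
    sets = [frozenset(int(v) for v in col if v != 0) for col in stacked.T]
    return np.column_stack([ys, xs]), sets


def extract_tissue_graph(labels: np.ndarray, merge_radius: float = 2.0) -> TissueGraph:
    """Build the tissue graph from a label image.

    Vertices are centroids of connected clusters of junction pixels
    (skeleton pixels touching >= 3 labels); clusters closer than
    ``merge_radius`` px are merged (transient 4-fold configurations).
    Interfaces are skeleton segments flanked by exactly two labels, with the
    two vertices adjacent to both labels as endpoints. An empty graph is
    returned when the image has no skeleton or fewer than three labels meet
    anywhere.
    """
    graph = TissueGraph(labels=np.asarray(labels))
    if (graph.labels == 0).sum() == 0:
        return graph
    pix, sets = _neighbor_label_sets(graph.labels)
    n3 = np.array([len(s) >= 3 for s in sets])
    # --- vertices ---------------------------------------------------------
    jmask = np.zeros(graph.labels.shape, dtype=bool)
    if n3.any():
        jmask[pix[n3, 0], pix[n3, 1]] = True
    clusters, nc = ndimage.label(jmask, structure=np.ones((3, 3)))
    cl_of_pix = clusters[pix[:, 0], pix[:, 1]]
    cents, cellsets = [], []
    for c in range(1, nc + 1):
        sel = n3 & (cl_of_pix == c)
        cents.append(pix[sel].astype(float).mean(axis=0))
        cellsets.append(frozenset().union(*[sets[i] for i in np.flatnonzero(sel)]))
    merged = [False] * nc
    for i in range(nc):
        if merged[i]:
            continue
        grp = [i]
        merged[i] = True
        for j in range(i + 1, nc):
            if not merged[j] and np.linalg.norm(cents[i] - cents[j]) <= merge_radius:
                grp.append(j)
                merged[j] = True
        pos = np.mean([cents[g] for g in grp], axis=0)
        cells = frozenset().union(*[cellsets[g] for g in grp])
        graph.vertices.append(
            Vertex(id=len(graph.vertices), y=float(pos[0]), x=float(pos[1]), cells=cells)
        )
    # --- interfaces -------------------------------------------------------
    pair_of_pix: dict[frozenset, list[int]] = {}
    for i, s in enumerate(sets):
        if len(s) == 2:
            pair_of_pix.setdefault(s, []).append(i)
    for pair, idxs in sorted(pair_of_pix.items(), key=lambda kv: sorted(kv[0])):
        cand = [v for v in graph.vertices if pair <= v.cells]
        if len(cand) < 2:
            continue
        pts = pix[idxs].astype(float)
        d = pts - pts.mean(axis=0)
        if len(pts) > 1:
            _, _, vt = np.linalg.svd(d, full_matrices=False)
            order = np.argsort(d @ vt[0])
            pts = pts[order]
        vsel = []
        for endpt in (pts[0], pts[-1]):
            dist = [np.hypot(v.y - endpt[0], v.x - endpt[1]) for v in cand]
            vsel.append(cand[int(np.argmin(dist))])
        if vsel[0].id == vsel[1].id:
            if len(cand) == 2:
                vsel = cand
            else:
                continue
        graph.interfaces.append(
            Interface(id=len(graph.interfaces), v0=vsel[0].id, v1=vsel[1].id,
                      cells=pair, pixels=pts.astype(int))
        )
    return graph
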