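"""Shared fixtures: synthetic movies and their tracked pipelines.

Heavy artifacts (the rendered T1 movie and its segmentation/tracking) are
session-scoped so the integration and acceptance tests share one copy.
"""

import numpy as np
import pytest

from vertexdyn import segmentation as seg
from vertexdyn import synthetic as syn
from vertexdyn import tracking as trk


@pytest.fixture(scope="session")
def t1_spec():
    """Default 25-cell, 100-frame study movie with one injected T1."""
    spec = syn.SimSpec(grid_shape=(5, 5), n_frames=100, seed=3)
    return syn.add_t1_event(spec, t_start_s=60.0, duration_s=150.0)


@pytest.fixture(scope="session")
def t1_movie(t1_spec):
    gt, stack = syn.simulate(t1_spec)
    return gt, stack


@pytest.fixture(scope="session")
def t1_tracked(t1_spec, t1_movie):
    _, stack = t1_movie
    graphs = [seg.extract_tissue_graph(seg.segment_frame(stack[f, 0]))
              for f in range(stack.shape[0])]
    cfg = trk.TrackConfig(pixel_size=t1_spec.pixel_size,
                          frame_interval=t1_spec.frame_interval)
    return trk.track(graphs, cfg)


@pytest.fixture(scope="session")
def small_gt():
    """Animated (not rendered) 5x5 tissue, 40 frames, default oscillation."""
    spec = syn.SimSpec(grid_shape=(5, 5), n_frames=40, seed=1)
    return syn.animate(syn.build_lattice(spec), spec)


@pytest.fixture(scope="session")
def quiet_render():
    """Tiny noiseless rendered movie for ROI/render fidelity checks."""
    spec = syn.SimSpec(grid_shape=(5, 5), n_frames=2, osc_amplitude=0.05,
                       marker_base_ratio=2.0, marker_gain=0.0,
                       read_noise_sd=0.0, poisson_scale=0.0, seed=2)
    gt, stack = syn.simulate(spec)
    return spec, gt, stack


def truth_skeleton(gt, spec, frame=0):
    """Rasterized ground-truth skeleton in rendered pixel coordinates."""
    from skimage.draw import line as draw_line

    px = syn.pixel_positions(gt, spec)
    H = int(np.ceil(px[..., 1].max())) + 26
    W = int(np.ceil(px[..., 0].max())) + 26
    skel = np.zeros((H, W), dtype=bool)
    for i, j in gt.interfaces:
        x0, y0 = np.round(px[frame, i]).astype(int)
        x1, y1 = np.round(px[frame, j]).astype(int)
        rr, cc = draw_line(y0, x0, y1, x1)
        skel[rr, cc] = True
    return skel, px
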