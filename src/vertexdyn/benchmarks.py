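"""Property-based benchmark evaluations on synthetic tissue.

Each function regenerates its study condition from a seed, runs the relevant
pipeline stages from scratch, and returns the measured quantities as a dict.
They back both the acceptance test suite and ``scripts/acceptance.py``.

Study conditions (fixed by design):

* segmentation/tracking -- 25-cell, 100-frame rendered movie with default
  noise and one injected full T1 contraction;
* phase recovery        -- 100 cells, 600 s at 3 s/frame, random periods in
  100-300 s, amplitude SNR 5;
* ratchet detection     -- 81-cell tissue, 130 frames, isotropic vs ratchet
  (0.4 um per cycle shed from vertical interfaces during contraction);
* conservation          -- pure sliding vs line-tension interface events on
  oscillation-free tissues, >= 56 triplets, last-5-min windows;
* coupling              -- in-phase radial oscillations (12% area amplitude)
  with 0.3 px localization jitter;
* lag recovery          -- channel-2 lead 3.0 s at 1.5 s frames, 50
  replicates of 20 vertices;
* 3-phase attribution   -- tangential rate driven solely by cell C's phase,
  50 seeded runs of 30 vertex triads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import kinematics as kin
from . import phase as ph
from . import phasemap as pm
from . import roi
from . import segmentation as seg
from . import synthetic as syn
from . import tracking as trk
from . import xcorr as xc

__all__ = [
    "segmentation_tracking_recovery",
    "phase_recovery",
    "ratchet_detection",
    "conservation_classification",
    "coupling_structure",
    "lag_recovery",
    "three_phase_attribution",
    "exact_unit_values",
]


# ---------------------------------------------------------------------------
def segmentation_tracking_recovery(seed: int = 3) -> dict:
    """Benchmark: cell recovery, area accuracy, and T1 detection on the
    default rendered movie."""
    spec = syn.SimSpec(grid_shape=(5, 5), n_frames=100, seed=seed)
    spec = syn.add_t1_event(spec, t_start_s=60.0, duration_s=150.0)
    gt, stack = syn.simulate(spec)
    graphs = [seg.extract_tissue_graph(seg.segment_frame(stack[f, 0]))
              for f in range(spec.n_frames)]
    tracked = trk.track(graphs, trk.TrackConfig(pixel_size=spec.pixel_size,
                                                frame_interval=spec.frame_interval))
    geom = trk.cell_geometry(tracked)
    px = syn.pixel_positions(gt, spec)
    interior = gt.interior_cells()
    matched, area_err = [], []
    for frame in (0, 50):
        lab = tracked.labels[frame]
        truth_area = gt.cell_areas(frame)
        hits = {}
        for c in interior:
            cx, cy = px[frame, gt.cell_vertices[c - 1]].mean(axis=0)
            l = int(lab[int(round(cy)), int(round(cx))])
            if l > 0:
                hits.setdefault(l, []).append(c)
        one_to_one = {l: cs[0] for l, cs in hits.items() if len(cs) == 1}
        matched.append(len(one_to_one) / len(interior))
        for l, c in one_to_one.items():
            row = geom[(geom.frame == frame) & (geom.cell == l)]
            if len(row):
                a = float(row.contour_area_um2.iloc[0])
                area_err.append(abs(a - truth_area[c - 1]) / truth_area[c - 1])
    fc = [m for m in tracked.interface_meta.values() if m.fully_contracting]
    return dict(
        cell_recovery_pct=100.0 * float(np.mean(matched)),
        area_error_pct=100.0 * float(np.mean(area_err)),
        n_fully_contracting=len(fc),
    )


# ---------------------------------------------------------------------------
def phase_recovery(seed: int = 5) -> dict:
    """Benchmark: circular RMSE at SNR 5 and exact convention on noiseless
    controls (phase 0 at troughs, +-180 at peaks)."""
    _, areas, true_ph = syn.make_oscillating_areas(100, 600, 3.0, snr=5.0,
                                                   seed=seed)
    errs = []
    for i in range(100):
        tr = ph.phase_from_area(areas[i], 3.0)
        d = (tr.phase_deg - true_ph[i] + 180.0) % 360.0 - 180.0
        errs.append(d[10:-10])
    rmse = float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))
    _, areas0, true0 = syn.make_oscillating_areas(10, 600, 3.0, snr=0.0,
                                                  seed=seed + 1)
    conv = []
    for i in range(10):
        tr = ph.phase_from_area(areas0[i], 3.0)
        d = (tr.phase_deg - true0[i] + 180.0) % 360.0 - 180.0
        # away from the endpoints: trim half an oscillation period, where the
        # local circle-fit window is necessarily one-sided
        u = np.unwrap(np.radians(true0[i]))
        frames_per_cycle = 2 * np.pi / np.mean(np.diff(u))
        trim = max(10, int(round(frames_per_cycle / 2)))
        tp = true0[i][trim:-trim]
        at_ext = (np.abs(tp) < 6.0) | (np.abs(np.abs(tp) - 180.0) < 6.0)
        if at_ext.any():
            conv.append(np.abs(d[trim:-trim][at_ext]).max())
    return dict(phase_rmse_deg=rmse,
                convention_error_deg=float(np.max(conv)))


# ---------------------------------------------------------------------------
def _fractional_length_inputs(mode: str, seed: int):
    spec = syn.SimSpec(grid_shape=(9, 9), n_frames=130, mode=mode,
                       ratchet_rate_um_per_cycle=0.4, seed=seed)
    gt = syn.animate(syn.build_lattice(spec), spec)
    T = spec.n_frames
    areas = np.array([gt.cell_areas(f) for f in range(T)])
    interior = set(gt.interior_cells())
    traces = {}
    for c in gt.cell_ids:
        if c not in interior:
            continue
        try:
            traces[c] = ph.phase_from_area(areas[:, c - 1], spec.frame_interval)
        except ValueError:
            continue
    perim = {}
    for c in traces:
        vidx = gt.cell_vertices[c - 1]
        perim[c] = np.array([
            np.sum(np.hypot(*(np.diff(gt.positions[f, vidx], axis=0,
                                      append=gt.positions[f, vidx][:1]).T)))
            for f in range(T)])
    L = np.array([gt.interface_lengths(f) for f in range(T)])
    lengths, perims, flanks = [], [], []
    for e in gt.vertical_interfaces():
        a, b = gt.interface_cells[e]
        if b is None:
            continue
        trs = [traces[c] for c in (a, b) if c in traces]
        ps = [perim[c] for c in (a, b) if c in traces]
        if not trs:
            continue
        lengths.append(pd.Series(L[:, e]))
        perims.append(ps)
        flanks.append(trs)
    return lengths, perims, flanks


def ratchet_detection(seed: int = 5) -> dict:
    """Benchmark: isotropic tissue shows no fractional-length phase
    structure; ratchet tissue retains contraction-phase shortening."""
    out = {}
    li, pi, fi = _fractional_length_inputs("isotropic", seed)
    grid, bins = pm.fractional_length_vs_phase(li, pi, fi)
    mean_lp = float(np.mean([(l / p[0]).mean() for l, p in zip(li, pi)]))
    out["n_interfaces"] = len(li)
    out["iso_max_grid_pct"] = 100.0 * float(np.nanmax(np.abs(grid.values))) / mean_lp
    lr, pr, fr = _fractional_length_inputs("ratchet", seed)
    _, rbins = pm.fractional_length_vs_phase(lr, pr, fr)
    # per-interface bin(0) values for a significance statement
    per_iface_bin0 = []
    for L, Ps, trs in zip(lr, pr, fr):
        vals = []
        for P, tr in zip(Ps, trs):
            phs, v = pm.cycle_shifted_samples(L / P, tr)
            b0 = pm.phase_bin_mean(phs, v, 0.0)
            if np.isfinite(b0):
                vals.append(b0)
        if vals:
            per_iface_bin0.append(np.mean(vals))
    wstat = stats.wilcoxon(per_iface_bin0, alternative="less")
    out.update(
        ratchet_bin0_frac=float(rbins["bin_0"]) / mean_lp,
        ratchet_bin175_frac=float(rbins["bin_175"]) / mean_lp,
        ratchet_expansion_over_bin0=abs(float(rbins["expansion_change"]))
        / abs(float(rbins["bin_0"])),
        ratchet_bin0_p=float(wstat.pvalue),
    )
    return out


# ---------------------------------------------------------------------------
def _separated_vertical_interfaces(gt, n=2, min_dist_um=8.0):
    interior = set(gt.interior_cells())
    cands = [e for e in gt.vertical_interfaces()
             if gt.interface_cells[e][1] is not None
             and gt.interface_cells[e][0] in interior
             and gt.interface_cells[e][1] in interior]
    chosen, used = [], set()
    mids = {e: gt.positions[0, gt.interfaces[e]].mean(axis=0) for e in cands}
    for e in cands:
        verts = set(map(int, gt.interfaces[e]))
        partners = set(gt.transverse_partners(e).values())
        involved = verts | {int(v) for p in partners for v in gt.interfaces[p]}
        if used & involved:
            continue
        if any(np.hypot(*(mids[e] - mids[c])) < min_dist_um for c in chosen):
            continue
        chosen.append(e)
        used |= involved
        if len(chosen) == n:
            break
    return chosen


def conservation_classification(seed: int = 7, movies_per_mode: int = 7) -> dict:
    """Benchmark: triplet totals flat under sliding, dropping by the L1 loss
    under line tension; flatness separates the modes (AUROC)."""
    flat = {"sliding": [], "line_tension": []}
    drop_ratio = []
    for mode in ("sliding", "line_tension"):
        for k in range(movies_per_mode):
            spec = syn.SimSpec(grid_shape=(5, 5), n_frames=75,
                               frame_interval=5.0, osc_amplitude=0.0,
                               seed=seed + k)
            gt0 = syn.build_lattice(spec)
            events = _separated_vertical_interfaces(gt0, n=2)
            spec.sliding_events = [
                syn.SlideEvent(interface=int(e), t_start_s=10.0,
                               duration_s=330.0, delta_um=1.8, mode=mode)
                for e in events]
            gt = syn.animate(gt0, spec)
            L = np.array([gt.interface_lengths(f) for f in range(spec.n_frames)])
            for e in events:
                partners = gt.transverse_partners(e)
                for cell in gt.interface_cells[e]:
                    tr = [te for (v, c), te in partners.items() if c == cell]
                    curves = kin.triplet_conservation(
                        pd.Series(L[:, e]),
                        (pd.Series(L[:, tr[0]]), pd.Series(L[:, tr[1]])),
                        spec.frame_interval)
                    if curves is None:
                        continue
                    flat[mode].append(kin.triplet_flatness(curves))
                    if mode == "line_tension":
                        drop = curves.total.iloc[0] - curves.total.iloc[-1]
                        l1_loss = curves.L1.iloc[0] - curves.L1.iloc[-1]
                        drop_ratio.append(drop / l1_loss)
    s, lt = np.abs(flat["sliding"]), np.abs(flat["line_tension"])
    u, _ = stats.mannwhitneyu(lt, s, alternative="greater")
    auroc = float(u) / (len(s) * len(lt))
    return dict(
        n_triplets=len(s) + len(lt),
        sliding_max_flatness_pct=100.0 * float(np.max(s)),
        linetension_drop_over_l1loss=float(np.mean(drop_ratio)),
        mode_auroc=auroc,
    )


# ---------------------------------------------------------------------------
def coupling_structure(seed: int = 4, jitter_um: float = 0.06) -> dict:
    """Benchmark: with in-phase radial oscillations, opposed vertex pairs
    couple positively and more strongly than adjacent pairs; common
    translation gives negative coupling."""
    spec = syn.SimSpec(grid_shape=(6, 6), n_frames=100, osc_amplitude=0.12,
                       seed=seed)
    gt = syn.animate(syn.build_lattice(spec), spec)
    rng = np.random.default_rng(seed + 100)
    T = spec.n_frames
    cats: dict[str, list[float]] = {"adjacent": [], "diagonal": [], "opposed": []}
    for c in gt.interior_cells():
        vidx = gt.cell_vertices[c - 1]
        cent = np.array([gt.positions[f, vidx].mean(axis=0) for f in range(T)])
        rel = {k: gt.positions[:, vidx[k], :] - cent
               + rng.normal(0, jitter_um, (T, 2)) for k in range(6)}
        for i in range(6):
            for j in range(i + 1, 6):
                cat = kin.pair_category(j - i)
                try:
                    pc = kin.pair_coupling(rel[i], rel[j], spec.frame_interval,
                                           category=cat)
                except ValueError:
                    continue
                cats[cat].append(pc.correlation)
    _, p = stats.mannwhitneyu(cats["opposed"], cats["adjacent"],
                              alternative="greater")
    ctrl = []
    for _ in range(50):
        base = np.cumsum(rng.normal(0, 0.05, (T, 2)), axis=0)
        p1 = base + rng.normal(0, 0.02, (T, 2))
        p2 = base + np.array([1.0, 0.0]) + rng.normal(0, 0.02, (T, 2))
        ctrl.append(kin.pair_coupling(p1, p2, spec.frame_interval).correlation)
    return dict(
        n_pairs=sum(len(v) for v in cats.values()),
        opposed_mean=float(np.mean(cats["opposed"])),
        adjacent_mean=float(np.mean(cats["adjacent"])),
        opposed_gt_adjacent_p=float(p),
        translation_control_mean=float(np.mean(ctrl)),
    )


# ---------------------------------------------------------------------------
def lag_recovery(seed: int = 9, n_replicates: int = 50,
                 lead_s: float = 3.0, frame_interval: float = 1.5) -> dict:
    """Benchmark: channel-2 lead recovered by the positive-peak centroid."""
    lags = []
    for rep in range(n_replicates):
        _, ch1, ch2 = syn.make_marker_traces(20, 300, frame_interval,
                                             lead_s=lead_s, seed=seed + rep)
        results = []
        for v in range(20):
            ra = xc.rate_of_change(ch2[v], frame_interval)
            rb = xc.rate_of_change(ch1[v], frame_interval)
            results.append(xc.normalized_xcorr(ra, rb, frame_interval,
                                               max_lag_s=30.0))
        lags.append(xc.lag_from_peak_centroid(xc.average_xcorr(results)))
    lags = np.asarray(lags)
    return dict(
        true_lead_s=lead_s,
        mean_lag_s=float(lags.mean()),
        lag_bias_s=float(lags.mean() - lead_s),
        lag_sd_s=float(lags.std()),
        n_replicates=n_replicates,
    )


# ---------------------------------------------------------------------------
def three_phase_attribution(seed: int = 13, n_runs: int = 50) -> dict:
    """Benchmark: a tangential rate driven only by cell C's phase is
    attributed to the C axis of the 3D phase map."""
    hits = 0
    for run in range(n_runs):
        rng = np.random.default_rng(seed + 1000 + run)
        _, _, phases = syn.make_oscillating_areas(90, 300, 3.0, snr=0.0,
                                                  seed=seed + run)
        ph3, rates = [], []
        for v in range(30):
            a, b, c = phases[3 * v], phases[3 * v + 1], phases[3 * v + 2]
            ph3.append(np.column_stack([a, b, c]))
            rates.append(-0.5 * np.cos(np.radians(c))
                         + rng.normal(0, 0.25, phases.shape[1]))
        grid, _ = pm.tangential_rate_3phase_map(np.concatenate(ph3),
                                                np.concatenate(rates))
        hits += int(np.argmax(pm.variance_attribution(grid)) == 2)
    return dict(attribution_success_pct=100.0 * hits / n_runs, n_runs=n_runs)


# ---------------------------------------------------------------------------
def exact_unit_values() -> dict:
    """Benchmark: exact arithmetic anchors of the measurement machinery."""
    # intensity ratio on an ideal V/J/B image
    skel = np.zeros((101, 101), dtype=bool)
    skel[50, 10:91] = True
    img = np.full((101, 101), 100.0)
    yy, xx = np.mgrid[0:101, 0:101]
    img[np.abs(yy - 50) <= 3] = 150.0
    img[np.hypot(yy - 50.0, xx - 50.0) <= 3] = 200.0
    rois = roi.build_rois(skel, (50.0, 50.0))
    ratio = roi.intensity_ratio(img, rois, eps=1e-9)["ratio"]
    # Savitzky-Golay cubic reproduction
    t = np.arange(120, dtype=float)
    cubic = 1.0 + t - 0.02 * t ** 2 + 3e-4 * t ** 3
    sg_dev = float(np.abs(ph.smooth(cubic, 3.0) - cubic).max())
    # autocorrelation peak
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 400)
    r = xc.normalized_xcorr(a, a, 1.0, max_lag_s=20.0)
    peak_err = float(abs(r.corr[len(r.corr) // 2] - 1.0))
    # wrap equivalence of grid edge nodes
    coords = rng.uniform(-180, 180, (500, 1))
    g = pm.interp_to_grid(coords, rng.normal(0, 1, 500))
    wrap_gap = float(abs(g.values[0] - g.values[-1]))
    return dict(
        intensity_ratio_example=float(ratio),
        vertex_roi_pixels=int(rois.vertex.sum()),
        sg_cubic_max_dev=sg_dev,
        autocorr_peak_error=peak_err,
        grid_wrap_gap=wrap_gap,
    )
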