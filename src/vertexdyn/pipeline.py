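"""Run configuration and end-to-end orchestration.

A run is described by a YAML/JSON config (physical units are mandatory:
pixel size in um, frame interval in s, and the image-frame angle of the
embryo's ventral direction). ``run`` executes the stages in order --
simulate (optional) -> segment -> track -> measure -> phase -> kinematics ->
maps -> correlations -- writing plain-text CSV/JSON artifacts plus a log
into one directory per run; the config is echoed verbatim for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinematics, phasemap, roi, segmentation, synthetic, tracking, xcorr
from .phase import phase_from_area

__all__ = ["RunConfig", "validate_config", "run"]

log = logging.getLogger("vertexdyn")


@dataclass
class RunConfig:
    pixel_size: float                    # um / px (required)
    frame_interval: float                # s (required)
    ventral_angle: float = 90.0          # deg, image-frame ventral direction
    input: str | None = None             # TIFF path; None => simulate
    membrane_channel: int = 0
    marker_channel: int = 1
    out_dir: str = "run_out"
    seed: int = 0
    # stage parameters
    sim: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=lambda: dict(
        sigma=1.5, h=None, min_cell_area=40))
    tracking: dict = field(default_factory=lambda: dict(
        vertical_half_angle=30.0, length_zero_tol_px=2.0, min_track_frames=5))
    roi: dict = field(default_factory=lambda: dict(
        window=41, vertex_radius=3.0, background_distance=7.0))
    phase: dict = field(default_factory=lambda: dict(
        detrend_sigma_s=180.0, sg_window_s=45.0))
    maps: dict = field(default_factory=lambda: dict(
        bandwidth=15.0, spacing=5.0))
    xcorr: dict = field(default_factory=lambda: dict(
        window_s=25.0, max_lag_s=60.0))

    def __post_init__(self):
        if self.pixel_size is None or self.pixel_size <= 0:
            raise ValueError("pixel_size must be a positive number (um/px)")
        if self.frame_interval is None or self.frame_interval <= 0:
            raise ValueError("frame_interval must be a positive number (s)")


_KNOWN = {f.name for f in dataclasses.fields(RunConfig)}
_REQUIRED = ("pixel_size", "frame_interval")


def validate_config(source: str | Path | dict) -> RunConfig:
    """Load and validate a YAML/JSON config into a typed RunConfig.

    Unknown keys are rejected by name; missing required keys are reported.
    """
    if isinstance(source, dict):
        data = dict(source)
    else:
        data = yaml.safe_load(Path(source).read_text())
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    unknown = sorted(set(data) - _KNOWN)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    missing = [k for k in _REQUIRED if k not in data]
    if missing:
        raise ValueError(f"missing required config keys: {', '.join(missing)}")
    return RunConfig(**data)


def _segment_movie(stack, cfg: RunConfig):
    graphs = []
    for f in range(stack.shape[0]):
        lab = segmentation.segment_frame(stack[f, cfg.membrane_channel],
                                         **cfg.segmentation)
        graphs.append(segmentation.extract_tissue_graph(lab))
    return graphs


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of written artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    artifacts = {"config": out / "config.yaml"}
    try:
        # ------------------------------------------------ input / simulate
        if config.input is None:
            sim = dict(config.sim)
            sim.setdefault("pixel_size", config.pixel_size)
            sim.setdefault("frame_interval", config.frame_interval)
            sim.setdefault("seed", config.seed)
            spec = synthetic.SimSpec(**sim)
            log.info("simulating %s cells x %s frames", spec.n_cells, spec.n_frames)
            gt, stack = synthetic.simulate(spec, outdir=out / "sim")
            artifacts["sim"] = out / "sim"
        else:
            import tifffile

            raw = tifffile.imread(config.input)
            if raw.ndim == 3:  # channel-interleaved pages
                stack = raw.reshape(raw.shape[0] // 2, 2, *raw.shape[1:])
            else:
                stack = raw
        # ------------------------------------------------ segment + track
        log.info("segmenting %d frames", stack.shape[0])
        graphs = _segment_movie(stack, config)
        tcfg = tracking.TrackConfig(pixel_size=config.pixel_size,
                                    frame_interval=config.frame_interval,
                                    ventral_angle=config.ventral_angle,
                                    **config.tracking)
        tracked = tracking.track(graphs, tcfg)
        geom = tracking.cell_geometry(tracked)
        cells = tracked.cells.merge(geom, on=["frame", "cell"])
        cells.to_csv(out / "cells.csv", index=False)
        tracked.vertices.to_csv(out / "vertices.csv", index=False)
        iface = tracked.interfaces.copy()
        iface["length_um"] = iface.length_px * config.pixel_size
        meta = pd.DataFrame([dataclasses.asdict(m) for m in
                             tracked.interface_meta.values()])
        iface.to_csv(out / "interfaces.csv", index=False)
        meta.to_csv(out / "interface_tracks.csv", index=False)
        artifacts.update(cells=out / "cells.csv", vertices=out / "vertices.csv",
                         interfaces=out / "interfaces.csv")
        # ------------------------------------------------ intensity ratios
        traces = {}
        for name, ch in (("membrane", config.membrane_channel),
                         ("marker", config.marker_channel)):
            tr = roi.measure_tracked(stack, tracked, channel=ch,
                                     window=int(config.roi["window"]))
            tr.to_csv(out / f"vertex_intensity_{name}.csv", index=False)
            traces[name] = tr
        _, (sd_mean, sd_sem) = roi.trajectory_variability(traces["marker"])
        # ------------------------------------------------ phase per cell
        border = set(cells[cells.border].cell)
        phases = {}
        rows = []
        for cell, grp in cells.groupby("cell"):
            if cell in border or len(grp) < tracked.n_frames:
                continue
            area = grp.sort_values("frame").contour_area_um2.to_numpy()
            try:
                tr = phase_from_area(area, config.frame_interval,
                                     detrend_sigma_s=config.phase["detrend_sigma_s"],
                                     sg_window_s=config.phase["sg_window_s"])
            except ValueError as e:
                log.info("cell %s excluded from phase analysis: %s", cell, e)
                continue
            phases[int(cell)] = tr
            for f, (p, a) in enumerate(zip(tr.phase_deg, tr.amplitude)):
                rows.append(dict(cell=int(cell), frame=f, phase_deg=p,
                                 amplitude=a, cycle=int(tr.cycle[f])))
        pd.DataFrame(rows).to_csv(out / "phase.csv", index=False)
        artifacts["phase"] = out / "phase.csv"
        # ------------------------------------------------ length vs phase map
        lengths, flanks = [], []
        for t, m in tracked.interface_meta.items():
            if m.cls != "vertical":
                continue
            trs = [phases[c] for c in m.cells if c in phases]
            if not trs:
                continue
            L = tracked.interface_lengths_um(t)
            L = L.reindex(range(tracked.n_frames))
            lengths.append(L)
            flanks.append(trs)
        summary = dict(marker_ratio_sd_mean=sd_mean, marker_ratio_sd_sem=sd_sem,
                       n_phase_cells=len(phases), n_vertical_interfaces=len(lengths))
        if lengths:
            grid, bins = phasemap.length_vs_phase(
                lengths, flanks, bandwidth=config.maps["bandwidth"],
                spacing=config.maps["spacing"])
            pd.DataFrame(dict(phase_deg=grid.axes[0], shifted_length_um=grid.values,
                              weight=grid.weights)).to_csv(
                out / "length_vs_phase.csv", index=False)
            summary["length_bins"] = bins
        # ------------------------------------------------ marker xcorr + lag
        try:
            results = []
            for v in traces["marker"].vertex.unique():
                t1 = traces["membrane"][traces["membrane"].vertex == v]
                t2 = traces["marker"][traces["marker"].vertex == v]
                r1 = t1.set_index("frame").ratio.reindex(range(tracked.n_frames))
                r2 = t2.set_index("frame").ratio.reindex(range(tracked.n_frames))
                ra = xcorr.rate_of_change(r1.to_numpy(), config.frame_interval,
                                          config.xcorr["window_s"])
                rb = xcorr.rate_of_change(r2.to_numpy(), config.frame_interval,
                                          config.xcorr["window_s"])
                try:
                    results.append(xcorr.normalized_xcorr(
                        rb, ra, config.frame_interval, config.xcorr["max_lag_s"]))
                except ValueError:
                    continue
            if results:
                avg = xcorr.average_xcorr(results)
                pd.DataFrame(dict(lag_s=avg.lags_s, corr=avg.corr)).to_csv(
                    out / "marker_xcorr.csv", index=False)
                summary["marker_lag_s"] = xcorr.lag_from_peak_centroid(avg)
                summary["marker_xcorr_n"] = avg.n_series
        except ValueError as e:
            log.info("marker cross-correlation skipped: %s", e)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        artifacts["summary"] = out / "summary.json"
        log.info("run complete: %s", out)
        return artifacts
    finally:
        log.removeHandler(fh)
        fh.close()
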