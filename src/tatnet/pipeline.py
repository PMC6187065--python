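"""Configuration handling, file I/O and the end-to-end pipeline runner.

A pipeline run is described by a YAML/dict configuration with optional stage
blocks.  Any block that is present activates its stage:

* ``network`` (+ ``imaging``, ``preprocess``, ``classification``): simulate a
  tubule network micrograph (or load one from ``inputs``), binarize it and
  compute network metrics and the AT/OT/TT component summary;
* ``width``: measure tubule widths at listed profile ROIs on the image;
* ``transients``: simulate (or load) systolic/caffeine Ca2+ transients, fit
  mono-exponential decays and partition fluxes;
* ``ap``: simulate (or load) an optical AP trace and compute its metrics.

Unknown configuration keys are rejected by name.  Reports are deterministic
for a given configuration and seed: JSON output is key-sorted and contains no
timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from tatnet import ap as ap_mod
from tatnet import calcium, network, prep, simulate, width as width_mod

log = logging.getLogger("tatnet")


# ---------------------------------------------------------------------------
# basic I/O
# ---------------------------------------------------------------------------


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), image)


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_trace_csv(path: str | Path, time: np.ndarray, value: np.ndarray,
                    time_col: str = "time_s", value_col: str = "value") -> None:
    pd.DataFrame({time_col: time, value_col: value}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 2-column (time, value) CSV")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_json(path: str | Path, obj: Any) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _build(cls, d: dict | None, block: str):
    """Construct a dataclass from a dict, rejecting unknown keys by name."""
    d = dict(d or {})
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block '{block}' "
            f"(allowed: {sorted(allowed)})"
        )
    return cls(**d)


@dataclass
class ClassificationParams:
    bin_width: float = 5.0  # degrees
    window: float = 22.5  # degrees, half-width of each component window
    structure_tensor_sigma: float = 5.0  # px
    prune_spurs_um: float = 0.2  # ~half a tubule width: thinning end-forks/spurs
    junction_merge_radius_um: float = 0.5  # ~2 PSF widths: X-split Y-pairs count once
    tip_extension: bool = True  # correct endpoint erosion of thinning


@dataclass
class WidthROI:
    center_row: float = 0.0
    center_col: float = 0.0
    axis_angle: float = 0.0  # tubule direction, degrees
    n_peaks: int = 2
    label: str = ""


@dataclass
class InputPaths:
    image: str | None = None
    roi_mask: str | None = None
    systolic_trace: str | None = None
    caffeine_trace: str | None = None
    ap_trace: str | None = None


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "tatnet_out"
    inputs: InputPaths = field(default_factory=InputPaths)
    network: simulate.NetworkSpec | None = None
    imaging: simulate.ImagingSpec | None = None
    preprocess: prep.PreprocessParams | None = None
    classification: ClassificationParams | None = None
    width: list[WidthROI] | None = None
    transients: simulate.TransientSpec | None = None
    ap: simulate.APTraceSpec | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        cfg = cls(
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "tatnet_out")),
            inputs=_build(InputPaths, d.get("inputs"), "inputs"),
        )
        if "network" in d:
            cfg.network = _build(simulate.NetworkSpec, d["network"], "network")
        if "imaging" in d or "network" in d:
            cfg.imaging = _build(simulate.ImagingSpec, d.get("imaging"), "imaging")
        if "preprocess" in d or "network" in d:
            cfg.preprocess = _build(prep.PreprocessParams, d.get("preprocess"), "preprocess")
        if "classification" in d or "network" in d:
            cfg.classification = _build(
                ClassificationParams, d.get("classification"), "classification"
            )
        if "width" in d:
            cfg.width = [_build(WidthROI, r, "width") for r in d["width"]]
        if "transients" in d:
            cfg.transients = _build(simulate.TransientSpec, d["transients"], "transients")
        if "ap" in d:
            cfg.ap = _build(simulate.APTraceSpec, d["ap"], "ap")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"seed": self.seed, "out_dir": self.out_dir,
                               "inputs": dataclasses.asdict(self.inputs)}
        for name in ("network", "imaging", "preprocess", "classification",
                     "transients", "ap"):
            v = getattr(self, name)
            if v is not None:
                out[name] = dataclasses.asdict(v)
        if self.width is not None:
            out["width"] = [dataclasses.asdict(r) for r in self.width]
        return out


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def analyze_network_image(
    image: np.ndarray,
    roi: prep.CellROI,
    params: prep.PreprocessParams,
    pixel_size: float,
    classification: ClassificationParams | None = None,
) -> dict:
    """Binarize → skeletonize → graph → metrics + component classification."""
    cl = classification or ClassificationParams()
    mask = prep.preprocess(image, roi, params, pixel_size=pixel_size)
    skel = network.skeletonize(mask, pixel_size)
    margin_px = int(round(params.exclude_margin * 1000.0 / pixel_size))
    analysis_mask = roi.analysis_mask(margin_px)
    roi_area = float(analysis_mask.sum()) * (pixel_size / 1000.0) ** 2
    prune_px = cl.prune_spurs_um * 1000.0 / pixel_size
    graph = network.build_graph(skel, prune_spurs_px=prune_px)
    extra = network.measure_tip_extension(mask, graph) if cl.tip_extension else 0.0
    metrics = network.network_metrics(
        graph, roi_area,
        junction_merge_radius_um=cl.junction_merge_radius_um,
        extra_length_um=extra,
        total_length_um=network.smoothed_total_length(graph),
    )
    if skel.pixels:
        hist = network.orientation_histogram(
            skel, roi.major_axis_angle, bin_width=cl.bin_width,
            window_sigma=cl.structure_tensor_sigma,
            prune_spurs_px=prune_px,
        )
        summary = network.classify_components(hist, roi_area, window=cl.window)
        hist_out = {
            "bin_edges_deg": hist.bin_edges.tolist(),
            "length_um": hist.weights.tolist(),
            "reference_angle_deg": hist.reference_angle,
        }
    else:
        summary, hist_out = None, None
    return {
        "mask": mask,
        "skeleton": skel,
        "graph": graph,
        "metrics": metrics,
        "histogram": hist_out,
        "components": summary,
        "roi_area_um2": roi_area,
        "orientation_estimator": "structure_tensor",
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages end to end and write a JSON + CSV report.

    Missing input files abort before any computation; a failing stage is
    recorded in the report with a failure flag instead of aborting the rest.
    Reports are byte-identical for identical configuration and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, path in dataclasses.asdict(config.inputs).items():
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input '{name}' does not exist: {path}")

    report: dict[str, Any] = {"seed": config.seed, "stages": {}, "failures": {}}
    rows: list[dict[str, Any]] = []

    image_ctx: dict[str, Any] = {}
    if config.network is not None or config.inputs.image is not None:
        try:
            report["stages"]["network"] = _run_network_stage(
                config, out_dir, rows, image_ctx
            )
        except Exception as exc:  # noqa: BLE001 — partial report contract
            report["failures"]["network"] = str(exc)
    if config.width:
        try:
            report["stages"]["width"] = _run_width_stage(config, rows, image_ctx)
        except Exception as exc:  # noqa: BLE001
            report["failures"]["width"] = str(exc)
    if config.transients is not None or config.inputs.systolic_trace is not None:
        try:
            report["stages"]["calcium"] = _run_calcium_stage(config, out_dir, rows)
        except Exception as exc:  # noqa: BLE001
            report["failures"]["calcium"] = str(exc)
    if config.ap is not None or config.inputs.ap_trace is not None:
        try:
            report["stages"]["ap"] = _run_ap_stage(config, rows)
        except Exception as exc:  # noqa: BLE001
            report["failures"]["ap"] = str(exc)

    report["config"] = config.to_dict()
    write_json(out_dir / "report.json", report)
    pd.DataFrame(rows).to_csv(out_dir / "report.csv", index=False)
    log.info("pipeline report written to %s", out_dir)
    return report


def _run_network_stage(config: PipelineConfig, out_dir: Path,
                       rows: list[dict], image_ctx: dict | None = None) -> dict:
    imaging = config.imaging or simulate.ImagingSpec()
    if config.inputs.image is not None:
        image = read_tiff(config.inputs.image)
        if config.inputs.roi_mask is not None:
            roi_mask = read_tiff(config.inputs.roi_mask).astype(bool)
        else:
            roi_mask = np.ones(image.shape, dtype=bool)
        roi = prep.CellROI(mask=roi_mask,
                           major_axis_angle=prep.estimate_major_axis(roi_mask))
        truth = None
    else:
        spec = config.network or simulate.NetworkSpec()
        imaging = dataclasses.replace(imaging, seed=config.seed)
        segs = simulate.generate_network_geometry(spec, seed=config.seed)
        image, _ = simulate.render_image(segs, imaging)
        roi = _roi_from_polygon(segs, image.shape, imaging.pixel_size)
        truth = segs.truth
        write_tiff(out_dir / "network_image.tif", image)
        (out_dir / "network_truth.json").write_text(segs.to_json())

    if image_ctx is not None:
        image_ctx["image"] = image
        image_ctx["pixel_size"] = imaging.pixel_size
    result = analyze_network_image(
        image, roi, config.preprocess or prep.PreprocessParams(),
        pixel_size=imaging.pixel_size, classification=config.classification,
    )
    m = result["metrics"]
    stage = {
        "metrics": dataclasses.asdict(m),
        "components": (
            dataclasses.asdict(result["components"])
            if result["components"] is not None else None
        ),
        "histogram": result["histogram"],
        "orientation_estimator": result["orientation_estimator"],
        "truth": truth,
    }
    rows.append({"stage": "network", "metric": "density_um_per_um2", "value": m.density})
    rows.append({"stage": "network", "metric": "junction_density_per_um2",
                 "value": m.junction_density})
    rows.append({"stage": "network", "metric": "mean_branch_length_um",
                 "value": m.mean_branch_length})
    if result["components"] is not None:
        for k, v in result["components"].relative_fraction.items():
            rows.append({"stage": "network", "metric": f"frac_{k.lower()}", "value": v})
    write_tiff(out_dir / "network_mask.tif", result["mask"].astype(np.uint8))
    write_tiff(out_dir / "network_skeleton.tif",
               result["skeleton"].to_image().astype(np.uint8))
    return stage


def _roi_from_polygon(segs: simulate.SegmentSet, shape: tuple[int, int],
                      pixel_size: float) -> prep.CellROI:
    from skimage.draw import polygon as draw_polygon

    ps_um = pixel_size / 1000.0
    ys = [p[1] / ps_um for p in segs.cell_mask_polygon]
    xs = [p[0] / ps_um for p in segs.cell_mask_polygon]
    rr, cc = draw_polygon(ys, xs, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return prep.CellROI(mask=mask, major_axis_angle=prep.estimate_major_axis(mask))


def _run_width_stage(config: PipelineConfig, rows: list[dict],
                     image_ctx: dict) -> dict:
    if "image" in image_ctx:
        image, pixel_size = image_ctx["image"], image_ctx["pixel_size"]
    elif config.inputs.image is not None:
        image = read_tiff(config.inputs.image)
        pixel_size = (config.imaging or simulate.ImagingSpec()).pixel_size
    else:
        raise ValueError("width stage needs an image (network stage or inputs.image)")
    out = []
    for i, roi in enumerate(config.width or []):
        profile = width_mod.extract_profile(
            image, (roi.center_row, roi.center_col), roi.axis_angle,
            pixel_size=pixel_size,
        )
        fit = width_mod.fit_gaussian(profile, n_peaks=roi.n_peaks)
        entry = {
            "label": roi.label or f"roi_{i}",
            "n_peaks": roi.n_peaks,
            "converged": fit.converged,
            "flagged": fit.flagged,
            "flag_reason": fit.flag_reason,
            "width_nm": fit.fwhm if (fit.converged and not fit.flagged) else None,
            "peak_separation_nm": fit.peak_separation,
        }
        out.append(entry)
        if entry["width_nm"] is not None:
            rows.append({"stage": "width", "metric": f"width_nm[{entry['label']}]",
                         "value": entry["width_nm"]})
    return {"rois": out}


def _run_calcium_stage(config: PipelineConfig, out_dir: Path,
                       rows: list[dict]) -> dict:
    if config.inputs.systolic_trace is not None:
        t_s, y_s = read_trace_csv(config.inputs.systolic_trace)
        if config.inputs.caffeine_trace is None:
            raise ValueError("caffeine_trace input is required with systolic_trace")
        t_c, y_c = read_trace_csv(config.inputs.caffeine_trace)
        truth = None
    else:
        spec = dataclasses.replace(config.transients or simulate.TransientSpec(),
                                   seed=config.seed)
        data = simulate.generate_transients(spec)
        t_s = t_c = data["time_s"]
        y_s, y_c = data["systolic"], data["caffeine"]
        truth = data["truth"]
        write_trace_csv(out_dir / "systolic.csv", t_s, y_s)
        write_trace_csv(out_dir / "caffeine.csv", t_c, y_c)
    fit_s = calcium.fit_monoexp(calcium.Trace(t_s, y_s, kind="systolic"))
    fit_c = calcium.fit_monoexp(calcium.Trace(t_c, y_c, kind="caffeine"))
    part = calcium.partition_fluxes(fit_s, fit_c)
    for name, v in (("k_syst_per_s", part.k_syst), ("k_caff_per_s", part.k_caff),
                    ("k_serca_per_s", part.k_serca), ("frac_serca", part.frac_serca)):
        rows.append({"stage": "calcium", "metric": name, "value": v})
    return {
        "fit_systolic": dataclasses.asdict(fit_s),
        "fit_caffeine": dataclasses.asdict(fit_c),
        "partition": dataclasses.asdict(part),
        "truth": truth,
    }


def _run_ap_stage(config: PipelineConfig, rows: list[dict]) -> dict:
    if config.inputs.ap_trace is not None:
        t, y = read_trace_csv(config.inputs.ap_trace)
        spec = config.ap or simulate.APTraceSpec()
        stim_end = spec.stim_end_time
        truth = None
    else:
        spec = dataclasses.replace(config.ap or simulate.APTraceSpec(),
                                   seed=config.seed)
        data = simulate.generate_ap_trace(spec)
        t, y = data["time_ms"], data["dff"]
        stim_end = data["stim_end_ms"]
        truth = data["truth"]
    metrics = ap_mod.ap_metrics(ap_mod.APRecord(time=t, dff=y, stim_end=stim_end))
    for name, v in (("amplitude_dff", metrics.amplitude),
                    ("onset_ms", metrics.onset),
                    ("max_slope_per_ms", metrics.max_slope)):
        rows.append({"stage": "ap", "metric": name, "value": v})
    return {"metrics": dataclasses.asdict(metrics), "truth": truth}
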