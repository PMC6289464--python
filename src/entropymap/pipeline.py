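"""End-to-end analysis: net map -> thresholds -> morphometry -> artifacts.

Workflow A (few inclusions): grey-quantize the raw map, threshold at
g0, count every white pixel in the selected region.  Workflow B (many
inclusions): zero negatives first, threshold at g1, the end of the
first entropy peak above g0 (that peak belongs to element-containing
structures other than the inclusions).  Auto mode runs A, counts the
inclusions and reruns as B when more than 10 are found.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as emio
from .entropy import (
    EntropyAnalysis,
    Thresholds,
    binarize,
    entropy_analysis,
    find_g0,
    find_g1,
    grey_histogram,
)
from .grey import GreyImage, NetMap, to_grey, zero_negatives
from .morphometry import (
    RegionMask,
    SectionResult,
    assign_compartments,
    label_inclusions,
    measure_section,
    workflow_for_count,
)

__all__ = ["AnalysisConfig", "AnalysisDetails", "analyze_map", "select_workflow", "run_analysis"]

log = logging.getLogger("entropymap")


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of one analysis run.

    Exactly one of ``map_path`` or the three window paths must be given
    for file-based runs; in-memory use goes through :func:`analyze_map`.
    """

    workflow: str = "auto"  # A | B | auto
    element: str = "other"
    min_run: int | None = None
    min_area: int = 1
    connectivity: int = 2
    smooth_window: int = 0
    threshold_override: int | None = None
    section_id: str = "section"
    # file-based runs
    map_path: str | None = None
    pre1_path: str | None = None
    pre2_path: str | None = None
    post_path: str | None = None
    energies: tuple[float, float, float] | None = None
    cell_mask_path: str | None = None
    compartments_path: str | None = None
    legend_path: str | None = None
    roi_path: str | None = None
    outdir: str = "."
    save_grey: bool = False

    def __post_init__(self) -> None:
        if self.workflow not in ("A", "B", "auto"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if self.threshold_override is not None and not 0 <= self.threshold_override <= 255:
            raise ValueError("threshold override must lie in [0, 255]")


@dataclass(frozen=True)
class AnalysisDetails:
    """Intermediate artifacts of one analysis, for inspection and output."""

    grey: GreyImage
    analysis: EntropyAnalysis | None
    thresholds: Thresholds
    threshold_used: int | None
    override_used: bool
    warnings: tuple[str, ...] = ()


def _empty_result(region: RegionMask, section_id: str, workflow: str) -> SectionResult:
    return measure_section([], region, section_id=section_id, workflow_used=workflow)


def _run_one(
    net: NetMap,
    region: RegionMask,
    workflow: str,
    min_run: int | None,
    min_area: int,
    connectivity: int,
    smooth_window: int,
    threshold_override: int | None,
    section_id: str,
) -> tuple[SectionResult, AnalysisDetails]:
    warnings: list[str] = []
    working = zero_negatives(net) if workflow == "B" else net
    grey = to_grey(working)
    analysis = entropy_analysis(grey_histogram(grey))
    g0 = find_g0(analysis, min_run=min_run)
    g1 = None
    if g0 is None and threshold_override is None:
        warnings.append("no inclusions: no sustained positive-entropy run above the mean")
        thresholds = Thresholds(g0=None, g1=None, workflow=workflow)
        details = AnalysisDetails(grey, analysis, thresholds, None, False, tuple(warnings))
        return _empty_result(region, section_id, workflow), details
    if workflow == "B" and g0 is not None:
        g1 = find_g1(analysis, g0, smooth_window=smooth_window)
    thresholds = Thresholds(g0=g0, g1=g1, workflow=workflow)
    if threshold_override is not None:
        t = threshold_override
    else:
        t = thresholds.active
    mask = binarize(grey, t)
    inclusions = label_inclusions(mask, region, min_area=min_area, connectivity=connectivity)
    inclusions = assign_compartments(inclusions, region)
    result = measure_section(inclusions, region, section_id=section_id, workflow_used=workflow)
    details = AnalysisDetails(
        grey, analysis, thresholds, int(t), threshold_override is not None, tuple(warnings)
    )
    log.info(
        "section %s workflow %s: g0=%s g1=%s threshold=%s n_inclusions=%d S_R=%.4f%%",
        section_id, workflow, g0, g1, t, result.n_inclusions, result.s_r,
    )
    return result, details


def analyze_map(
    net: NetMap,
    region: RegionMask,
    workflow: str = "auto",
    min_run: int | None = None,
    min_area: int = 1,
    connectivity: int = 2,
    smooth_window: int = 0,
    threshold_override: int | None = None,
    section_id: str = "section",
) -> tuple[SectionResult, AnalysisDetails]:
    """Run the full in-memory pipeline on one net map.

    Returns the section morphometry plus the intermediate grey image,
    entropy analysis and thresholds.  ``workflow="auto"`` applies the
    inclusion-count rule (<= 10 -> A, > 10 -> rerun as B).
    """
    kwargs = dict(
        min_run=min_run,
        min_area=min_area,
        connectivity=connectivity,
        smooth_window=smooth_window,
        threshold_override=threshold_override,
        section_id=section_id,
    )
    if workflow in ("A", "B"):
        return _run_one(net, region, workflow, **kwargs)
    result, details = _run_one(net, region, "A", **kwargs)
    chosen = workflow_for_count(result.n_inclusions)
    if chosen == "A":
        return result, details
    log.info(
        "auto: %d inclusions under workflow A -> rerunning as workflow B",
        result.n_inclusions,
    )
    return _run_one(net, region, "B", **kwargs)


def select_workflow(
    mode: str, net: NetMap, region: RegionMask, **kwargs
) -> str:
    """Resolve the workflow tag: explicit modes pass through, auto counts.

    Auto mode runs workflow A and applies the count rule (<= 10
    inclusions -> A, more -> B); with no detectable threshold it reports
    A (the no-inclusion outcome).
    """
    if mode in ("A", "B"):
        return mode
    result, _ = _run_one(
        net,
        region,
        "A",
        min_run=kwargs.get("min_run"),
        min_area=kwargs.get("min_area", 1),
        connectivity=kwargs.get("connectivity", 2),
        smooth_window=kwargs.get("smooth_window", 0),
        threshold_override=kwargs.get("threshold_override"),
        section_id="workflow-probe",
    )
    return workflow_for_count(result.n_inclusions)


def _load_inputs(cfg: AnalysisConfig) -> tuple[NetMap, RegionMask]:
    from .three_window import ELEMENT_ENERGIES, WindowImage, compute_net_map, fit_powerlaw_background

    if cfg.map_path is not None:
        if cfg.pre1_path is not None:
            raise ValueError("give either a net map or a window triplet, not both")
        net = emio.read_map(cfg.map_path, element=cfg.element)
    else:
        if not (cfg.pre1_path and cfg.pre2_path and cfg.post_path):
            raise ValueError("need a net map or all three window images")
        energies = cfg.energies or ELEMENT_ENERGIES.get(cfg.element)
        if energies is None:
            raise ValueError("window energies required (give --e1/--e2/--e3 or --element N|P)")
        pre1 = WindowImage(emio.read_map(cfg.pre1_path).values, energies[0], "pre1")
        pre2 = WindowImage(emio.read_map(cfg.pre2_path).values, energies[1], "pre2")
        post = WindowImage(emio.read_map(cfg.post_path).values, energies[2], "post")
        model = fit_powerlaw_background(pre1, pre2)
        net = compute_net_map(post, model, element=cfg.element)
        if net.invalid_pixels:
            log.warning("%d pixels had undefined background fits (net set to 0)", net.invalid_pixels)
    if cfg.cell_mask_path:
        cell = emio.read_mask(cfg.cell_mask_path)
    else:
        cell = net.values == net.values  # whole frame
        log.warning("no cell mask given: S_cell covers the whole frame")
    comp = emio.read_mask(cfg.compartments_path, boolean=False) if cfg.compartments_path else None
    legend = emio.read_legend(cfg.legend_path) if cfg.legend_path else None
    roi = emio.read_mask(cfg.roi_path) if cfg.roi_path else None
    return net, RegionMask(cell=cell, compartments=comp, legend=legend, roi=roi)


def run_analysis(cfg: AnalysisConfig) -> SectionResult:
    """File-based analysis: load inputs, run the pipeline, write artifacts.

    Writes into ``cfg.outdir``: the entropy table (CSV), the analysis
    record (JSON: g_mean, sigma2, q, g0, g1, workflow, threshold), the
    processed binary mask (TIFF), per-section and per-inclusion CSVs,
    and optionally the 8-bit grey image.
    """
    net, region = _load_inputs(cfg)
    result, details = analyze_map(
        net,
        region,
        workflow=cfg.workflow,
        min_run=cfg.min_run,
        min_area=cfg.min_area,
        connectivity=cfg.connectivity,
        smooth_window=cfg.smooth_window,
        threshold_override=cfg.threshold_override,
        section_id=cfg.section_id,
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for w in details.warnings:
        log.warning("%s", w)
    if details.analysis is not None:
        emio.write_entropy_csv(outdir / "entropy.csv", details.analysis)
    record = {
        "section_id": result.section_id,
        "workflow": result.workflow_used,
        "g_mean": details.analysis.g_mean if details.analysis else None,
        "sigma2": details.analysis.sigma2 if details.analysis else None,
        "q": details.analysis.q if details.analysis else None,
        "g0": details.thresholds.g0,
        "g1": details.thresholds.g1,
        "threshold_used": details.threshold_used,
        "threshold_override": cfg.threshold_override,
        "S_cell_px": result.s_cell,
        "S_TI_px": result.s_ti,
        "S_R_percent": result.s_r,
        "n_inclusions": result.n_inclusions,
        "invalid_pixels": net.invalid_pixels,
        "warnings": list(details.warnings),
    }
    with open(outdir / "analysis.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if details.threshold_used is not None:
        emio.write_mask(outdir / "processed_mask.tif", binarize(details.grey, details.threshold_used).white)
    if cfg.save_grey:
        emio.write_grey(outdir / "grey.tif", details.grey)
    emio.write_section_csv(outdir / "section.csv", [result])
    emio.write_inclusion_csv(outdir / "inclusions.csv", [result])
    return result
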