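"""Inclusion labeling, compartment assignment and per-section morphometry.

White pixels of the binarized map are grouped into connected components
(inclusions), optionally restricted to an analyst-drawn region of
interest, assigned to subcellular compartments by majority pixel
overlap, and reduced to the per-section quantities:

    S_cell  total cell-section area (pixels)
    S_TI    total inclusion area (pixels)
    S_R     relative reserve area = 100 * S_TI / S_cell  (percent)

Multi-section summaries sort sections by S_R (descending) and report the
compartment holding the main reserves per section, mirroring how
per-culture heterogeneity is presented across ~18 random sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import measure

from .entropy import BinaryMask
from .errors import ShapeMismatchError

__all__ = [
    "RegionMask",
    "InclusionRecord",
    "SectionResult",
    "SectionSummary",
    "COMPARTMENTS",
    "label_inclusions",
    "assign_compartments",
    "measure_section",
    "summarize_sections",
    "workflow_for_count",
]

#: canonical compartment names; label images map integer labels to these
COMPARTMENTS = ("vacuole", "cytosol", "chloroplast", "nucleus", "PHB", "background")

NOT_DETERMINED = "not_determined"

#: sections with more inclusions than this use workflow B
WORKFLOW_A_MAX_INCLUSIONS = 10


@dataclass(frozen=True)
class RegionMask:
    """Cell outline, optional compartment labels and optional ROI.

    ``cell`` is a boolean mask of the cell section; ``compartments`` an
    integer label image with ``legend`` mapping label -> compartment
    name (0 conventionally background); ``roi`` restricts inclusion
    counting to an analyst-selected region.
    """

    cell: np.ndarray
    compartments: np.ndarray | None = None
    legend: dict[int, str] | None = None
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell, dtype=bool)
        if cell.ndim != 2:
            raise ValueError("cell mask must be 2-D")
        object.__setattr__(self, "cell", cell)
        if self.compartments is not None:
            comp = np.asarray(self.compartments)
            if comp.shape != cell.shape:
                raise ShapeMismatchError("compartment labels must match the cell mask shape")
            object.__setattr__(self, "compartments", comp.astype(np.int32))
        if self.roi is not None:
            roi = np.asarray(self.roi, dtype=bool)
            if roi.shape != cell.shape:
                raise ShapeMismatchError("roi must match the cell mask shape")
            object.__setattr__(self, "roi", roi)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell.shape


@dataclass(frozen=True)
class InclusionRecord:
    """One labeled inclusion: pixel area S, centroid, bbox, compartment.

    ``coords`` holds the (row, col) pixel coordinates of the component
    (used for compartment overlap counting; not compared or printed).
    """

    id: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    compartment: str = NOT_DETERMINED
    coords: np.ndarray | None = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class SectionResult:
    """Morphometry of one cell section.

    ``inclusion_count`` is only set when the result was reloaded from a
    table without its per-inclusion records.
    """

    section_id: str
    s_cell: int
    s_ti: int
    s_r: float
    inclusions: tuple[InclusionRecord, ...]
    per_compartment: dict[str, int] = field(default_factory=dict)
    workflow_used: str = "A"
    inclusion_count: int | None = None

    @property
    def n_inclusions(self) -> int:
        if self.inclusion_count is not None:
            return self.inclusion_count
        return len(self.inclusions)


@dataclass(frozen=True)
class SectionSummary:
    """Sorted multi-section summary of S_R values."""

    table: pd.DataFrame
    s_r_min: float
    s_r_max: float
    n_sections: int
    n_above_threshold: int
    n_zero: int
    threshold_pct: float
    main_compartment_fractions: dict[str, float]


def label_inclusions(
    mask: BinaryMask,
    region: RegionMask,
    min_area: int = 1,
    connectivity: int = 2,
) -> list[InclusionRecord]:
    """Group white pixels inside the cell (or ROI) into inclusions.

    Connected components use 8-connectivity by default
    (``connectivity=2`` in scikit-image terms; 1 gives 4-connectivity).
    Components smaller than ``min_area`` pixels are discarded.
    ``min_area=1`` keeps every white pixel, reproducing raw white-pixel
    counting inside the selected region.

    Raises
    ------
    ValueError
        If the cell mask is empty.
    """
    if mask.shape != region.shape:
        raise ShapeMismatchError("mask and region shapes differ")
    if not region.cell.any():
        raise ValueError("empty cell mask")
    select = region.roi if region.roi is not None else region.cell
    labels = measure.label(mask.white & select, connectivity=connectivity)
    records: list[InclusionRecord] = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        records.append(
            InclusionRecord(
                id=len(records) + 1,
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                bbox=tuple(int(v) for v in prop.bbox),
                coords=prop.coords.copy(),
            )
        )
    return records


def assign_compartments(
    inclusions: list[InclusionRecord], region: RegionMask
) -> list[InclusionRecord]:
    """Label each inclusion with its strict-majority compartment.

    An inclusion gets the compartment covering more than half of its
    pixels; ties and sub-majority overlaps give ``not_determined``.
    Without a compartment image every inclusion is ``not_determined``.
    """
    if region.compartments is None or region.legend is None:
        return [replace(inc, compartment=NOT_DETERMINED) for inc in inclusions]
    comp = region.compartments
    out = []
    for inc in inclusions:
        if inc.coords is None:
            out.append(replace(inc, compartment=NOT_DETERMINED))
            continue
        labels_here = comp[inc.coords[:, 0], inc.coords[:, 1]]
        counts: dict[str, int] = {}
        for lab, n in zip(*np.unique(labels_here, return_counts=True)):
            name = region.legend.get(int(lab), NOT_DETERMINED)
            if name == "background":
                continue
            counts[name] = counts.get(name, 0) + int(n)
        name = NOT_DETERMINED
        if counts:
            best = max(counts, key=counts.get)
            if counts[best] * 2 > inc.area:
                name = best
        out.append(replace(inc, compartment=name))
    return out


def measure_section(
    inclusions: list[InclusionRecord],
    region: RegionMask,
    section_id: str = "section",
    workflow_used: str = "A",
) -> SectionResult:
    """Compute S_cell, S_TI and S_R = 100 * S_TI / S_cell for one section.

    Raises
    ------
    ValueError
        If the cell mask is empty (S_cell = 0).
    """
    s_cell = int(region.cell.sum())
    if s_cell == 0:
        raise ValueError("S_cell = 0: empty cell mask")
    s_ti = int(sum(inc.area for inc in inclusions))
    per_comp: dict[str, int] = {}
    for inc in inclusions:
        per_comp[inc.compartment] = per_comp.get(inc.compartment, 0) + inc.area
    return SectionResult(
        section_id=section_id,
        s_cell=s_cell,
        s_ti=s_ti,
        s_r=100.0 * s_ti / s_cell,
        inclusions=tuple(inclusions),
        per_compartment=per_comp,
        workflow_used=workflow_used,
    )


def summarize_sections(
    results: list[SectionResult],
    threshold_pct: float = 8.0,
    group_by_compartment: bool = False,
) -> SectionSummary:
    """Summarize S_R across sections of one sample.

    Sections are sorted by S_R descending (optionally grouped by main
    compartment first); the summary reports min/max S_R, the number of
    sections above ``threshold_pct``, the number with no reserves at
    all, and the fraction of sections whose main reserves sit in each
    compartment (the compartment with the largest per-compartment area).

    Raises
    ------
    ValueError
        On empty input.
    """
    if not results:
        raise ValueError("no sections to summarize")
    rows = []
    for res in results:
        main = (
            max(res.per_compartment, key=res.per_compartment.get)
            if res.per_compartment
            else NOT_DETERMINED
        )
        rows.append(
            {
                "section_id": res.section_id,
                "workflow": res.workflow_used,
                "S_cell_px": res.s_cell,
                "S_TI_px": res.s_ti,
                "S_R_percent": res.s_r,
                "n_inclusions": res.n_inclusions,
                "main_compartment": main,
            }
        )
    table = pd.DataFrame(rows)
    if group_by_compartment:
        table = table.sort_values(
            ["main_compartment", "S_R_percent"], ascending=[True, False]
        )
    else:
        table = table.sort_values("S_R_percent", ascending=False)
    table = table.reset_index(drop=True)
    s_r = table["S_R_percent"]
    with_reserves = table[table["S_TI_px"] > 0]
    fractions = (
        (with_reserves["main_compartment"].value_counts() / len(with_reserves)).to_dict()
        if len(with_reserves)
        else {}
    )
    return SectionSummary(
        table=table,
        s_r_min=float(s_r.min()),
        s_r_max=float(s_r.max()),
        n_sections=len(table),
        n_above_threshold=int((s_r > threshold_pct).sum()),
        n_zero=int((s_r == 0).sum()),
        threshold_pct=threshold_pct,
        main_compartment_fractions=fractions,
    )


def workflow_for_count(n_inclusions: int) -> str:
    """Workflow choice from the inclusion count: "A" for <= 10, "B" above."""
    return "A" if n_inclusions <= WORKFLOW_A_MAX_INCLUSIONS else "B"
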