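"""Reading and writing maps, masks and result tables.

Net maps are accepted as single-channel TIFF (float or integer) or as
delimited text matrices (CSV/TSV/whitespace); masks are 8-bit TIFFs with
a JSON legend for compartment labels.  All writers are deterministic so
repeated runs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .entropy import EntropyAnalysis
from .grey import GreyImage, NetMap
from .morphometry import InclusionRecord, RegionMask, SectionResult

__all__ = [
    "read_map",
    "read_mask",
    "read_legend",
    "write_map",
    "write_mask",
    "write_grey",
    "entropy_table",
    "write_entropy_csv",
    "write_section_csv",
    "write_inclusion_csv",
]

log = logging.getLogger("entropymap")

_TEXT_SUFFIXES = {".csv", ".tsv", ".txt", ".dat"}


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in _TEXT_SUFFIXES:
        delimiter = {"csv": ",", "tsv": "\t"}.get(path.suffix.lower().lstrip("."), None)
        return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))
    return tifffile.imread(path)


def read_map(path: str | Path, element: str = "other") -> NetMap:
    """Read a net map from TIFF or delimited text.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        If the image is not single-channel 2-D (the offending shape is
        named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _load_array(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel 2-D map, got shape {arr.shape} "
            f"({arr.ndim} dimensions)"
        )
    log.info("read map %s: shape=%s dtype=%s", path.name, arr.shape, arr.dtype)
    return NetMap(values=arr.astype(np.float64), element=element, provenance="file")


def read_mask(path: str | Path, boolean: bool = True) -> np.ndarray:
    """Read a mask TIFF; nonzero means inside for boolean masks."""
    arr = _load_array(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{Path(path).name}: mask must be single-channel 2-D, got shape {arr.shape}")
    return arr != 0 if boolean else arr.astype(np.int32)


def read_legend(path: str | Path) -> dict[int, str]:
    """Read a JSON legend mapping integer compartment labels to names."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_map(path: str | Path, net: NetMap) -> None:
    """Write a net map as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), net.values.astype(np.float32))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean or label mask as 8-bit TIFF (True -> 255)."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    tifffile.imwrite(Path(path), arr.astype(np.uint8))


def write_grey(path: str | Path, img: GreyImage) -> None:
    """Write the 256-level grey image as 8-bit TIFF."""
    tifffile.imwrite(Path(path), img.levels)


def entropy_table(analysis: EntropyAnalysis) -> pd.DataFrame:
    """The 256-row g / H / G / R / RH table of one analysis."""
    return pd.DataFrame(
        {
            "g": np.arange(256),
            "H": analysis.hist.counts,
            "G": analysis.gaussian,
            "R": analysis.rel_entropy,
            "RH": analysis.weighted,
        }
    )


def write_entropy_csv(path: str | Path, analysis: EntropyAnalysis) -> None:
    entropy_table(analysis).to_csv(path, index=False, float_format="%.10g")


def write_section_csv(path: str | Path, results: list[SectionResult]) -> None:
    rows = []
    for res in results:
        row = {
            "section_id": res.section_id,
            "workflow": res.workflow_used,
            "S_cell_px": res.s_cell,
            "S_TI_px": res.s_ti,
            "S_R_percent": res.s_r,
            "n_inclusions": res.n_inclusions,
        }
        for comp, area in sorted(res.per_compartment.items()):
            row[f"S_{comp}_px"] = area
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_inclusion_csv(
    path: str | Path, results: list[SectionResult]
) -> None:
    rows = []
    for res in results:
        for inc in res.inclusions:
            rows.append(
                {
                    "section_id": res.section_id,
                    "inclusion_id": inc.id,
                    "area_px": inc.area,
                    "centroid_row": inc.centroid[0],
                    "centroid_col": inc.centroid[1],
                    "compartment": inc.compartment,
                }
            )
    columns = [
        "section_id",
        "inclusion_id",
        "area_px",
        "centroid_row",
        "centroid_col",
        "compartment",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.10g")
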