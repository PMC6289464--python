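"""Synthetic EFTEM maps with planted inclusions and known ground truth.

Generates the inputs every pipeline stage consumes, with exact ground
truth for testing: net maps (zero-mean Gaussian background noise, an
optional mid-intensity structure class standing in for element-containing
cell structures other than the inclusions, and bright disks standing in
for the roundish reserve granules), region masks (elliptical cell
outline, simple compartment layout) and three-window triplets built
from planted power-law background fields.

Contrast presets express the inclusion signal in units of the background
noise: "high" plants disks at 20 sigma, "low" at 5 sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grey import NetMap
from .morphometry import RegionMask
from .three_window import WindowImage

__all__ = [
    "Ellipse",
    "Disk",
    "StructureClass",
    "SimulationSpec",
    "GroundTruth",
    "CONTRAST_PRESETS",
    "ellipse_mask",
    "disk_mask",
    "random_spec",
    "generate_net_map",
    "generate_window_triplet",
]

#: inclusion signal over background noise sd, per preset
CONTRAST_PRESETS = {"high": 20.0, "low": 5.0}

DEFAULT_LEGEND = {0: "background", 1: "cytosol", 2: "vacuole", 4: "nucleus"}


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (row, col) and semi-axes (row, col), px."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]


@dataclass(frozen=True)
class Disk:
    """A planted inclusion: disk center (row, col), radius (px), mean signal (counts)."""

    center: tuple[float, float]
    radius: float
    signal: float

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("disk radius must be >= 1 px")
        if self.signal <= 0:
            raise ValueError("disk signal must be positive")


@dataclass(frozen=True)
class StructureClass:
    """Mid-intensity class emulating element-containing non-inclusion structures.

    Rendered as an elliptical annulus between ``outer`` and ``inner``
    (both relative to the cell), with additive mean ``signal`` counts.
    """

    signal: float
    outer: Ellipse
    inner: Ellipse


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to render one synthetic section deterministically."""

    shape: tuple[int, int] = (512, 512)
    cell: Ellipse | None = None
    background_sigma: float = 10.0
    structure: StructureClass | None = None
    inclusions: tuple[Disk, ...] = ()
    with_compartments: bool = False
    seed: int = 0

    def cell_ellipse(self) -> Ellipse:
        if self.cell is not None:
            return self.cell
        r, c = self.shape
        return Ellipse(center=(r / 2, c / 2), semi_axes=(0.42 * r, 0.42 * c))


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one synthetic section."""

    inclusion_mask: np.ndarray
    true_s_ti: int
    true_s_r: float
    n_inclusions: int
    inclusion_areas: tuple[int, ...]
    inclusion_compartments: tuple[str, ...]
    structure_mask: np.ndarray | None = None


def ellipse_mask(shape: tuple[int, int], ellipse: Ellipse) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    (r0, c0), (ar, ac) = ellipse.center, ellipse.semi_axes
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _signal_field(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Deterministic additive signal plus the planted masks."""
    cell = ellipse_mask(spec.shape, spec.cell_ellipse())
    signal = np.zeros(spec.shape)
    structure_mask = None
    if spec.structure is not None:
        structure_mask = ellipse_mask(spec.shape, spec.structure.outer) & ~ellipse_mask(
            spec.shape, spec.structure.inner
        )
        signal[structure_mask] += spec.structure.signal
    inclusion_mask = np.zeros(spec.shape, dtype=bool)
    for disk in spec.inclusions:
        m = disk_mask(spec.shape, disk.center, disk.radius)
        if (m & ~cell).any():
            raise ValueError(f"inclusion at {disk.center} extends outside the cell")
        signal[m] += disk.signal
        inclusion_mask |= m
    if structure_mask is not None:
        structure_mask = structure_mask & ~inclusion_mask
    return signal, inclusion_mask, structure_mask


def _region_mask(spec: SimulationSpec) -> RegionMask:
    cell = ellipse_mask(spec.shape, spec.cell_ellipse())
    if not spec.with_compartments:
        return RegionMask(cell=cell)
    (r0, c0), (ar, ac) = spec.cell_ellipse().center, spec.cell_ellipse().semi_axes
    comp = np.zeros(spec.shape, dtype=np.int32)
    comp[cell] = 1  # cytosol fills the cell
    vacuole = ellipse_mask(
        spec.shape, Ellipse((r0, c0 - 0.45 * ac), (0.35 * ar, 0.35 * ac))
    )
    nucleus = ellipse_mask(
        spec.shape, Ellipse((r0, c0 + 0.45 * ac), (0.3 * ar, 0.3 * ac))
    )
    comp[vacuole & cell] = 2
    comp[nucleus & cell] = 4
    return RegionMask(cell=cell, compartments=comp, legend=dict(DEFAULT_LEGEND))


def generate_net_map(spec: SimulationSpec) -> tuple[NetMap, RegionMask, GroundTruth]:
    """Render a net map: Gaussian background + structure class + disks.

    The background is zero-mean Gaussian noise with sd
    ``background_sigma`` everywhere (background-subtracted counts
    fluctuate around zero), so negatives occur naturally.  Identical
    spec and seed give bit-identical output.
    """
    signal, inclusion_mask, structure_mask = _signal_field(spec)
    region = _region_mask(spec)
    rng = np.random.default_rng(spec.seed)
    noise = (
        rng.normal(0.0, spec.background_sigma, spec.shape)
        if spec.background_sigma > 0
        else np.zeros(spec.shape)
    )
    net = NetMap(values=signal + noise, provenance="synthetic")
    truth = _ground_truth(spec, region, inclusion_mask, structure_mask)
    return net, region, truth


def _ground_truth(
    spec: SimulationSpec,
    region: RegionMask,
    inclusion_mask: np.ndarray,
    structure_mask: np.ndarray | None,
) -> GroundTruth:
    s_cell = int(region.cell.sum())
    areas = []
    comps = []
    for disk in spec.inclusions:
        m = disk_mask(spec.shape, disk.center, disk.radius)
        areas.append(int(m.sum()))
        if region.compartments is None or region.legend is None:
            comps.append("not_determined")
        else:
            labels_here = region.compartments[m]
            lab, counts = np.unique(labels_here, return_counts=True)
            best = int(lab[counts.argmax()])
            name = region.legend.get(best, "not_determined")
            comps.append(name if counts.max() * 2 > m.sum() else "not_determined")
    s_ti = int(inclusion_mask.sum())
    return GroundTruth(
        inclusion_mask=inclusion_mask,
        true_s_ti=s_ti,
        true_s_r=100.0 * s_ti / s_cell,
        n_inclusions=len(spec.inclusions),
        inclusion_areas=tuple(areas),
        inclusion_compartments=tuple(comps),
        structure_mask=structure_mask,
    )


def random_spec(
    n_inclusions: int,
    shape: tuple[int, int] = (512, 512),
    background_sigma: float = 10.0,
    contrast: str | float = "high",
    radius_range: tuple[float, float] = (5.0, 10.0),
    with_structure: bool = False,
    structure_signal_sigma: float = 6.0,
    with_compartments: bool = False,
    seed: int = 0,
) -> SimulationSpec:
    """Place ``n_inclusions`` non-overlapping disks randomly inside the cell.

    ``contrast`` is a preset name ("high" = 20 sigma, "low" = 5 sigma)
    or an explicit multiple of ``background_sigma``.  With
    ``with_structure`` an elliptical-annulus mid-intensity class at
    ``structure_signal_sigma`` * sigma is added (the two-class scenario
    that workflow B is designed for); disks are kept off the annulus.
    """
    mult = CONTRAST_PRESETS[contrast] if isinstance(contrast, str) else float(contrast)
    signal = mult * background_sigma
    rng = np.random.default_rng(seed)
    probe = SimulationSpec(shape=shape, seed=seed)
    cell = probe.cell_ellipse()
    structure = None
    structure_m = None
    if with_structure:
        (r0, c0), (ar, ac) = cell.center, cell.semi_axes
        structure = StructureClass(
            signal=structure_signal_sigma * background_sigma,
            outer=Ellipse((r0, c0), (0.8 * ar, 0.8 * ac)),
            inner=Ellipse((r0, c0), (0.5 * ar, 0.5 * ac)),
        )
        structure_m = ellipse_mask(shape, structure.outer) & ~ellipse_mask(
            shape, structure.inner
        )
    cell_m = ellipse_mask(shape, cell)
    disks: list[Disk] = []
    attempts = 0
    while len(disks) < n_inclusions:
        attempts += 1
        if attempts > 10000 * n_inclusions:
            raise RuntimeError("could not place non-overlapping inclusions")
        radius = rng.uniform(*radius_range)
        (r0, c0), (ar, ac) = cell.center, cell.semi_axes
        row = rng.uniform(r0 - ar, r0 + ar)
        col = rng.uniform(c0 - ac, c0 + ac)
        # fully inside the cell, with margin
        if ((row - r0) / (ar - radius - 2)) ** 2 + ((col - c0) / (ac - radius - 2)) ** 2 > 1:
            continue
        if any(
            math.hypot(row - d.center[0], col - d.center[1]) < radius + d.radius + 4
            for d in disks
        ):
            continue
        if structure_m is not None and disk_mask(shape, (row, col), radius + 2)[
            structure_m
        ].any():
            continue
        disks.append(Disk(center=(row, col), radius=radius, signal=signal))
    return SimulationSpec(
        shape=shape,
        cell=cell,
        background_sigma=background_sigma,
        structure=structure,
        inclusions=tuple(disks),
        with_compartments=with_compartments,
        seed=seed,
    )


def generate_window_triplet(
    spec: SimulationSpec,
    amplitude: np.ndarray | float,
    exponent: np.ndarray | float,
    energies: tuple[float, float, float] = (104.0, 121.0, 144.0),
    poisson: bool = False,
) -> tuple[WindowImage, WindowImage, WindowImage, GroundTruth]:
    """Render a three-window triplet from planted power-law backgrounds.

    Each window image is A * E**(-r) at its energy; the planted signal
    field (structure + inclusion disks) is added to the post-edge image
    only, which is exactly what background subtraction should recover.
    With ``poisson`` each image is resampled pixel-wise from a Poisson
    distribution (seeded from the spec).

    Raises
    ------
    ValueError
        If any amplitude is nonpositive or exponents are negative.
    """
    a = np.broadcast_to(np.asarray(amplitude, dtype=np.float64), spec.shape).copy()
    r = np.broadcast_to(np.asarray(exponent, dtype=np.float64), spec.shape).copy()
    if (a <= 0).any():
        raise ValueError("background amplitude must be positive everywhere")
    if (r < 0).any():
        raise ValueError("background exponent must be nonnegative")
    signal, inclusion_mask, structure_mask = _signal_field(spec)
    e1, e2, e3 = energies
    images = [a * e1 ** (-r), a * e2 ** (-r), a * e3 ** (-r) + signal]
    if poisson:
        rng = np.random.default_rng(spec.seed)
        images = [rng.poisson(np.maximum(img, 0)).astype(np.float64) for img in images]
    region = _region_mask(spec)
    truth = _ground_truth(spec, region, inclusion_mask, structure_mask)
    pre1 = WindowImage(images[0], e1, "pre1")
    pre2 = WindowImage(images[1], e2, "pre2")
    post = WindowImage(images[2], e3, "post")
    return pre1, pre2, post, truth
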