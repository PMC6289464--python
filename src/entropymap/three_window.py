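"""Three-window net-map computation with a power-law background model.

The non-specific background under an ionization edge is modelled per
pixel as I(E) = A * E**(-r).  Two pre-edge window images determine A and
r exactly (the unique power law through two points); extrapolating to
the post-edge energy and subtracting from the post-edge image yields the
net elemental map.  Standard window energies: 371 / 388 / 412 eV for the
N K-edge and 104 / 121 / 144 eV for the P L2,3-edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError
from .grey import NetMap

__all__ = [
    "WindowImage",
    "BackgroundModel",
    "ELEMENT_ENERGIES",
    "fit_powerlaw_background",
    "compute_net_map",
]

# Default slit positions (eV) per element edge.
ELEMENT_ENERGIES: dict[str, tuple[float, float, float]] = {
    "N": (371.0, 388.0, 412.0),
    "P": (104.0, 121.0, 144.0),
}


@dataclass(frozen=True)
class WindowImage:
    """One energy-filtered window image.

    ``intensity`` is a 2-D array of electron counts, ``energy_loss`` the
    slit position in eV, ``role`` one of ``pre1``/``pre2``/``post``.
    """

    intensity: np.ndarray
    energy_loss: float
    role: str = "pre1"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("window image must be 2-D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("window image contains non-finite values")
        if self.energy_loss <= 0:
            raise ValueError("energy loss must be positive (eV)")
        if self.role not in ("pre1", "pre2", "post"):
            raise ValueError(f"unknown window role {self.role!r}")
        object.__setattr__(self, "intensity", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pixel power-law background I(E) = A * E**(-r).

    Where ``valid`` is False (a pre-edge intensity was <= 0 so the fit is
    undefined) ``amplitude`` and ``exponent`` hold NaN sentinels and must
    not be extrapolated.
    """

    amplitude: np.ndarray
    exponent: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


def fit_powerlaw_background(pre1: WindowImage, pre2: WindowImage) -> BackgroundModel:
    """Fit the unique power law through the two pre-edge points, per pixel.

    For intensities I1, I2 at energies E1 < E2:

        r = ln(I1 / I2) / ln(E2 / E1),    A = I1 * E1**r

    Pixels with any nonpositive pre-edge intensity are marked invalid
    (the logarithm is undefined there).

    Raises
    ------
    ShapeMismatchError
        If the two images differ in shape.
    ValueError
        If the two energies are equal (or not increasing).
    """
    if pre1.shape != pre2.shape:
        raise ShapeMismatchError(
            f"pre-edge shapes differ: {pre1.shape} vs {pre2.shape}"
        )
    e1, e2 = pre1.energy_loss, pre2.energy_loss
    if e1 == e2:
        raise ValueError("pre-edge energies must differ")
    if e1 > e2:
        raise ValueError("pre-edge energies must be increasing (pre1 < pre2)")
    i1, i2 = pre1.intensity, pre2.intensity
    valid = (i1 > 0) & (i2 > 0)
    r = np.full(i1.shape, np.nan)
    a = np.full(i1.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        r[valid] = np.log(i1[valid] / i2[valid]) / np.log(e2 / e1)
        a[valid] = i1[valid] * e1 ** r[valid]
    return BackgroundModel(amplitude=a, exponent=r, valid=valid)


def compute_net_map(
    post: WindowImage, model: BackgroundModel, element: str = "other"
) -> NetMap:
    """Subtract the extrapolated background from the post-edge image.

    net = I_post - A * E_post**(-r) where the fit is valid; invalid
    pixels get net 0 and are counted in ``NetMap.invalid_pixels``.
    Negative net values are preserved.
    """
    if post.shape != model.shape:
        raise ShapeMismatchError(
            f"post-edge shape {post.shape} != model shape {model.shape}"
        )
    net = np.zeros(post.shape)
    v = model.valid
    net[v] = post.intensity[v] - model.amplitude[v] * post.energy_loss ** (
        -model.exponent[v]
    )
    return NetMap(
        values=net,
        element=element,
        provenance="three_window",
        invalid_pixels=int((~v).sum()),
    )
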