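"""Net elemental maps and their 256-level grey quantization.

A net map holds background-subtracted signed intensities (electron
counts) for one cell section.  Before histogram analysis it is mapped
linearly onto 256 grey levels; workflow B additionally zeroes negative
values first, which concentrates the background half of the noise at
level 0 and is what makes the structure-class peak in the entropy curve
separable from the inclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateMapError

__all__ = ["NetMap", "GreyImage", "zero_negatives", "to_grey"]


@dataclass(frozen=True)
class NetMap:
    """A signed 2-D background-subtracted intensity map for one section.

    Parameters
    ----------
    values
        2-D float array of net counts; negatives are allowed (noise
        fluctuates around zero after background subtraction).
    element
        Which ionization edge the map belongs to: ``"N"``, ``"P"`` or
        ``"other"``.
    provenance
        ``"three_window"`` if computed from a window triplet, ``"file"``
        if loaded, ``"synthetic"`` for generated maps.
    negatives_zeroed
        True once :func:`zero_negatives` has been applied (workflow B
        preprocessing).
    invalid_pixels
        Number of pixels where three-window background extrapolation was
        undefined and the net value was set to 0.
    """

    values: np.ndarray
    element: str = "other"
    provenance: str = "file"
    negatives_zeroed: bool = False
    invalid_pixels: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"net map must be 2-D, got ndim={values.ndim}")
        if values.size < 2:
            raise DegenerateMapError("net map needs at least 2 pixels")
        if not np.all(np.isfinite(values)):
            raise ValueError("net map contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GreyImage:
    """256-level quantization of a :class:`NetMap`.

    ``levels`` are integers in [0, 255] with the map minimum at 0 and the
    map maximum at 255.  ``preprocessing`` records whether negative net
    values were zeroed before quantization (``"negatives_zeroed"``) or
    not (``"none"``).
    """

    levels: np.ndarray
    preprocessing: str = "none"

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        if levels.ndim != 2:
            raise ValueError("grey image must be 2-D")
        if levels.min() < 0 or levels.max() > 255:
            raise ValueError("grey levels must lie in [0, 255]")
        object.__setattr__(self, "levels", levels.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape


def zero_negatives(net: NetMap) -> NetMap:
    """Set all negative net values to zero (workflow B preprocessing).

    Idempotent; the returned map records ``negatives_zeroed=True``.
    """
    return replace(net, values=np.maximum(net.values, 0.0), negatives_zeroed=True)


def to_grey(net: NetMap) -> GreyImage:
    """Linearly quantize a net map to 256 grey levels.

    The affine map sends the minimum value to level 0 and the maximum to
    level 255, rounding half away from zero:

        g = floor(255 * (x - min) / (max - min) + 1/2)

    Raises
    ------
    DegenerateMapError
        If the map is constant (zero dynamic range).
    """
    values = net.values
    lo = values.min()
    span = values.max() - lo
    if span == 0:
        raise DegenerateMapError("constant net map: grey quantization undefined")
    # scaled values are >= 0, so floor(y + 0.5) is round-half-away-from-zero
    g = np.floor(255.0 * (values - lo) / span + 0.5).astype(np.uint8)
    prep = "negatives_zeroed" if net.negatives_zeroed else "none"
    return GreyImage(levels=g, preprocessing=prep)
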