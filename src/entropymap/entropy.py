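"""Relative-entropy histogram analysis and binary thresholding.

The grey-level histogram H(g) of a map is compared to a Gaussian prior
G(g) with the same total pixel count, mean and variance:

    g_mean = (1/P) sum g H(g)
    sigma2 = (1/(P-1)) sum (g - g_mean)^2 H(g)
    G(g)   = P / sqrt(2 pi sigma2) * exp(-(g - g_mean)^2 / (2 sigma2))
    R(g)   = ln(H(g) / G(g))          for H(g) > 0, else 0
    q      = (1/P) sum R(g) H(g)

A pure-noise map has H ~ G, so R fluctuates around zero; element-rich
structures pile excess counts into the bright tail, where H >> G and
R > 0.  Workflow A thresholds at g0, the onset of the first sustained
positive-entropy run above the mean; workflow B thresholds at g1, the
end of the first peak of the weighted curve R(g)H(g) above g0 (that
peak belongs to element-containing structures other than the
inclusions; the inclusions lie beyond it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError, WorkflowError
from .grey import GreyImage

__all__ = [
    "GreyHistogram",
    "EntropyAnalysis",
    "Thresholds",
    "BinaryMask",
    "grey_histogram",
    "entropy_analysis",
    "find_g0",
    "find_g1",
    "binarize",
    "auto_min_run",
]

#: family-wise false-detection probability targeted by the automatic
#: run-length rule in :func:`find_g0` on a signal-free map
FALSE_TRIGGER_RATE = 0.05


@dataclass(frozen=True)
class GreyHistogram:
    """Exact 256-bin grey-level histogram; ``total`` is the pixel count P."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if (counts < 0).any():
            raise ValueError("histogram counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EntropyAnalysis:
    """Gaussian prior and relative-entropy curves for one histogram.

    Attributes
    ----------
    hist
        The analysed histogram.
    g_mean, sigma2
        Histogram mean and variance (P-1 denominator).
    gaussian
        G(g), the Gaussian prior in counts, for g = 0..255.
    rel_entropy
        R(g) = ln(H(g)/G(g)) where H(g) > 0, else 0.
    weighted
        R(g) * H(g), the plotted relative-entropy curve.
    q
        Scalar relative entropy (1/P) sum R(g) H(g).
    """

    hist: GreyHistogram
    g_mean: float
    sigma2: float
    gaussian: np.ndarray
    rel_entropy: np.ndarray
    weighted: np.ndarray
    q: float


@dataclass(frozen=True)
class Thresholds:
    """Grey-level cut(s) for binarization.

    ``g0`` is the workflow-A cut (white means g > g0); ``g1`` (workflow B
    only) satisfies g1 > g0.  Either may be None when not determined.
    """

    g0: int | None
    g1: int | None = None
    workflow: str = "A"

    def __post_init__(self) -> None:
        if self.g0 is not None and not 0 <= self.g0 <= 255:
            raise ValueError("g0 must lie in [0, 255]")
        if self.g1 is not None:
            if self.g0 is None or self.g1 <= self.g0:
                raise ValueError("g1 must exceed g0")

    @property
    def active(self) -> int | None:
        """The threshold the active workflow binarizes with."""
        return self.g1 if self.workflow == "B" else self.g0


@dataclass(frozen=True)
class BinaryMask:
    """Boolean classification of a grey image: True = element-rich (white)."""

    white: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.white, dtype=bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "white", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.white.shape


def grey_histogram(img: GreyImage) -> GreyHistogram:
    """Count pixels per grey level (exact 256-bin histogram)."""
    return GreyHistogram(np.bincount(img.levels.ravel(), minlength=256))


def entropy_analysis(hist: GreyHistogram) -> EntropyAnalysis:
    """Compute the Gaussian prior and relative-entropy curves.

    Raises
    ------
    DegenerateHistogramError
        If P < 2 or the variance is zero (all pixels at one level).
    """
    h = hist.counts.astype(np.float64)
    p = h.sum()
    if p < 2:
        raise DegenerateHistogramError("need at least 2 pixels")
    g = np.arange(256, dtype=np.float64)
    g_mean = float((g * h).sum() / p)
    sigma2 = float((((g - g_mean) ** 2) * h).sum() / (p - 1))
    if sigma2 == 0:
        raise DegenerateHistogramError("zero-variance histogram: Gaussian prior undefined")
    gauss = p / math.sqrt(2 * math.pi * sigma2) * np.exp(
        -((g - g_mean) ** 2) / (2 * sigma2)
    )
    occupied = h > 0
    rel = np.zeros(256)
    with np.errstate(divide="ignore"):
        # G(g) underflows to 0 far from the mean; ln(H/0) = +inf is a
        # genuine "infinitely unlikely under the prior" signal, but keep
        # the curve finite by evaluating the Gaussian exponent in logs.
        log_gauss = (
            math.log(p)
            - 0.5 * math.log(2 * math.pi * sigma2)
            - ((g - g_mean) ** 2) / (2 * sigma2)
        )
        rel[occupied] = np.log(h[occupied]) - log_gauss[occupied]
    weighted = rel * h
    q = float(weighted.sum() / p)
    return EntropyAnalysis(
        hist=hist,
        g_mean=g_mean,
        sigma2=sigma2,
        gaussian=gauss,
        rel_entropy=rel,
        weighted=weighted,
        q=q,
    )


def auto_min_run(analysis: EntropyAnalysis) -> int:
    """Run length required for a positive-entropy run to count as signal.

    Under a signal-free map the sign of R(g) in each occupied bin is
    close to a fair coin flip (counts fluctuate around the prior), so a
    run of k consecutive positives arises by chance with probability
    about n * 2**-k over n candidate bins.  The returned k bounds that
    family-wise false-trigger probability at ``FALSE_TRIGGER_RATE``.
    """
    h = analysis.hist.counts
    n_candidates = int(((np.arange(256) > analysis.g_mean) & (h > 0)).sum())
    if n_candidates == 0:
        return 1
    return max(1, math.ceil(math.log2(n_candidates / FALSE_TRIGGER_RATE)))


def find_g0(analysis: EntropyAnalysis, min_run: int | None = None) -> int | None:
    """Locate the workflow-A threshold g0.

    Scans grey levels above the histogram mean for the first run of at
    least ``min_run`` consecutive occupied bins with positive relative
    entropy that is *separated from the histogram bulk*; g0 is the
    level just below that run, so the white rule g > g0 selects the
    positive-entropy right tail.  Returns None when no such run exists
    (a pure-noise map).

    Separation matters because the prior's variance is fitted to the
    whole histogram, signal included: any signal inflates sigma2, makes
    G flatter than the noise bulk, and turns the bins immediately above
    the mean systematically positive.  That bulk-adjacent positive run
    carries no detection information, so the scan starts after the
    first nonpositive (or empty) bin above the mean — the signal group
    must stand apart from the noise, not lean against it.

    ``min_run=None`` (default) uses :func:`auto_min_run`, which
    calibrates the required run length against chance runs on a
    signal-free map.  ``min_run=1`` accepts any separated positive bin.
    """
    if min_run is None:
        min_run = auto_min_run(analysis)
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    h = analysis.hist.counts
    good = (h > 0) & (analysis.rel_entropy > 0)
    start = int(math.floor(analysis.g_mean)) + 1  # smallest integer g > g_mean
    # skip the variance-inflation run hugging the mean, if present
    while start < 256 and good[start]:
        start += 1
    for g in range(start, 256 - min_run + 1):
        if good[g : g + min_run].all():
            return g - 1
    return None


def find_g1(
    analysis: EntropyAnalysis,
    g0: int,
    smooth_window: int = 0,
    peak_prominence_frac: float = 0.25,
) -> int:
    """Locate the workflow-B threshold g1 (> g0).

    On the weighted curve RH(g) = R(g)H(g) restricted to g > g0, the
    first contiguous positive run is the peak of element-containing
    structures other than the inclusions.  g1 is the end of that peak:
    its last positive level, or — when a second prominent peak merges
    into the same run through a dip that never reaches zero — the
    dip's local-minimum level.  Pixels with g > g1 are classified as
    inclusions.

    A merged second peak only counts when its prominence exceeds
    ``peak_prominence_frac`` times the run maximum; smaller wiggles are
    counting noise on the curve, not structure.  ``smooth_window`` > 1
    additionally applies a moving average to RH before peak detection
    (off by default).

    Raises
    ------
    WorkflowError
        If RH(g) <= 0 for all g > g0 (workflow B inapplicable).
    """
    from scipy.signal import find_peaks

    rh = analysis.weighted.copy()
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        rh = np.convolve(rh, kernel, mode="same")
    pos = np.where((np.arange(256) > g0) & (rh > 0))[0]
    if pos.size == 0:
        raise WorkflowError("no positive relative entropy above g0; workflow B inapplicable")
    a = int(pos[0])
    b = a
    while b < 255 and rh[b + 1] > 0:
        b += 1
    segment = rh[a : b + 1]
    peaks, _ = find_peaks(
        np.concatenate(([0.0], segment, [0.0])),
        prominence=peak_prominence_frac * segment.max(),
    )
    if len(peaks) >= 2:
        # two prominent peaks share the run: cut at the dip between them
        p0, p1 = peaks[0] - 1, peaks[1] - 1  # undo the padding offset
        return a + p0 + int(np.argmin(segment[p0 : p1 + 1]))
    return b


def binarize(img: GreyImage, threshold: int) -> BinaryMask:
    """Classify pixels: white (element-rich) where g > threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return BinaryMask(white=img.levels > threshold)
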