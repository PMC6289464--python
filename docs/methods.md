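# Methods

## Model

The analysis treats a background-subtracted elemental map as a mixture
of (i) zero-mean counting noise, (ii) optionally a mid-intensity class
of element-containing cell structures that are not reserve inclusions,
and (iii) bright, compact reserve inclusions. After linear quantization
to 256 grey levels, the histogram `H(g)` is compared to a Gaussian
prior `G(g)` that carries the same pixel count `P`, mean and variance
as the data. The per-level relative entropy `R(g) = ln[H(g)/G(g)]`
is positive exactly where the observed counts exceed the prior
(`sign R = sign(H − G)` on occupied bins); the scalar
`q = (1/P) Σ R·H` is the Kullback–Leibler divergence of the histogram
from the prior, in nats. Empty bins contribute `R = R·H = 0` (the
`x·ln x → 0` limit). The variance uses the `P − 1` denominator; the
prior is evaluated at bin centres, so `Σ G(g) ≈ P` to well under 1 %
whenever `σ² ≥ 4` and the mean is inside the grey range.

Assumptions worth stating: the noise is adequately described by a
single Gaussian over the whole map (no spatially varying gain); the map
is already aligned; inclusion pixels are brighter than everything else
on the map. The method quantifies *area only* — it deliberately ignores
inclusion density/brightness differences, so `S_R` is not an absolute
element amount.

## Quantization

`g = floor(255·(x − min)/(max − min) + 1/2)`, i.e. round half away
from zero, with the map minimum at level 0 and the maximum at 255. The
transform is monotone and invariant under positive affine rescaling of
the map. A constant map has no defined quantization and raises an
error rather than returning a degenerate histogram — a constant net
map indicates an acquisition problem. No outlier clipping is applied
before scaling.

## Threshold g0 (workflow A)

`g0` is the level just below the first run of at least `min_run`
consecutive occupied, positive-entropy bins above the histogram mean
**that is separated from the histogram bulk** by at least one
nonpositive or empty bin. The separation clause matters: because the
prior's variance is fitted to the whole histogram, any signal inflates
`σ²`, flattens `G` relative to the noise bulk, and turns the bins
immediately above the mean systematically positive. That bulk-adjacent
run reflects the variance inflation, not detections, and is skipped.
The signal group, by contrast, stands apart from the noise — the
formal counterpart of requiring positive values *grouped* in the right
half of the histogram.

`min_run` defaults to an automatic calibration: under a signal-free
map the sign of `R` per occupied bin is close to a fair coin flip, so
a chance run of `k` positives among `n` candidate bins occurs with
probability ≈ `n·2^(−k)`. The default
`k = ceil(log2(n/0.05))` (≈ 12 for a fully occupied upper half) bounds
that family-wise false-trigger probability at about 5 %. On pure-noise
maps this leaves `g0` undetected — or, when a chance run does occur,
it sits in the far tail where the white area is negligible. Explicit
`min_run` values remain available for small, hand-built histograms.

A map with no qualifying run yields "no inclusions" (a warning-level
outcome, not an error): sections without reserves are biologically
meaningful.

## Threshold g1 (workflow B)

Zeroing negative map values before quantization concentrates roughly
half of the background pixels at level 0; on inclusion-rich maps this
makes a distinct first peak appear on the weighted curve `R(g)·H(g)`
above `g0`, belonging to element-containing structures other than the
inclusions. `g1` is the end of that peak: the last positive level of
the first contiguous `RH > 0` run above `g0`. When a second peak
merges into the same run through a dip that never reaches zero, the
cut is placed at the dip's local minimum instead — but only if the
second peak's prominence exceeds 25 % of the run maximum
(`scipy.signal.find_peaks`); smaller wiggles are counting noise on the
curve, and treating every re-rise as a merged peak truncates the
structure peak early (observed on synthetic two-class maps: a naive
local-minimum rule cut at the first ripple and let a third of the
structure pixels through). An optional moving-average smoothing window
(`--smooth-window`, off by default) is available for very noisy
curves. Binarization is strict: white ⟺ `g > threshold`.

## Workflow selection

Explicit `A`/`B` are honored; `auto` runs workflow A, counts the
labeled inclusions and reruns as B when more than 10 are found. A
count of exactly 10 stays with A (the published rule assigns "less
than 10" to A and "more than 10" to B, leaving 10 unassigned; up to 10
inclusions are still quick to verify by eye, which is what workflow A
was designed for). Workflow A applied to inclusion-rich two-class maps
reproduces the known failure mode — the structure class stays white —
which the acceptance suite checks explicitly.

## Morphometry

Connected components use 8-connectivity by default (configurable to
4). `min_area` defaults to 1 pixel, so `S_TI` equals the raw white
pixel count inside the selected region, matching manual white-pixel
counting; larger values are exposed for noise suppression only.
Inclusions are assigned to the compartment covering a strict majority
(> 50 %) of their pixels, else `not_determined`. Components are
labeled on `white ∧ cell` (or `white ∧ roi`), so a component touching
the cell boundary is counted with its inside-cell pixels. Multi-section
summaries sort by `S_R` descending, report min/max, the count of
sections above a threshold (default 8 %), the count with zero
reserves, and the fraction of sections whose main reserves sit in each
compartment (largest per-compartment area).

## Three-window background

Two pre-edge images determine the power law exactly per pixel:
`r = ln(I1/I2)/ln(E2/E1)`, `A = I1·E1^r` — the unique power law
through two points, not a least-squares fit, since exactly two
pre-edge measurements exist. Pixels with a nonpositive pre-edge
intensity have no defined fit; they are marked invalid, contribute net
0, and are counted per map. Negative net values are preserved (zeroing
is workflow-B preprocessing, not a map-computation step). On noiseless
synthetic triplets the planted signal is recovered to ~1e−15 relative.

## Synthetic data

The generator emulates the structure the thresholds operate on, not
electron optics. Net maps: zero-mean Gaussian background noise
(default σ = 10 counts) everywhere, an optional elliptical-annulus
structure class (default 6 σ), and disk inclusions placed without
overlap inside an elliptical cell (default radii 5–10 px on a 512×512
frame). Contrast presets put inclusions at 20 σ ("high") or 5 σ
("low"). Window triplets evaluate planted `A·E^(−r)` fields at the
three energies with optional Poisson resampling, adding the signal
field to the post-edge image only. Everything is deterministic per
seed, and ground truth (inclusion mask, areas, compartments, `S_R`)
follows from the geometry exactly.

What the generator does **not** reproduce: textured organelles,
spatially correlated noise, drift, diffraction contrast, thickness
gradients, and irregular inclusion shapes. Passing tests therefore
demonstrate that the statistical machinery behaves as designed under
its own model — Gaussian noise, separated intensity classes — not that
real micrographs of any particular organism will yield particular
`S_R` values.

## Problem sizes and tolerances

The verification suite uses 200 random 32×32 images for the
scalar-loop equivalence (1e−10 relative), 256×256 noiseless triplets
for three-window closure (1e−9), twenty 512×512 high-contrast
simulations for area/count recovery (S_R within 15 % relative, counts
exact, ≥ 18/20), one hundred 256×256 pure-noise maps for false-positive
control (≥ 95 with no detection or < 0.5 % white), and ten 512×512
two-class maps for workflow-B discrimination (≥ 90 % structure pixels
excluded, ≥ 80 % inclusion pixels retained). Repeated runs are
bit-identical — there is no manual selection step, so the
repeated-measurement spread is exactly zero.

## Known limitations

* The Gaussian prior is fitted to the whole histogram, so heavy
  signal loads inflate `σ²`; the bulk-separation rule absorbs this for
  detection, but `q` itself still reflects the inflated prior.
* Workflow B assumes the non-inclusion structure class is dimmer than
  the inclusions and bright enough to form its own entropy peak; maps
  violating either assumption fall back to whatever the peak scan
  finds, and should be inspected with the diagnostic plot.
* A cell section dominated by signal (most pixels element-rich) leaves
  too little noise to anchor the prior; thresholds become unreliable.
* All areas are per-section pixel areas; no stereological correction
  to volumes is attempted.
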