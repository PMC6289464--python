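# entropymap

Relative-entropy thresholding and morphometry for energy-filtered TEM
(EFTEM) elemental maps of phosphorus- and nitrogen-rich cell inclusions.

Microalgae, cyanobacteria and many other cells store phosphorus as
polyphosphate granules and nitrogen as cyanophycin or related deposits.
On a background-subtracted EFTEM P- or N-map these reserve bodies appear
as bright, roundish regions — but so do weaker element-containing
structures (thylakoids, nucleus, starch envelopes), all on top of
counting noise. `entropymap` separates the inclusions from both, and
reduces each cell section to the relative reserve area

    S_R = 100 * S_TI / S_cell   [%]

where `S_TI` is the total inclusion pixel area and `S_cell` the cell
section pixel area. It is aimed at microscopists and cell biologists who
want reproducible, script-driven inclusion quantification instead of
manual contrast thresholds.

## The method

A net map is quantized to 256 grey levels `g` (map minimum → 0, maximum
→ 255). Its histogram `H(g)` — the *a posteriori* evidence of what is in
the image — is compared against a Gaussian *a priori* noise model with
the same pixel count, mean and variance:

    g_mean = (1/P) Σ g·H(g)
    σ²     = (1/(P−1)) Σ (g − g_mean)²·H(g)
    G(g)   = P/√(2πσ²) · exp(−(g − g_mean)²/(2σ²))
    R(g)   = ln[H(g)/G(g)]            (occupied bins)
    q      = (1/P) Σ R(g)·H(g)

Grey levels where the observed counts exceed the noise prior carry
positive relative entropy `R(g) > 0`; element-rich structures pile
excess counts into the bright tail, where a *group* of positive levels
stands apart from the noise bulk. Two workflows turn this into a binary
mask:

* **Workflow A** (sections with ≤ 10 inclusions): threshold at `g0`,
  the level just below the first sustained positive-entropy run above
  the histogram mean that is separated from the bulk; pixels with
  `g > g0` are white (element-rich).
* **Workflow B** (more than 10 inclusions): negative map values are
  zeroed before quantization, which makes a distinct peak of
  element-containing *non-inclusion* structures appear on the weighted
  curve `R(g)·H(g)`. The threshold `g1 > g0` is the end of that first
  peak; only the inclusions satisfy `g > g1`.

White pixels inside the cell mask (or an analyst ROI) are grouped into
connected components, assigned to compartments (vacuole, cytosol,
chloroplast, nucleus, PHB) by strict-majority pixel overlap, and
summarized per section and per sample. Net maps can be computed from a
three-window triplet: the pre-edge background is fitted per pixel as a
power law `I(E) = A·E^(−r)` through the two pre-edge images and
extrapolated to the post-edge energy (defaults 371/388/412 eV for N,
104/121/144 eV for P).

## Worked example

Simulate a 512×512 section with 5 high-contrast inclusions and analyse
it end to end:

```bash
entropymap simulate --n-inclusions 5 --shape 512 512 --seed 3 --compartments -o sim
entropymap analyze --map sim/map.tif --cell-mask sim/cell_mask.tif \
    --compartments sim/compartments.tif --legend sim/legend.json \
    --workflow auto --section-id demo -o out
entropymap summarize out/section.csv
```

prints

```
simulated 5 inclusions, true S_R=0.496% -> sim
demo: workflow A, 5 inclusions, S_TI=721 px, S_cell=145269 px, S_R=0.496%
section_id workflow  S_cell_px  S_TI_px  S_R_percent  n_inclusions main_compartment
      demo        A     145269      721     0.496321             5          cytosol
n=1  S_R min=0.496% max=0.496%  >8%: 0  zero: 0
main reserves in cytosol: 100% of sections
```

The auto mode counted 5 inclusions, kept workflow A, and recovered the
planted relative area exactly (S_TI = 721 of 145 269 cell pixels =
0.496 %); the per-inclusion table (`out/inclusions.csv`) lists each
granule's area, centroid and compartment. The same pipeline is available
in Python:

```python
from entropymap import analyze_map, generate_net_map, random_spec

net, region, truth = generate_net_map(random_spec(5, seed=3))
result, details = analyze_map(net, region, workflow="auto")
print(result.s_r, truth.true_s_r, details.thresholds)
```

Other subcommands: `entropymap three-window` (net map from a window
triplet), `entropymap export-histogram` (the `g/H/G/R/RH` table for
spreadsheet users), and `--plot` on `analyze` for the H/G/RH diagnostic
figure with `g0`/`g1` markers.

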