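# multinuc

Quantitative image analysis for studies of **cell multinucleation** — cells
that accumulate two or more nuclei when karyokinesis proceeds but cytokinesis
is suppressed (e.g. by culturing *Xenopus* XTC-YF epithelial cells on a
hydrophobic dish with the ROCK inhibitor Y-27632). The package covers the
three measurement arms such a study needs, plus a synthetic-image generator
that provides exact ground truth for all of them:

1. **Dish wettability** — sessile-drop contact angle from a lateral droplet
   silhouette, by least-squares circle fitting and the half-angle method.
2. **Multinucleation rate** — nucleus segmentation from the fluorescence
   channel, centroid assignment of nuclei to cells, nuclei-per-cell counting,
   and the multinucleated fraction R_multi per condition × timepoint.
3. **Morphometry** — cell and nucleus areas, best-fit-ellipse major axes,
   circularity, and nuclear-to-cytoplasmic (Wilson) area ratios, with
   mono-vs-multi group statistics.

It is aimed at cell biologists and bioimage analysts who want these
measurements scripted and testable rather than clicked through an image
viewer.

## The quantities

**Contact angle.** Edge points (xᵢ, yᵢ) digitized on the droplet outline are
fit by the algebraic (Kåsa) least-squares circle x² + y² + Ax + By + C = 0,
solved from the 3×3 normal equations; the radius is r = √(A²/4 + B²/4 − C).
With the apex height h measured from the silhouette and the contact-line
radius a = √(h(2r − h)) (the chord the fitted circle cuts on the dish
surface), the half-angle method gives

    θ = 2·arctan(h / a),

exact for a spherical-cap droplet at any θ in (0°, 180°). Larger θ = less
hydrophilic dish.

**Multinucleation rate.** With N_all counted cells and N_multi cells holding
≥ 2 nuclei,

    R_multi = 100 · N_multi / N_all   [%].

**Morphometry.** For each region, S is the area, M the full major axis of the
moment-matched best-fit ellipse, and circularity is reported in two
conventions: *roundness* α = 4S/(πM²) (1 for a disk, → 0 for a line; the
default) and the *literal* α = 4πS/M² = π² × roundness. The Wilson ratio
S_nucleus/S_cell is computed per nucleus and, for multinucleated cells, also
summed over all nuclei of the cell. Mono-vs-multi contrasts use unpaired
two-sided t-tests (nuclei as the unit for nuclear metrics, cells for cellular
ones); ≥ 3 dish groups are compared with Tukey's HSD.

## Worked example

```python
from multinuc import (CellFieldSpec, generate_cell_field, records_from_label_mask,
                      assign_nuclei_to_cells, count_multinucleated)

spec = CellFieldSpec(n_cells=100, frac_multinucleated=0.88, seed=1)
image, cell_mask, nucleus_mask, truth = generate_cell_field(spec)
records = assign_nuclei_to_cells(
    records_from_label_mask(nucleus_mask, spec.pixel_size_um), cell_mask)
summary = count_multinucleated(records, condition="treated", timepoint_h=48.0)
print(summary.n_all, summary.n_multi, summary.r_multi)
```

prints

```
100 88 88.0
```

— of 100 generated cells, 88 carry ≥ 2 nuclei, so R_multi = 88.0 %, exactly
the configured truth (integer counting leaves no rasterization slack).
Longer narrative scripts live in `examples/`, one per capability:
`contact_angle_measurement.py` recovers the three dish means (93°, 71°, 66°)
within a fraction of a degree and separates all pairs by Tukey HSD;
`morphometry_comparison.py` recovers the Wilson ratios (5.93 % mono vs
2.49 % per-nucleus multi on its seed) and shows the expected group
directions; `full_reproduction.py` runs everything end to end.

There is also a thin CLI (`multinuc simulate|contact-angle|count-nuclei|
morphometry|report|reproduce`) for shell use on image files.

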