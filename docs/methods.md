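# Methods

This note documents the models, conventions and design choices behind
`multinuc`, in the spirit of a methods section: what each stage computes,
what the synthetic generator does and does not emulate, and where the
design was genuinely open.

## Coordinate and unit conventions

Images are `(row, col)`, 0-based, rows increasing downward. Digitized
droplet-edge points are `(x, y) = (col, row)`, as read off an image viewer.
Label masks are 16-bit with background 0 and labels 1..N. Physical areas use
a configurable pixel size, default **0.664 µm/px** (a 680 µm field of view on
a 1024-px sensor); every output table carries both px and µm columns so the
calibration can be audited.

## Contact angle

A sessile microliter-scale water drop is modeled as a spherical cap. The
measurement chain is:

1. **Edge digitization.** Either user-supplied points (the classical manual
   procedure) or automatic extraction: Otsu binarization (droplet dark on a
   bright, backlit background), largest connected component above the
   baseline, per-row left/right boundary pixels ordered along the arc and
   subsampled to ≥ 10 points roughly uniform in arc position.
2. **Circle fit.** The algebraic least-squares (Kåsa) fit minimizing
   Σ(x² + y² + Ax + By + C)², solved from its 3×3 normal equations. The raw
   normal matrix is ill-conditioned for coordinates far from the origin, so
   the solve runs on mean-centered coordinates (where the matrix is nearly
   diagonal) and the parameters are shifted back; on exact circle points the
   radius is recovered to machine precision, and collinear inputs raise a
   degeneracy error rather than a spurious circle.
3. **Height.** h = baseline row − topmost silhouette row.
4. **Half-angle method.** θ = 2·arctan(h/a) with a the **contact-line
   radius**. For a spherical cap, h = a·tan(θ/2) identically, so the
   estimator is exact at every θ in (0°, 180°). The fitted circle radius r
   is the *sphere* radius (r = a/sin θ), which differs from a away from 90°;
   using r directly in the half-angle formula would bias a 66° droplet to
   ≈ 61°. We therefore derive a from the fit as the chord half-width on the
   baseline, a = √(h(2r − h)), and report both radii. This also handles
   θ > 90°, where the silhouette bulges wider than its contact line.

**Baseline detection.** Default: the bottommost foreground row (the
silhouette ends at the dish for any θ). The widest-row heuristic is also
available but is only valid for θ ≤ 90°, where the drop is widest at the
surface; an explicit baseline row overrides both.

**Accuracy.** Pixel quantization biases h and the fitted radius by ~0.5 px
each, in the same direction, so their ratio — and hence θ — is nearly
unbiased: noise-free round trips over 30–150° at base radius 100 px recover
θ within ±0.5° (tested to ±1°).

**Aggregation and testing.** Dish groups are summarized as mean ± SD (n − 1
denominator) and compared with Tukey's HSD on the studentized-range
distribution, applied to raw per-droplet angles under the usual
equal-variance pooling. The scipy implementation is used; tests cross-check
it against statsmodels to 1e-6 in p.

## Nucleus counting and R_multi

The fluorescence nucleus channel is binarized (Otsu default; fixed and
percentile thresholds available), holes are filled, connected components are
labeled with 8-connectivity, and components below a minimum area (default
20 µm², a debris filter) are dropped. Labels are assigned in raster order,
so runs are reproducible. Nuclei touching the image border are kept by
default (fields are counted whole), with an exclusion flag available.

Each nucleus is assigned to the cell region containing its **centroid**
(label mask or polygon outlines); centroid containment is robust to small
outline digitization errors, deterministic, and cheap compared with maximal
overlap. Nuclei in no cell are flagged unassigned and excluded; overlapping
polygon claims tie-break to the lowest cell id with a warning. N_all counts
cells with ≥ 1 assigned nucleus, N_multi those with ≥ 2, and
R_multi = 100·N_multi/N_all is pure integer counting — on ground-truth masks
it reproduces the generator truth exactly. The nuclei-per-cell histogram
keeps odd counts (3, 5, …), which arise when multinucleated cells divide
unevenly.

For synthetic fields the counting route of record uses the generator's
ground-truth nucleus mask (the real-data analogue is manual outlining plus
binarized nuclei); segmentation of the rendered image is run alongside as a
diagnostic. The two differ only through the debris filter, because the
configured Wilson-ratio distributions genuinely produce some nuclei smaller
than 20 µm².

## Morphometry

Areas are pixel counts (masks) or exact shoelace areas (polygons). The
best-fit ellipse is the moment-matched ellipse of the region (axes from the
second central moments, the de-facto standard behind "fit ellipse" in common
image software); for an ideal ellipse it returns the true axes, and tests
hold rasterized disks and ellipses to 2 % and rotation invariance to 1 %.

Circularity from S and M is reported in **two conventions** carried side by
side in every output table: the default *roundness* 4S/(πM²), which is 1 for
a perfect disk and tends to 0 for a segmented line, matching the standard
normalization statement; and the *literal* 4πS/M², which equals π² ×
roundness exactly (π² for a disk). The literal form is retained behind a
flag because published formulas sometimes appear in that scaling even when
the accompanying text anchors a disk at 1; keeping both makes either
interpretation reproducible. Perimeter-based circularity (4πS/P²) is out of
scope.

Wilson ratios are 100·S_nucleus/S_cell per nucleus, plus the per-cell sum;
the summed ratio is algebraically the sum of the per-nucleus ratios (same
denominator), asserted to 1e-12. Group contrasts are classical
pooled-variance unpaired t-tests at α = 0.05. The statistical unit is the
nucleus for nuclear metrics and the cell for cellular metrics, avoiding
pseudo-replication when multinucleated cells contribute several nuclei.

## Synthetic data generator

The generator is the oracle for every stage; all randomness flows through a
single `numpy` Generator seeded from the spec, so identical spec + seed is
bit-identical.

**Droplets.** A filled circular cap, dark on bright (backlit silhouette),
parameterized by contact angle θ and base (contact-line) radius a, default
100 px; apex height h = a·tan(θ/2) and silhouette-circle radius R = a/sin θ
follow exactly. Truth records θ, h, R, a and the baseline row. Optional
additive Gaussian gray-level noise, default SD 0 (no noise characterization
exists to emulate).

**Cell fields.** Non-overlapping elliptical cells on a jittered grid (grid
placement guarantees disjointness; an explicit image size that cannot hold
the requested cells raises a sizing error naming the minimum). Each cell
receives 1–5 elliptical nuclei, strictly inside the cell with ≥ 3 px
clearance between nuclei so 8-connected labeling can never merge them.
Exactly `round(n_cells × frac_multinucleated)` cells are multinucleated;
their nucleus counts are drawn from a configurable distribution, default
{2: 0.80, 3: 0.15, 4: 0.04, 5: 0.01} echoing the late-timepoint drift toward
higher counts (the published per-timepoint frequencies are graphical only,
so these are modeling choices, not measured values).

Nucleus sizes are set through nucleus:cell area-ratio distributions
(truncated normals, bounds 0.4–25 %): mononuclear cells default to
**5.9 ± 2.1 %**, multinucleated cells either per nucleus (**2.4 ± 0.6 %**)
or as a whole-cell sum (**5.0 ± 1.3 %**, split near-evenly by a Dirichlet
weight), selected by `ratio_mode`. These defaults are the measured 48-h
values of the study system. Cell areas default to 1600 ± 400 µm²; the
morphometry-comparison stage draws multinucleated cells larger
(2400 ± 500 µm² vs 1400 ± 350 µm²) with more eccentric nuclei, emulating the
reported directions (a cell that skipped cytokinesis keeps roughly the
contents of two, while its nuclei are individually smaller and less round).
The published group means for areas and circularities are shown only
graphically, so these magnitudes are plausible choices, not printed values.

Truth tables store the analytic ellipse values (area πab, major axis 2a,
roundness b/a); mask pixel counts agree within 2 % for objects of
equivalent radius ≥ 15 px (cells comfortably qualify; the smallest nuclei
are noisier per object but unbiased, so ratio *means* are recovered to well
within sampling error). The rendered nucleus channel adds per-nucleus
intensity jitter and optional blur/noise, defaults off.

**What the generator does not emulate:** irregular (non-elliptical) cell
shapes beyond a small optional boundary-perturbation knob, intensity
gradients and uneven illumination, overlapping or touching cells, mitotic
intermediates, and time-lapse dynamics. Passing recovery tests therefore
demonstrates correctness of the measurement chain, not robustness to the
full messiness of real micrographs — segmentation parameters still need
tuning on real data.

## End-to-end pipeline and problem sizes

`run_reproduce` chains all stages at the study's scale: 3 dish types × 10
droplets (noise-free for the mean-recovery check, angle-jittered at the
reported SDs of 2–4° for the Tukey check), a 4-condition × 3-timepoint
multinucleation timecourse at 100 cells per field (treatment plateau 88 % at
48 h, controls ≤ 5 %; intermediate trajectory points are illustrative), and
the 100-cells-per-group morphometric comparison. The whole run takes a few
seconds on one core. The global seed fans out to per-stage seeds through
fixed offsets so stages can be rerun in isolation; CSV outputs use a fixed
float format and are byte-identical across reruns. The timecourse
trajectories and group-size choices are configuration, not hard-coded.

`scripts/acceptance.py` recomputes the headline quantities from scratch at
the same sizes (10 droplets per dish; 100-cell fields). The Wilson-ratio
group means are sample means of ~100–230 truncated-normal draws, so their
recovery tolerance is statistical (2 standard errors ≈ 0.42 % mono,
0.08 % multi per-nucleus, 0.26 % summed); a correct implementation lands
outside a 2 SE band for a given seed about 5 % of the time by construction.

## Known limitations

- Automatic droplet edge extraction assumes a dark silhouette on a bright
  background and a single droplet per frame.
- Centroid assignment can misattribute a nucleus whose centroid falls
  outside a strongly concave cell; generated cells are convex, so this
  appears only with imported real outlines (an overlap-based mode would be
  the extension point).
- No watershed splitting: touching real nuclei merge into one record; the
  generator's 3 px clearance sidesteps this by construction.
- The debris filter (min nucleus area) trades false positives against
  dropping genuinely small nuclei; its default 20 µm² is exposed in config
  and logged.
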