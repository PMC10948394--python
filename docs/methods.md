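# Methods

## The measurement model

A DAPI image of a NET formation assay contains, to first approximation,
four object populations distinguishable by two quantities: total DNA
content (raw integrated density, RID — the sum of member-pixel
intensities) and projected area.

| object | area vs condensed nucleus | DNA vs condensed nucleus |
|---|---|---|
| condensed nucleus | 1× | ~1× |
| NET | ≥ ~4–5× | ~1× (same chromatin, spread thin) |
| doublet / clump | ~2× | ~2× |
| cell fragment | ≪ 1× | ≪ 0.5× |

Both classification axes are *relative*: each field supplies its own
condensed-nucleus reference area `A_ref` and DNA reference `D_ref`, so
calls are invariant to exposure scaling and to pixel-size changes. The
NET call uses `area / A_ref ≥ 4.30` and the eliminations use
`RID / D_ref` (strictly `< 0.5` fragment, strictly `> 1.2` multiple).
The upper elimination cutoff is applied to relative DNA content: that is
the only reading under which a 1.2 cutoff coherently separates doublets
(~2× DNA) from NETs, which exceed 4.3 in *area* while staying near 1 in
DNA.

### Decision sequence

Order matters and is fixed: (1) border objects out (truncated area/DNA
would corrupt both ratios); (2) fragments out, so shards do not dilute
the area reference; (3) NET call; (4) multiples out among non-NETs
only — a diffuse halo can push a NET's relative DNA slightly above 1.2,
and eliminating first would systematically under-call NETs; (5) the
rest are nuclei. Inclusivity is fixed (NET at ≥ cutoff, eliminations
strict) so results are bit-reproducible.

### The condensed-nucleus reference

`A_ref` must estimate the typical *non-NET* nucleus area from a mixture
that contains NETs. We use a median with iterative NET exclusion,
seeded from the lower quartile: initial candidates are ROIs whose area
is ≥ 4.30× the 25th percentile of all areas; the reference is the
median of non-candidates; ROIs reaching the cutoff against that
reference join the candidates; repeat until stable (the candidate set
grows monotonically, so at most n iterations). Two properties drove
this design:

* With NET prevalence up to ~50 % a plain median of all areas sits
  between the populations and never excludes anything — at 15 nuclei +
  15 NETs the unseeded iteration converges with zero candidates and no
  NET is ever called. The quartile seed anchors the estimator on the
  nucleus cluster as long as nuclei dominate the lower quartile.
* The mean fails already at 10 nuclei + 1 NET; the median does not.

The iteration can never exclude its own anchor (the smallest ROI's
ratio against any median of a set containing it stays below 2), so the
reference is always defined when at least one non-fragment ROI exists.

`D_ref` is the median RID of border-filtered ROIs — a robust single-pass
choice. The reported "average cellular DNA" (mean RID over retained
nuclei + NETs) is deliberately *not* reused as the elimination
denominator, to avoid circularity between the call and its threshold.

### Sparse fields

A field with fewer than `min_rois_for_field_reference = 10` non-border
ROIs cannot support its own order statistics (a {100, 430} pair yields a
reference of 265 and under-calls the obvious NET). Such fields borrow
`A_ref`/`D_ref` from the pooled measurements of their slide-condition.

### Aggregation

`NET% = 100 · Σ nets / Σ retained`, pooled over a slide's fields — a
ratio of counts, not a mean of per-field percentages, so fields with
more cells weigh more and empty fields contribute nothing.

## Segmentation

Two thresholds with published defaults:

* **Intermodes global threshold** — one-bin-per-level histogram for
  8-bit-range integer data, else 256 equal bins over the observed range;
  3-bin running-mean smoothing (edge-replicated) until exactly two
  strict local maxima survive; threshold = midpoint of the two mode
  centres. A histogram that never passes through a two-mode state
  (constant or truly unimodal image) raises an error carrying the
  iteration count; `on_unimodal: otsu_fallback` is available but off by
  default, because silently thresholding an empty field would bias NET%.
* **Phansalkar local threshold** — radius 15, k 0.25, r 0.5, p 2, q 10
  on the [0, 1]-normalised image, edge-replicated windows, foreground
  strictly above threshold. These are the algorithm's published
  defaults; the source analysis states none.

How the two combine is a genuinely open design point; we default to
`local_seeded_by_global`: keep each connected component of the local
mask that overlaps ≥ 1 pixel of the global mask. The local threshold
delineates boundaries (including faint NET rims); the global threshold
vetoes background-texture components. A pixelwise AND is available but
truncates diffuse halos to their bright cores. Components below
`min_area_px = 10` (an absolute speckle floor, below any plausible
nucleus) are dropped; connectivity is 8. All knobs live under
`segmentation:` in the YAML config.

Solidity uses the convex hull of the ROI taken as a union of unit pixel
squares (hull over pixel corners). A hull over pixel *centres* would
make a filled 10×10 square have hull area 81 < 100 and solidity > 1;
the corner convention gives hull area = pixel count for convex regions
and solidity ≤ 1 always. Roundness is the ImageJ definition
4A/(π·major²), allowed a 0.05 discretisation epsilon above 1 on tiny
regions. Min/max brightness are measured and reported but drive no
filter by default.

## Quality control and method agreement

Outliers are flagged strictly outside mean ± k·SD (k = 2, sample SD)
of their (group, condition) stratum; strata with n < 3 are reported
unflaggable. Manual recounts replace the automated value with a
provenance flag; flagged-but-unreviewed slides keep the automated value
with an `unreviewed_outlier` flag — nothing is silently dropped.

Bland–Altman limits use multiplier 1.96 (the published validation
limits are consistent with 1.96, not 2.0: 4.38 + 1.96·16.33 = 36.39 as
printed). Differences are oriented by-eye − automated, so a positive
bias reads "the automated method undercounts". Recomputing limits from
*rounded* printed (bias, SD) summaries can disagree with printed limits
in the last digit (−27.63 vs −27.62), because the original software
used unrounded values; comparisons are therefore made at printed
precision.

## The synthetic scene generator

`SceneSpec` renders 512×512, 16-bit fields: flat background 0.02 of
full scale, Gaussian read noise SD 0.005 (added last; ground truth is
drawn before noise), and non-overlapping objects placed by rejection
sampling with a 6 px spacing floor (an exhausted placement budget
raises an error naming the failing class):

* **nuclei** — uniform disks, area ~N(240, 20²) px, peak 0.95 of full
  scale (exposure set on the condensed nuclei, just below saturation;
  clipping is validated to stay under 0.1 % of pixels);
* **NETs** — ellipses of 5–6 nucleus areas, aspect 3–5, whose *total*
  integrated intensity is drawn at 1.0–1.2 nucleus-equivalents and
  spread with a centre-weighted linear taper (1.5× mean at the centre
  to 0.75× at the rim), plus a ~9 px bright remnant kernel of condensed
  chromatin at nuclear intensity. The elongated, tapered, kernel-bearing
  shape encodes how real NETs look (a dim cloud around a brighter core)
  and is what makes the dual-threshold segmentation meaningful: the
  kernel seeds the global mask, the cloud is delineated locally;
* **doublets** — two overlapping disks (centre distance 1.9× the mean
  radius, areas at ±6 %), max-blended: ~1.85–2.1 nucleus-equivalents;
* **fragments** — 10–16 px shards at nuclear intensity,
  ~0.04–0.07 nucleus-equivalents.

Determinism: one RNG stream per field, derived as
CRC32(master seed, slide, field) < 2³¹, so manifests reproduce
piecewise. DNA conservation (NET ∈ [0.8, 1.2], doublet ∈ [1.8, 2.2]
nucleus-equivalents on the noiseless render) is asserted by test.

What the generator does **not** emulate: optics (PSF), uneven
illumination, intensity heterogeneity within nuclei, filamentous NET
morphology, and touching non-doublet cells. Passing recovery tests
therefore demonstrates the internal coherence of segmentation +
calling + pooling under the stated object model, not performance on
clinical images — which is exactly why the supervised QC and
Bland–Altman steps exist in the workflow.

## Validation problem sizes

The recovery suite runs ten 512×512 fields of ~20 cells per true NET
fraction {0, 0.2, 0.5} (plus 2 doublets and 3 fragments each), across
ten seeds — large enough that pooled NET% errors are driven by
systematic mis-segmentation rather than counting noise, and small
enough to iterate on quickly. Observed pooled errors are ≤ 0.5
percentage points with 100 % doublet and fragment elimination; the
suite's acceptance band is ±5 points.

## Known limitations

* The 4.30 / 1.2 cutoffs were optimised for a specific acquisition
  setup (600× magnification, Olympus BX51); other optics likely need
  re-optimisation, which is why every cutoff is configurable.
* Physical pixel size is not modelled; all areas are in pixels, and
  relative areas carry the burden of comparability.
* Touching nuclei are not split (no watershed); they are eliminated as
  multiples instead, which slightly shrinks the denominator rather than
  miscounting NETs.
* The lower fragment cutoff (0.5 nucleus-equivalents of DNA) has no
  published counterpart; it is a documented default.
* Duplicate wells are reported as separate slides; averaging duplicates
  is left to downstream analysis.
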