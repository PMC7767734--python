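# Methods

## The measurement problem

Epidermal keratinocytes change metabolism as they differentiate while
moving from the basement membrane to the stratum corneum. To relate a
per-cell readout — formazan precipitate from G6PD enzyme histochemistry,
or an immunofluorescence marker — to a cell's position and
differentiation state, every cell in a tissue section must be (i) found,
(ii) assigned to an epidermal stratum and (iii) measured in each channel.
`epicyto` does this with exactly two guidance features that need no
immunostaining: the tight linear arrangement of nucleated basal cells
along the basement membrane (nuclei channel) and the optical contrast of
the epidermis, including the anucleate cornified layer, against the
dermis (brightfield channel).

## Pipeline stages and their parameters

All lengths are specified in µm and divided by `pixel_size_um` at use.
Every stage logs its effective parameters; thresholds must be explicit
config inputs because staining intensity is in arbitrary camera units
and differs between experiments.

**Nucleus detection** (`nuclei.detect_nuclei`). Gaussian smoothing
(`nuclei_smooth_sigma_um`, default 1 µm) → global threshold (Otsu
default) → watershed from smoothed-intensity maxima at a minimum peak
separation (`nuclei_peak_min_distance_um`, 3 µm ≈ one nucleus radius) →
area filter (`nuclei_min_area_um2`, 10 µm²). This is a standard,
fully reproducible chain chosen over proprietary segmentation engines.

**Nuclei map** (`nuclei.build_nuclei_map`). Nuclei in close proximity
are connected by morphological closing with a disc; the radius defaults
to 1.5× the median nearest-neighbour centroid spacing measured on the
section itself, so the map adapts to cell density. Enclosed holes are
filled and components below `map_min_area_um2` (100 µm²) removed. Note
the area opening means an isolated nucleus far from all others (e.g. a
dermal fibroblast) is deliberately dropped from the map; within the
epidermal band the map always covers every nucleus pixel.

**Brightfield area** (`strata.brightfield_area`). The inverted
brightfield is smoothed (2 µm), thresholded (Otsu default), holes are
filled and components below 200 µm² removed.

**Epidermis prediction** (`strata.predict_epidermis`). The nuclei map is
the seed, the brightfield area the growth region: the prediction is the
union of brightfield-area components that contain seed pixels. Dense
dermal debris without nuclei is thereby excluded, as are dermal nuclei
outside the dense band. Manual correction is supported only as optional
add/remove masks applied after the automatic step — no interactive
editing, so runs stay reproducible.

**Strata partition** (`strata.partition_strata`). The band is assumed
simply connected and roughly horizontal (each column meets it in one
run of pixels); closed or branching contours are rejected with an error.

* *Corneal side*: of the two long contour sides, the one with the higher
  area per nucleus within a margin of depth 2× the median nucleus
  diameter (`side_margin_factor`) is corneal. The decision uses nuclei
  density only, so it is invariant to flipping the image.
* *Stratum corneum*: the nuclei density map (Gaussian kernel,
  `density_bandwidth_um` 3 µm) is thresholded at 5 % of its maximum
  (`density_support_fraction`); the corneum is everything between the
  corneal contour and the support component **connected to the basement
  side**. Requiring connectivity matters: isolated retained nuclei in
  the corneum (parakeratosis) generate their own density blobs, and
  without the connectivity rule they would drag the corneum boundary
  outward and escape their corneal classification. The bandwidth/threshold
  pair was chosen from the kernel geometry so the support edge tracks the
  nucleated border: larger bandwidths or lower thresholds let the support
  swallow the corneum, smaller ones fragment it across sparse upper rows.
* *Basal and low suprabasal*: Euclidean distance from the basement edge
  (for a thin band this equals the geodesic distance). The first nucleus
  layer is the set of nuclei whose centroid distance is within 2 median
  radii of the closest nucleus; the basal band depth is the 95th
  percentile of those nuclei's far edges + 1 px, so the layer depth
  adapts to the actual nucleus size. The same step, started from the
  basal band, yields the low suprabasal layer; the remainder below the
  corneum is high suprabasal. If no second nucleus layer exists the
  whole nucleated band is basal (single-row tissue), keeping the
  partition exact.

The four strata are pairwise disjoint and tile the epidermis
pixel-exactly by construction; this is asserted in the tests.

**Cell masks** (`cells.grow_cell_masks`). Measurement masks grow
simultaneously from all nuclear seeds, confined to the nucleated strata,
capped at `cell_max_radius_um` (default 10 µm) from the **nucleus
boundary** — basal cells are themselves about 10 µm wide, so a
centroid-based cap would truncate them. Distance is the chamfer (1, √2)
geodesic inside the allowed region, kept as exact integer step counts
(a + b·√2), which makes tie-breaking (equidistant pixels go to the lower
nucleus id) deterministic and lets the tests demand pixel-exact equality
with an independent per-pixel nearest-seed oracle. Nuclei lying wholly
in the corneum are flagged `corneal` (the parakeratosis readout) and
excluded from growth; each grown cell contains its complete nucleus.

**Measurement** (`histocytometry.measure_cells`). Per cell and channel,
nuclear, cytoplasmic (cell minus nucleus) and whole-cell means are all
reported, since conventions differ on which of the latter two "mean
intensity" should denote; γH2AX gating uses the nuclear mean and
activity the cytoplasmic one. Optical density is the linear inversion
I_max − I of the brightfield (a log transform can be applied downstream
if desired), with I_max the modal intensity of the non-tissue
background, so OD is anchored at 0 in empty regions and comparable
across sections. OD is floored at 0; cells whose nucleus fills the whole
mask get missing cytoplasmic values and a `cyto_missing` flag.

**Gating and summaries.** Gates are absolute, Otsu-on-distribution, or
control mean + k·σ (default k = 3 for γH2AX, where no published
positivity criterion exists); the rule and threshold are recorded in the
table metadata. Stratum distributions normalise to 1 over non-empty
subsets; the 95 % density contour of a scatter summary is the smallest
set of highest-count bins holding 95 % of that stratum's cells, with a
shared binning across strata.

**Kinetics** (`kinetics`). The linear range of the formazan reaction is
the largest prefix window (≥ 3 points) whose OLS fit reaches R² ≥ 0.95;
a constant series is reported as `flat` rather than propagating NaN.
The DHEA negative-control series is subtracted pointwise and floored at
0, with the number of floored points reported — silent clipping would
hide mis-registration. The default per-timepoint quantity is the mean OD
over a stratum mask; a cell-level mean-of-means is available by running
the pipeline per timepoint.

**Statistics** (`stats`). The default two-sample test is the classical
equal-variance unpaired two-tailed Student's *t* (Welch by flag); stars
follow the conventional 0.05/0.01/0.001/0.0001 thresholds. Cells are
treated as independent observations, which mirrors cell-level violin
statistics in tissue cytometry but is pseudo-replication with respect to
donors; `aggregate_by=` runs the same test on per-section means for a
conservative alternative. The treatment × stratum analysis is a type-II
two-way ANOVA with Bonferroni-adjusted (p_adj = min(1, m·p)) pairwise
condition contrasts within each stratum.

## The synthetic generator

`synthetic.generate_section` draws a cross-section in column geometry:
a sinusoid-plus-noise basement membrane (amplitude 6 µm, wavelength
150 µm), one basal nucleus row at fixed spacing (8 µm) one nucleus
radius above it, `n_suprabasal_rows` (4) further rows at 9 µm spacing
whose occupancy decays by 0.85 per row, an anucleate gap (5 µm) and a
stratum corneum (15 µm). Ground-truth strata are bands in
height-above-membrane coordinates derived from the same geometry, so
they tile the epidermis exactly and contain their cells' centroids.

Channels: nuclei are Gaussian blobs (σ ≈ r/1.9); brightfield starts at a
bright background (210 a.u.), drops to 165 in the nucleated band and 115
in the corneum, and each cell's activity is subtracted as uniform
attenuation over its nearest-nucleus (Voronoi) footprint within the
nucleated band — so the inverted brightfield recovers activity up to a
constant band offset. IF markers paint flat per-cell values over the
same footprints (nuclear discs for γH2AX); additive Gaussian noise is
applied last. Per-stratum mean activities default to 30/45/60 a.u.
(basal/low/high), i.e. a gradient peaking in the granular layer; the
figure sources for these report no absolute values, so the defaults are
free parameters with a realistic ~1.4–2× suprabasal/basal ratio.
Composition fractions (6 % K14-negative basal cells — the midpoint of
the 5–7 % non-epithelial residents expected in the basal layer; γH2AX+
fraction; 20 % tracker-labelled) are drawn as exact-count random
subsets: the fraction is a property of the tissue, not a per-cell coin.

Perturbation presets: `uv` adds per-stratum activity increments
(+12/+20/+10, largest in the low suprabasal stratum), sets 40 % of cells
γH2AX-positive and couples activity to the nuclear γH2AX value with
slope 0.04 a.u./a.u.; `prelabelled` confines 20 % tracker-labelled cells
to the suprabasal strata with a −10 a.u. activity offset;
`metformin` adds +25 a.u. uniformly; `metformin_7d` adds no increment
but 5 % retained corneal nuclei. Time courses accumulate attenuation
linearly at rate = activity/25 min per cell; the DHEA-inhibited variant
clamps every cell to a 0.1 a.u./min background rate.

What the generator does **not** emulate: optical point-spread and
shading, autofluorescence, chromatin texture, rete ridges and
appendages, 3-D sectioning artefacts, and biological covariance between
markers beyond the modelled couplings. Passing the synthetic suite
therefore demonstrates the correctness of the algorithms and the
recoverability of effects under the stated noise model — not performance
on real stained tissue, where thresholds must be tuned per experiment.

## Problem sizes and numerical choices

Validation runs use sections of 480–8100 px width (60–1200 basal cells,
~220–4500 cells total) at 1 µm/px; the headline composition-recovery run
uses ≥ 1000 basal cells so the 6 % subpopulation is estimated from ≥ 60
cells. Statistical calibration uses 1000 null replicates (n = 100 per
group) for the *t*-test and 200 replicates for the ANOVA family-wise
check. Degenerate inputs (blank planes, constant series, empty subsets,
nucleus-filling masks) return explicit empty/flagged results rather than
NaN; all randomness flows from a single integer seed per run.

## Known limitations

* The strata logic assumes one simply connected, roughly horizontal
  band per image; folded sections need manual-correction masks, and
  closed contours (cysts, follicle cross-cuts) are rejected.
* Chamfer (1, √2) geodesics overestimate Euclidean length by up to ~8 %
  along some directions, so "10 µm" masks are marginally conservative
  off-axis.
* Otsu gating presumes a bimodal marker distribution; for weak effects
  the control-based `bg+k*sd` rule is preferable.
* Cell-level tests inherit pseudo-replication; per-section aggregation
  is provided but reduces power accordingly.
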