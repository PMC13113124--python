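# Methods

## Scope and data model

All pipelines operate on `ImageStack`: a `(channel, z, y, x)` float
array with a physical voxel size (Δz, Δy, Δx) in µm. Stacks round-trip
through plain multi-page TIFF with a JSON description tag carrying the
calibration; a file without recognizable calibration is an error unless
the caller overrides it, because voxel size is physical input that must
never be silently defaulted. Confocal fixtures use a 0.1 µm z-step with
three planes and 0.1 µm in-plane pixels; expansion-microscopy (ExM)
fixtures use a 1 µm z-step with 0.1 µm pixels. Only the z-steps are
fixed acquisition constants of the workflow; the in-plane pixel size is
a package choice made consistent with a high-NA 100×/60× objective.

## Confocal morphometry

The per-cell chain is: median z-projection → median filter (disk
radius 1 px) → white top-hat (disk radius 5 px) → Triangle threshold →
binarize → connected components (8-connectivity) → per-object
measurement. Structuring elements are discrete disks by Euclidean
distance; all borders reflect. The mask is built on the filtered image,
but mean intensity is measured on the unfiltered projection inside the
mask, so background flattening never distorts the intensity readout.
Objects smaller than `min_size_vox` (default 4 voxels) are discarded as
shot-noise specks; the original workflow states no size filter, so the
default can be set to 0.

**Triangle threshold.** The 256-bin histogram spans the image min–max.
Counts are normalized by the peak so the chosen bin is invariant to
uniform count rescaling. The tail side is the longer run from the peak
to the extreme nonzero bin (ties go to the bright side, where
fluorescence foreground lives); the threshold bin maximizes the
perpendicular distance to the chord from the peak to that tail bin,
lowest bin on ties. On strongly peaked histograms the algorithm places
the cut just above the background mode — the expected behaviour, which
is why object *counting* is robust while absolute mask areas depend on
the histogram shape.

**Fragmentation surrogate.** The published phenotype call is blinded and
visual; the package replaces it with the fraction of mitochondrial area
held in objects smaller than `area_cut_um2` (default 1 µm²), calling a
cell fragmented when that fraction exceeds `frac_cut` (default 0.5).
These two defaults are artifact-defined (validated on the synthetic
cohorts, where they separate the two simulated phenotypes with 100%
accuracy down to SNR 3), not values stated by any protocol. The score is
monotone: merging sub-threshold objects into one supra-threshold object
cannot raise it.

**Colocalization.** Object-based, not intensity-based: within a 30 µm
neurite segment, each connected mitochondrial object is positive when it
shares at least `coloc_min_overlap_vox` voxels (default 1) with the LC3
mask. One shared voxel is the least-assumptive object-based rule; the
overlap requirement is configurable. A segment without mitochondria
raises an explicit empty-denominator error rather than returning 0%.

**Soma mask.** Triangle threshold on the tubulin projection, largest
connected component, holes filled. When soma and neurite are connected
the component contains both — "intensity in the soma" follows the
tubulin-positive territory, and two disjoint somas keep only the larger.

## Expansion microscopy

The gel's expansion is measured macroscopically as an area ratio;
isotropic expansion scales areas by the square of the linear factor, so
voxel dimensions are divided by √(area ratio). An option treats the
reported ratio as already linear for labs that record it that way.

The quantification chain is 3D Gaussian smoothing → per-channel
threshold → 26-connected components on the c-Abl mask → the four
metrics. Density uses the full analyzed biological volume by default (a
cell-mask restriction is available). Association and occupancy are
voxel-volume ratios of `cabl∧mito`, `cabl∧¬mito` and `mito`; the two
AND-masks partition the c-Abl mask exactly. A fully mitochondrial c-Abl
signal makes the association ratio infinite — reported as `inf` with a
flag, never silently clipped.

**Smoothing is physically isotropic.** The default pre-threshold filter
is a Gaussian of σ = 0.2 µm (acquisition scale), converted per axis to
voxels. On the 10:1 anisotropic ExM grid a voxel-unit sigma would mean a
1 µm axial blur, which measurably erodes clusters whose axial extent is
a few z-steps and makes biological-scale volume estimates depend on the
expansion factor; with resolution-scale smoothing the same biological
scene quantified at linear factors 2 and 4 agrees to within ~3% in mean
cluster volume (and exactly in density). A voxel-unit sigma
(`smooth_sigma_vox`) remains available.

**Thresholds.** The original ExM workflow selected thresholds
interactively, which is irreproducible; the package defaults to the
Triangle algorithm and accepts explicit per-channel numeric overrides as
the reproducible stand-in. The validation suite quantifies synthetic
scenes at the half-maximum level (background + amplitude/2), the
choice an operator makes when the object/background contrast is known —
half-maximum is also the level at which a blurred step edge stays at its
true position, which is what makes volume estimates nearly unbiased.

## Synthetic scenes

The generator emulates each imaging experiment with uniform-amplitude
voxel supports plus optional degradations, and records ground truth at
construction:

- **Mitochondrial networks** — punctate mode renders ellipsoidal blobs
  (diameter 0.5 ± 0.1 µm, floored at 0.4 µm so every object survives
  the 3-plane median projection and the speck filter); tubular mode
  renders 0.15 µm-radius tubes along persistent random walks
  (length 5 ± 1 µm). Objects are placed with a 1 µm clearance
  ("well separated"); placement is rejection-sampled with a budget of
  100 attempts per object, after which the scene is declared
  overcrowded.
- **Neurite colocalization** — mitochondria are packed into a 3 µm-wide
  strip over a 30 µm segment; exactly `round(f·n)` of them get an LC3
  punctum centred on them (≥ 1 shared voxel by construction), remaining
  LC3 puncta are decoys placed clear of every mitochondrion. The
  measured percent-positive therefore has an exact expected value.
- **ExM volumes** — the layout (sphere centres and radii) is drawn
  entirely at biological scale inside a 10 × 9.6 × 9.6 µm specimen, so
  one seed defines one biological scene regardless of the expansion
  factor; rendering multiplies coordinates by the factor and samples on
  the acquisition grid. Associated clusters are wrapped in a 0.4 µm
  mitochondrial shell (containment by construction); two cluster-free
  mitochondrial spheres (r = 1.2 µm) are added; non-associated clusters
  stay clear of the mitochondrial mask. Clearances are anisotropic
  (1 µm axial, 0.3 µm lateral) because the 1 µm z-step undersamples
  axial gaps. Default conditions: density 0.015 µm⁻³, mean cluster
  volume 2 µm³ (CV 0.25), association fraction 0.5.
- **Neuron geometry** — a soma (r = 8 µm) with a straight ≥ 30 µm
  neurite (r = 0.8 µm), rendered z-uniform in the thin 3-plane stack;
  truth includes the soma mask, centerline and segment mask.

**Optics and noise.** Scenes are noise- and blur-free by default: the
exact-recovery contracts (counting, colocalization, classification) are
statements about undegraded supports. Degradations are explicit: an
isotropic Gaussian PSF surrogate applied before noise, and
Poisson–Gaussian camera noise (Poisson at gain *g* photons per intensity
unit plus additive read noise). `NoiseParams.for_snr` solves for the
gain that yields a target peak SNR, defined as amplitude over total
noise SD at an object voxel. What passing tests show is that the
pipelines recover construction parameters under this camera model; real
images add structured background, out-of-focus haze, chromatic shifts
and touching organelles that the generator deliberately does not model —
watershed-free component counting, in particular, undercounts touching
mitochondria in dense real cells.

## Statistics

Welch's one-way ANOVA is computed from the Welch (1951) formulas
(weights nᵢ/s²ᵢ, Satterthwaite-style denominator df); its empirical
type-I error on heteroscedastic nulls (3 groups, σ = 1, 2, 3, n = 10) is
calibrated at 5% ± 1.5% over 1,000 simulations in the validation suite.
The repeated-measures ANOVA uses the standard condition/subject/error
sum-of-squares decomposition on complete blocks. Kruskal–Wallis defers
to scipy, with the identical-data edge case (H = 0, p = 1) handled
explicitly.

Post hoc procedures: Tukey HSD (scipy); Bonferroni (pairwise Welch or
paired t-tests, p × m capped at 1); Dunn's rank z-tests with the
standard tie correction and Bonferroni familywise adjustment
(implemented in-package, as no installed library provides it; verified
against an independent in-test computation); and Dunnett-style
many-to-one comparisons computed on *unpooled* Welch standard errors
with Welch–Satterthwaite df, honouring the Welch-then-Dunnett pairing
used in this workflow's figure legends. The Dunnett familywise
adjustment integrates P(max|T| ≥ t) over the control-induced correlation
structure by a fixed-seed Monte-Carlo draw (2·10⁵ samples), so adjusted
p-values are deterministic to ~3·10⁻³ and converge to scipy's classical
Dunnett under homoscedasticity. Adjusted p-values never fall below raw
ones. Shapiro–Wilk normality is reported per group as a gatekeeper but
never switches tests silently. Both Tukey (protocol text) and
Bonferroni/Dunnett/Dunn (figure-legend) pairings are implemented; the
caller records which was requested.

Normalizations: percent-of-vehicle is 100·(v − bg)/mean(vehicle − bg);
densitometry is (target/reference)/(control ratio); the autophagic index
is the p62 ratio with/without lysosomal block. All validate their
denominators and refuse non-positive ones.

## Validation problem sizes

The suite runs at desk scale, chosen so the full run stays interactive:
200 random histograms for the Triangle oracle, 100 random masks for the
flood-fill oracle, 20-seed cohorts for SNR-conditioned recovery, 40-cell
cohorts for phenotype discrimination, one ExM scene pair (factors 2
and 4) for scale consistency, and 1,000 null simulations for the Welch
calibration. `scripts/acceptance.py` recomputes all of these from
scratch for any seed.

## Known limitations

- No watershed splitting: touching objects count as one.
- Automatic single-cell segmentation is out of scope; per-cell ROIs are
  supplied (or taken from truth masks in synthetic work).
- The ExM pipeline does not model gel distortion or chromatic
  registration; the expansion factor is a single global scalar.
- Intensity-correlation colocalization (Pearson/Manders) is deliberately
  absent: the readouts here are object-based.
- The fragmentation thresholds are surrogates tuned on synthetic
  cohorts; absolute agreement with any particular blinded human scorer
  is not claimed.
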