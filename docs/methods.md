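# Methods

## Scope and model

`tagtrace` quantifies single-mRNA translation imaging in the syncytial
blastoderm: given 3D centroids and summed intensities of fluorescent puncta
(mRNA channel, nascent-protein channel, optional 5′/3′ probe channels) and a
nucleus table, it produces per-territory and AP-binned translation
efficiency, per-site ribosome numbers, 5′–3′ end separations, and
translation-site tracks. The measurement chain treats the embryo surface as a
nuclear monolayer: all axis work is done in the xy projection, z entering
only 3D point-to-point distances (colocalization, territory assignment).

## Synthetic embryo generator

No imaging data ship with the package; the generator produces statistically
matched stand-ins with truth labels. What it emulates, and its defaults:

* **Geometry.** The embryo outline is a 500 × 160 µm ellipse (conventional
  egg length 500 µm; widths of this order are typical) whose anterior tip
  sits 25 µm inside a 220 × 220 × 12 µm imaging frame — the field of view
  covers roughly the anterior third of the egg. The midline is tilted
  uniformly within ±15° of the frame x-axis with a random 180° flip and up to
  ±10 µm lateral offset: acquisitions are roughly aligned with the embryo
  axis but never exactly. Nuclei sit on a hexagonal lattice whose constant is
  set from the visible embryo area and the requested count (140/280/550 for
  nc12/13/14, matching the doubling of nuclear density per cycle), jittered
  by 0.8 µm, as spheres of radius 3.5/3.0/2.5 µm. Nuclei modelled as spheres
  (not segmented surfaces) suffice to exercise nuclear masking.
* **mRNA field.** Per-territory counts are Poisson in an AP expression
  profile — by default an anterior plateau with a logistic fall at 250 µm
  (50% EL), the shape of an anterior-enhancer expression domain. A
  configurable fraction (default 0.12) of mRNAs is placed inside the nucleus
  sphere to exercise masking; cytoplasmic mRNAs are rejected out of all
  nucleus spheres. Each cytoplasmic mRNA is translated with probability given
  by an AP profile: flat 0.55 (nc12), flat 0.50 (nc13), or a logistic rise
  from 0.05 anteriorly to 0.60 in the posterior of the domain (nc14,
  midpoint 150 µm ≈ 30% EL) — the anterior-repression pattern.
* **Protein field.** A translated mRNA carries a site displaced by an
  isotropic Gaussian of σ = 0.1 µm (well inside the 0.6 µm pairing radius)
  with intensity `ribosomes × I_single × c × lognormal`, ribosome loads
  Poisson(20) truncated at ≥ 1. Free single proteins (5·10⁻⁴ µm⁻³, lognormal
  about I_single = 100 with 25% CV — the single-protein CV is not a measured
  quantity, so it is a configurable default) and rare bright aggregates
  (5·10⁻⁵ µm⁻³, ~20× brighter) populate the volume. All intensity noise is
  lognormal (median-1 multiplicative factors): strictly positive, matching
  multiplicative imaging noise; site-level CV defaults to 10%.
* **Probe pairs.** The 5′ spot sits at the mRNA; the 3′ spot is displaced in
  a uniformly random 3D direction by a lognormal distance with median 0.25 µm
  (translating) or 0.20 µm (silent), shape σ = 0.3. A low density of
  unpaired 3′ spots emulates probes on untagged endogenous transcripts. The
  epitope-cassette and downstream CDS lengths default to 1350/2250 nt
  (total 3600 nt, correction factor c = 0.8125); the true transgene lengths
  are not published, so they are required configuration inputs — these
  defaults are consistent with a ~3.1 kb spacing between probe-set centres.
* **Time-lapse.** Tethered sites jitter about fixed anchors (σ = 0.15 µm);
  free proteins take Gaussian steps with D = 5 µm²/s; detections drop out
  independently per frame. Nuclei persist across frames.

Each generator stage draws from its own seeded substream, so any output is
reproducible from (config, seed) and independent of call order.

**What the generator does not emulate:** transcription dynamics, mRNA decay,
morphogen gradients, photobleaching, chromatic aberration or probe
localization error, segmented (non-spherical) nuclear surfaces, z-curvature
of the blastoderm surface, and mitotic nuclear movements. Tests passing on
synthetic data therefore demonstrate correctness of the measurement chain
under its stated assumptions, not robustness to every property of real
stacks.

## Numerical and procedural choices

* **Thresholds are strict (`<`).** All colocalization radii (0.6 µm
  translation, 0.3 µm probe pairing/translating classification) exclude
  boundary equality. A radius of zero is legal and matches nothing.
* **Matching is one-to-one, greedy by ascending distance**, ties broken by
  ascending ids — deterministic, and verified in tests to agree with an
  exhaustive optimal assignment at realistic densities.
* **Internuclear distance** is the *median* (not mean) xy nearest-neighbour
  spacing: robust to packing defects.
* **Edge trimming** removes nuclei within 1.5 internuclear distances of the
  frame boundary (the acquisition frame when known, else the nuclei bounding
  box).
* **Boundary extraction** uses a 2D alpha-shape with α = 2× the internuclear
  distance (convex hulls miss concave outlines); boundary points within 2.6
  internuclear distances of the frame edge are treated as crop artefacts and
  excluded from the two lateral arcs, as are points within one internuclear
  distance of the axial extremes.
* **Midline** is total least squares (orthogonal residuals) through the
  midpoints of all cross pairs between the two arcs — no privileged
  coordinate.
* **Anterior orientation** compares nucleus counts in windows of 3 × 20 µm
  measured inward from the two axis ends and calls the sparser end anterior.
  The window spans several bins deliberately: the anterior cap narrows over
  tens of µm, whereas a tilted frame crop depletes only the outermost ~20 µm
  sliver of the posterior end; a single-bin comparison mistakes that sliver
  for the anterior. An exact tie raises an error (no silent guess).
* **AP origin.** AP = 0 at the anterior-most retained nucleus's projection;
  %EL = 100·AP/500. Whether the in-frame anterior-most nucleus coincides
  with 0% EL of the egg is an assumption of the conversion.
* **Bins** are half-open, left-closed, anchored at AP = 0, width 20 µm.
  Binned percent translated is the pooled (count-weighted) value; per-embryo
  profiles aggregate across embryos as mean ± s.d.
* **Nuclear masking before pairing, both channels** — the analysis is
  explicitly cytoplasmic. Duplicated records (same channel and centroid to
  1e-6 µm) collapse to one.
* **Ribosome calibration is per embryo** (imaging gain varies between
  acquisitions); the single-protein pool excludes spots brighter than 5× the
  pool median, one iteration. Estimates n̂ ≤ 5 are flagged low-confidence
  (strictly greater than five counts as confident, per the stated detection
  floor) and excluded from summaries; both the continuous estimate and a
  rounded count are reported, summaries use the continuous value.
* **Spot detection** is a difference-of-Gaussians band-pass at the expected
  PSF scale (σ_xy = 0.15 µm, σ_z = 0.35 µm), local maxima above 6× the MAD
  of the filtered image (stacks hold millions of voxels, so the threshold
  must sit well beyond 5σ of correlated noise; matched-filter gain keeps
  recall at 1.0 down to SNR ≈ 4 on rendered stacks), border maxima excluded,
  near-coincident maxima merged keeping the brighter. Quantification is
  Gaussian-mask estimation: iterative Gaussian-weighted recentring for the
  subvoxel centroid, then a least-squares amplitude of the erf-integrated
  Gaussian against the background-subtracted window (background = median of
  the window border). This is deliberately not full PSF fitting.
* **Live-channel smoothing** is an à-trous B3-spline wavelet band selection
  (details at scales 2–3 by default); a constant image maps to zero.
* **Tracking** replaces proprietary autoregressive-motion models with
  nearest-neighbour linking plus gap closing (6 µm travel cap, 5-frame gap):
  membrane-tethered sites are nearly stationary, so a motion model adds
  nothing. The output contract (no over-cap displacement, no over-budget
  gap) is assertable and asserted.
* **Statistics.** Region comparisons use one-way ANOVA with Tukey HSD;
  compaction uses per-embryo medians and a paired two-sided t-test (identical
  classes are reported as t = 0, p = 1 rather than NaN); site-level medians
  carry seeded percentile-bootstrap 95% CIs (10,000 resamples).

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
embryos of 140–550 nuclei with 2,000–6,000 mRNAs, 100-embryo Monte-Carlo
batches for geometry, 7-embryo batches for compaction, 40-frame movies of 80
sites, and 250×250×32-voxel rendered stacks. These sizes are large enough
that binomial/bootstrap error bounds in the tests are meaningful, and the
entire suite completes in well under a minute of compute per module.

## Known limitations

* The AP coordinate is planar; strongly curved or laterally mounted embryos
  would need a curved-surface unrolling that is out of scope.
* Greedy matching is near-optimal, not provably optimal, at high density;
  pairing accuracy degrades gracefully as spot spacing approaches the
  colocalization radius.
* Unmatched 3′ probe spots are dropped without modelling the
  endogenous-transcript population they likely represent.
* The tracker has no motion model and no fusion/fission handling.
* Ribosome counts inherit any bias in the single-protein standard; partial
  epitope occupancy is corrected only in aggregate via c.
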