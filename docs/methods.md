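# Methods

This note documents the models, conventions and defaults implemented in
`apicodyn`, the reasoning behind choices the underlying measurement
procedures leave open, and what the synthetic-data validation does and
does not demonstrate.

## Measurement model

### Apical morphometry

A cell's apical surface is a simple polygon (ordered vertices, µm) traced
at the inner border of the bright junctional actomyosin rim. Its area is
the absolute shoelace area (computed via shapely; invariant to vertex
rotation, orientation and rigid motion). Two measurement regions derive
from it:

* **cap** — the polygon interior (the apicomedial myosin pool);
* **cortex** — the polygon offset outward by `band_width` (default
  0.5 µm) minus the polygon, i.e. a closed junctional band. Round joins
  (Minkowski sum with a disc) are the default because they have exact
  closed forms for validation (convex polygon: band area = P·w + πw²);
  mitre joins are available. The join style of the original
  line-widening tools is not specified anywhere, so the canonical
  definition was chosen. "Outward" means away from the polygon interior;
  no centroid construction is involved.

Region intensity is the mean of raster values whose **pixel centers**
fall inside the region (row-major raster, y down, pixel (r,c) centered
at ((c+0.5)·px, (r+0.5)·px)). This matches common raster-measurement
semantics and is exactly reproducible by a brute-force pixel loop. A
0.5 µm band needs pixel size ≲ 0.25 µm to be sampled reliably; the
default synthetic pixel size is 0.2 µm. Cells whose offset band leaves
the raster are flagged and excluded from intensity statistics.

Staining intensity varies between embryos (fixation, antibody
penetration, detector settings), so intensities are normalized **per
embryo and per compartment**: normalized = 100 · raw / mean(raw over
that embryo's analysed cells, all groups pooled). The within-embryo mean
of normalized values is exactly 100%, and the operation is idempotent up
to that scale. Pooling both mitotic and interphase cells into the embryo
mean is deliberate: the normalizer is the embryo's overall staining
level, not a group-specific quantity.

Area–intensity association is summarized per group and compartment by
Pearson r (two-sided p from the t distribution with n−2 df) plus the OLS
line. The biological expectation encoded in the synthetic generator: the
relation is negative in mitotic cells and absent in interphase cells,
where pulsatile constriction/dilation decouples instantaneous area from
myosin load.

### Pulse dynamics

Traces are uniform-Δt apical-area series (µm², minutes). Each trace is
normalized by its own mean (output mean exactly 1), removing inter-cell
size variability. Alignment sets T0 = the annotated anaphase frame for
mitotic cells and the minimum-area frame for interphase cells (earliest
frame on ties — a deterministic rule). When two post-division daughters
are present, exactly one is retained: the one flagged in the lineage
annotation, else the first by cell id. (A nearest-centroid rule would
need positional data that the trace container deliberately does not
carry.) Aggregation reports per-timepoint n, mean and SEM = sd/√n; SEM
is undefined at n = 1.

Pulse amplitude is |A| from a trust-region nonlinear least-squares fit
of y = c + A·sin(2πt/T + φ), initialized from the dominant discrete-
Fourier component with the period bounded in [2Δt, 2·span]. Fallback
seeds at periods span, span/2, span/3 rescue traces whose dominant
period falls between Fourier bins; seeding stops early once a candidate
explains half the variance. If no solver run succeeds the amplitude
falls back to half the peak-to-trough range with `converged=False`.
The fit is exact (≤1e-6) on noiseless sinusoids at any phase and any
in-bounds period.

Two fitting windows exist because the amplitude of a mitotic cell is
ambiguous: by default the full trace is fitted (event included), which
measures total oscillation magnitude and is what the mitotic-vs-
interphase amplitude contrast uses; `interphase_window=True` truncates
mitotic traces to >30 min before anaphase, which is the right mode for
recovering the underlying sine amplitude ratio (the full-trace mitotic
amplitude is inflated ~50% by the constriction event).

Tests: paired two-sided t of area at T−lag vs T0 (lag default 30 min;
cells lacking the T−lag sample are excluded and counted), and unpaired
two-sided t of fitted amplitudes between groups. Zero-variance edge
cases are flagged degenerate rather than raising (all-zero differences:
t=0, p=1; constant nonzero difference: p=0 with infinite statistic).

### Tissue curvature

Profiles are ordered 2D polylines from an optical reslice plane; 3D
surface curvature is out of scope. Two summaries:

* **arc/chord ratio** — polyline length over endpoint distance; 1 for
  flat profiles, (θ/2)/sin(θ/2) for a circular arc subtending θ.
  Caveats: the ratio depends on the chord span (profiles compared
  should span similar chords; `check_chord_spans` warns at >20%
  spread), and the polyline length is inflated by point noise, so on
  near-flat noisy profiles the ratio overestimates curvature.
* **circle-fit radius** — the Taubin algebraic fit (gradient-weighted
  algebraic distance, solved by one SVD). It is deterministic, exact on
  noiseless circles, and nearly unbiased on noisy short arcs, where the
  simpler Kåsa fit systematically underestimates the radius (measured
  here: ~2.3% vs ~1.2% mean radius error at radius 80 µm, 1 rad arc,
  0.5 µm noise, 100 points). Collinear input yields an infinite-radius
  "flat" flag, not an exception. The RMS radial residual is reported so
  poor arcs can be rejected.

Per-embryo radius of curvature vs median mitotic apical area is
summarized by Pearson correlation; under the convex-geometry hypothesis
the expected sign is negative (flatter tissue, smaller mitotic apices).

### Ki-67 staging

Ki-67 redistributes through interphase stereotypically: many small
nucleolar-associated foci in early G1, two condensates in S, one punctum
in G2, then spreading over condensing chromosomes at mitotic entry. Foci
are connected components (26-connectivity) of supra-threshold voxels
inside the nuclear mask; the threshold is Otsu over masked voxels by
default (exposed), and components under 2 voxels are discarded as noise.
The stage rule, applied in order:

1. **M** if the condensed-chromatin flag is set and the Ki-67-positive
   volume fraction exceeds f_M = 0.5;
2. **G2** if exactly one focus;
3. **S** if exactly two foci, each >2% of nuclear volume;
4. **early G1** if ≥4 foci, each <1% of nuclear volume;
5. otherwise **unclassified** (a value, not an error).

All numeric thresholds are engineering defaults (`StagingThresholds`);
the underlying staining patterns are qualitative. The condensed-
chromatin flag is an input annotation (from a DNA channel or ground
truth), never inferred from Ki-67. Nuclear volume is voxel count ×
voxel volume; apical distance is the unsigned plane or nearest-polyline
distance from the mask centroid. Stage summaries default to merged
"G1/S" reporting (matching how apical areas are usually grouped), with
the 4-class breakdown available; the volume-ordering flag
(earlyG1 < S < G2 mean volume) is always evaluated on unmerged stages.
The "nuclear index" is implemented as epithelial thickness divided by
mean apicobasal nuclear extent, reported to one decimal — an explicit
operational stand-in for a qualitative pseudo-row count.

## Synthetic data: what it emulates

Every analysis input can be generated with an explicit seed and exported
ground truth; identical (params, seed) gives bit-identical output, and
every generated object has exactly one ground-truth record.

**Apical mosaics.** Cells are seeded by Poisson-disc dart throwing
inside horizontal strata (one per cell-cycle group, height proportional
to the group's share of total target area), relaxed once by Lloyd's
method and tessellated by Voronoi (mirror-clipped to the field). Seed
density controls **group mean** areas; exact per-cell area control is
not attempted. Because field size, cell count and group means are
overconstrained, the field is rescaled to the implied total area.
Geometry presets encode the observed stage-area patterns: "flat" has G2
(45 µm²) > G1/S ≈ M (25 µm²); "convex" keeps mitotic apices large
(G2 45 ≥ M 40 > G1/S 25); a mitotic-marker preset uses the mouse
posterior-neuropore means (pHH3+ 20.5, pHH3− 34.5 µm²). Mitotic
intensities follow α + β·area (β = −3 AU/µm² ≤ 0); interphase
intensities are area-independent; cap and cortex share the model with
correlated noise (ρ = 0.7, mirroring the observed cap–cortex
correlation); embryos occupy contiguous vertical columns and scale
intensities multiplicatively (lognormal sd 0.25 when not specified;
exactly 1.0 for a single embryo). The table-only sampler
(`sample_cell_table`) draws per-cell lognormal areas (σ = 0.35,
CV ≈ 36%, consistent with the broad spread of reported apical areas)
for statistical studies that need no geometry, and
`calibrated_regression_table` additionally calibrates intensity noise to
the **realized** area dispersion so each dataset's true R² is exact —
the right construction for parameter-recovery studies of the fitted R².

**Traces.** Interphase: mean·(1 + A·sin(2πt/T + φ)) + noise, A = 0.05,
T ~ U(40, 80) min, φ uniform, additive noise sd 2% of mean. Mitotic:
the same baseline with sine amplitude doubled (ratio 2.0) times a
piecewise-linear event: mild dilation (peak +10%) from 60 to 30 min
before anaphase, linear constriction to 1 − depth (depth 0.4) exactly
at the anaphase frame, then linear re-dilation to baseline over 30 min.
Anaphase frames are drawn so the full event window fits inside the
trace, guaranteeing aligned coverage of T0−60…T0+30 min. The frame
interval (5 min) and duration (180 min) are engineering choices — the
source observations only fix the 30-min pre-anaphase window — and both
are configurable. Default cohort size is 29 mitotic + 54 interphase
cells, the reported T0 group sizes.

**Profiles.** Points on a circular arc of given radius and subtended
angle plus isotropic Gaussian noise; the 75–106 µm radius range of the
bead cultures motivates the defaults.

**Nuclei.** An ellipsoidal nucleus (semi-axes 3.6 × 3.0 × 2.8 µm scaled
per stage: earlyG1 0.85, S 0.95, G2 1.10, M 0.80, with 4% lognormal
jitter) rendered at 0.3 µm voxels, background Ki-67 0.1 AU inside the
nucleus, foci 1.0 AU, Gaussian noise sd 0.05. Early G1 places 4–10
disjoint foci of radius 0.35–0.45 µm (each ≲0.5% of nuclear volume); S
places two condensates (0.95–1.10 µm) on opposite sides of the nucleus;
G2 one punctum (1.3–1.5 µm); M uses the condensed-chromatin mass itself
as the mask (nuclear envelope breakdown) with signal over ~85% of it.
Focus placement is rejection sampling with bounded retries and full
restarts; persistent failure raises.

**What passing tests do not show.** The generator renders piecewise-
constant intensities without a PSF, photobleaching, z-attenuation or
segmentation error; polygons are exact (no tracing noise); traces have
no gaps, tracking errors or missed anaphases; nuclei are ellipsoids with
spherical foci. Validation therefore demonstrates that the *measurement
chain* is correct and well-calibrated (closed-form geometry, exact
normalization, unbiased amplitude and radius recovery, nominal type-I
rates, perfect staging on clean patterns), not that the pipeline is
robust to the full noise structure of real microscopy. Statistical power
figures (e.g. amplitude discrimination at the default cohort sizes)
are properties of the synthetic noise levels.

## Statistics

Two-group comparisons default to the classic pooled-variance t-test
(Welch behind a flag, paired where measures repeat); all p-values are
two-sided and reported in full — α = 0.05 is a reporting annotation,
never a filter. One-way ANOVA is computed from the sum-of-squares
decomposition; two-way designs use an OLS fit with interaction when
balanced, degrading to main effects with a logged warning when not
(near-balanced designs are the intended use; no mixed-effects or
repeated-measures machinery is provided). Post-hoc pairwise t-tests are
Bonferroni-adjusted (raw p × number of comparisons in the family, capped
at 1). Zero-variance inputs are flagged degenerate (t-tests) or raise
(correlation). All tests are cross-checked in the suite against
independent brute-force implementations.

## Numerical choices and degenerate inputs

* Polygon validity (≥3 vertices, simple) is enforced with errors naming
  the offending cell.
* Offset bands use `quad_segs=64` arc segments per quarter circle by
  default; closed-form comparisons at 1e-6 absolute tolerance need
  ~600.
* The sine fit uses xtol=ftol=gtol=1e-10, ≤500 function evaluations per
  seed; constant traces short-circuit to amplitude 0.
* Collinearity (circle fit) is detected by the maximum perpendicular
  deviation from the endpoint chord relative to coordinate scale
  (1e-12).
* Paired differences constant to within 1e-12 relative count as zero
  variance.
* Pipeline runs embed a config hash and seed in the report; reruns with
  identical config and seed are byte-identical.

## Known limitations

* Curvature is 2D-profile based; no 3D surface fitting.
* The arc/chord ratio is span- and noise-sensitive (see above); the
  fitted radius is the more robust cross-sample summary.
* Ki-67 staging thresholds are tuned to the synthetic patterns; real
  data will need threshold review, and G1/S separation is intentionally
  conservative (merged by default).
* The cap region is the full polygon interior; if the traced outline
  sits at the inner border of a thick cortical rim, cap measurements
  include any rim signal inside that border.
* Two-way ANOVA supports balanced designs only (with interaction);
  unbalanced input is analysed additively with a warning.
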