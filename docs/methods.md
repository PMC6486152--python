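# Methods

This note documents the models, the defaults and why they were chosen, what
the synthetic data do and do not emulate, and the numerical conventions.

## Intensity model and normalization

Observed nuclear intensity is modelled as multiplicative attenuation of a
log-normal signal with imaging depth:

    I_obs = exp(mu + eps) * exp(-k z),    eps ~ N(0, sigma^2)

so log intensity is linear in z. The correction fits OLS of log(I + eps0) on
z per embryo and channel, pooling all frames, and removes the fitted slope
relative to the embryo's **median z** — a scale-preserving, robust reference
point. The offset eps0 is 0 whenever all intensities are positive and 1
otherwise; this keeps the correction an exact inverse of the generative
decay (a nonzero offset would make log(I + eps0) nonlinear in z) while still
accepting zero-intensity pixels. An embryo whose nuclei share a single z has
no identifiable slope; the correction is then the identity, with a warning.

Standardization is per embryo over all frames (sample sd, ddof 1). An
embryo with fewer than 2 usable nuclei or zero variance is an error naming
the embryo, not a silent NaN.

Positivity thresholds are per *batch* (embryos processed and imaged
together), mirroring how imaging sessions differ in gain. The automatic
mode fits a two-component Gaussian mixture to log intensities and cuts at
the equal-posterior point between the component means; degenerate mixtures
(empty component, coincident means, no crossing between the means) fall back
to the midpoint of the widest gap between adjacent order statistics, with a
warning. Manual per-batch values are always available and take precedence
in practice, since by-eye thresholding against cytoplasmic background is the
field's reference procedure.

Cassette assignment for three-antibody mosaic experiments is a total
function on the 8 call patterns: HA-positive (including triple-positive,
which arises from antibody cross-reactivity with the tagged construct) is
GOF; GFP-positive without HA is LOF; RFP only is the recombined wildtype
cassette; all-negative is unrecombined. GFP+HA+ without RFP is still GOF —
the cross-reactivity direction makes HA the dominant marker.

## Ellipsoid model and inner/outer classification

The embryo outline is modelled as a general (rotated) 3-D ellipsoid.
`fit_ellipsoid` is the direct least-squares quadric fit with the quadratic
constraint (k = 4) that guarantees an ellipsoid solution; points are
centered and isotropically scaled first for conditioning. The
parametrization excludes surfaces through the coordinate origin, which
cannot occur for centroids in positive micrometre coordinates. Fewer than 9
points is an error naming the embryo and frame; coplanar point sets and
non-ellipsoidal solutions fall back to the axis-aligned bounding ellipsoid
(half-extents × √3 so all points are enclosed), flagged `degenerate`.

Normalized radius r is the Euclidean norm after translating to the center,
rotating into the axis frame and dividing by the semi-axes; r = 1 on the
surface. Classification: outer ⇔ r ≥ threshold, default **0.7**, ties
outward. The threshold is a configuration value; 0.7 sits midway between
the radial bands the generator uses for inner and outer cells and matches
the intuition that an outer (polarized) cell's nucleus sits in the outer
third of the embryo radius.

A plain surface fit through *all* nuclear centroids is dragged inward by the
deep inner cells (the fit minimizes algebraic distance to a solid cloud, not
a shell). `fit_embryo_surface` therefore (1) seeds the fit with the convex
hull vertices, (2) iteratively refits on the points in the outer shell of
the current model (r ≥ 0.75·r_max), and (3) inflates the semi-axes by half
the 10–90 % spread of the shell radii: the fit passes through the centroids
of the surface monolayer, while the embryo envelope lies about half a
monolayer further out. All three steps are data-driven; no absolute cell
size enters. For points sampled on a surface the procedure reduces to the
plain fit. One ellipsoid is fit per embryo per frame by default; pooling
frames is available and preferable when frames are many and the embryo is
stationary.

## Lineage classification

The forest is built over cell-frame observations: each observation after
frame 0 has exactly one predecessor (same track, or the parent of a
division); divisions must have exactly two daughters; observations with no
path to frame 0 are reported as orphans and excluded. "First/final time
points" are the movie's frame 0 and last frame — a family is a frame-0 cell
plus all descendants. Cells lost mid-movie contribute to trajectories while
present but not to leaf labels; families with no surviving leaves are
UNCLASSIFIABLE and flagged. The four named classes cover founder/leaf label
combinations that share at least the founder's side; the two uncovered
patterns (e.g. an inner founder whose descendants all end outer) are OTHER,
flagged rather than merged. Intensity summaries use the per-embryo
standardized reporter channel, never raw intensities.

## Statistics

Conventions fixed package-wide: two-sided tests; classical equal-variance
Student's t by default (Welch behind a flag); Bonferroni multiplier = number
of pairs, adjusted p = min(1, m·p_raw); chi-square without continuity
correction, warning when an expected count is below 5; Fisher's exact
two-sided p = sum of hypergeometric probabilities of all tables with the
observed margins whose probability does not exceed the observed table's
(the conventional definition — competing two-sided rules exist, so it is
stated here). Correlation results carry both r and r², since figure legends
in this literature are often ambiguous about which is printed.

## Motif scanning and the candidate funnel

Log-odds scores (log2, against a background model, uniform unless supplied)
are discretized to an integer grid of 1/1000 log-odds unit. The null score
distribution is computed exactly by convolving the per-position score
distributions under the background (dynamic programming); the threshold for
tail probability α (default 1e-4, per strand model) is the smallest integer
score s with P(S ≥ s) ≤ α. Scanning reports every window at or above the
threshold on both strands, minus-strand windows scored on the reverse
complement and reported in forward coordinates; windows overlapping N are
skipped. Zero-probability matrix cells map to a sentinel far below any
attainable score.

The built-in RBPJ model is a synthetic consensus-based matrix (0.85 on the
consensus base TGTGGGAAA, 0.05 elsewhere); it is deliberately sharp so the
canonical site scores far above threshold while the GG→CC mutation known to
abolish binding scores far below. Any CIS-BP-style table or JASPAR block
can be loaded instead; count matrices are converted with the pseudocount
rule (c + pc)/(total + 4·pc).

Funnel semantics: the DEG filter (adjusted p < 0.05 and |logFC| > 1) is
applied to the *input* table — differential expression itself is upstream of
this package. A gene "has a motif" if at least one super-threshold hit lies
fully inside the window TSS ± 10 kb (TSS = start of + genes, end of −
genes; windows clipped at chromosome bounds); hits are not deduplicated
across overlapping windows. "Open chromatin" requires full containment of
the hit in a peak, not mere overlap. Genes in the DEG table without
coordinates count as no-motif and are listed in a warnings section. The
counts are monotone by construction: DEG ≥ with-motif ≥ in-open-chromatin.

## The synthetic generators

**Movies** (`simulate_embryo_series`): cells live on a fixed axis-aligned
ellipsoid (semi-axes 30/25/20 µm), inner cells at normalized radius
U[0, 0.6], outer cells on the shell U[0.8, 1.0] — an unambiguous ground
truth with a 0.2 margin. Daughters appear at the parent's position ± a
small jitter; each cell switches shell per frame with probability
`reposition_prob` (default 0.02), re-sampling its radius in the new band.
Log intensity follows the cell's *current* shell:
mean_in + slope_in·t or mean_out + slope_out·t, plus N(0, noise_sd), then
exponentiation and multiplication by exp(−z_decay·z). Defaults for the
reporter channel: 4.0/4.6 intercepts, ∓0.015 per-frame slopes, noise 0.25 —
a clear but noisy class separation on the log scale, chosen as a plausible
reporter effect size (the real magnitude is not published; it is a
configuration value, not a measured one). z_decay defaults to 0.01/µm
(≈ 40 % loss over a 50 µm stack, typical confocal attenuation), centroid
noise to 1 µm (sub-nuclear segmentation error). Movies default to 7
embryos, 16 → up to 32 cells, 25 frames — one round of divisions at
desk-scale problem sizes.

What the movies do **not** emulate: segmentation errors and track breaks,
the blastocoel cavity (inner cells fill the whole deep volume), cell death,
compaction mechanics, and intensity bleaching over time beyond the class
slopes. Passing tests therefore demonstrate correctness of the estimators
under a clean generative model, not robustness to tracking failures.

**Cohorts** (`simulate_fixed_cohort`): single-frame tables with
ch3 = a·ch1 + b·ch2 + noise on the raw scale; closed-form population R²
helpers make the statistical tests self-checking. Default a = b = 1, equal
channel sds, noise variance half a channel variance — each pairwise R² is
0.4 and the joint R² 0.8, a regime where the joint fit visibly beats either
marker.

**Genome fixtures** (`simulate_genome_fixture`): genes spaced so TSS
windows never overlap, planted consensus sites at recorded offsets/strands,
peaks covering exactly the sites flagged in-peak and avoiding all others,
background rejection-resampled until a full two-strand scan at the exact
threshold finds nothing outside the planted footprints — so the expected
funnel counts are exact by construction, and the scanner independently
verifies them.

## Problem sizes in the validation runs

The benchmark module fixes desk-scale sizes: 20 embryos × 64 cells for
position recovery (early-blastocyst scale), 100 replicates of 7 movies for
fate recovery and detection, 100 cohorts of 400 cells, 1000 random 10 kb
sequences for scanner exactness, 50 random funnel designs, all 2×2 tables
with total ≤ 40 for Fisher, and 10⁴ null replicates for t/chi-square
calibration. These sizes give sub-percent Monte-Carlo error on every rate
while keeping a full run to a few minutes on one CPU.

## Known limitations

- The surface estimator assumes a roughly convex, roughly ellipsoidal
  embryo; cavitated blastocysts (an off-center cavity breaks the radial
  symmetry of inner cells) would need a cavity-aware model.
- Automatic thresholding assumes an approximately two-component log-normal
  intensity mixture; heavy-tailed background can shift the cut.
- The exact-threshold DP assumes independent background positions (order-0
  background); no Markov background is implemented.
- Orphan handling discards unrooted track fragments rather than attempting
  gap closure.
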