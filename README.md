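# blastoquant

Quantitative analysis of nuclear markers in preimplantation mouse embryos:
from segmented-nucleus intensity tables to positional (inner/outer) and
lineage-fate statistics, plus a regulatory-genomics arm that funnels
differentially expressed genes through transcription-factor motif and
open-chromatin filters.

## Who this is for

Developmental biologists quantifying fixed or live-imaged morula/blastocyst
stage embryos. The package consumes the measurement tables produced by
nuclear-segmentation tools (one row per nucleus: embryo, timepoint, x/y/z
centroid, per-channel mean intensity) and the edge lists produced by cell
trackers; it does not segment or track images itself. A synthetic-data
module generates all of these inputs with known ground truth, so every stage
is testable without microscopy data.

## What it computes

**Intensity normalization.** Confocal signal decays with imaging depth; the
attenuation is multiplicative, so within each embryo and channel the model
is log *I* = *c* − *k·z*. The slope *k̂* is estimated by OLS and removed
relative to the embryo's median *z*, preserving the intensity scale. To
compare embryos, intensities are standardized per embryo to mean 0, sd 1.
Positivity calls use a manual per-batch threshold or a two-component Gaussian
mixture on log intensities cut at the equal-posterior point; three-marker
calls yield Venn partitions and the mosaic-cassette rule
(HA⁺ → GOF, GFP⁺HA⁻ → LOF, RFP⁺ only → wildtype, else unrecombined).

**Position.** Each embryo's shape is fit with an ellipsoid (direct
least-squares quadric fit constrained to an ellipsoid); a nucleus at
position **p** has normalized radius
r = ‖diag(1/a, 1/b, 1/c) Rᵀ(**p** − **c**)‖, which is 1 exactly on the
surface. Cells with r ≥ 0.7 (configurable) are outer, the rest inner. For
solid clouds of nuclei the surface is estimated robustly: fit the hull
vertices, refit iteratively on the outer shell, and inflate by half the
shell's radial spread (nuclear centroids of the surface monolayer lie inside
the embryo envelope).

**Lineage.** Tracking edges are assembled into a forest over cell-frame
observations; each frame-0 founder and its descendants form a family.
Families are classified from the founder's position and the leaf positions
at the final frame: IN-ICM, IN-TE+ICM, OUT-TE, OUT-TE+ICM (plus flagged
OTHER/UNCLASSIFIABLE patterns). Per-family reporter trajectories, initial
(frame-0) intensities and position-change fractions are summarized per
class.

**Statistics.** Squared Pearson correlation, multiple-R² of a joint fit,
classical Student's t, one-way ANOVA with Bonferroni pairwise post-tests,
chi-square homogeneity, and a two-sided Fisher's exact test computed by
hypergeometric-probability summation.

**Regulatory funnel.** A position-weight matrix (built-in RBPJ consensus
model for the site TGTGGGAAA, or any CIS-BP/JASPAR table) is scored as
integer-discretized log-odds; the score threshold at a chosen tail
probability α is calibrated *exactly* by dynamic programming over the
background model. Windows of ±10 kb around each differentially expressed
gene's TSS are scanned on both strands; genes with a super-threshold hit,
and genes whose hit is fully contained in an open-chromatin peak, give the
staged counts DEG → motif → open chromatin.

## Worked example

```python
import blastoquant as bq

params = bq.SimParams(seed=1)                 # 7 movies, 16 -> 32 cells
nuclei, tracks, truth = bq.simulate_embryo_series(params)

pos = bq.classify_nucleus_table(nuclei)       # ellipsoid fit + inner/outer
forest = bq.build_forest(tracks, nuclei)
classes = bq.classify_families(forest, pos)

df = bq.correct_z_attenuation(nuclei, "ch1")  # depth correction
df = bq.standardize_embryo(df, "ch1")         # per-embryo mean 0 / sd 1
init = bq.initial_intensity(forest, df, "ch1_std", classes)
print(init.groupby("family_class").initial.agg(["mean", "count"]).round(2))

groups = [init.loc[init.family_class == k, "initial"].values
          for k in ("IN-ICM", "OUT-TE")]
res = bq.anova_bonferroni(groups, ["IN-ICM", "OUT-TE"])
print(f"OUT-TE vs IN-ICM: F = {res.statistic:.1f}, p = {res.p_value:.2e}")
```

prints

```
              mean  count
family_class
IN-ICM       -0.84     11
IN-TE+ICM    -0.65     11
OTHER        -0.24     27
OUT-TE        0.12     51
OUT-TE+ICM    0.08     12
OUT-TE vs IN-ICM: F = 29.4, p = 1.09e-06
```

Families founded by inner cells carry lower standardized reporter levels
already at the first frame than families founded by outer cells
(−0.84 vs +0.12 sd units; highly significant), with mixed-fate families in
between — the reporter anticipates the lineage outcome.

The same pipeline is available from the shell:

```bash
blastoquant simulate embryos --seed 1 --out sim/
blastoquant position --in sim/nuclei.csv --out positions.csv
blastoquant quantify --in sim/nuclei.csv --threshold-mode auto --out calls.csv
blastoquant lineage --tracks sim/tracks.csv --positions positions.csv \
    --calls calls.csv --out families.csv
blastoquant simulate genome --seed 5 --out genome/
blastoquant scan --genome genome/genome.fa --genes genome/genes.bed \
    --deg genome/deg.tsv --peaks genome/peaks.bed --out report/
```

## Layout

```
src/blastoquant/
  simulate.py     synthetic movies, cohorts and genome fixtures (ground truth)
  quantify.py     z-correction, standardization, positivity, Venn, cassettes
  spatial.py      ellipsoid fitting and inner/outer classification
  lineage.py      forests, fate classes, family trajectories
  stats.py        correlations and classical tests
  regulatory.py   PWM scanning, exact threshold calibration, candidate funnel
  benchmarks.py   self-contained validation runs shared by tests and scripts
  cli.py          `blastoquant` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
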