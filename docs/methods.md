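# Methods

This note documents the models, statistics and numerical choices behind
`pdl1bench`, in the order data flows through the pipeline.

## Coordinate convention

All geometry lives in continuous micrometer coordinates, origin at the ROI
top-left, x rightward, y downward. Pixel `(i, j)` of a raster with spacing
`s` µm/px has its center at `((j+0.5)·s, (i+0.5)·s)`. The convention is
fixed project-wide; annotations from sources with different pixel spacings
are converted to µm before any distance is computed.

## Synthetic ground truth

An ROI is a *marked hard-core point pattern*: cell counts are Poisson with
the configured intensities (cells/mm²) over the ROI area, positions are
drawn by sequential rejection sampling with a minimum separation `d_min`,
and each tumor cell is PD-L1 positive independently with the configured
positivity fraction. Defaults: 150×150 µm ROIs at 0.5 µm/px (the scale of
reader-study fields), tumor density 4000/mm², other-cell density 2000/mm²
(mid-range NSCLC cellularity), `d_min` = 6 µm so that distinct cells remain
distinguishable under the 8 µm matching radius. If a sampled count cannot
be placed at `d_min` within a bounded number of attempts the generator
raises rather than silently truncating, so tests can rely on the exact
Poisson marginal. Proposals are checked against a spatial-hash grid of bin
size `d_min`, keeping generation linear in the number of cells.

Rendering is optional (all downstream statistics operate on point sets).
When enabled, every nucleus is drawn as a hematoxylin-toned blob (flat core
with a Gaussian shoulder, radius 2.8 µm, peak optical density 0.9) and each
PD-L1 positive cell receives a DAB-toned membrane ring (radius 4.2 µm).
Stains compose additively in optical-density space with the
Ruifrok–Johnston H and DAB vectors and exponentiate to RGB (Beer–Lambert),
which makes color deconvolution with the same vectors a left inverse of
rendering — a property the tests exploit. The renderer makes no attempt at
histological texture realism; it exists so the stand-in detector has
physically meaningful signal.

## Reader and detector error model

A `ReaderModel` applies, per true cell and in a documented fixed order
(miss-uniform, confusion-categorical, jitter-normal pair): a per-class miss
probability, a relabeling draw from the 3×3 row-stochastic confusion
matrix, and isotropic Gaussian localization jitter. Jittered points are
clipped to the ROI bounds so the miss rate is governed solely by the miss
parameter. Spurious points are then added as a homogeneous Poisson process
with a class distribution. Simulated detectors reuse the same machinery
with their own parameters.

Because real reader error structure on this task is not publicly
characterized, the default panel is a *plausibility stand-in*, not an
estimate of any real readers: misses 2.5–6%, jitter 1.2–2.0 µm, spurious
points 40–70/mm², and a confusion structure dominated by
negative-tumor ↔ other-cell swaps (the prevalent human disagreement mode on
PD-L1 IHC, where benign/malignant discrimination is the hard part). The
default detector localizes better than the readers (jitter 0.8 µm, miss
3%) but confuses positive tumor cells with other cells more often (18%),
mirroring the characteristic macrophage-driven failure mode of learned
PD-L1 detectors; its negative→positive rate is very small (0.3%) because
membrane staining is a strong, hard-to-hallucinate signal. Consequently
passing tests show internal consistency of the statistics under this noise
model — they do not validate any claim about real pathologists, whose
errors are spatially correlated, fatigue- and case-difficulty-dependent in
ways this independent-per-cell model deliberately omits.

Closed forms used as oracles: with jitter σ and hit radius r, the
displacement is Rayleigh(σ), so a jitter-only reader is re-matched with
probability `1 − exp(−r²/(2σ²))`; the tests check simulated matched
fractions against this within three binomial standard errors on sparse
patterns (mean spacing ≫ r, so neighbor competition is negligible).

## Semi-automatic annotation

The two-step scheme decouples localization from classification: a nucleus
detector proposes class-agnostic centers, and free-hand polygons over
homogeneous regions supply the labels by intersection. The detector here is
deliberately classical — optical-density transform, least-squares unmixing
onto the H/DAB stain vectors (plus an orthogonal residual axis; matrices
with condition number above 1e6 are rejected), scale-normalized
Laplacian-of-Gaussian filtering over σ = 1.0–3.6 µm (blobs of 3–10 µm
diameter), maximum over scales, and peak extraction with non-maximum
suppression at 4 µm and an absolute prominence threshold of 0.05 OD. It is
a stand-in that makes the pipeline runnable end to end, not a competitive
nucleus detector; like single-blob detectors generally, it reports each
lobe of a multinucleated cell separately, and that behavior is accepted.

Label transfer uses boundary-inclusive point-in-polygon tests. A point
inside several polygons takes the class of the smallest-area one (free-hand
annotators refine inside larger regions); a strict mode errors instead.
Points inside no polygon are discarded by default (configurable to keep
them as 'other'). Point annotations extend to 20×20 µm axis-aligned boxes
for box-based detectors, and box centers convert back to points exactly.

## Hit-criterion matching

All reference–prediction pairs within the radius (default 8 µm; a distance
exactly equal to the radius counts) are sorted by distance and accepted
greedily whenever neither member is already matched. This makes the pair
set one-to-one, independent of which set is called "reference", and
invariant to input order. Distance ties break deterministically by
(reference rank, prediction rank) with ranks from lexicographic (y, x)
point order. The alternative reading of the rule — each reference takes its
closest prediction, predictions reusable — is available as
`mode="reference-sided"` for sensitivity analysis. Greedy closest-first is
the semantics implemented and tested (against an exhaustive-enumeration
oracle); minimum-cost bipartite assignment is deliberately *not* used, as
the rule is closest-first rather than globally optimal.

Matched pairs tally into a 4-class confusion matrix as (reference class,
prediction class); unmatched references as (class, background); unmatched
predictions as (background, class). The background/background cell is
structurally zero. The background-disagreement fraction is the background
row+column share of all off-diagonal counts, and is reported as NaN (never
0) when there are no disagreements at all.

## F1 and pooling

Per class: TP is the diagonal count, FP the rest of the column, FN the rest
of the row; `F1 = 2·TP/(2·TP+FP+FN)`. A class absent from both sides
everywhere has undefined F1 and is excluded from the macro mean (flagged),
rather than scored 0, to avoid penalizing ROIs that lack a class. Two
pooling granularities are implemented because they genuinely differ:
`pooled` sums TP/FP/FN over all shared ROIs before the ratio, `per_case`
(the default) pools within each case and averages case-level macro F1
across cases. Group summaries report mean ± 1.96·SD, gated by a
Shapiro–Wilk test at the 0.05 level (groups too small to test, n < 3, or
with zero variance are treated as normal); non-normal groups are flagged
and summarized by median and range.

## TPS and agreement statistics

TPS = 100·n_pos/(n_pos+n_neg) over tumor cells only; zero tumor cells raise
an explicit "TPS undefined" error — a slide-level QC condition that must
never silently read as 0%. Discretization: `<1%` is [0,1), `1–49%` is
[1,50), `≥50%` is [50,100]; both interior boundaries include their lower
bound, following clinical convention.

*Linear weighted kappa* over the three ordered categories uses agreement
weights `w_ij = 1 − |i−j|/(k−1)` and chance agreement from the product of
marginals; with two categories it reduces exactly to unweighted kappa.
Degenerate marginals follow two conventions, each matching the operation's
meaning: for category ratings, a rater with zero marginal variance gives
kappa 1 under perfect agreement and NaN otherwise; for single-cutoff kappa,
having every case on the same side of the cutoff for both raters yields NaN
outright, because the statistic then carries no information about behavior
at that cutoff.

*ICC(2,1)* comes from the two-way random-effects ANOVA with absolute
agreement: `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`. The
confidence interval is the exact F-based interval for this estimator with a
Satterthwaite-approximated denominator df — not a 1.96·SD rule, which is
appropriate for means of kappas/F1 but not for a variance-ratio estimator.
Rows with missing values are dropped and counted. Numerical degeneracies
are handled explicitly: zero between-case variance makes the coefficient
undefined (NaN); exact inter-rater agreement leaves only floating-point
cancellation noise in the residual sums of squares and is snapped to
ICC = 1 (threshold 1e-10 of total SS).

*Bland–Altman* reports the mean of a−b and mean ± 1.96·SD(ddof=1) limits of
agreement; the pipeline's comparison is detector minus median reader, so a
negative mean difference means the detector under-scores.

*Majority vote*: per case, ratings binarize at the cutoff and the human
readers vote; the target source is always excluded from its own reference
majority, so a reader is never compared against a vote containing their own
rating. Ties (possible with even voter counts) are dropped and counted by
default; an alternative rule breaks them toward the positive category.

## Pipeline and study sizes

`run_pipeline` derives every random stream from one integer seed through
`numpy.random.SeedSequence` spawning, making runs byte-identical under a
fixed (config, seed). The default study sizes — 8 cases × 4 ROIs with 3
readers + detector at cell level, 100 cases × 6 readers + detector at slide
level, one rendered-ROI annotation round trip — keep a full run around two
seconds while leaving enough events (~4,300 cells, ~600 TPS ratings) for
stable statistics; all sizes are configurable. The slide-level true-TPS
distribution is a three-band mixture (≈30% below 1%, 35% in 1–49%, 35% at
or above 50%) so that every clinical category and both cutoffs are
exercised; it is a diverse test panel, not an estimate of any cohort. The
detector's slide-level TPS is computed from simulated per-cell counts (500
tumor cells per case pushed through the detector's confusion rows), keeping
that arm count-based like a real detector, while readers contribute visual
estimates (Gaussian SD 8 TPS points, clipped to [0,100], rounded to 5%
increments, half away from zero).

A `noiseless=True` configuration (perfect readers, perfect detector,
unrounded estimates) exists purely as a degeneracy check: it must yield
F1 = 1, all kappas 1, ICC 1 and a Bland–Altman mean difference of 0.

## Known limitations

- The reader/detector noise model is independent per cell; real annotator
  errors cluster spatially and correlate across readers on hard cases, so
  synthetic interobserver statistics should not be read as predictions of
  clinical ones.
- The renderer draws circular nuclei on a clean background; the stand-in
  detector's near-perfect recovery on such images says nothing about its
  performance on real tissue, and it is not intended for it.
- Matching symmetry relies on distance ties being broken deterministically;
  for inputs with exactly duplicated coordinates the tie order, not the
  geometry, decides which pairs form.
- TPS panels treat each reader's noise as independent of the case's true
  difficulty; borderline-case ambiguity (the main clinical pain point) is
  represented only through rounding and the cutoff geometry.
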