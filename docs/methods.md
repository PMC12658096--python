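# Methods

## Data model

A gallery holds per-image embedding ensembles: m vectors of dimension d per
image (defaults m=12, d=512), one syndrome label per image, vectors
renormalized to unit Euclidean norm at load. Renormalization is an explicit
design choice — it is not assumed that upstream encoders emit unit vectors —
and makes cosine distance a pure dot product. Rows already at unit norm
(within 1e-12) are left bit-identical, so write → load → write round-trips
are byte-stable under the shortest round-trip float format.

## Distance metric

Image-to-image distance is the mean of the m *matched-member* cosine
distances: member k of image A against member k of image B, giving exactly
m distances per pair. The alternative (all m² cross-member pairs) was
rejected because the ensemble channels are semantically aligned — member k
is the same model/augmentation for every image — and matched pairing is
what makes the per-member systematic offsets cancel. Internally the
equivalent form `1 − a·b = ‖a − b‖²/2` (exact for unit vectors) is used so
that coincident vectors give a distance of exactly 0; full matrices are
computed member-wise with `scipy.spatial.distance.cdist` and symmetrized
exactly. The cohort statistic is the arithmetic mean of the n(n−1)/2
pairwise distances among cohort members; member indices are sorted before
summation so the value is bitwise invariant to member order.

## Synthetic galleries

The generator emulates the structure the analysis relies on, not the
geometry of any real embedding model:

* syndrome centers `c_s` drawn isotropically on the d-sphere;
* image latents `x_i = normalize(c_s + σ_within g_i)`, `g_i ~ N(0, I_d)`;
* per-member offsets `o_k = σ_member h_k`, drawn once per gallery and shared
  by all images (systematic ensemble bias);
* stored vectors `v_ik = normalize(x_i + o_k + σ_tta e_ik)`.

Gaussian-perturb-then-normalize stands in for a von Mises–Fisher sampler:
the clustering behaviour is equivalent for this purpose and the zero-noise
limits are exact (σ = 0 reproduces the center bitwise). Because the
perturbation acts per coordinate, angular spread scales with √d: the
expected within-cluster distance is ≈ 1 − 1/(1 + σ²d), so at d=512 the
default σ_within = 0.12 gives weakly clustered syndromes (within-syndrome
distances ≈ 0.85–0.9 against ≈ 1.0 for random pairs), the regime reported
for real facial-embedding galleries; σ_member = 0.02 and σ_tta = 0.01 keep
ensemble bias and augmentation noise an order of magnitude smaller. The
stock control configuration is 328 syndromes totalling 1,555 images (243 of
size 5, 85 of size 4), matching the reference gallery's census. Four named
RNG substreams (centers, latents, offsets, TTA) keep draws independent, so
changing one noise dimension leaves the others' realizations fixed.
Target cohorts are drawn around a fresh center with their own dispersion
but reuse the gallery's member offsets.

What the generator does **not** emulate: real class imbalance beyond the
size profile, anisotropic or manifold-structured embedding geometry,
image-quality artifacts, multiple images per subject, or inter-syndrome
similarity structure. Passing tests therefore demonstrate the statistical
machinery (calibration, recovery, exactness of the combinatorics), not
performance on clinical photographs.

## Threshold selection

Same-syndrome and random control cohorts (100 per (syndrome, size) cell,
deduplicated by sorted member tuple; full enumeration whenever a cell
admits ≤ 100 distinct combinations) are pooled across all syndromes and
sizes into a single two-class sample — one threshold, not per-size
thresholds. Random cohorts are unrestricted draws from the whole gallery;
accidental same-syndrome co-membership is not excluded. Positives are
same-syndrome cohorts; classification is `value < c` (strict), since lower
distance means greater resemblance.

The ROC sweeps thresholds at midpoints between adjacent distinct observed
values plus two sentinels (the minimum, which classifies nothing positive,
and the next float above the maximum, which classifies everything). AUC is
computed as the Mann–Whitney statistic (ties ½). The Youden threshold
maximizes J = sensitivity + specificity − 1; ties in J resolve to the
smallest threshold (the stricter classifier), and J is compared via exact
integer counts (tp·n_neg + tn·n_pos) so floating-point rounding cannot
reorder mathematically tied candidates. Stratified k-fold cross-validation
(default 5) fits a Youden threshold per training fold and pools the
held-out classifications into honest sensitivity/specificity; the headline
threshold itself is the Youden solution on the full pooled sample (the
aggregation across folds is not standardized; full-sample Youden is the
committed rule, with per-fold thresholds retained for inspection). Both the
full-sample and the pooled held-out rates are reported.

## Cohort test

Sub-cohorts of the target C are drawn by picking a size n uniformly from
{2..|C|} and then a uniform subset (no size weighting is imposed beyond
uniform-over-size, the simplest declared rule); duplicates are removed; the
procedure stops at 10,000 distinct sub-cohorts or exhausts all
2^|C| − |C| − 1 of them, whichever is first (≤ that many exist ⇒ full
enumeration). The below-threshold fraction uses strict inequality. Because
"subject combinations" can be read as either the resampled sub-cohorts or
just the pairs, an auxiliary pairs-only fraction over the C(|C|, 2)
pairwise distances is always reported alongside.

The empirical p-value takes T = median of the sub-cohort values and
computes the add-one lower-tail probability `p = (1 + #{null ≤ T}) /
(1 + #null)`. The null sample matters: raw random-cohort mean distances
pooled over sizes are *not* exchangeable with T — a median over thousands
of correlated sub-cohort means concentrates far more tightly than any
single random cohort's value, which makes that comparison grossly
conservative (measured type-I error 0.000 at α = 0.05). The package
therefore builds the null with `matched_median_null`: random cohorts of the
same size are run through the identical sub-cohort resampling and their
medians form the null. Under the null hypothesis the target statistic and
the null statistics are exchangeable, so p is uniform by construction
(measured on the calibration fixture: KS p = 0.36 against uniform, type-I
error 0.058 over 500 replicates). `empirical_p_value` itself accepts any
null sample, so the raw pooled comparison remains available to callers.

## Rank analysis

For probe i the competitor set is the background gallery plus i's
cohort-mates, each image exactly once and never the probe itself.
rank(i→j) = 1 + #{competitors strictly closer} + #{non-target ties}; ties
take the worst rank — conservative in that they never inflate resemblance —
and the matrix is directed. "Rank below 50" and "below 10" are strict.
A subject is matched when the better of the two directed ranks against any
cohort-mate is below the cutoff. If a gallery carried several images per
subject, subject-level distance would be the minimum over that subject's
images; the synthetic default is one image per subject. For display the
matrix is symmetrized by the elementwise minimum and clustered
agglomeratively; no linkage is canonical for this display, so the method is
a parameter (average by default, single/complete available). Subjects are
pre-sorted by id and each internal node places the subtree with the smaller
minimal id first, making leaf order deterministic under ties; the
dendrogram is also emitted as Newick with branch lengths from merge
heights.

## Numerical and degenerate-input rules

* Distances are double precision, dense (galleries here are ≲ 10⁴ images);
  entries are clipped to [0, 2] against last-bit excursions and the
  diagonal is exactly 0.
* Cohorts need n ≥ 2; statistics on smaller inputs raise structured errors
  naming the offending field, as do malformed gallery rows (row number and
  field), duplicate ids, zero-norm vectors and unknown config keys.
* Rejection sampling for distinct cohorts/sub-cohorts caps attempts at
  100 × the requested count before returning what was found; the cap is
  effectively unreachable because full enumeration takes over whenever the
  distinct pool is no larger than the request.
* All randomness flows through `numpy.random.Generator`; every CLI stage
  takes a seed and writes deterministic text (sorted-key JSON, shortest
  round-trip floats), so re-runs are byte-identical.

## Fixture configurations used by the test suite

* *Calibration*: one cluster of 300 images (d=32, m=4, σ_within=0.3,
  σ_member=σ_tta=0.05), cohorts of 10, 200 sub-cohort draws, a 999-cohort
  matched-median null, 500 replicates. Dimensions are kept small because
  exchangeability — the property under test — does not depend on d or m.
* *Power*: same gallery; target cohorts at dispersion 0.06 (0.2 × the
  background's σ_within); detection at α = 0.05 in ≥ 95% of 200 replicates.
* *Recovery*: 30 syndromes × 20 images at the conventional shape (d=512,
  m=12), σ_within ∈ {0.35, 0.25, 0.15} — spanning weak to clear clustering
  per the 1 − 1/(1 + σ²d) scale — with cross-validated AUC required to
  increase monotonically, exceed 0.95 at the tightest level, and collapse
  to chance under label permutation.
* *Rank recovery*: a 15-subject cohort at dispersion 0.05 inside a
  1,000-image unclustered background, plus a dispersed (dispersion 50)
  cohort whose ranks must be uniform on [1, 1014] in mean.

`scripts/acceptance.py` runs the full pipeline at the reference structural
scale (328 syndromes / 1,555 control images at 12 × 512; 15-subject cohort;
10,000 sub-cohort draws) with one exception: the ranking background is
2,000 unclustered images rather than 7,459, a size chosen to keep the dense
distance matrix comfortably in memory while leaving the rank scale
qualitatively unchanged.

## Known limitations

* The matched-member pairing of ensemble channels is an interpretation
  committed here; an implementation averaging all cross-member pairs would
  differ on galleries with large member offsets.
* The empirical p-value is an addition of this package (the below-threshold
  fraction alone is not a test); it is labelled as such in outputs.
* Image-level ranking only; collapsing multiple images per patient or per
  disorder would require subject metadata the synthetic galleries do not
  model.
* No confidence intervals on AUC; no per-syndrome thresholds.
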