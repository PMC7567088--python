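# Methods

## Problem and data model

The unit of analysis is the *exam pair*: two radiographs of the same
patient taken within a short interval during which the disease is assumed
unchanged, plus a pool of unpaired normal exams. Reference lesions are
radiologist ROIs reduced to axis-aligned bounding boxes (the detector
emits boxes, and the match criterion is box IOU, so polygon detail would
not enter the statistics). All coordinates are 0-based pixels, top-left
origin, `(x_min, y_min, width, height)` — the COCO convention, so one
matcher serves the CSV and COCO-JSON dialects alike. Degenerate
(zero-area, non-finite) boxes are rejected when records are constructed
rather than being treated as IOU 0.

## Matching

A detection is correct when IOU with a reference lesion is **strictly
greater than** the threshold (default 0.5; both the value and strictness
are configurable). Detections below the confidence cutoff are discarded
before matching and count as nothing. Survivors are assigned greedily in
descending confidence (ties: descending best-IOU, then input order), each
taking the unmatched same-class lesion of greatest IOU, one-to-one;
losers are false positives and unmatched lesions are misses. Greedy
assignment is the de-facto standard in detection evaluation. It is
count-maximal whenever reference lesions are mutually disjoint (a box
cannot exceed IOU 0.5 with two disjoint lesions); with heavily
overlapping lesions a count-optimal assignment can differ, a regime the
test suite therefore does not claim. Multiple detections over one lesion
are not deduplicated: the extras are false positives.

An exam is "detected" iff it has at least one true-positive match.
False positives never flip an exam to detected — a pair whose boxes are
all false alarms still lands in the *d* cell. For multi-lesion exams,
≥1 matched lesion suffices; requiring all lesions would conflate lesion
counting with exam-level reproducibility.

## FROC, operating points, JAFROC

The FROC curve evaluates matching on every scored exam (lesion-bearing
and normal both enter the FP denominator) over a fixed grid of 101
cutoffs in [0, 1]; a fixed grid makes curves reproducible and
rating-independent. Sensitivity and average FP per image are
non-increasing in the cutoff by construction, which the tests check over
the whole grid.

An operating point for an average-FP budget is the **smallest** grid
cutoff whose average FP is within the budget — maximum sensitivity
subject to the FP constraint, landing on the conservative (higher-cutoff)
side between grid points. If even the top cutoff exceeds the budget, the
top cutoff is returned with an explicit `unattainable` flag rather than
silently.

The JAFROC figure of merit uses per-lesion ratings (confidence of the
matched detection at cutoff 0, −∞ if unmatched) against per-normal-exam
ratings (highest false-positive confidence, −∞ if none): the mean of the
Wilcoxon kernel ψ(x, y) = 1 if y > x, ½ if y = x, 0 otherwise over all
(lesion, normal exam) pairs. "Normal" means zero reference lesions *of
the class under evaluation* — the standard JAFROC noise set when a test
set mixes normals and other-disease exams. The ½ tie kernel is the
conventional choice; −∞ ties (unmatched lesion vs. silent normal exam)
get ½ like any other tie. The 95% CI uses leave-one-**exam**-out
jackknife pseudovalues `n·θ − (n−1)·θ₍ᵢ₎` with a normal approximation,
clipped to [0, 1] and widened if necessary to contain the point estimate;
the exam is the resampling unit because lesions within an exam are
correlated. With one lesion per case the pseudovalue mean equals the
plug-in FOM exactly; with multi-lesion cases it differs at O(1/n).

## Agreement statistics

Cells: a (detected both), b (initial only), c (follow-up only), d
(neither); d is excluded from both statistics because the question is
how consistently the detector repeats the detections it makes. PPA =
100·2a/(2a+b+c) and Chamberlain's CPPA = 100·a/(a+b+c) satisfy
CPPA ≤ PPA with equality iff b+c = 0 or a = 0, and the identity
PPA = 100·2p/(1+p), p = CPPA/100, exactly on shared counts. When
a = b = c = 0 both statistics return a typed `Undefined` marker, never a
silent 0 or 100. Swapping the initial/follow-up roles swaps b and c and
leaves both statistics unchanged.

Per-class results are aggregated across the operating points (the six
average-FP budgets 0.1–0.6) as sample mean ± sample SD (n−1 denominator),
excluding undefined points with a count of exclusions. Reporting the
spread across operating points is an interpretive choice: it
characterises how sensitive the agreement is to the cutoff. Percentages
are displayed to 2 decimals; full precision is retained internally and in
`report.json`.

## Exact Spearman

With five classes the asymptotic p-value for Spearman's ρ is meaningless,
so for n ≤ 10 tie-free inputs the two-sided p is the exact fraction of
all n! rank permutations with |ρ*| ≥ |ρ_observed|, the observed
permutation included (hence p ≥ 2/n! at ρ = ±1). Ties or n > 10 fall
back to the t-approximation with the method recorded in the result.
Enumeration is vectorised in chunks; n = 10 (3.6M permutations) runs in
seconds, and the pipeline's n is 5.

## Synthetic cohort model

The generator emulates the paired-study structure so the full pipeline
runs and is validated without any image data. Defaults: per-class pair
counts {N: 121, C: 28, IO: 12, PLE: 67, PN: 20}; lesion count per
positive exam 1 + Poisson(μ) with per-class μ from ROI-per-image ratios
of roughly 1.06–1.92; per-class sensitivities {0.78, 0.71, 0.93, 0.97,
0.88}; 1000×1000-pixel images with lesion boxes uniform in [50, 250] px;
follow-up lesions are the initial boxes displaced by ±15 px jitter,
clipped to the image; 200 normal exams as the JAFROC noise pool (a
desk-scale stand-in for a test-set normal pool; the statistics depend on
it only through noise-set size).

Pair dependence is a Gaussian copula: each lesion draws a latent
detectability u ~ N(0,1) shared across the pair, and exam e scores
z_e = √ρ·u + √(1−ρ)·ε_e with ε_e independent N(0,1). The lesion is
detected on exam e iff z_e < Φ⁻¹(s), so the marginal per-exam detection
probability is exactly s for every ρ, while ρ interpolates between
independent test–retest detections (ρ = 0, where PPA → 100·s and
CPPA → 100·s/(2−s)) and identical ones (ρ = 1, where b = c = 0
exactly). The default ρ = 0.7 reflects that paired exams of the same
patient days apart are strongly but not perfectly correlated inputs to a
deterministic network (residual variation: positioning, inspiration,
image quality).

Detected lesions emit a box translated to a target IOU drawn uniformly
from (0.55, 0.95) — always above the 0.5 matching threshold but
stressing it — with confidence ~ Beta(4, 1) (mean 0.8). False alarms
arrive as Poisson(λ) candidates per exam, λ = 3 by default, placed with
IOU ≤ 0.1 to every lesion on the exam, labels uniform over the classes,
confidences ~ Beta(2, 3) (mean 0.4). With five classes this puts the raw
per-class FP rate near 0.6 per image at cutoff 0, so the 0.1–0.6
average-FP budgets map to distinct cutoffs, and the screened headline
operating point sits well under 0.6 FP/image. Because true positives
always exceed the match threshold and false alarms never reach it, the
generator's recorded per-pair outcomes coincide exactly with what the
pipeline recomputes at cutoff 0 — the self-consistency check the tests
enforce.

What the generator does **not** emulate: pixel appearance, registration
error beyond box jitter, disease progression, class confusions by the
detector, and any dependence of confidence on lesion size or class.
Passing tests therefore validate the *statistical machinery* — matching,
FROC/JAFROC, agreement arithmetic, correlation — not any real detector's
performance.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; streams derive from
`numpy.random.SeedSequence`, and repeated runs with the same
configuration write byte-identical CSVs and reports (sorted JSON keys,
fixed float repr). Monte-Carlo validation sizes were chosen so that
sampling error is a small fraction of the tested tolerance: 2000 pairs
for the independence-limit closed forms (binomial SE ≈ 0.9 points against
a 2-point band), 500 lesions for the recall check (SE ≈ 1.3 points
against 3), 200–600 pairs for the copula monotonicity and discordance
checks.

## Known limitations

- Greedy matching is not globally optimal when reference lesions overlap
  each other above the IOU threshold (rare in practice; documented above).
- The jackknife CI uses a normal approximation; for very small noise sets
  (a handful of normal exams) it is only indicative.
- The operating-point spread (± SD across FP budgets) is one reasonable
  summary of cutoff sensitivity, not a sampling-error estimate.
- Exam pairs are treated as registered at the exam level only; no attempt
  is made to co-locate boxes across the two exams of a pair, so agreement
  is about *detection*, not localisation consistency across time.
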