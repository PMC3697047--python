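# Methods

## The feature

A candidate feature couples a degenerate tetranucleotide (four IUPAC
codes over the RNA alphabet; 15⁴ = 50 625 patterns) with a
position-weight profile F over the L−3 window start positions of an
L-nt fragment. The feature value is the sum of F(i) over all start
positions whose 4-base window matches the pattern. Windows are counted
at every position with no overlap exclusion — the sum is literally over
all starts, so overlapping matches each contribute — and values lie in
[0, L−3]. Sequences are handled internally as RNA (T silently mapped to
U on input); user-facing positions are 1-based.

Input sequences follow the capitals convention of the training tables:
lowercase letters mark trimmed flanking bases and the maximal uppercase
run is the analysis fragment. All-uppercase input falls back to the
leading window of the declared length, with a warning.

## The profile library

The method fixes only the counts (180 S-shaped + 180 U-shaped curves),
the [0, 1] weight range, and the "higher weight, larger contribution"
reading. The functional forms and grids here are this package's own
parameterization, chosen for smoothness and reproducibility:

* S family: logistic ramp `floor + (1−floor)·σ(±(t−c)/w)` over relative
  position t ∈ [0, 1];
* U family: Gaussian bump `floor + (1−floor)·exp(−((t−c)/w)²)` (peak)
  and its complement (valley);
* grid: center c ∈ {0.1, …, 0.9} (9), width w ∈ {0.02, 0.05, 0.1, 0.2,
  0.4} (5), two orientations, floor ∈ {0, 0.25} (2) — 180 per family.

Every profile is max-normalized (max F = 1). This removes the
scale/slope ambiguity the curve shapes leave open; any linear rescaling
of a profile is absorbed by the downstream regression anyway. Profiles
are deterministic functions of their parameters, stored at 12
significant digits, so the library is identical across runs and
platforms. A FLAT profile (F ≡ 1, plain motif count) is available for
diagnostics outside the 360.

Because the exact curves behind the published feature columns
([WRHW]_F1, [DRYD]_F2, [RHHK]_F3, [YRHB]_F4) are not recoverable, the
packaged tables carry those columns as data; no code path claims to
regenerate them.

## The 11 criteria and their α conventions

Five correlation tests (small α favourable): Pearson (two-sided t),
Spearman (average ranks), Kendall tau-b (normal approximation), and
chi-square (df = 1, no continuity correction) plus two-sided Fisher
exact on the shared median-split 2×2 table. Ties at the median go to
the "low" group — deterministic, and the exact counterpart (Fisher)
makes a corrected chi-square redundant.

Six applicability diagnostics (small α unfavourable): uniformity of
each variable (Kolmogorov–Smirnov against Uniform(min, max)), and for
each directed least-squares regression the normality of residuals (KS
against a normal with the residuals' moments) and their independence
(Wald–Wolfowitz runs test on residual signs ordered by the regressor).
The method names these criteria without naming tests; KS-type and runs
tests were chosen as closed-form, cross-language-reproducible choices.

Degenerate situations return α = 1 (no evidence): constant inputs,
empty 2×2 margins, zero-variance residuals (a perfect fit passes), and
subsets smaller than a test's minimum n. Alphas are floored at 1e−10 so
the log-scale utility stays finite.

## Utility and Ξ

υ(α) is piecewise log-linear with υ(0.05) = 0, saturating at +1 for
α ≤ 1e−6 and at −1 for α = 1. Only the zero point, sign convention and
monotonicity are method-fixed; the saturation points are this package's
reconstruction of the published curve shape.

For the six applicability diagnostics the utility is the negation of
υ, **capped at zero**: a significant departure from an assumption
reduces Ξ (down to −1 per cell), but merely passing an assumption
check earns nothing. The cap is a deliberate design choice: with an
uncapped negation, six passing diagnostics would contribute ≈ +0.55 to
every feature's Ξ, the best-of-space Ξ on sequence-independent
activities is positive essentially always, and Ξ > 0 could not serve
as the usefulness threshold. With the cap, the maximum attainable Ξ is
5/11 ≈ 0.45 (all five correlation tests saturated, no violations),
matching the regime in which reported best scores of ≈ 0.3–0.5 with
all runner-ups below zero make sense, and the engine's null behaviour
(below) is correct.

Ξ is the exact arithmetic mean of the 7 × 11 utilities. A constant
feature vector scores Ξ = −1 by convention. Subset half-size is
⌈n/2⌉, ties in the sorted orders broken by record index.

## Search and verification

The search is two-staged for tractability: stage 1 screens every
variant by full-dataset |Pearson r| (vectorized over the feature
matrix); stage 2 computes the full 77-test Ξ for the top K screened
variants (default K = 1000; with K ≥ the space size the search is
exhaustive). Ties on Ξ break toward the more specific pattern (fewest
concrete expansions), then lexicographic pattern, then profile index.
The winner must have Ξ > 0; otherwise the result is an explicit "no
useful correlation".

Permutation verification reshuffles activities (seeded) and re-runs the
identical search each cycle, reusing the precomputed feature matrix and
its cached column moments. A recurrence is a cycle whose winner equals
the original or whose feature vector correlates with it at |r| ≥ 0.8 on
the original data (the threshold is configurable; the original tool's
value is unstated). The reported α is the lower binomial tail
P(X ≤ recurrences | cycles, p = 0.05): zero recurrences in 100 cycles
gives 0.95¹⁰⁰ ≈ 0.0059, i.e. the absence of recurrence is significant
evidence that the finding is tied to the real sequence–activity
pairing.

## Published models and the inverse problem

The constant models are shipped digit-for-digit as published; their
original derivation is not disclosed (ordinary least squares on the
printed, 2-decimal feature columns demonstrably does not reproduce
them), so no fitting path claims to re-derive the constants. Internal
identities are enforced instead: the Ago-preference model equals the
coefficient-wise difference of the two Ago models, and the
limiting-stage estimator equals exp(min(ago2, ago3) − 4.97)
identically.

The inverse-problem reduction composes three maps: the Ago affinity
model, the availability heuristic κ·X₂ − X₃ (κ = 1/3 under normal
growth, 1/2 under transcription arrest), and a range calibration
γ·v + δ. "Correspondence between the ranges … without any
optimization" is implemented as min/max endpoint matching — the only
parameter-free reading — with mean/sd matching available as an
alternative. The γ values 1.9 and 2.82 appearing in tests are
back-derived consistency constants (they make the composed slopes match
the two published condition models within 0.5%); they are test
artifacts, not shipped science. Condition models for new data always
come from a user-supplied calibration.

The four-protein occupancy picture behind the reduction (abundance as
β₁…β₄-weighted Ago occupancies plus error) is documentation only: the
β are not identifiable from two affinities, which is precisely why the
problem is ill-posed and only the Ago2-term reduction is implemented.

## Cluster control

The control analysis is single-linkage agglomerative clustering on
Euclidean distances, cut at the final merge to give exactly two
clusters (the predefined linkage/metric combination; the cut rule is
this package's choice, as the original partition rule is unstated).
Reports give per-cluster sizes and rounded percentages, per-coordinate
mean ± sd (n−1 denominator), within-cluster Pearson r (undefined below
n = 3), and the coefficient of variation C_V = sd/mean × 100%.

## Synthetic data

The generator emulates the study design: n i.i.d. random fragments of
fixed length L over a base composition (uniform by default; an
A/U-rich preset ≈ 62% A+U mirrors plant miRNA composition), with
activity = intercept + slope·feature + Gaussian noise. Noise can be
given directly (sd) or as a target signal-to-noise ratio. Ground truth
(planted variant, true feature values, realized noise) is returned
beside the dataset and can be written to a sidecar file so tests never
re-derive it.

What it does *not* emulate: phylogenetic correlation between sequences,
biogenesis- or structure-driven composition biases, heteroscedastic or
non-Gaussian measurement error, and multiple overlapping signals.
Passing the recovery and null tests therefore shows the engine works
when its own linear-additive premise holds, not that the premise holds
for real miRNA data.

## Default problem sizes

The tests and examples restrict the variant space to a seeded random
sample of patterns (a few hundred, always forcing the planted one in)
times a handful of profiles, score the top 10–30 screened candidates,
and use 60 permutation cycles — the smallest sizes at which the
binomial recurrence criterion can reach α < 0.05 (0.95⁵⁹ < 0.05) and
the recovery/null rates are stable across seeds. Recovery tests use
n = 24 fragments of 22 nt at signal/noise 5; null tests use slope 0
with unit noise. The full 18 225 000-variant enumeration is exercised
for its size only; screening it end to end is a CLI-scale operation
(minutes, not test-suite material).

## Known limitations

* The published Ξ values of the original analyses are not reproducible:
  they depend on the original utility curve and profile set, neither of
  which is published. Acceptance rests on the printed correlations,
  analytic counts, identities, and behavioural guarantees instead.
* The υ curve's saturation points and the profile parameterization are
  reconstructions; Ξ magnitudes are therefore comparable within this
  package, not across tools.
* Fragment lengths other than the window the profiles were built for
  require regenerating the profile library (it is parameterized by L).
* The permutation test controls recurrence of the specific winner, not
  family-wise error over the whole variant space.
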