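# Methods

## The diagnostic situation

A judgment episode presents one student response to one of three
decimal-comparison tasks. The hypothesis space is restricted to three
mutually exclusive misconceptions — whole-number (WN), ignore-decimal-point
(ID), shorter-is-larger (SL) — deliberately excluding students who compare
decimals correctly. Each task type has a characteristic most-likely response
under each misconception:

| task            | WN    | ID    | SL    |
|-----------------|-------|-------|-------|
| 4.8 vs 4.63     | wrong | wrong | right |
| 3.7 vs 3.02     | right | wrong | right |
| 3.49 vs 3.4     | right | right | wrong |

A single sensitivity s applies to every task: the likelihood of the
pattern-consistent response is s, of the other response 1 − s. The default
s = 0.8 keeps the evidence informative but ambiguous; the package requires
0.5 < s ≤ 1 (at s = 0.5 a task carries no information). Base rates default
to (0.60, 0.30, 0.10) for (WN, ID, SL).

The default six-case battery pairs each task type with one correct and one
wrong response so that three cases have a high likelihood under exactly one
misconception and three under exactly two. Every case represents a
*different* student: priors reset to the base rates each time, and no
posterior is carried across cases (chained updating is deliberately out of
scope).

## Strategy models

For likelihood triple L and priors p:

- **BUS**: posterior ∝ p · L (componentwise), normalized.
- **CES**: posterior ∝ L, normalized — equivalent to BUS under uniform
  priors, which the tests exploit as an exact identity.
- **SES**: with a unique maximal likelihood m, the winner receives m and
  the remaining 1 − m is split equally over the other two hypotheses.

SES is underdetermined when two likelihoods tie at the maximum (two of the
default battery's cases are of this kind). The default `spread` rule
generalizes the unique-max behaviour: the non-maximal hypothesis keeps
1 − m and the tied maxima split the remainder equally, so two maxima at 0.8
give (0.4, 0.4, 0.2). An alternative `max_normalize` rule (renormalize the
indicator of the maxima, giving (0.5, 0.5, 0)) is selectable so the
sensitivity of downstream classification to this modelling choice can be
measured. This tie rule is a reasoned reconstruction, not an empirically
fixed convention.

Under the default design the three predicted positions are pairwise
separated by at least 0.109 in Euclidean probability-space distance on
every battery case — the identifiability precondition the classifier relies
on. The binding pair is CES vs SES, whose summed squared separation over
the whole battery is only 0.1156; this single number drives most of the
certainty behaviour discussed below.

## Distances and the drawing plane

Judgments live on the 2-simplex; the drawing plane (unit-side equilateral
triangle, WN bottom-left, ID bottom-right, SL top) is presentation only.
All distances are computed between 3-component probability vectors. Plane
distances would differ by the constant factor 1/√2 and silently rescale the
kernel bandwidth.

## The classifier

Under strategy hypothesis Ĥ_S a judgment Ê for a case with prediction Ê_S
has density (1/N)·exp(−|Ê − Ê_S|²/d). The bandwidth d is a *squared*-
distance scale: the density falls to 1/e of its maximum when
|Ê − Ê_S|² = d. Describing d as a "radius" would instead imply
exp(−r²/d²); that reading is available behind the `radius_mode` flag for
sensitivity analysis only, and the squared-scale form is the default. The
default d = 0.1 trades discrimination against the imprecision of
qualitative pointing judgments; a robustness band 0.05 ≤ d ≤ 0.20 is
flagged (not enforced) in reports.

N depends only on the kernel shape, is shared by all strategies at fixed d,
and cancels from every posterior and Bayes-factor ratio; it is therefore
never computed in the classifier. A test verifies this cancellation against
a brute-force implementation that multiplies six explicit densities
*including* an explicitly computed lattice normalization.

Scores are accumulated as sums of logs; posteriors come from a log-space
softmax; Bayes factors beyond overflow are reported alongside as log₁₀
values. The per-subject certainty measures are BF₁:₂ (dominant over
runner-up; with equal strategy priors this equals the posterior odds, so
p = BF/(1 + BF) in any two-hypothesis restriction) and the maximal
posterior. Evidence categories over BF₁:₂: (1,3] weak, (3,10] moderate,
(10,30] strong, (30,100] very strong, >100 extreme; the >100 and >1000
bins share the "extreme" label but stay separate columns in the certainty
table. Exact ties in the top scores yield the label `indeterminate` with
BF₁:₂ = 1 rather than a silent tie-break — real data makes ties
measure-zero, synthetic edge cases should surface them.

Naive independence of the six judgments given the strategy is an assumption
of the model, not an empirically tested property.

A triangular-lattice mode (judgments and predictions snapped to the lattice
of a configurable subdivision level before computing distances) exists as a
fidelity option; the continuum is the default. No standard triangular
subdivision has exactly 1,250 points ((m+1)(m+2)/2 never equals 1250), so
where a lattice is requested the default is m = 48 (1,225 points).

## Condition comparison

The 2×3 strategy-by-condition count table is tested with the Gunel–Dickey
Bayes factor under joint-multinomial sampling. Dependence model: one
multinomial over all 6 cells with a symmetric Dirichlet(a) prior.
Independence model: cell probabilities factor into row × column marginal
probabilities, each margin with its own symmetric Dirichlet(a) prior. Both
marginal likelihoods are Dirichlet-multinomial, so

BF₁₀ = [B(y + a)/B(a)] / ( [B(y_r + a)/B(a_r)] · [B(y_c + a)/B(a_c)] ),

with B the multivariate beta, y the cells, y_r/y_c the margins. All gamma
arithmetic is in log space; results are reported to 3 decimals. The default
concentration a = 1 reproduces the published three-decimal values for both
reference tables, and a sensitivity sweep over a ∈ {0.5, 1, 2} is included
in every comparison result. Evidence strength uses the Lee–Wagenmakers
scale (anecdotal/moderate/strong/very strong/extreme), with reciprocal bins
read as evidence for independence — note this scale's first bin is
"anecdotal" where the per-subject table scale says "weak". Only the
joint-multinomial scheme is implemented; Poisson, independent-multinomial
and hypergeometric variants are out of scope.

## Synthetic cohorts

Each simulated subject is committed to one strategy; every judgment is the
predicted position plus isotropic Gaussian noise truncated to the simplex,
i.e. a draw from the classifier's own assumed density
∝ exp(−|x − Ê_S|²/d_gen). Sampling is by rejection: propose a 2-D Gaussian
with per-component variance d_gen/2 in an orthonormal coordinate frame of
the simplex plane (isometric to the 3-component metric, so the exponent is
exact) and reject proposals leaving the simplex. Rejection — not projection
or clipping — preserves the truncated-kernel shape; a guard aborts if the
acceptance rate falls below 10⁻⁴ (pathological d_gen). Matching the
generator's noise to the classifier's kernel means parameter-recovery
experiments test the pipeline, not model mismatch; a logistic-normal mode
with matched scale exists for mismatch robustness experiments only. The
default d_gen = 0.1 is a convention anchored to the classifier's d — the
true noise magnitude of human subjects is not identifiable from published
summaries. Mixture or strategy-switching subjects are excluded by default.

What the generator does *not* emulate: real subjects' judgment biases
(e.g. attraction to vertices, edges or round positions), any case-order or
learning effects, and intra-individual strategy variation. Passing recovery
tests therefore demonstrate internal consistency of the
generator–classifier pairing, not validity for human data.

## Certainty of noiseless classification

A consequence of the CES–SES proximity deserves explicit statement: even a
*noiseless* CES subject (judgments exactly on the CES predictions) attains
only BF₁:₂ = exp(0.1156/d) versus SES — about 3.2 at d = 0.1 — and a
maximal posterior of about 0.76; a noiseless BUS subject attains
exp(0.8111/d) ≈ 3.3·10³ at d = 0.1 but only ≈ 58 at d = 0.2. Extreme
(>1000) certainty for every strategy-consistent subject is therefore not a
prediction of this model at any bandwidth in the robustness band; one
acceptance test records that expectation and is expected to fail. Labels,
by contrast, are exactly recovered for noiseless cohorts at every
d ∈ {0.05, 0.1, 0.2}, which is the substantive bandwidth-robustness
property.

## Recovery experiment scales

The regression-tested recovery run uses 30 subjects per strategy and 20–100
replicates (seeded, hence exactly reproducible); at matched noise
d_gen = d = 0.1 the per-strategy recovery rates are ≈ 0.92 (BUS), ≈ 0.84
(CES), ≈ 0.54 (SES) with Monte-Carlo SEs below 0.02 — all far above the
1/3 chance level, with SES again limited by its proximity to CES. With
equal strategy priors and the shared isotropic kernel, the
maximum-posterior decision coincides exactly with the
nearest-predicted-position rule in total squared distance, and a test
asserts that equivalence.

## Numerical conventions

- Simplex membership and normalization: 1e-9 absolute; user-supplied
  (hand-entered) triples are cleaned with 1e-6 and renormalized; triples
  already within 1e-12 of unit sum are left untouched.
- Small negative components within tolerance are clipped to zero before
  renormalization; rejected otherwise.
- SES tie detection uses an absolute tolerance of 1e-12 on likelihoods.
- Degenerate evidence (all-zero likelihoods, or evidence annihilating every
  positive-prior hypothesis) raises an error rather than returning NaN.
- Seeds: cohorts are reproducible bitwise from a single integer seed;
  replicate seeds are spawned from it and kept below 2³¹.
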