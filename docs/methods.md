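# Methods

## Model

The package implements a two-stage multicriteria decision pipeline for
ranking vineyard cover-crop candidates.

**Stage 1 — criterion weights (AHP).** Expert judgments arrive as an
`n × n` positive reciprocal matrix on the Saaty 1–9 scale. Weights are the
principal right eigenvector, computed by power iteration on the raw matrix
with L1 renormalization each step. For a positive matrix the
Perron–Frobenius theorem guarantees a unique positive dominant eigenvector,
so no deflation or restart logic is needed; convergence is declared when
the max-abs change in the weight vector falls below `1e-10` (default cap
10,000 iterations — in practice a consistent 10×10 matrix converges in a
handful of steps). `λ_max` is estimated at convergence as the mean Rayleigh
ratio `mean((A·w)_i / w_i)`, which is exact at the fixed point and stable
for positive matrices. The consistency index is `CI = (λ_max − n)/(n − 1)`
and the consistency ratio `CR = CI/RI(n)` with the standard random-index
table (`RI = 0, 0, 0.52, 0.89, 1.11, 1.25, 1.35, 1.40, 1.45, 1.49` for
`n = 1..10`; sizes above 10 are rejected). `CR < 0.10` passes the gate; a
2×2 reciprocal matrix is always consistent, so `CI = CR = 0` by convention
there. Entries outside `[1/9, 9]` are admitted with a warning rather than
rejected: the eigen machinery is valid for any positive reciprocal matrix,
and intermediate values are legitimate compromise judgments.

**Stage 2 — ranking (TOPSIS).** Alternatives × criteria scores are
column-normalised by the Euclidean norm, weighted, and compared with the
positive and negative ideal solutions (per-column best/worst weighted
value; max is best for benefit criteria and min for cost criteria).
Relative closeness `RC = d⁻/(d* + d⁻)` ranks alternatives descending.

Cost criteria are handled by the min/max swap when selecting the ideals,
on raw-sign normalised values — not by pre-transforming the scores. This
is the convention that reproduces the published study values (below). An
optional `invert_costs` preprocessing mode (replace `x` by `max_col − x`
in cost columns before normalisation) is provided for reproduction
experiments with the alternative reading and is regression-tested, but it
fits the published numbers strictly worse and is off by default.

## Numerical and edge-case choices

- Weight vectors must sum to 1 within `1e-6` at the ranking interface;
  the published weight table columns are rounded (one sums to 0.999), so
  the study layer renormalizes them proportionally before use.
- A constant criterion column is allowed: its PIS equals its NIS and it
  contributes nothing to either separation; a warning is emitted. An
  all-zero column is an error (the normaliser is 0/0). Negative scores are
  rejected — every criterion here is a nonnegative mass or ordinal score,
  and Euclidean normalisation is sign-ambiguous otherwise.
- If an alternative has zero separation from both ideals (all alternatives
  identical), its closeness is defined as 0.5 with a degeneracy warning.
- Tied closeness values (within `1e-12`) receive consecutive ranks in
  input order, deterministically, and the tie is reported on the result.
- Comparison-matrix CSV input accepts exact fraction literals (`1/3`);
  rounded reciprocals (0.33) violate the `1e-9` reciprocity tolerance and
  are only accepted under an explicit, loudly logged repair mode that
  resets the lower triangle from the upper.

## Study data and reproduction

The packaged fixtures transcribe the field screening tables: 9 in-row and
15 inter-row species scored at two sites (CFF and KOW) on dry biomass
(kg/ha) and ground coverage (site-specific, means of 5 replicate plots)
plus shared ordinal scores — fruiting-zone interference 1–3 (in-row only),
invasiveness risk 1–3, pest sensitivity 1–3, drought tolerance 1–3, winter
hardiness 1–7, traffic tolerance 1–2 (inter-row only) — together with the
expert-derived weights per context (in-row; inter-row annual; inter-row
perennial) and the published closeness scores. Fixtures carry a SHA-256
manifest checked at load. The coverage header scale is nominally 1–5 but
the class legend runs 0–4; the printed per-plot means (0.6–3.9) are used
verbatim with no remapping. Mixtures ("Field pea + Cereal rye") are single
alternatives. Seeding-rate metadata never enters the matrices.

Annuals and perennials within a position are ranked as separate matrices.
The published two-species in-row perennial closeness pairs sum exactly to
1.00, which is forced algebraically only in a standalone two-alternative
run (each ideal coordinate comes from one of the two rows, so
`d₁* = d₂⁻`), confirming that reading.

The direction map is reconstructed from criterion semantics: benefit =
{biomass, coverage, drought tolerance, winter hardiness, traffic
tolerance}; cost = {fruiting-zone interference, invasiveness, pest
sensitivity}. It is configurable per matrix. Winter hardiness for
inter-row annuals is kept as benefit even though winter-killed residue
arguments could justify the opposite; the alternative was evaluated and
fits the published values worse.

### What reproduces and what does not

With the default convention, six of the eight site × category cells match
the published closeness scores to within ~0.01 with perfect rank
agreement. In the CFF inter-row annual cell, six of seven species match
within 0.012 and all seven ranks agree, but hairy vetch + cereal rye
computes to 0.207 against a published 0.18 (the same species at KOW
matches: 0.109 vs 0.11); no examined convention or direction variant
closes that gap without breaking the other six values, so the computed
value is reported as-is.

The two in-row perennial cells do **not** reproduce: the published
0.86/0.14 (CFF) and 0.82/0.18 (KOW) splits favour white clover, but under
the printed scores buffalo grass is preferred on pest sensitivity (1 vs 2,
weight 0.129) and drought tolerance (3 vs 2, weight 0.026), which
outweighs clover's biomass + coverage + hardiness advantages
(combined weight 0.105), so every monotone cost convention ranks buffalo
grass first (computed 0.43/0.57 and 0.36/0.64). Two internal features of
the published account indicate its perennial-pair numbers came from
criterion scores different from the printed table: (a) the published
sensitivity analysis reports this pair changing (0.86→0.98) when the
invasiveness criterion is removed, yet the printed invasiveness scores are
identical (1, 1) for both species and a constant column contributes
exactly zero to every TOPSIS separation, so removing it cannot change a
two-alternative ranking; and (b) the published post-removal weights (0.67
for interference) cannot arise from proportional renormalization of the
printed weight table (0.307/0.567 = 0.541). The reproduction harness
reports these disagreements rather than hiding them, and the
corresponding end-to-end test states the published claim and fails on
exactly these cells.

The criterion-removal experiment itself is reproduced qualitatively:
removing invasiveness (proportional renormalization) keeps spring lentil
rank 1 among CFF in-row annuals, promotes hairy vetch + cereal rye to
rank 1 among CFF inter-row annuals (0.207→0.752), and raises the
closeness of white mustard (KOW in-row, 0.224→0.452) and Indian ricegrass
+ buckwheat (KOW inter-row perennial, 0.301→0.596). Exact post-removal
closeness values are not asserted numerically, for reason (b) above; a
`weights_override` hook accepts externally re-elicited weights.

## Synthetic data

The generators exist so every stage is testable with known ground truth,
offline:

- `consistent_pcm_from_weights(w)` builds `a_ij = w_i/w_j`, the unique
  perfectly consistent matrix with priorities `w`; `perturbed_pcm(w,
  sigma, seed)` multiplies upper-triangle entries by lognormal noise
  `exp(N(0, σ²))` and mirrors exact reciprocals, so positivity and
  reciprocity hold by construction and σ is the single inconsistency knob
  (σ = 0.05/0.15/0.3 give mean CR ≈ 0.0006/0.006/0.024 at n = 7).
- `synth_decision_matrix` draws field-table-like matrices: a lognormal
  biomass column (μ = 7.2, σ = 0.9 on the log scale, matching the
  right-skewed 1–8,600 kg/ha range observed in the field tables) and
  uniform ordinal score columns on their 1–3/1–5/1–7 ranges, with mixed
  directions and an optional planted winner shifted strictly past every
  column extreme, which dominance guarantees is rank 1 with closeness 1.

What the synthetic data does not emulate: correlations between criteria
(real biomass and coverage co-vary), site effects, or expert judgment
structure beyond symmetric lognormal noise. Passing the planted-truth
tests therefore demonstrates correctness of the machinery, not calibration
to any field population.

## Problem sizes

The test suite uses the study matrices themselves (2–8 alternatives × 7
criteria), 200 consistent-matrix recovery trials at n = 3..10, 1,000
random TOPSIS property trials, and 200 noisy-matrix draws per noise level
in the validation script; the whole suite runs in a few seconds.

## Known limitations

- Plain TOPSIS is subject to rank reversal when alternatives are added or
  removed; this is inherent to the method and documented, not mitigated.
- Group aggregation of multiple experts' matrices (e.g. geometric-mean
  consensus) is out of scope; the study layer consumes published
  aggregate weights.
- The published expert comparison matrices themselves are not included in
  the source material, so the published weight table cannot be re-derived,
  only consumed; its reported CR range (0.06–0.09) is unverifiable.
- Only the criterion-removal sensitivity design is implemented;
  continuous weight perturbation (tornado-style) is left to the API user.
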