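# Methods

This note documents the models, the parameter choices, the numerical
details, and the limits of what the synthetic validations demonstrate.

## Sequence autocorrelation

For a set of module sequences, `Π(r)` is the pooled fraction of identical
nucleotide pairs at lag r minus the composition baseline `p̄² = Σ_α p_α²`,
evaluated per pair in a local window (default 500 bp) centered on the
pair's midpoint and truncated at module edges. The local window removes
composition heterogeneity between and within modules; changing its length
shifts the baseline but not the short-lag structure.

`p̄²` is estimated as the probability that two *distinct* letters drawn
from the window match, `Σ_α c_α(c_α−1) / (W(W−1))`, which is unbiased for
`Σ_α p_α²`. The plug-in estimator `Σ_α (c_α/W)²` would bias the baseline
up by `(1−Σp²)/W ≈ 1.5×10⁻³` at W = 500 — larger than the standard error
of `Π(r)` on 10⁵ bp of sequence, hence the choice. Its one visible cost:
for a deterministic periodic window the baseline is `(W−4)/(4(W−1))`
rather than exactly 1/4, a `3/(4(W−1)) ≈ 1.5×10⁻³` offset.

Pairs containing N are dropped from both numerator and baseline. Reported
bins are variable-width, grown until each holds at least 10⁴ pairs; the
raw per-lag values are always emitted too.

## Similarity information and the pair-selection DP

A pair of sites of length ℓ with mean per-position match probability q
carries similarity information `H(q; q₀) = ℓ[q ln(q/q₀) +
(1−q) ln((1−q)/(1−q₀))]` nats relative to the background match
probability `q₀ = Σ_α p₀(α)²`. H ≥ 0 with equality iff q = q₀. For sites
drawn from one motif, H per pair recovers roughly half the motif
information per site; the tests assert only the bound 0 < H < 2I.

At fixed lag r and length ℓ, the selected pair set maximizes the total
similarity `Σ k(x)` subject to (i) left sites pairwise non-overlapping
(|x_j − x_k| ≥ ℓ) and (ii) every pair above threshold, k(x) ≥ q_c. The
recursion `S_x = max(S_{x−1}, S_{x−ℓ} + k(x)·[k(x) ≥ q_c])` with
backtracking solves this exactly (weighted interval scheduling).
Similarities are handled as integer match counts, so optimization and
tie-breaking are exact; on ties the position is *not* selected, giving the
leftmost-minimal optimal set. N never matches. Sequences shorter than
r + ℓ yield the empty set. The inner loop is compiled with numba: a scan
over 50 lags × 7 lengths × a 100-realization null ensemble touches ~10⁵–10⁶
DP instances.

### Null calibration and threshold selection

The expected pair count n₀ comes from a first-order Markov ensemble
matching the data's mono- and dinucleotide statistics (default 1000
realizations in the CLI; the validation suite uses 100, which already
gives n₀ standard errors well below the planted effects tested). The total
information is `Ĩ(r, ℓ) = (n − n₀)·H(q̄; q₀)/N` with N the total sequence
length; negative excess is reported as computed and flagged, never
clipped.

The threshold q_c is chosen on the achievable grid {k/ℓ : k ≥ ⌈q₀ℓ⌉} by
maximizing Ĩ. This maximization gives the statistic a positive null mean
and mildly heavy tails, so the same maximized statistic is also evaluated
on every null realization, yielding

- a selection-corrected significance `z_information = (Ĩ − mean(Ĩ_null)) /
  sd(Ĩ_null)`, and
- a null-mean-corrected value `Ĩ_corrected` whose sum over lags is the
  quantity compared across lengths; `ℓ*` is its argmax.

Without the correction, shorter lengths (denser candidate grids, more
thresholds) accumulate more selection bias over a 50-lag sum and can
displace the true optimum. When judging whether *many* (r, ℓ) cells are
quiet, remember that the maximum of K calibrated z-values grows like
√(2 ln K) ≈ 3.4 for K ≈ 350; the validation suite treats z > 5 as signal
and tolerates a ≤ 2% rate of z > 3 in pure background.

## Evolutionary model

Fitness landscapes are additive: `f_i(α) = ln(q_i(α)/p₀(α))`, scaled in
units of the effective population size, so that the motif distribution is
the mutation–selection–drift equilibrium and the mean fitness of
functional sites equals the motif's sequence information. Epistasis within
and between sites is not modeled; neither are indels between sites (pair
distance is an observable, never scored).

Substitution rates are Kimura–Ohta: `u(α→β) = μ·m(α→β)·g(s)` with
`g(s) = s/(1−e^{−s})` and `s = f_i(β) − f_i(α)`. g is evaluated via
`expm1` with a series expansion for |s| < 10⁻⁸ and the explicit asymptotic
branch for large |s|; g(0) = 1. Time is measured in units of 1/μ (μ = 1):
t and μ are not separately identifiable.

The default mutation model is background-weighted, `m(α→β) = p₀(β)`, which
makes the selected process reversible with stationary distribution q_i —
the detailed-balance identity `Q_A(c)G_A(a|c;t) = Q_A(a)G_A(c|a;t)` that
the common-descent likelihood uses to rewrite the ancestor sum. A
`uniform` mutation model (m = 1/4) is available for comparison; under it
stationarity holds only for uniform background, and propagators fall back
to the general Padé matrix exponential instead of the symmetrized
eigendecomposition used in the reversible case. Propagator entries below 0
are clipped and rows renormalized (round-off only).

### Descent likelihoods and the duplication score

`P_ind(a,b) = Q_A(a)Q_B(b)`. `P_dup(a,b;t)` averages, with equal priors,
the two ancestral assignments (ancestor at equilibrium under A or under
B), each a product over positions of
`Σ_c q_i(c) G_A(a_i|c;t) G_B(b_i|c;t)`. Both are normalized over sequence
pairs; hence the score `S = ln(P_dup/P_ind)` satisfies `E_ind[e^S] = 1`
exactly, `E_ind[S] ≤ 0 ≤ E_dup[S]`, and S → 0 as t → ∞ (the two histories
become indistinguishable). These identities are verified exhaustively for
short motifs in the test suite.

Unequal motif lengths are compared gaplessly over min(L_A, L_B) columns;
the offset maximizes P_dup at the working t (ties to the smallest offset)
and the same columns enter P_ind, so the ratio is well defined. Overhang
columns of the longer motif contribute their own motif marginal to both
models and cancel in S.

### Fitting t*

`infer_tstar` maximizes the total score Σ S(t) on a log grid (default 30
points spanning 10⁻³–10³/μ; recovery analyses use 41 points on 10⁻²–10²,
whose 1.26× spacing resolves the region around τ̄). A boundary maximum is
flagged: it is the expected outcome for pure independent descent, where
E[S] ≤ 0 for all t and → 0 as t → ∞. With divergence times τ ~
Exponential(τ̄), the single-t fit lands systematically somewhat below τ̄
(≈ 0.6 τ̄ in the simulations here): the fitted t is a similarity-scale
parameter, not a linear clock.

## Mixed-descent model

`Q(S) = (1−ρ)Q_ind(S) + ρQ_dup(S)`. Q_ind is a Gaussian KDE (Scott
bandwidth) of scores from far-apart pairs within modules — this assigns
module-level composition similarity to the background, leaving only excess
similarity as duplication evidence. Q_dup is Gaussian with location μ_d
and scale σ_d, fitted together with ρ by maximum likelihood (coarse grid,
then Nelder–Mead; ties resolved toward smaller ρ).

Two constraints make the component identifiable: σ_d ≥ 0.3·sd(Q_ind)
(otherwise a vanishing-width component latches onto repeated score values)
and μ_d ≥ mean(Q_ind) + sd(Q_ind). Without the location margin, a
component overlapping the bulk absorbs sampling noise and inflates ρ by
≈ 0.15 at a true ρ of 0; with it, recovery of planted fractions 0–0.5 at
n = 300 carries |bias| < 0.03 and the estimate at ρ = 0 is ≈ 0.02.

The evidence is `Λ = n·D`, with D the relative entropy between the
near-score histogram and Q_ind on a common 20-bin grid (bin probabilities
of Q_ind by exact KDE integration, floored at 10⁻¹²). D has the usual
positive small-sample bias, so "consistent with zero" is judged against a
resampling null band (`lambda_null_quantile`). A bootstrap percentile
interval on ρ is attached on request; the CLI also reports Λ scaled to the
lower ρ bound as a conservative figure.

**Interpretation limit.** On ensembles with exponential divergence times,
duplications with τ ≫ 1/μ leave no sequence trace; the fitted ρ is a lower
bound on the historical duplicated fraction. The recovery quoted above
refers to mixtures whose duplicated component is actually displaced from
the background, which is what the score can see.

The scramble control compares per-factor-pair mean scores with means
recomputed after permuting scores across pairs (two-sample KS test): a
broad duplication signal is indistinguishable from its scramble, whereas
similarity confined to particular factor pairs (e.g. shared motif
structure or epistasis) produces a small p-value.

`distance_entropy_profile` computes D between each distance-bin's score
distribution and Q_ind (pairs at ≥ 100 bp by default); bins under 10 pairs
are skipped. A decay of D(r) localizes the mechanism generating excess
similarity.

## Binding correlation

`C(A→B) = Σ_i Σ_α q^A_i(α) ln(q^B_i(α)/p₀(α))` over the aligned columns
(full-overlap offset maximizing C, ties to the smallest; all reported
quantities — C, I_A, I_B, and the background mean `−D(P₀‖Q_B)` — refer to
the same columns, so the identities `C(A→A) = I_A` and `C(A→B) = I_A −
D(Q_A‖Q_B)` hold exactly). Results are available in nats and bits.
`site_fitness_values` attaches F_B of known B-sites for the weak-site
comparison: a duplicated A-site has adaptive potential toward B when
C(A→B) is comparable to the fitness of weak B-sites and well above the
background mean.

## Synthetic data: what it emulates and what it does not

- `sample_markov`: first-order Markov sequences with specified mono- and
  dinucleotide statistics, inverse-CDF sampling from a single stream, one
  position at a time across sequences (documented stream order makes runs
  bit-reproducible).
- `plant_correlated_modules`: Markov background with left/right duplicated
  segments at controlled lags in disjoint blocks, plus a ground-truth
  table. Recovered left positions can jitter by 1–3 bp when chance matches
  extend a duplicated block.
- `simulate_pair_ensemble`: per factor pair, duplication events with
  ancestor drawn from Q_A or Q_B (equal probability), τ ~ Exponential(τ̄),
  and a batch of site pairs per event evolved position-wise through the
  two propagators; independent pairs drawn from the motif equilibria.
  Validation conditions: six factor pairs (four different, two equal), 100
  events × 10 pairs, τ̄ = 1/μ — a desk-scale version of a 500 × 50
  protocol, chosen so the full suite runs in minutes on one CPU; the
  generator accepts the larger numbers unchanged.

Defaults: motif length 7 bp (the characteristic scale of eukaryotic
binding sites), random peaked motifs with per-position preferred-base
weight in [0.6, 0.95] (≈ 6–12 bits per motif), uniform background, near/far
distance classes 50/100 bp. Real regulatory sequence differs in ways the
generator does not emulate: composition heterogeneity beyond first-order
Markov structure (e.g. homopolymer runs in nucleosome-depleted regions),
tandem-repeat indel dynamics, correlated motifs of interacting factors,
and selection on site spacing. Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated model, not
the size of the signal in any particular genome.

## Curation and other conventions

Coordinates are 0-based half-open; minus-strand sites are
reverse-complemented into motif orientation before scoring; pair distance
is between 5′-most plus-strand starts. Site curation applies, in order:
exclusion of X-chromosome sites, removal of both members of any
overlapping site pair, and removal of factors present in fewer than two
modules — this order makes one pass idempotent. Footprints not matching
their motif length are cut/extended to the gapless length-L window
overlapping the annotation that maximizes F (ties leftmost); windows with
N are disqualified. Motif matrices and background estimates receive a
pseudocount of 0.5 per position/sample distributed proportionally to the
background (uniform for the background itself). Local backgrounds use
1000 bp flanks by default (configurable; the appropriate scale depends on
the composition heterogeneity of the data), falling back to module-wide
frequencies when a site has no flanking sequence.

## Known limitations

- Additive fitness: no epistasis within sites; inferred t* is compressed
  relative to models with epistasis.
- Single shared t for all pairs; divergence-time heterogeneity is absorbed
  into the score distribution, and ρ is a lower bound (above).
- The DP scores only gapless pair similarity at fixed lag; indel histories
  between duplicates are not modeled.
- Q_dup is location–scale Gaussian; strongly multimodal duplicated-score
  distributions would be summarized, not resolved.
- Repeat masking is accepted as input intervals (`--mask`); the package
  does not detect repeats itself.
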