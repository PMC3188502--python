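# dupscan

Statistical detection of transcription-factor binding-site formation by
**local sequence duplication** in cis-regulatory modules.

Regulatory modules of higher eukaryotes contain dense clusters of short
(~5–10 bp) binding sites. Point mutations can rapidly destroy a site but
can only *create* one where a marginally binding seed sequence already
exists. Local duplications place such seeds specifically next to existing
sites, so neighboring site pairs that arose by duplication retain excess
sequence similarity long after the duplication event. `dupscan` implements
the statistics to detect and quantify that signal:

- **Sequence autocorrelation** `Π(r) = P(r) − p̄²`: the excess probability
  that two nucleotides a distance *r* apart match, with the composition
  term `p̄² = Σ_α p_α²` estimated in a local window around each pair.
- **Distance-resolved similarity information** `Ĩ(r, ℓ)`: a dynamic
  program selects the maximum-similarity set of non-overlapping site pairs
  at lag *r* and length *ℓ* above a threshold `q_c`; the pair-count excess
  `Δn = n − n₀` over a first-order Markov null ensemble is converted to
  nats per bp via the binary relative entropy
  `H(q̄; q₀) = ℓ [ q̄ ln(q̄/q₀) + (1−q̄) ln((1−q̄)/(1−q₀)) ]`,
  giving `Ĩ = Δn·H/N`.
- **An evolutionary likelihood for common vs independent descent.** Each
  motif defines an information-based (Halpern–Bruno) fitness landscape
  `F(a) = Σ_i ln(q_i(a_i)/p₀(a_i))` (units of 1/N_e), whose
  mutation–selection–drift equilibrium is the motif distribution Q(a).
  Substitutions follow Kimura–Ohta rates `u = μ m s/(1−e^{−s})`. The
  **duplication score** of a site pair (a, b) bound by factors A and B is
  the log-likelihood ratio

  `S(a,b;t) = ln P_dup(a,b;t) − ln[Q_A(a) Q_B(b)]`,

  where `P_dup = ½ Σ_c [Q_A(c) + Q_B(c)] G_A(a|c;t) G_B(b|c;t)` sums over
  the common ancestor c and averages the two possible ancestral functions
  (ancestor at equilibrium under A's or under B's selection). `S > 0`
  favors duplication of a
  common ancestor followed by divergence under the two landscapes.
- **Mixed-descent decomposition** `Q(S) = (1−ρ) Q_ind(S) + ρ Q_dup(S)` of
  an observed score distribution, with `Q_ind` estimated nonparametrically
  from far-apart pairs; the evidence is `Λ = n·D(Q‖Q_ind)` (nats).
- **Binding correlation** `C(A→B) = Σ_i Σ_α q^A_i(α) ln(q^B_i(α)/p₀(α))`:
  the mean fitness of A-sites under B's landscape, quantifying the adaptive
  potential of a duplicated A-site to seed a new B-site. It satisfies
  `C(A→A) = I_A` and `C(A→B) = I_A − D(Q_A‖Q_B)`.

A seeded synthetic-data generator (Markov background, planted duplications
at controlled lags, and site-pair ensembles evolved by common or
independent descent) lets the entire pipeline run and be validated without
any external downloads.

## Worked example

Simulate site-pair ensembles for two 7-bp factors, fit the evolutionary
distance t\*, and decompose a mixed score class:

```python
import numpy as np
from dupscan import (SimulationConfig, fit_mixture, infer_tstar,
                     random_motif, simulate_pair_ensemble)
from dupscan.duplication_inference import score_pairs

factor_a = random_motif("factor_a", length=7, seed=1)
factor_b = random_motif("factor_b", length=7, seed=2)

config = SimulationConfig(
    motif_pairs=[(factor_a, factor_b)],
    tau_bar=1.0,          # mean divergence time since duplication (1/mu units)
    n_events=100,         # duplication events
    pairs_per_event=5,    # site pairs drawn per event
    n_independent=1500,   # pairs of independent origin
    seed=0,
)
ensemble = simulate_pair_ensemble(config)
common = ensemble.subset("common")
independent = ensemble.subset("independent")

table = infer_tstar(common, np.geomspace(1e-2, 1e2, 41))
print(f"t* = {table.t_star:.3f}  (true mean divergence time: 1.0)")

# a 'near' class holding a planted 50/50 mixture, scored at t*
s_near = np.concatenate([table.scores, score_pairs(independent[:500], table.t_star)])
s_far = score_pairs(independent[500:], table.t_star)
fit = fit_mixture(s_near, s_far, n_bootstrap=50, seed=0)
print(f"duplicated fraction rho = {fit.rho:.2f}  (planted: 0.50)")
print(f"rho 95% CI = ({fit.rho_ci[0]:.2f}, {fit.rho_ci[1]:.2f})")
print(f"evidence Lambda = n * D = {fit.n} * {fit.D:.3f} = {fit.Lambda:.0f} nats")
```

Output:

```
t* = 0.631  (true mean divergence time: 1.0)
duplicated fraction rho = 0.28  (planted: 0.50)
rho 95% CI = (0.25, 0.33)
evidence Lambda = n * D = 1000 * 2.261 = 2261 nats
```

The fitted t\* sits within a factor two of the true mean divergence time
(the total-score maximum is systematically somewhat below the mean for
exponentially distributed times). The fitted ρ is a **lower bound** on the
planted duplicated fraction: pairs whose divergence time far exceeds 1/μ
carry no remaining sequence trace of their common origin and are correctly
absorbed into the independent-descent component. The evidence Λ ≫ 0
nevertheless detects the duplication signal decisively.

## Command line

A thin CLI wraps the library for shell pipelines (FASTA modules, BED6+1
sites with the module id in column 7, JASPAR matrices):

```bash
dupscan curate   --fasta modules.fa --sites sites.bed --motifs pwm.jaspar --out curated.tsv
dupscan autocorr --fasta modules.fa --rmax 100 --window 500 --out profile.tsv
dupscan pairsim  --fasta modules.fa --r 1:50 --l 3:12 --null 1000 --seed 7 --out pairsim.tsv
dupscan dupscore --fasta modules.fa --sites sites.bed --motifs pwm.jaspar --out scores.tsv
dupscan mixture  --scores scores.tsv --near 50 --far 100 --out mixture.json
dupscan bindcorr --motifs pwm.jaspar --pairs pairs.txt --out bindcorr.tsv
dupscan simulate --config sim.yaml --seed 7 --out-dir sim/
```

## Layout

| module | contents |
| --- | --- |
| `dupscan.seq_io` | FASTA/BED/JASPAR I/O, site curation filters, strand-aware site extraction, local backgrounds |
| `dupscan.autocorrelation` | distance-dependent autocorrelation with local-window composition |
| `dupscan.similarity_dp` | similarity information, DP pair selection, Markov-null calibration, (r, ℓ) scans |
| `dupscan.evolution_model` | fitness landscapes, Kimura–Ohta rates, propagators, descent likelihoods |
| `dupscan.duplication_inference` | duplication scores, t\* fitting, mixture model, distance profile, scramble control |
| `dupscan.binding_correlation` | cross-motif fitness C(A→B) and reference quantities |
| `dupscan.synthetic_data` | seeded generators for every input the pipeline consumes |

See `docs/methods.md` for the model assumptions, parameter choices, and
numerical details.
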