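# Methods

## The disturbances autoregression

The statistical core is the Gaussian linear network-autocorrelation model in
its *disturbances* form: the autocorrelation lives in the residual, not the
response. With outcome vector `y` over `n` countries, design `X` (here a lone
intercept), and weight matrices `W_k`,

    y = Xβ + ε,   ε = Wε + ν,   W = Σ_k ρ_k W_k,   ν ~ N(0, σ² I),

equivalently `y ~ N(Xβ, σ² A⁻¹A⁻ᵀ)` with `A = I − W`. As `W → 0` the model
collapses to ordinary linear regression; `ρ_k > 0` means countries tied in
network `k` are more alike in `y` than chance, `ρ_k < 0` that they are more
different (cultural differentiation — the reactionary dynamic that deliberate
divergence from close relatives, esoterogeny in the linguistic literature,
would produce).

**Likelihood.** β and σ² are profiled analytically: for fixed ρ,
`β̂ = lstsq(AX, Ay)`, `σ̂² = ‖Aŷ_resid‖²/n`, and the concentrated
log-likelihood is `−(n/2)·ln(2πσ̂²) + ln|det A| − n/2`. The density uses
`ln|det A|`: the model covariance `σ²A⁻¹A⁻ᵀ` is positive definite for any
nonsingular `A`, so the ρ are genuinely unbounded. This matters in practice:
on a row-normalized adjacency the first singularity sits at ρ = 1, and on a
dense affinity matrix with unit diagonal at ρ = 1/λ_max (often < 0.05), yet
empirically meaningful estimates routinely lie beyond those points —
restricting to the det(A) > 0 component around 0 would make such values
unreachable. Only exactly singular `A` is excluded.

**Optimization.** Because `ln|det|` has log-singularities that split each ρ
axis into ridges, the likelihood can be multimodal. Each matrix's axis is
first scanned on a 25-point grid spanning `ρ·λ_max ∈ [−3, 3]` (others held at
0); Nelder-Mead then refines from ρ = 0, from the per-axis best vector, and
from the single strongest axis, and the best optimum wins (convergence
tolerance 1e−8 on the log-likelihood, deterministic — no randomness in the
fitting path). A fit that fails to converge is flagged and ranked last, never
raised.

**Inference.** Standard errors come from the inverse numerical Hessian of
the negative full log-likelihood in (β, σ², ρ) at the optimum
(finite differences); p-values are two-sided normal z-tests. BIC is
`−2·loglik + k·ln(n)` with `k` counting every free parameter: intercept(s),
σ², and one ρ per matrix. The degrees-of-freedom convention (z rather than t)
and the parameter count are stated here because published gap values depend
on them.

## Weight matrices

Distances become expected correlations via `(max(D) − D_ij)/max(D)`:
diagonal 1, the maximally distant pair exactly 0, scale-invariant. Affinity
matrices are *not* re-derived when a time bin drops countries — rows/columns
are sliced from the full-sample matrix so affinities stay comparable across
bins — whereas sliced adjacency matrices are re-row-normalized, since losing
a node changes its neighbors' shares. Adjacency uses strict `D_ij <
threshold` with a 1e−9 guard band so boundary values are deterministically
"not less than". Geographic distances use the Haversine formula on a sphere
of radius 6371 km; border adjacency is data, never computed from geometry.

## Model selection machinery

Per time bin, all 2^k subsets of the candidate matrices (null model included)
are fitted and ranked by BIC ascending, ties (< 1e−6) broken by parsimony
then label order. Aggregates mirror the standard selection-table layout:
counts of each matrix in the preferred and second-best models (a matrix in
both counts twice toward "overall", so each matrix's ceiling is 2 × #bins),
median BIC gaps preferred→2nd and preferred→3rd, and the doubled-scale Bayes
factor `BF = 2·ΔBIC` read against the conventional bands (0–2 weak, 2–6
positive, 6–10 strong). The top-*two* convention is justified when the gap to
the third model is strong while the gap to the second is not. Single-matrix
censuses fit each matrix alone per bin, count p < α (α = 0.05, no
multiple-testing correction — deliberately matching common practice in this
literature), and summarize the significant ρ with a one-sample t-test
(df = count − 1). Even/odd robustness reports the fraction of a matrix's
top-two inclusions on even-indexed bins: temporally clustered findings split
unevenly.

## Outcome panels

Polity-style scores are sampled biennially (1898–2012 → 58 state bins, 57
change bins); the special codes −66/−77/−88 (interruption, interregnum,
transition) are treated as missing since they are not values on the −10..10
scale. Default events are yearly 0/1 flags per stream (foreign, domestic)
summed into 5-year bins from 1899; each stream contributes 1 per event-year.
Change panels are first differences, missing when either side is. Per bin,
countries missing that bin are dropped and every matrix is sliced to the
retained set; bins with fewer than 3 countries or a constant outcome are
skipped and logged — totals always report the estimable-bin count so any
discrepancy with a fixed bin ladder is visible.

## Diffusion bias study

To measure what the selection machinery does to data with known provenance,
independent standard-normal traits are planted on the nodes and updated in
one synchronous step: `x_i = z_i + r·(m_i − z_i)` with `r = 0.2` and `m_i`
the weight-weighted mean of `z` over `i`'s neighbors (all `j ≠ i` with
positive weight; isolates keep `z_i`). The attracting sign is the default —
the process is adoption/diffusion — and a negative rate gives the repelling
variant for sensitivity analysis. Each of the four networks receives its own
batch of traits (250 at full scale), and every trait goes through the
complete 16-model sweep. One master seed spawns per-(network, trait)
substreams, so runs are bit-reproducible and parallelizable.

A structural finding worth stating: on *dense valued* networks the weighted
neighbor mean is close to a global mean, so a single 20% step leaves little
recoverable signal, while the estimator on such matrices has a known
small-sample pull toward negative ρ (the intercept absorbs the constant
Perron mode that the log-determinant still prices; the pull scales like the
inverse of the non-Perron spectral mass). The practical consequence —
reproduced by `run_bias_study` — is that dense valued matrices, spatial
proximity above all, collect inclusions across *all* simulated conditions,
while sparse adjacency conditions recover their own network cleanly. This is
the topology-dependent selection bias the study exists to expose, and it is
why empirical results in which spatial proximity and an adjacency matrix are
jointly prominent warrant caution.

## Synthetic worlds

The generator fabricates the statistical shape of the study inputs, not
historical geopolitics:

* **Phylogeny** (`make_toy_phylogeny`): recursive binary splitting with
  bimodal node depths — major branches keep 78–95% of the parent age until a
  clade is subfamily-sized, then the age collapses to 8–25% — yielding the
  block-structured pairwise profile of real deep language families (most
  country pairs diverge near the root; compact recent radiations). Root
  depth defaults to 8700 years (an old family). Colonies attach to random
  parents at 50–400-year splits, giving the short non-phylogenetic distances
  colonial independence dates contribute. Distances are additive (tested via
  the four-point condition).
* **Geography**: ~8 regional centers; subfamilies draw a home region with a
  bias toward a few core regions (several branches crowd the family's
  heartland), colonies scatter to random regions with probability 0.9 (the
  colonial diaspora sits far from its parents). Scatter σ ≈ 7–9°.
* **Borders**: pairs closer than the 12th percentile of pairwise distance are
  adjacent — a stand-in for the manually sourced border table.
* **Outcomes**: `sample_disturbance_outcome` is the exact sampler
  `y = intercept + (I − W)⁻¹ν` (stability-checked). Polity-like panels make
  rare bounded integer moves: per bin, each country changes with probability
  `change_prob` (default 0.1 — regime change is rare) by a network-correlated
  increment rounded half-away-from-zero (symmetric for moves toward autocracy
  or democracy) and clipped to [−10, 10]; the default planted ρ is 80% of the
  generating matrix's spectral stability bound so the signal is strong but
  recoverable by a fit started at 0. Default-like panels are Bernoulli
  event-years (rate 0.05 — defaults are rare; no serial dependence in v1).

What passing tests on these worlds do **not** show: that the magnitudes of
the real study's inclusion counts or ρ values transfer — those depend on the
actual matrices' spectra and cross-correlations. In particular, on synthetic
worlds the socio-linguistic-affinity diffusion condition is largely absorbed
by the (confusable, bias-advantaged) spatial-proximity matrix rather than
recovered as its own top inclusion; the qualitative bias pattern, the
adjacency-condition recoveries, and the gap orderings are the stable,
asserted behaviors.

## Problem sizes and defaults

The bundled runs use worlds of 48–64 countries (tests) and 64 countries with
50 diffusion reps (acceptance script) — the package's chosen desk-scale
sizes; `n_reps`, world size, bin counts, α, the 1000-year intelligibility
threshold and the 0.2 diffusion rate are all config-exposed
(`pipeline.RunConfig`). Recovery properties are benchmarked on a ring lattice
(n = 100, k = 4), a sparse regular topology on which the MLE's small-sample
bias is negligible; dense-topology bias is a finding, not a defect, and is
asserted as such.

## Known limitations

* Linear Gaussian modelling of bounded/count outcomes is an approximation
  (adopted deliberately over information-destroying binarization).
* SEs use the normal approximation; no small-sample df correction.
* The unbounded `ln|det|` likelihood admits multiple ridges; the scan grid
  (±3 spectral widths) bounds the search, so optima far outside it would be
  missed.
* The bias study implements one diffusion kernel (single synchronous
  weighted-mean step); threshold/contagion processes are out of scope.
* Synthetic borders and centroids are statistical stand-ins; no geometry or
  gazetteer realism is attempted.
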