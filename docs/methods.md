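# Methods

This note documents the statistical procedures implemented in `outletrisk`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## 1. Record linkage of retail listings

Two registries (one for tobacco retailers, one for off-premise alcohol
permits) describe overlapping stores. Listings are normalized before
comparison: text upper-cased, whitespace collapsed, punctuation removed
(keeping `&`, which is part of many business names), street-suffix variants
mapped to one canonical token (STREET/STR→ST, AVENUE→AVE, ROAD→RD,
BOULEVARD→BLVD, DRIVE→DR, HIGHWAY→HWY, LANE→LN, COURT→CT, PLACE→PL,
PARKWAY→PKWY), and trailing store-identification tokens (`#123`, `NO 123`,
`STORE 123`, or a bare trailing digit run) stripped from business names
only. Suffix canonicalization applies to addresses; business names rarely
carry street suffixes and rewriting them would risk corrupting legitimate
name tokens.

String similarity is one minus the optimal-string-alignment (OSA) distance
divided by the longer string's length. OSA is the restricted
Damerau–Levenshtein distance: unit-cost insertions, deletions,
substitutions and adjacent transpositions, with no substring edited twice
(so `d("CA","ABC") = 3`). Both strings empty is defined as similarity 1.
Spatial proximity enters through two indicator thresholds on the haversine
great-circle distance (sphere radius 6371.0088 km = 20,902,259 ft). The
total similarity of a tobacco listing `t` and alcohol listing `a` is

    sim(t,a) = 0.25*namesim + 0.25*addresssim
             + 0.20*I(dist < 520.9 ft) + 0.30*I(dist < 260.45 ft)

The distance cutoffs are used exactly as printed in the originating
analysis even though one-tenth/one-twentieth of a statute mile would be
528/264 ft; both are exposed as parameters (`outer_ft`, `inner_ft`).
Indicators use strict `<`; the match rule uses `>= 0.70`.

Within each block group containing listings from both registries, all
cross-registry pairs are scored and matched **one-to-one, greedily in
descending similarity**, ties broken by `(tro_id, aro_id)` lexicographic
order; matched pairs become dual-product (TARO) outlets and leave both
class counts. The pairing discipline was an open choice; greedy matching is
transparent, deterministic, and on realistically separated similarity
distributions (true duplicates near 1, cross pairs far below the cutoff) it
coincides with the exhaustive max-cardinality/max-similarity assignment,
which the tests verify on 500 simulated small groups. On adversarial
similarity matrices the two can differ; the implementation makes no
optimality claim there. Block groups with listings from a single registry
use the fallback: listings whose normalized name is on the
commonly-appearing dual-product chain list count as TAROs. The fallback is
*not* additionally applied to unmatched listings of mixed groups.

## 2. Covariate preparation

Units with zero population are dropped first, then units missing any
covariate; both passes are logged with unit ids. Segregation ratios are the
block-group percent of a group divided by the state-average percent.
Per-capita income is inverted as `max(x) − x` so all nine covariates point
toward disadvantage; inversion happens before decile scoring (the scores
are invariant to the order, since inversion is monotone; fixing the order
keeps the pipeline deterministic and auditable).

Decile scores use type-7 (linear-interpolation) quantiles at probabilities
0.1…0.9 as breakpoints, left-closed bins, ties at a breakpoint assigned to
the lower bin, giving integer scores 0–9. No quantile convention was
prescribed; type-7 is the numpy/R default and the tie rule makes scoring a
deterministic function of the data. Scores run 0–9 rather than 1–10 — the
choice only shifts the intercepts, not the effects or weights. A constant
covariate scores all zeros with a warning.

Expected counts are `E_ik = r_k p_i` with `r_k = sum_i y_ik / sum_i p_i`,
so each column of `E` conserves the observed total. Density categories use
persons per square mile of the supplied land area: rural `< 500`, suburban
`[500, 1000)`, urban `>= 1000`.

## 3. The shared-component index model

Priors: `w ~ Dirichlet(1,…,1)` (configurable concentration);
`alpha_k` improper flat; `beta_k ~ Normal(1, sigma_beta^2)` with
`sigma_beta ~ Uniform(0, 100)` — with this bound the prior is practically
flat over any plausible effect size, so the unusual prior mean of 1 is
inert (both are configurable); `u_i ~ N(0, 1/tau_u)`;
`v_i ~ ICAR(tau_v)`; `s_ik ~ ICAR(tau_k)`; all precisions
`~ Gamma(0.05, 0.005)` (shape, rate). The prior for `tau_u` was not
prescribed; the same Gamma used for the other precisions is adopted. No
scaling parameter links the shared component across outcomes: each outcome
loads on `u_i + v_i` with coefficient 1, with outcome-specific departures
carried entirely by `s_ik`.

The ICAR log pseudo-density is
`((n − c)/2) log tau − (tau/2) Σ_{i~j} (z_i − z_j)^2` with `c` the number
of connected components of the adjacency graph (the Laplacian's rank
deficiency). Identifiability is imposed by recentering `v` and each `s_k`
to sum zero after every sweep; the removed global mean is added to the
(flat-prior) intercepts, which for a connected graph is an exact
reparametrization rather than an approximation. For disconnected graphs
the residual per-component recentering is the usual projection onto the
constraint and is the one approximate step; lattice data are connected.

### Sampler

Metropolis-within-Gibbs, per sweep:

* **Weights** — random-walk on the softmax logits (last logit pinned at 0),
  one coordinate at a time; the Dirichlet density plus softmax log-Jacobian
  reduce to `Σ_j alpha_j log w_j`. Coordinate-wise updates keep acceptance
  tunable per weight and are irreducible on the 9-simplex.
* **Intercepts and effects** — independent scalar random walks per outlet
  type (their full conditionals are independent given the rest). The
  sampler internally parametrizes the intercept at the *mean* index value,
  which removes the strong alpha/beta correlation that a raw-scale random
  walk would face; stored intercepts are transformed back per draw.
* **tau_beta** — exact Gibbs: with `beta_k ~ N(m0, 1/tau_beta)` and
  `sigma_beta ~ U(0, B)`, the conditional of `tau_beta` is a shifted
  exponential, `tau_beta = B^{-2} + Exp(rate = Σ_k (beta_k − m0)^2 / 2)`.
* **u** — all sites proposed and accepted in parallel (they interact with
  nothing but their own likelihood row and prior).
* **v, s** — single-site random walks parallelized over the classes of a
  greedy proper coloring of the adjacency graph (two classes on a lattice):
  within a class no two sites are neighbors, so the simultaneous
  acceptances are those of independent single-site updates. Neighbor sums
  come from one sparse mat-vec per color.
* **Precisions** — conjugate Gamma updates; the ICAR quadratic form is
  `z' L z`, with effective dimension `n − c`.

Proposal scales adapt every 50 iterations toward 44% acceptance during
burn-in only and are frozen afterward, preserving the asymptotic target.
Chain `c` uses seed `seed + c`; initial intercepts are set from the crude
log rate with seeded jitter so chains start overdispersed. A non-finite
posterior aborts with a diagnostic message. Convergence is monitored with
the Gelman–Rubin potential scale reduction factor
`sqrt(((m−1)/m·W + B/m)/W)` and the conventional 1.2 rule.

Reference schedule: 2 chains × 75,000 iterations, 60,000 burn-in, thin 1.
The package defaults (`n_iter=8000`, `n_burnin=4000`) are the desk-scale
schedule used throughout the tests; on 15×15-lattice data they give
Gelman–Rubin values comfortably under 1.2 for the effects and weights.

### Summaries

Point estimates are posterior medians with equal-tailed 95% credible
intervals (HPD intervals were not required and equal-tailed is the common
reporting choice). Per-draw relative risks
`theta_ik = exp(alpha_k + beta_k NDI_i + u_i + v_i + s_ik)` yield unit-level
medians/intervals; exceedance probabilities `Pr(theta_ik > 1)` flag a unit
as significantly elevated when `>= 0.90` (boundary included — the rule's
boundary handling was unstated). `exp(u+v)` and `exp(s_k)` are summarized
as the shared and outlet-specific risk surfaces. Index effects are reported
as `exp(beta_k)` (relative risk per one-decile index increase) along with
pairwise `Pr(beta_j > beta_k)` across draws — an explicit posterior
ordering probability offered in addition to interval overlap, with no claim
that it replicates interval-based significance wording. Weight medians need
not sum to one; the renormalized column is flagged as renormalized. Density
tables report the arithmetic mean of unit rr-medians and the fraction of
elevated units per category and type; empty categories are reported as
missing, not zero.

## 4. Synthetic data

**Areal generator.** Rook adjacency on a rectangular lattice (the simplest
connected areal graph). Nine covariates come from a Gaussian copula with a
common pairwise correlation (default 0.3, exposed as a parameter since no
empirical correlation structure was prescribed) mapped through
heterogeneous marginals (lognormal segregation ratios and income, beta
percentages); decile scoring downstream discards the marginals, which is
the point of decile scoring. ICAR effects are drawn exactly by sampling the
non-null Laplacian eigenvectors with variances `1/lambda_m` and centering
per component — no MCMC inside the generator. Counts are drawn as
`y ~ Poisson(theta * E0)` with provisional exposure `E0_i = p_i/mean(p)`;
the analysis stage recomputes expected counts from realized totals exactly
as it would on real data (the true intercepts are therefore on the `E0`
scale; effects and weights are unaffected, and recovery tests target
those). Default truth: per-decile relative risks (1.12, 1.15, 1.21),
weights (0.60, 0.23, 0.09, six × 0.0133…), `sd_u = 0.1`, `sd_v = 0.2`,
`sd_s = 0.1` each, populations 200–4000 — moderate spatial heterogeneity
around outlet counts averaging a few per unit, the regime the model is
meant for.

**Listing generator.** Chain names are composed from a fixed vocabulary;
single-registry businesses use a disjoint local-name vocabulary so ground
truth stays unambiguous. Addresses are `<number> <street> <suffix>` with
suffix variants deliberately discordant between the two copies of a true
dual outlet (exercising suffix canonicalization); 30% of tobacco-registry
copies carry a `#<digits>` store number (exercising store-number
stripping). The alcohol-registry copy receives per-character typos
(substitute/delete/insert at `typo_rate`) and an isotropic Gaussian
coordinate perturbation with per-axis standard deviation `coord_jitter_ft`
— the standard geocoding-error convention. A configurable fraction of the
chain pool forms the known dual-product list.

**What passing tests show.** Recovery experiments demonstrate internal
consistency: data generated by the model, matched and refitted by the same
package, return the generating effects inside their credible intervals and
the dominant weight ranks, with converged chains. They do not validate the
model against real registries — real listings have richer name variation
(abbreviations, franchise renaming, multi-entity addresses), real
covariates have spatial structure the copula lacks, and real adjacency
graphs are irregular with islands. Linkage sensitivity/specificity numbers
are likewise specific to the simulated noise process.

## 5. Numerical details and limitations

* Problem sizes in the tests (10×10 to 15×15 lattices, 2 chains × 8,000
  iterations; 2,000 units for distributional checks) are the package's
  desk-scale defaults; all scale linearly in units × iterations.
* Likelihood bookkeeping caches `E·exp(eta)` within a sweep and refreshes
  it at the start of each sweep, bounding floating-point drift.
* Expected counts of exactly zero (a type with no outlets anywhere) are
  flagged at preparation and rejected by `fit`, since a flat-prior
  intercept for an all-zero outcome has no finite posterior mode.
* The greedy matcher is order-deterministic; exact similarity ties between
  distinct pair sets are broken by id order, not globally optimized.
* `gelman_rubin` returns NaN (with a warning) for a parameter with zero
  within-chain variance.
* At small numbers of areal units (a few hundred), the weight posterior is
  noticeably less concentrated than a sharply peaked truth — the Dirichlet
  prior keeps mass spread over the simplex — which narrows the spread of
  the estimated index and *inflates* the index effects `beta_k` by roughly
  10–15% in compensation. This is a property of the joint index model, not
  of the sampler (it persists unchanged under 5x-longer chains, and
  disappears when the weights are pinned); it shrinks as the number of
  units and the count totals grow. Credible-interval coverage of the
  effects at desk scale is correspondingly a little below nominal.
* Posterior storage keeps full spatial fields in memory
  (`chains × draws × n × 3` for `s`); a 15×15 lattice at 2×4,000 stored
  draws is ~50 MB. Longer reference-scale runs should thin.
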