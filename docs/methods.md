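# Methods

`comorbnet` implements a comorbidity-network analysis of ICD-10 outpatient
visit records for an elderly population: record cleaning and recoding, a
binary patient × disease matrix, Ising network estimation by eLasso,
weighted centrality, and fast-greedy modularity communities. Because
patient-level claims registries of this kind cannot be redistributed, the
package ships a synthetic-data module that generates both Gibbs-sampled
cohorts from known Ising models and messy raw record files with an exact
bookkeeping ledger; all validation runs against those ground truths or
against the published table-level aggregates.

## Model

Diseases are nodes of a pairwise binary Markov random field. With
`x ∈ {0,1}^p` a patient's disease profile, the joint is

    P(x) ∝ exp( Σ_{i<j} w_ij x_i x_j + Σ_i b_i x_i ),

whose conditionals are logistic:

    P(x_i = 1 | x_-i) = σ( b_i + Σ_{j≠i} w_ij x_j ).

`w_ij > 0` means the two diseases co-occur more often than their baseline
propensities predict (comorbidity); `w_ij < 0` means less often. `b_i` is
the baseline (threshold) of disease `i`.

### Estimation (eLasso)

Each node is regressed on all others with l1-penalized logistic regression
over a decreasing penalty path, and one model per node is selected by the
Extended BIC

    EBIC(λ) = −2 ℓ̂ + df·log n + 2 γ df log(p − 1),

where `df` counts non-zero slopes only (the intercept is unpenalized and
uncounted) and `γ = 0.25` by default. Binary predictors share a common
scale, so no standardization is applied before penalization. The λ path has
100 log-spaced values from `λ_max` (the smallest penalty zeroing all slopes
of the intercept-only model, `max_j |x_jᵀ(y − ȳ)|/n`) down to `0.01·λ_max`.
Directed coefficient pairs are symmetrized with the AND rule: an edge
survives only if both node-wise regressions select it, with weight the mean
of the two coefficients (OR available; AND edge sets are always subsets of
OR edge sets on the same fits).

### Path solver numerics

The solver is a warm-started IRLS/coordinate-descent scheme: at each outer
step the logistic loss is expanded to a quadratic with curvature weights
`p(1−p)` floored at `1e-6`, coordinate descent runs on the expansion over
the active set (current support plus KKT violators), and a step-halving
safeguard on the true penalized objective guarantees monotone progress.
Two guards bound worst-case work on near-separable, near-constant columns:
when the fraction of null deviance explained exceeds 0.999 the remaining
(smaller) penalties reuse the current solution, and after a total budget of
500 outer expansions per node path each remaining λ gets a single
warm-started expansion. Healthy fits converge far below both limits; a
pure-numpy FISTA implementation serves as an independent oracle in the test
suite (penalized objectives agree to ~1e-10 on small problems, asserted at
1e-6). A node whose column is constant cannot be regressed; it is returned
with zero slopes, a half-count-smoothed empirical log-odds intercept, and a
`degenerate` flag.

## ETL

Stage order (each stage logged as records-in/out/dropped in the
`ExclusionReport`):

1. **age window** — keep ages in [60, 99];
2. **deduplicate** — one record per (patient, disease), repeat visits
   collapse to the first occurrence;
3. **recode** — raw ICD-10 codes map to panel labels by exact or prefix
   match (longest source wins; sources of distinct rules must be disjoint,
   including by prefix, checked at load time); records that merge under one
   label re-deduplicate. Only well-formed ICD-10 codes (one uppercase
   letter, two digits, optional dot plus 1–3 digits) are eligible, so a
   garbled string can never be laundered into a valid label;
4. **invalid codes** — drop codes that neither satisfy ICD-10 rules nor are
   recognized recoded labels;
5. **non-chronic** — drop diseases outside the chronic allowlist (default:
   the 38 recoded panel labels shipped in `panel38.yaml`);
6. **low prevalence** — drop diseases below 1% prevalence. Prevalence is
   computed once, on the population entering this stage, with distinct
   patients as denominator (a `records` switch exists; the single-pass
   reading keeps the filter order-independent of the drops it causes);
7. **single disease** — drop patients left with one disease (uninformative
   for comorbidity).

The single-disease exclusion applies to the full recoded disease set,
*before* restriction to the analysis panel; rows that become single-one
within the panel are kept, so the matrix reflects panel restriction only.

**Panel construction**: the `n_top = 5` most prevalent diseases seed the
panel; for each, all other diseases rank by comorbidity rate — conditional
prevalence `P(other | index) = |A∩B| / |A|` by default, Jaccard optional —
and the top `n_comorbid = 40` pool into the panel (union, de-duplicated,
ordered by overall prevalence, ties lexicographic). On the study data this
yields a 38-label panel. The shipped `panel38.yaml` reconstructs the source
ICD-10 codes behind each merged label from the disease names' ICD-10
semantics; only two merged source sets are published, so the file is an
editable default, not an authoritative mapping.

**Sex-stratified sampling** draws `n_per_sex` matrix rows (default 150,000,
the study's per-sex sample) uniformly without replacement within each sex,
reproducibly under one named seed (default 20230601); a smaller stratum is
used whole with a warning. Sampling operates on matrix rows (patients); the
alternative record-level reading is not implemented.

Tie-breaking throughout is lexicographic by code.

## Centrality

On the estimated weighted network: strength `s_i = Σ_j |w_ij|`; paths use
the distance transform `d_ij = 1/|w_ij|` (absent edges are absent, not
zero-length); closeness is the *unnormalized* inverse total geodesic
distance to reachable nodes, undefined (printed "-") for isolated nodes and
component-restricted on disconnected graphs; betweenness is raw Brandes
shortest-path counting with fractional splitting of tied geodesics and
endpoints excluded, reported both raw and integer-rounded. Absolute weights
are used for all three indices: distances must be positive, and a node with
only negative associations still has positive strength. Consequences:
scaling all weights by `c > 0` scales strength and closeness by `c` and
leaves betweenness unchanged. The unnormalized-closeness convention is what
reproduces the published table's 0.004–0.008 range at 38 nodes.

## Communities

Clustering operates on the **positive subgraph** (negative edges dropped
and counted): the weighted modularity null model is ill-defined for
negative strengths, and comorbidity communities are positive groupings by
definition. Modularity is evaluated exactly as

    Q = 1/(2m) Σ_ij ( A_ij − γ k_i k_j / (2m) ) δ(c_i, c_j),

with `m` the total edge weight, `k_i` node strength, and resolution `γ = 1`
by default. Note the sum includes the `i = j` null term, so the
all-singletons partition of a single-edge pair scores `−γ/2`, not 0; the
fast-greedy detector therefore merges that pair (Q = 0). The detector is
the agglomerative CNM scheme: start from singletons, merge the community
pair with the largest `ΔQ = E_ab/m − γ k_a k_b/(2m²)` (ties broken by the
lexicographically lowest community-id pair, for determinism), record the
full merge history, and cut at the earliest maximum of Q along the path —
so zero-gain merges are not performed and isolated nodes remain singletons.
Exhaustive partition search bounds the greedy result on every fixture up to
8 nodes in the tests, with equality on planted-clique fixtures;
`python-igraph` cross-checks the modularity values (its fast-greedy takes
no resolution parameter, which is why the detector is implemented here).

## Synthetic data

`make_planted_network(p, k, w_in, w_out, b)` plants `k` near-equal blocks;
within-block pairs get weight `w_in` (independently with configurable
density, default 1.0 so the structure is unambiguous), between-block pairs
`w_out`, all thresholds `b`.

`gibbs_sample` runs a single systematic-scan (fixed node order) Gibbs chain
with burn-in 500 sweeps and thinning 10, chosen so small-`p` chains are
directly testable against exact `2^p` enumeration (total-variation distance
< 0.01 observed at n = 50,000 for p ≤ 4). One caveat discovered by that
enumeration and worth knowing when choosing parameters: dense
strongly-coupled blocks saturate. A 6-clique at `w_in = 1.5, b = −1` has
P(all ones) = 0.991 (7-clique: 0.998), so samples are nearly constant and
carry no pairwise information — this is a property of the model, not of the
sampler. Recovery experiments therefore either use small blocks (triangles
at `w_in = 1.5`) or weaker coupling for larger blocks (`w_in = 0.5,
b = −1.5` for 6–7-node blocks keeps marginals near 0.25–0.55); both settings
give exact or near-exact edge recovery at n = 10,000.

`make_record_file` emits a raw visit file shaped like the study's input:
patients with sex (default 50/50) and ages drawn from the published
four-band mix (47.28 / 33.99 / 14.37 / 4.36 %), disease profiles drawn
either iid from per-disease prevalences (default: smoothly declining
45%→3%) or from a planted Ising model, with every base patient carrying at
least two diseases (rejection sampling), plus injected artefacts in stated
numbers: exact duplicate visits, garbled codes, valid-but-non-chronic
diagnoses, out-of-window patients, single-disease patients, mergeable raw
code pairs, and an optional designated rare disease. The `RecordLedger`
retains the full assignment and injection bookkeeping and can predict every
exclusion-stage drop count exactly; ETL reproduces the ledger exactly on
every tested seed. The generator emulates marginal structure only — no
visit dates, no longitudinal dynamics, no realistic raw-code frequency
profile beyond the panel — so passing tests demonstrate correctness of the
pipeline's accounting and estimation, not calibration to any real registry.

## Descriptive tables

Percentages print to two decimals with half-away-from-zero rounding, which
reproduces the published tables' derivable cells exactly (21 of 22; one
printed cell, male 80–89 = 6.13%, is inconsistent with its own printed
counts, which give 6.12%). After deduplication one record equals one
(patient, disease) pair, so visit counts double as patient counts; all
percentages use total processed records as denominator. Age summaries are
record-weighted means ± SD (population SD) per sex and pooled; the pooled
mean equals the count-weighted mean of the stratum means by construction.

## Problem sizes

Tests and the acceptance script run at desk scale: recovery experiments at
n = 10,000 rows (10 seeds on the two-triangle fixture, 2–3 seeds at the
38-node block design), sampler exactness at n = 50,000 with p ≤ 4, ETL
ledger checks on 600–800-patient cohorts over 5 seeds, and the end-to-end
pipeline demonstration on a 4,000-patient cohort sampled to 1,500 rows per
sex. These sizes were chosen to keep the full validation cycle in minutes
while leaving estimator behaviour (EBIC selection, AND-rule sparsity)
representative.

## Limitations

- The estimator is pseudo-likelihood-based; edge weights are regularized
  conditional log-odds, not maximum-likelihood Ising couplings, and no
  confidence intervals or edge-stability bootstrap are provided.
- No covariate adjustment: sex is handled by stratification, age not at all.
- Closeness/betweenness conventions (absolute weights, unnormalized
  closeness) are one defensible choice among several; outputs record them
  so cross-study comparisons stay caveated.
- The signed network is clustered only through its positive part; signed
  modularity variants are out of scope.
- ICD-9 mapping, clinical severity weighting and visit-date handling beyond
  the age window are out of scope.
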