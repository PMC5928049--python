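# Methods

## The statistical model

Given a cohort of `M` samples whose somatic point-mutation status has been
determined over a gene background `G` (`|G| = N`), the data are a binary
indicator `f(g, s_j)` — 1 when gene `g` carries at least one point mutation
in sample `s_j`.  For a pathway gene set `P` (size `k`), each sample is an
independent Bernoulli trial that "succeeds" when the sample carries a
mutation in at least one member of `P`.  The test asks whether the number of
successful samples is larger than expected by chance — a population-level
question: no single sample needs to be individually enriched, and pathways
whose member genes are hit in a mutually exclusive fashion across samples
(different genes in different samples) are detected just as well.

Three interchangeable models supply the per-sample chance probability
`p_j = Pr(X_j >= 1)`, where `X_j` counts mutated members of `P` in sample
`s_j`:

* **hypergeom_genes** — draw the sample's `n_j` mutated genes from the
  `N`-gene background without replacement:
  `p_j = 1 − H(0; N, k, n_j)` with `H` the hypergeometric PMF.
* **hypergeom_length** — the same draw over nucleotides: `N′ = Σ_G λ(g)`
  and `k′ = Σ_P λ(g)` are total exonic block lengths and `n′_j` the
  sample's variant count; `p_j = 1 − H(0; N′, k′, n′_j)`.
* **bernoulli_length** (default) — a Poisson nucleotide model,
  `p_j = 1 − exp(−ρ_j k′)`, with `ρ_j` the per-nucleotide background
  mutation rate.  Expanding the exponent sums per-gene contributions
  `ρ_j λ(g)`, so gene lengths enter gene by gene.

A `user` kind accepts any callable `(sample index, gene set, dataset,
lengths) → probability`, which is how covariate-aware models (trinucleotide
context, expression, chromatin state) can be plugged in; the engine only
validates the returned range.

With `π = {p_j}`, the count of altered samples `O(P)` follows a
Poisson-binomial distribution with mean `E(P) = Σ_j p_j`.  The pathway
alteration score is `Δ(P) = log10(O/E)` and the p-value is the exact upper
tail `Pr(O(P) ≥ z)` at the observed `z`.  The PMF is computed by iterative
convolution (O(M²), exact); no normal or saddlepoint approximation is used,
and a 2^M subset-enumeration oracle cross-validates the convolution in the
test suite.  Because the statistic is "at least one mutation per sample",
hypermutated samples cannot saturate the signal: their trials simply have
`p_j` near 1.

After testing all pathways that survive the pre-test filters, p-values are
adjusted (Bonferroni, Benjamini–Hochberg, or Storey q-values) and each
pathway receives an exclusive coverage score `C(P) = 100·O′(P)/O(P)`, where
`O′(P)` counts samples with *exactly one* mutated member.  A pathway is
called enriched when `FDR < 5%` **and** `C(P) > 50%` (defaults); high
exclusive coverage — mutual exclusivity across samples — is read as
additional evidence of positive selection rather than co-occurring
passenger load.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `model` | `bernoulli_length` | per-sample probability model |
| `rho` | `auto` | per-nucleotide rate; `auto` estimates `ρ_j = n′_j/N′` per sample, or a fixed value such as 1e-6/nt |
| `min_mutated_sample_fraction` | 0.05 | pathway must be altered in ≥ `ceil(0.05·M)` samples |
| `min_distinct_mutated_genes` | 2 | ≥ 2 distinct member genes mutated anywhere in the cohort |
| `fdr_method` / `fdr_threshold` | `bh` / 0.05 | multiple-testing control across *tested* pathways |
| `ec_threshold` | 50 (%) | exclusive-coverage flag threshold (strict `>`) |
| `storey_lambda` | 0.5 | fixed-λ null-proportion estimator for q-values |

Collection preprocessing drops gene sets with fewer than 4 or more than
1,000 genes (bounds inclusive) and compresses redundancy: sets with
pairwise Jaccard similarity strictly above 0.8 are linked, each connected
component is replaced by the *intersection* of its members under a joint
" // " label, and the members are discarded.  One compression round is
applied; residual over-threshold pairs among the outputs are reported, not
re-merged, and merged intersections that fall below the minimum size are
dropped with an explicit report entry (an intersection can annihilate under
loose chaining, and documented loss beats silent emptiness).

## Design choices where the design was open

* **ρ estimation.**  The per-sample estimate `ρ_j = n′_j/N′` uses the
  sample's total point-mutation count over the background exonic length,
  falling back to the mutated-gene count when variant multiplicities are
  unavailable (binary matrix input).  A fixed global rate is available via
  configuration.
* **FDR scope.**  Adjustment runs across pathways that survive the
  pre-test filters only; the filters are applied before any test statistic
  is computed.  The exclusive-coverage criterion is applied *after* FDR as
  a flag — rows failing it stay in the table with `is_enriched = False` —
  because exclusivity filters enrichments, it does not re-test them.
* **Waterfall sort.**  Mutual-exclusivity (oncoprint-style) ordering sorts
  genes by mutation count descending (ties alphabetically) and samples by
  their binary vector read as a number in that gene order, descending; a
  pure, idempotent permutation.
* **Core components.**  Enriched pathways are clustered by Jaccard ≥ 0.3
  into connected components; each component's core is the genes present in
  a strict majority of member sets (for a pair, the intersection; for a
  singleton, the set itself).
* **Probability clamp.**  `p_j` is clamped to `[0, 1 − 1e-12]` before the
  Poisson-binomial stage so that a single near-certain sample cannot force
  a degenerate distribution.
* **Hypergeometric evaluation** runs in log space (log-gamma) with
  `Pr(X ≥ 1) = −expm1(log H(0))`, exact to ~1e-10 even for megabase-scale
  backgrounds.
* **Symbol updating** is a pure rewrite against a user-supplied static
  old→new table; collisions are merged by logical OR (datasets) or set
  union (gene sets), with counts reported.  No live nomenclature service is
  queried.

## The synthetic cohort generator

The generator is first-class, tested code and defines the study conditions
for every statistical claim the package makes about itself.  It emulates:

* log-normal exonic gene lengths (median 1,500 bp, σ = 0.8);
* heterogeneous per-sample burdens — negative-binomial with mean 46
  mutations per sample and dispersion 2, spanning the range seen across
  real cohorts (tens for low-burden carcinomas to hundreds for melanoma);
* a background process placing a Poisson number of point mutations on each
  gene with intensity `ρ_j λ(g)`, `ρ_j = burden_j/N′`.  The indicator is
  `count > 0` and multiplicities are carried, so the marginal gene-mutation
  law is exactly `1 − exp(−ρ_j λ(g))` — the generative twin of the default
  analysis model — and the per-sample variant total is Poisson(burden),
  making the `auto` rate estimate unbiased.  Null cohorts therefore test
  calibration under the exactly-specified model; a deliberately
  mis-specified mode (`length_aware_background=False`, uniform per-gene
  probabilities) probes robustness separately from correctness.
* planted pathways: dedicated member genes whose mutation *rate* is
  multiplied by the effect size (`p′ = 1 − (1−p)^effect`, i.e. `effect·p`
  to first order — applying the effect on the hazard scale keeps a valid
  probability for hypermutated samples, where a linear probability
  multiplier would exceed 1).  In mutually exclusive mode, a pathway-level
  hit is drawn per sample and exactly one member gene assigned round-robin,
  giving deterministic 100% exclusive coverage before noise.

What the generator does *not* emulate: mutational signatures
(trinucleotide context), copy-number events, indels, gene–gene correlation
beyond pathway planting, or cohort substructure.  Passing tests therefore
demonstrate statistical correctness and robustness of the machinery under
the stated model, not biological validity on any particular tumour cohort.

Noise injection models imperfect variant calling: at sensitivity `s` each
call is kept independently with probability `s`; at specificity `q`, zero
cells are flipped so the expected false-positive count is `(1−q)/q` times
the current call count — specificity is defined against calls, not against
the full `N×M` cell space, where even 1% would imply absurd counts.
Robustness is scored as ranked retrieval of the noise-free enriched set:
the AUROC of the perturbed run's evidence, where the enrichment call
dominates and the p-value breaks ties.  This makes zero-noise recovery
exactly 1 by construction (a pure p-value ranking cannot guarantee that,
since a low-p pathway can fail the exclusivity flag).

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the pipeline at desk scale,
chosen to keep Monte-Carlo error small while the whole suite stays fast:
null calibration pools 1,200 pathway tests (4 seeds × 300 pathways,
M = 200, N = 2,000 genes); power uses 50 replicates of a 374-pathway
collection with one 8-gene mutually exclusive pathway planted at 5× in a
100-sample cohort; robustness uses 10 replicates per sensitivity level on
a 150 + 8 pathway collection; down-sampling draws 50 half-cohorts.

## Known limitations

* The Poisson-binomial test is exact but discrete, hence mildly
  conservative at small `M`; it is never anti-conservative under the
  generating model (verified empirically in the calibration tests).
* With binary-matrix input, variant multiplicities are unknown and
  `n′_j = n_j` is assumed; driver-excluded re-analysis then removes
  alterations at gene resolution.  Pair-table input preserves
  multiplicities and subtracts them exactly.
* Sample-wise independence is assumed; related samples or batch-shared
  artefacts violate the null.
* Gene sets are treated as flat sets — no topology, direction, or edge
  information is used.
* The shipped hallmark keyword map is a small demonstration; any serious
  hallmark analysis should supply a curated map through the same
  interface.
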