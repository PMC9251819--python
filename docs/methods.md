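# Methods

## Scope and data model

`symptomnet` analyzes item-level scores from three clinician-rated
instruments commonly collected in first-episode psychosis cohorts:

| Instrument | Items | Range | Communities |
|---|---|---|---|
| PANSS | 30 (P1–P7, N1–N7, G1–G16) | 1–7 | positive (7), negative (7), general (16) |
| CDSS  | 9 (CDSS1–CDSS9) | 0–3 | depression (9) |
| PSP subscores | 4 (PSP-A–PSP-D) | 0–6, higher = worse | functioning (4) |

The canonical node order is fixed (P, N, G, CDSS, PSP, numbered within
block) so that matrices are comparable across runs. The global PSP total
(0–100, higher = better) is carried as per-participant metadata only; the
network always has exactly 43 nodes. The clinician's global severity rating
(CGI) is not represented. The default community partition for bridge
statistics is the five instrument/subscale blocks above; it is an explicit,
logged argument because domain partitions are an analytic choice, not a
property of the data. No reverse-coding is applied: all 43 items score
pathology upward, including the PSP subscores.

Missing data: the strict reader rejects any incomplete or out-of-range row
with row/column diagnostics; the lenient reader drops such rows and logs
the count. Complete-case analysis is the only supported mode — it is the
most conservative reproducible default for rating-scale data.

## Network estimation

1. **Correlation input.** Pearson (default), Spearman, or polychoric.
   Polychoric correlations are estimated per pair by two-step maximum
   likelihood: thresholds from the marginal category proportions (normal
   quantiles), then a bounded 1-D likelihood maximization over ρ using a
   deterministic bivariate-normal CDF (Owen's T function). A pair that
   fails to converge falls back to Spearman with a warning. Pearson is the
   default because it is deterministic, fast and adequate for 4–7-category
   items; polychoric is exposed for users who want the latent-scale
   correlations. Non-PSD matrices are repaired by eigenvalue clipping at
   1e−8 with diagonal renormalization, and flagged.
2. **Graphical lasso.** Block coordinate descent (one L1-penalized
   regression per column subproblem, solved by coordinate descent),
   implemented with numba. The penalty applies to off-diagonal precision
   entries only, so shrunk-out edges are exactly zero. Convergence: maximum
   absolute change of the working covariance between sweeps < 1e−5, cap 500
   sweeps; the inner lasso tolerance is one-tenth of that. The
   implementation supports an elementwise penalty matrix, which the scalar
   path uses with a constant matrix.
3. **Path and selection.** λ runs over a 100-point log-spaced grid from
   λ_max = max off-diagonal |S| (which yields the empty network) down to
   0.01·λ_max, with warm starts. The EBIC (γ = 0.5) selects the model; ties
   within 1e−9 keep the larger λ, i.e. the sparser network, for
   determinism. Sample-size convention: `S` uses denominator n and the
   likelihood is ℓ = (n/2)(log det K − tr(SK)); n enters the procedure only
   through the EBIC.
4. **Adaptive variant.** Behind a flag, a two-stage fit with per-edge
   penalty factors `1/|W̃_ij|^0.5` from a ridge pre-fit
   (`K̃ = (S + 0.1 I)^{-1}`, factors normalized to mean 1). The plain lasso
   is the reported default.

## Node-level inference

Strength, expected influence (one-step by default, two-step behind a
flag), predictability `R²_i = 1 − 1/K_ii` (clipped to [0, 1]; valid because
the model is fitted to a correlation matrix, i.e. standardized variables),
bridge strength, and bridge betweenness, as defined in the README. Bridge
betweenness uses distances `1/|W_ij|` (negative edges by absolute weight,
the convention of the standard bridge-centrality tooling); tied shortest
paths give each intermediate node fractional credit `1/m`. Predictability
is read off the model-implied precision rather than re-regressing each node
on the data: it is deterministic and consistent with the Gaussian model
actually fitted.

Bridge-node selection takes the top `ceil(fraction · p)` nodes by bridge
strength (default fraction 0.20 → 9 of 43), breaking ties by canonical node
order.

## Stability diagnostics

* **Edge bootstrap** (default B = 1000): participants resampled with
  replacement at the original n; the full pipeline (correlation, path,
  EBIC) reruns per replicate; per-edge quantile intervals at level α
  (default 0.05). Only edges nonzero in the point estimate are reported by
  default — bootstrap intervals of regularized zeroed edges are not
  significance tests. Replicates whose estimation fails are dropped and
  counted; more than 10% failures aborts.
* **Case-dropping bootstrap** (default B = 500, grid 0.05–0.75 in steps of
  0.05): subsamples retain `ceil((1−q)·n)` rows without replacement;
  the Pearson correlation between full-sample and subsample centrality
  vectors is recorded per replicate.
* **CS coefficient**: largest q whose replicate correlations reach ≥ 0.7
  with probability ≥ 0.95. The 0.7/0.95 constants are the conventional
  choice and are exposed as arguments.

One master seed spawns independent per-replicate RNG streams
(`numpy.random.SeedSequence.spawn`), so every resample's row indices are
reproducible and independent of execution order.

## Synthetic cohorts

The generator is a latent-Gaussian threshold model, the standard
psychometric data-generating assumption compatible with a GGM analysis:

1. **Ground truth.** A sparse partial-correlation structure with
   within-community edge probability 0.3, between-community probability
   0.02, magnitudes uniform in (0.2, 0.4), and a 0.1 probability of a
   negative sign (clinical symptom networks are predominantly positive).
   Four *bridge nodes* each receive two strong (0.4, positive)
   cross-community edges; four is a realistic number of planted connectors
   that leaves room inside the 9-node top-20% selection set. The precision
   matrix is `I − W₀` with the off-diagonal block shrunk geometrically
   until the smallest eigenvalue is ≥ 0.05; the shrinkage preserves the
   zero pattern, and the stored ground-truth partials are recomputed from
   the final precision.
2. **Sampling.** n = 446 latent multivariate-normal vectors with the
   implied latent correlation matrix, discretized per item through ordered
   thresholds. Default thresholds are right-skewed (cumulative category
   probabilities `(k/C)^0.6`), putting more mass at low severity as in real
   clinical item distributions; uniform thresholds are a config switch.
   The skew matters because discretization attenuates Pearson correlations.
3. **Demographics.** Age ~ Normal(40.0, 10.9) truncated to [18, 65]; sex ~
   Bernoulli(0.70 male). A synthetic global PSP total is attached as a
   noisy monotone inverse of the mean PSP subscore, clipped to [0, 100]; it
   is *not* the official PSP scoring algorithm, just structurally
   consistent metadata.

What the generator does **not** emulate: real per-item marginal
distributions (only subscale-level summaries of real cohorts are ever
published), item-specific threshold asymmetries, longitudinal structure,
treatment effects, dropout, site effects, or diagnosis subgroups. Passing
recovery tests on these cohorts therefore shows that the estimation and
inference machinery is correct under the model's own assumptions — not
that any particular clinical finding would replicate.

## Numerical and design choices

* Graphical lasso solutions are validated three ways in the test suite:
  against a brute-force numerical maximizer of the penalized objective
  (Cholesky-parametrized, smoothed |·|), against scikit-learn's
  `graphical_lasso`, and against closed-form limits (empty network at
  λ ≥ max|S|; marginal correlation at p = 2, λ = 0).
* Degenerate inputs: zero-variance items are rejected by name; an
  unpenalized fit on a singular correlation matrix raises with advice to
  use λ > 0; an empty estimated network yields zero centralities,
  undefined (reported-as-missing) case-drop correlations, and CS = 0.
* Layout: weighted Fruchterman–Reingold (networkx `spring_layout`,
  attraction ∝ |weight|, seeded), rescaled to the unit square; figures are
  styled per convention (blue positive, red negative, width ∝ |weight|,
  bridge nodes highlighted) with no attempt at pixel parity with any
  published figure.
* The pipeline manifest hashes all table outputs (CSV/JSON/GraphML) so
  re-runs can be verified byte-for-byte; figures are excluded from hashing
  because image encoders do not guarantee byte stability across library
  versions.
* Problem sizes in the test suite: recovery properties use 20 seeds at the
  full n = 446, p = 43 design with a 40-point λ path (the criterion path
  density, chosen to keep the 20-seed sweep brisk; end-user default stays
  100); bootstrap logic is exercised on a 6-node schema with B in the tens,
  since the resampling machinery is size-agnostic. The full-scale
  coverage simulation (B = 500, 20 truth seeds, p = 43) is a multi-hour
  computation and is represented in the suite by a reduced-scale version
  with the same logic.

## Known limitations

* Pearson correlations on skewed ordinal items are attenuated relative to
  the latent scale; edge weights are therefore conservative. Use
  `method="polychoric"` when latent-scale effect sizes matter (slower:
  ~900 pairwise likelihood maximizations at p = 43).
* EBIC with γ = 0.5 is deliberately conservative; weak true edges (partials
  near 0.2 at n ≈ 450) are frequently missed, which is the expected
  sensitivity/specificity trade-off of regularized estimation.
* Bootstrap confidence intervals inherit regularization bias: they describe
  the sampling variability of the *penalized* estimator and under-cover
  strong true partials; they are not significance tests.
* Bridge betweenness is computed exactly (all tied shortest paths); on
  dense networks much larger than 43 nodes this may become slow.
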