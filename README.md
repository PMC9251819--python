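# symptomnet

Network analysis of item-level clinical rating data for first-episode
psychosis: estimation of a regularized Gaussian graphical model over the 43
items of three clinician-rated instruments — the PANSS (30 items, scored
1–7), the Calgary Depression Scale for Schizophrenia (9 items, 0–3) and the
Personal and Social Performance scale (4 domain subscores, 0–6) — together
with the node-level inference and stability diagnostics used in the
symptom-network literature.

The package is aimed at researchers who want to study how psychopathology
and real-world functioning interconnect at the level of individual symptoms:
which symptoms are most central, which act as *bridges* between symptom
domains (e.g., between depression and psychosis, or between positive
symptoms and functioning), and how robust those conclusions are to sampling
variability. Because item-level clinical trial data are typically
restricted, the package ships a seeded synthetic-cohort generator that
emulates the instruments' ordinal structure, so every stage of the pipeline
is runnable and testable end to end.

## The model

Let `X` be the n × p matrix of item scores (p = 43). A Gaussian graphical
model represents conditional dependencies: given a correlation matrix `S`,
the precision matrix `K` is estimated by maximizing the L1-penalized
log-likelihood

```
log det K − tr(S K) − λ Σ_{i≠j} |K_ij|
```

(graphical lasso, block coordinate descent). Edge weights are partial
correlations `W_ij = −K_ij / √(K_ii K_jj)`; the lasso penalty shrinks small
edges to exactly zero. The penalty λ is chosen on a log-spaced path by
minimizing the extended Bayesian information criterion

```
EBIC = −2 ℓ(K) + E log n + 4 γ E log p ,   ℓ = (n/2)(log det K − tr(S K)) ,
```

with γ = 0.5 by default (γ = 0 gives the BIC). On the selected network the
package computes, per node *i*:

* **strength** `s_i = Σ_j |W_ij|` and **expected influence**
  `EI_i = Σ_j W_ij` (signed; negative when negative edges dominate);
* **predictability** `R²_i = 1 − 1/K_ii`, the variance of node *i*
  explained by all other nodes under the fitted model;
* **bridge strength** `BS_i` (the part of `s_i` crossing community
  boundaries) and **bridge betweenness** `BB_i` (inter-community shortest
  paths through *i*, with distances `1/|W_ij|`), using the five
  instrument/subscale communities (PANSS-positive, PANSS-negative,
  PANSS-general, CDSS, PSP) by default;
* the **bridge nodes**: the top 20% of nodes by bridge strength
  (`ceil(0.2 × 43) = 9` nodes).

Stability is assessed by a nonparametric edge-weight bootstrap (quantile
CIs) and a case-dropping bootstrap summarized by the correlation-stability
coefficient (CS): the largest proportion of participants that can be
dropped while the subsample-to-full centrality correlation stays ≥ 0.7 with
95% probability.

## Worked example

```python
import symptomnet as sn

# a synthetic 446-participant cohort from a known sparse ground truth
table, truth = sn.simulate_cohort(sn.SimConfig(seed=1))

model = sn.estimate_network(table)            # lasso path + EBIC selection
rep = sn.centrality_report(model)             # strength, EI, R², bridges
print(f"n = {table.n}, lambda = {model.lam:.4f}, edges = {model.n_edges}")
print("bridge nodes:", ", ".join(rep.bridge_nodes))
print("planted bridge nodes:", ", ".join(truth.bridge_node_ids))
```

prints

```
n = 446, lambda = 0.1323, edges = 117
bridge nodes: P7, N7, G3, G6, G7, CDSS6, CDSS9, PSP-B, PSP-D
planted bridge nodes: G3, N7, P7, PSP-D
```

The EBIC-selected penalty (λ ≈ 0.13) retains 117 of the 903 possible edges,
and the 9-node top-20% bridge set contains all four cross-community
connectors planted in the generating model. The same analysis is available
from the shell:

```
symptomnet simulate --seed 1 --out data/
symptomnet estimate --in data/cohort.csv --out net/
symptomnet centrality --in data/cohort.csv --out centrality.csv
symptomnet run --seed 1 --out results/   # full pipeline incl. figures
```

`sklearn` users can treat `sn.GaussianGraphicalModel(method="pearson",
gamma=0.5)` as an ordinary estimator (`fit`, `get_params`, cloning, fitted
attributes `weights_`, `precision_`, `lambda_`, ...).

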