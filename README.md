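# consentropy

Consensus clustering and entropy diagnostics for spatially aware clustering
(SAC) of spatial omics data.

Dozens of methods exist for partitioning spatially resolved transcriptomics
observations (spots, cells, bins) into spatial domains, and their outputs
disagree — across methods, configurations, and even random seeds. Manual
anatomical annotations, the usual "ground truth", carry their own biases.
Instead of crowning a single winner, `consentropy` aggregates the cluster
labelings produced by many methods into a **consensus labeling** and maps
**where** the ensemble agrees and disagrees, so that method disagreement
becomes a signal a tissue expert can act on rather than noise to average
away.

It is aimed at analysts who already have per-sample cluster labelings from
several SAC methods (any tools — only their label tables are needed, in a
plain TSV/JSON format) and at method developers who want ensemble baselines
and disagreement maps on synthetic tissues with known structure.

## What it computes

**Entropy diagnostics** (natural log, values in nats):

- *Smoothness entropy (SE)* of one labeling: for each observation i, the
  Shannon entropy H of the labels in its k-nearest-neighbor neighborhood
  (itself included, default k = 6), averaged over observations. Lower SE
  means spatially smoother domains.
- *Cross-method entropy (CME)* across M labelings: cluster codes are first
  matched to a reference labeling with the Hungarian method on the
  confusion matrix; the per-observation entropy across the M aligned labels
  is then averaged over all M choices of reference. High-CME regions are
  where methods disagree.

**Consensus algorithms** over the N×M matrix of base cluster labels:

- *K-modes* — partitions observations into K groups minimizing the total
  Hamming distance to each group's column-wise mode vector.
- *Latent class analysis (LCA)* — a categorical mixture model
  P(x_i) = Σ_k π_k Π_m θ_{mk,x_im} fitted by EM; the latent class is the
  consensus cluster.
- *Weighted Jensen–Shannon consensus* — finds a consensus co-association
  matrix S and per-method weights ω by minimizing

      Σ_m ω_m JSD(S ‖ S^(m)) + λ Σ_m ω_m log ω_m,   Σ_m ω_m = 1, ω ≥ 0,

  where S^(m) is the binary co-association matrix of base clustering m and
  JSD is applied entrywise to Bernoulli parameters; S is then partitioned
  with the Leiden algorithm (with a binary search over the resolution when
  a target cluster count is requested). The weights report how much each
  method shaped the consensus.

**Selection and validation**: class-imbalance filtering (drop labelings
with one cluster holding > 90% of observations), concordance-block
detection on the pairwise-ARI matrix (hierarchical clustering, Euclidean
distance, complete linkage), smoothest-per-algorithm ranking, leave-one-out
pseudo-ground-truth ARI, and a mean-CME sweep over (number of clusters ×
number of methods) to find the granularity the ensemble supports best.

**Synthetic tissues**: a lattice generator with layered or block domains
plus a noise model (label flips, boundary jitter, domain merges/splits,
label permutation) emulating the outputs of disagreeing SAC methods, so the
whole workflow is testable without any external data.

## Worked example

```python
import numpy as np
from consentropy import (generate_tissue, default_noise_specs, generate_collection,
                         smoothness_entropy, cross_method_entropy, lca_consensus)
from sklearn.metrics import adjusted_rand_score

# a 24x20 lattice tissue with 4 layered domains, observed by 8 noisy "methods"
tissue = generate_tissue("layers", n_rows=24, n_cols=20, n_domains=4, seed=0)
specs = default_noise_specs(m=8, seed=1)
coll, gt = generate_collection(tissue, specs)

se = [smoothness_entropy(coll.column_labeling(m))[1] for m in range(coll.n_labelings)]
print("per-method smoothness entropy:", np.round(se, 3))

cme = cross_method_entropy(coll)
print(f"mean cross-method entropy: {cme.mean():.3f} nats")

result, model = lca_consensus(coll, k=4, seed=0)
print(f"consensus ARI vs ground truth: {adjusted_rand_score(result.labels, tissue.gt_labels):.3f}")
```

prints

```
per-method smoothness entropy: [0.556 0.518 0.546 0.532 0.537 0.503 0.548 0.503]
mean cross-method entropy: 0.512 nats
consensus ARI vs ground truth: 0.798
```

The eight base clusterings each carry 10% flip noise plus boundary jitter
and individually reach at best ARI ≈ 0.51 against the true domains; the
LCA consensus of all eight reaches ARI ≈ 0.80. The CME field (`cme.values`)
localizes the residual uncertainty along the domain boundaries.

The consensus algorithms are also available as scikit-learn-style
estimators (`KModesConsensus`, `LCAConsensus`, `WeightedJSDConsensus`) with
`fit` / `fit_predict` / `labels_` on the N×M label matrix, so they compose
with sklearn pipelines and model selection.

## Command line

The same workflow is scriptable via the `consentropy` CLI, one subcommand
per stage, all speaking a tab-separated dialect (`obs_id<TAB>label`,
`obs_id<TAB>x<TAB>y`, optional `*.meta.json` provenance sidecars):

```sh
consentropy simulate --n-domains 4 --m 8 --seed 0 --outdir sim/
consentropy metrics   --coords sim/coords.tsv --labels sim/labeling_00.tsv ... --outdir out/
consentropy select    --coords ... --labels ... --n-groups 2 --n-smoothest 6 --outdir out/
consentropy consensus --coords ... --labels ... --algorithm lca --k 4 --outdir out/
consentropy loo       --coords ... --labels ... --k 4 --outdir out/
consentropy sweep     --coords ... --labels ... --n-values 2,4,6 --outdir out/
```

Every run writes a `resolved_config_*.json` next to its outputs; rerunning
with the same config and seed reproduces every artifact byte-for-byte.

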