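# slgnn — factor-aware knowledge-graph neural network for synthetic-lethality prediction

Synthetic lethality (SL) is a genetic interaction in which knocking out two
genes together kills a cell while either single knockout is tolerated — the
mechanism behind PARP-inhibitor therapy in BRCA-mutant cancers. Screening
gene pairs in the lab is slow and expensive, so computational ranking of
candidate SL pairs from prior knowledge is widely used. This package
implements **SLGNN**, a graph neural network that predicts SL gene pairs
from two inputs:

* a biomedical **knowledge graph** (KG) of typed entities and relations,
  given as `(head, relation, tail)` triples (genes, biological processes,
  pathways, compounds, diseases, ...);
* an **SL graph** of known interacting gene pairs.

Its distinguishing idea is that SL interactions arise from a small number
of latent mechanisms — *SL-related factors* such as co-participation in a
repair pathway — and that each factor can be modeled as a **trainable
combination of KG relations**, which makes the learned factors nameable and
the predictions interpretable.

## Model

With entity embeddings `e_i`, relation embeddings `e_r`, and factor set `P`:

* **Factors** (trainable coefficients `α`):
  `e_p = Σ_r α(r,p) · e_r`, with a distance-correlation penalty
  `L_IND = Σ_{p≠p'} dCor(e_p, e_p')` keeping factors independent.
* **KG message aggregation** (explicit relation products, no attention):
  `e_i^(l+1) = (1/|N_i|) Σ_{(r,j)∈N_i} e_r ⊙ e_j^(l)`, and
  `e_i = e_i^(0) + … + e_i^(L)`.
* **Factor-based SL aggregation**: per-gene factor attention
  `β(i,p) = softmax_p(e_pᵀ h_i^(l))`; one GAT per factor over SL neighbors,
  `h_{i,p}^(l+1) = Σ_{j∈N_i} γ_p(i,j) e_j^(l+1)` with LeakyReLU-scored
  attention `γ_p`; fusion `h_i^(l+1) = Σ_p β(i,p) · e_p ⊙ h_{i,p}^(l+1)`;
  a second independence penalty `L_GAT` on the gene-averaged per-factor
  outputs; and `h_i = h_i^(0) + … + h_i^(L)`.
* **Scoring and loss**: `ŷ_ij = σ(h_iᵀ e_j)` (averaged over both pair
  orientations by default, since SL is unordered), trained with
  `L = L_BCE + λ1 (L_IND + L_GAT) + λ2 L_norm` by full-batch Adam with
  early stopping on validation AUC.

The whole model — including a compact reverse-mode autodiff engine it runs
on — is implemented in NumPy; see `docs/methods.md` for assumptions,
defaults and numerical choices.

Because the original SL databases require an external download, the package
ships a **planted-factor synthetic benchmark generator**: relations are
partitioned across K hidden factors, genes get factor memberships, KG
triples link genes to factor-specific context entities, and SL edges are
drawn preferentially within factors. The ground truth (relation→factor map,
per-gene memberships, per-edge generating factor) makes every stage of the
model testable.

## Worked example

```bash
# generate the default benchmark: 300 genes, 6 relation types, 4 planted
# factors, 3000 KG triples, 900 SL edges, signal 0.9
slgnn simulate --out bench --seed 0

cat > config.yaml <<EOF
dim: 32
n_layers: 2
n_factors: 4
lr: 0.02
max_epochs: 300
patience: 40
seed: 1
EOF

slgnn train --kg bench/kg.tsv --sl bench/sl.tsv --config config.yaml --out run
# test AUC 0.7616  AUPR 0.7325  F1 0.7426

slgnn explain --model run
# factor 0: r3_associates (-0.928), r2_binds (-0.703)
# factor 1: r1_regulates_rev (-0.810), r5_interacts (+0.665)
# factor 2: r3_associates (-0.750), r5_interacts (+0.604)
# factor 3: r5_interacts (+0.630), r5_interacts_rev (+0.579)
# mean pairwise factor dCor: 0.9007

printf 'g0007\tg0012\ng0003\tg0290\n' > queries.tsv
slgnn predict --model run --pairs queries.tsv
# g0007 g0012 0.690
# g0003 g0290 0.227
```

The train command reports held-out metrics on a stratified 8:1:1
train/validation/test split of the positive pairs plus an equal number of
sampled non-edges: AUC is the probability a held-out SL pair outranks a
non-edge (0.76 here, against a 0.58 degree-product null and a 0.81 ceiling
for an oracle that knows the planted factor memberships). `explain` lists
each factor's highest-|α| KG relations — the interpretability surface — and
the mean pairwise distance correlation between factor embeddings (near 1
means the factors have collapsed to similar directions; increase `lam1` to
force them apart). `predict` scores arbitrary gene pairs with the trained
model; here the first query pair shares a planted factor and the second
does not. A 5-fold cross-validated run is available via `slgnn cv`.

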