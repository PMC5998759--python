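# rwrdti

Drug–target interaction (DTI) prediction with **random-walk-with-restart
(RWR) feature weighting** on interactome networks.

Identifying which proteins a small-molecule drug binds is central to drug
discovery, and assay-based identification is slow and expensive. Feature-based
machine-learning models predict DTIs from a drug's substructure fingerprint
and a protein's sequence descriptors, and they improve when the features are
informed by interaction networks: a protein is more likely to bind a drug if
its interaction partners do ("guilt by association"). One-hop neighbor
averaging, however, ignores everything beyond direct neighbors. This package
weights drug and protein features with the **global** network topology
instead: a random walk with restart, run separately on the protein–protein
interaction (PPI) network and on the drug–drug interaction (DDI) network
(drugs linked when they share a target), assigns every node an affinity to a
seed node, and those affinities linearly mix feature vectors across the whole
interactome. A k-nearest-neighbor classifier with the cubic (Minkowski
exponent-3) distance is then trained on the weighted drug–protein pair
vectors.

Intended users: computational drug-discovery researchers who have a PPI edge
list (HIPPIE-style confidence scores), a DTI pair list (DrugBank-style),
1024-bit drug fingerprints and protein FASTA sequences — or who want to study
the method itself on fully synthetic, structure-planted data.

## The model

For a network with column-stochastic normalized adjacency $\tilde{A}$ and a
seed indicator vector $q$, the walker distribution iterates

$$r \leftarrow (1 - c)\,\tilde{A} r + c\,q$$

until convergence. The restart probability $c \in (0, 1]$ (default **0.25**)
sets how much of the seed's original signal is retained: the fixed point
satisfies $r_{seed} \ge c$ and $\sum_j r_j = 1$ within the seed's connected
component. Stacking the fixed points row-per-seed gives the affinity matrix
$W$ ($W^p$ for proteins on the PPI, $W^d$ for drugs on the DDI), and features
are weighted by the matrix product

$$D' = W^d D, \qquad P' = W^p P,$$

so each entity's weighted feature vector is a convex combination of its
network neighborhood's features. A pair $(d_i, p_j)$ is the concatenation of
the 1024-bit fingerprint row and the 1287-dim protein descriptor row
(amino-acid composition 20, dipeptide composition 400, normalized
Moreau-Broto / Moran / Geary autocorrelations 240 each, and
composition/transition/distribution descriptors 21 + 21 + 105) — 2311
dimensions in total. Training balances the known positives with an equal
number of randomly sampled non-interacting pairs, replicated over 20
independent negative sets; classification scores are the positive fraction
among the $k$ cubic-distance-nearest training pairs,

$$d(x, y) = \Big(\sum_i |x_i - y_i|^3\Big)^{1/3},$$

and performance is reported as mean ± sd AUC over the replicates, with a
paired t-test when two weighting schemes are compared. The one-hop
guilt-by-association weighting is included as a baseline.

## Worked example

The synthetic generator plants exactly the structure the method exploits: a
modular PPI (stochastic block model), drugs targeting proteins inside one
module (so module co-drugs share targets and form DDI cliques), and
module-templated fingerprints. Held-out test interactions follow the same
rule but are excluded from training.

```python
from rwrdti import generate_world, DTIPropagationModel
from rwrdti.descriptors import descriptor_matrix
from rwrdti.evaluation import paired_t_test

world = generate_world(rng_seed=11)          # 4 modules x 25 proteins x 5 drugs
prot = descriptor_matrix(world.sequences)    # 100 x 1287 descriptors

model = DTIPropagationModel.from_world(world, protein_features=prot,
                                       weighting="rwr", restart_c=0.25)
res = model.fit(rng_seed=11)
report = res.evaluate_world(world, rng_seed=11)
print(res.summary(test_report=report))
```

```
      DTI propagation model — cubic kNN on weighted features
====================================================================
weighting:              rwr (c = 0.25)
drugs / proteins:       20 / 100
positive pairs:         60
negative replicates:    20 x 60 pairs
pair vector width:      2311 (1024 drug + 1287 protein)
kNN neighbors (k):      10
score threshold:        0.62
fit rng seed:           11
--------------------------------------------------------------------
held-out AUC:           0.6415 (+/- 0.0478, 20 replicates)
====================================================================
```

The held-out AUC is the mean over the 20 replicate negative sets of the area
under the ROC curve on 40 held-out positives plus 40 sampled negatives.
Repeating with `weighting="none"` gives AUC 0.503 (± 0.058) — chance level,
because on synthetic data the protein sequences carry no module signal and
the fingerprints are noisy — and the paired comparison across the replicate
sets is decisive:

```python
baseline = DTIPropagationModel.from_world(world, protein_features=prot,
                                          weighting="none").fit(rng_seed=11)
base_report = baseline.evaluate_world(world, rng_seed=11)
t, p = paired_t_test(report.auc_per_negative_set, base_report.auc_per_negative_set)
# t = 9.34, p = 1.57e-08
```

The same pipeline runs from the shell:

```bash
rwrdti simulate --preset small --seed 3 --out world/
rwrdti pipeline --preset small --seed 4 --n-negative-sets 5 --out run/
rwrdti evaluate --data world/ --weighting rwr --restart-c 0.25 --out eval/
rwrdti sweep-c --data world/ --c-grid 0.1,0.25,0.5,0.75,1.0 --out sweep/
```

On user-supplied real exports, `rwrdti build-networks` filters the PPI at a
confidence cut-off (strictly greater than, default 800) and derives the
shared-target DDI network, and `rwrdti descriptors` computes the 1287-dim
vectors from FASTA.

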