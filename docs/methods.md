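# Methods

## Networks

Three networks feed the pipeline. The **PPI network** is read from a plain
3-column TSV edge list (`idA idB score`); only interactions whose confidence
score is *strictly greater than* the cut-off (default 800 on the 0–1000
scale; releases that ship 0–1 scaled scores simply use a cut-off on that
scale) are kept, duplicate edges keep the maximum score, and self-loops are
dropped. Surviving edges keep their confidence score as edge weight. The
**DTI set** is a two-column pair list. The **DDI network** is derived from
it: an unweighted edge joins every two drugs that share at least one target.
Drugs sharing no target remain as isolated nodes so that every drug keeps a
feature row and a random-walk row. DDI edges carry unit weight because the
shared-target construction provides no natural weighting; PPI edges keep
their scores so that confident interactions carry more of the walk.

## Protein descriptors (1287 dimensions)

Eight blocks concatenated in fixed order — AAC (20), DPC (400), normalized
Moreau-Broto (240), Moran (240), Geary (240), CTD composition (21), CTD
transition (21), CTD distribution (105). The three autocorrelation families
each use 8 physicochemical property scales × 30 lags. The bundled scales
(hydrophobicity, average flexibility, polarizability, free energy of
solution, accessible surface area, residue volume, steric parameter,
relative mutability) and the seven 3-group CTD attributes (Dubchak-style
hydrophobicity, normalized van der Waals volume, polarity, polarizability,
charge, secondary structure, solvent accessibility) are the community
standard sets, shipped as TSV data files precisely so users can substitute
any AAindex-style table; the dimension counts, not the particular scales,
are what the descriptor contract fixes.

Definitions, for a sequence of length L and a property profile P
standardized to zero mean and unit (population) SD over the 20 canonical
residues:

* normalized Moreau-Broto, lag d: `(1/(L-d)) Σ P_i P_{i+d}`
* Moran, lag d: `[(1/(L-d)) Σ (P_i-P̄)(P_{i+d}-P̄)] / [(1/L) Σ (P_i-P̄)²]`
* Geary, lag d: `[(1/(2(L-d))) Σ (P_i-P_{i+d})²] / [(1/(L-1)) Σ (P_i-P̄)²]`
* CTD transition: adjacent-residue group changes per unordered group pair,
  divided by L−1.
* CTD distribution: positions (percent of L, 1-based) of the first,
  25%, 50%, 75% and last occurrence of each group; an absent group
  contributes five zeros. The q-quantile occurrence is the
  `max(ceil(q·n), 1)`-th of the group's n occurrences.

Numerical/degenerate choices: sequences must be longer than the maximum lag
(30), so the practical minimum length is 31; non-canonical residues
(B, J, O, U, X, Z) are removed with a warning before computation (an error
mode is available); zero-variance profiles (homopolymers under a scale)
return 0 for Moran and Geary rather than NaN so downstream matrices stay
finite, with the variance test performed at relative tolerance 1e-12 to
absorb floating-point residue.

## Random walk with restart

The adjacency is normalized **column-stochastically** over edge weights
(`Ã_ij = w_ij / Σ_k w_kj`); for an undirected graph this is the standard
"walker at node j picks a neighbor proportional to edge weight" dynamics. A
symmetric `D^{-1/2} A D^{-1/2}` normalization is available behind a switch
for experimentation, but the affinity-row invariants below hold only for the
column mode. Columns of isolated nodes are all-zero; an isolated seed
returns a point mass at itself, which is the restart limit.

The fixed point of `r = (1-c) Ã r + c q` is found by power iteration from
`r = q`, declaring convergence when the L1 change drops below 1e-10 (cap
1000 iterations; exceeding it raises with the residual). A closed-form
solver `c (I − (1−c) Ã)^{-1} q` is provided alongside and doubles as the
independent oracle in the tests; iteration is the default because it scales
to interactome-sized sparse networks where a dense solve does not.
Invariants maintained (and tested): affinities are non-negative, sum to 1
within the seed's connected component and are 0 outside it, the seed's
self-affinity is at least c and is non-decreasing in c.

All seeds are iterated jointly (`R ← (1−c) Ã R + c I`), which is exactly the
per-seed iteration vectorized; rows of the resulting affinity matrix `W` are
the per-seed distributions. Weighting is the matrix product `W·F` restricted
to shared identifiers, so every weighted row is a convex combination of
original feature rows — weighted values never leave the per-feature range of
the seed's component. Entities that appear in the DTI set but not in a
network are added as isolated nodes: their features pass through unchanged,
consistent with the restart behaviour.

The **guilt-by-association baseline** mixes each node's own features
(self-weight, default 1.0) with its direct neighbors' features proportional
to edge weight, normalized to sum 1. The original one-hop scheme this
reconstructs is described only qualitatively in the literature we follow, so
the self-weight is exposed as a parameter rather than hard-coded.

## Classifier

Pair vectors are the drug fingerprint block (first) concatenated with the
protein descriptor block. Negatives are sampled uniformly without
replacement from the non-positive (drug, protein) combinations over the
observed entity sets, one balanced set per replicate, 20 replicates by
default; replicates are independent draws and may overlap each other but
never the positives. The kNN uses the exact cubic distance over all training
points (no approximate index — the datasets this targets are modest);
`k = 10` by default. k is a genuinely open choice in this design: nothing in
the method fixes it, so it is exposed (`knn_k` / `--knn-k`) and the default
is the conventional preset for cubic kNN. Distance ties at the k-th neighbor
are broken by training-row order after a stable sort, making scores
deterministic; scores are therefore invariant to training-row permutation
only in the absence of exact distance ties. The decision threshold for label
output defaults to 0.62, but every headline evaluation is threshold-free
(AUC).

AUC is trapezoidal (equivalently the Mann-Whitney statistic with half credit
for ties), cross-validation is stratified with a seeded shuffle, and two
weighting schemes are compared by a two-sided paired t-test of the
per-replicate AUCs, paired by negative-set index. Identical AUC lists return
(t = 0, p = 1); a non-zero but constant difference (zero variance) is an
error, detected at relative tolerance 1e-12. Training performance can be
reported either as cross-validation or as resubstitution; both modes exist
because protocols in this literature are ambiguous between them, and CV is
the default everywhere a single number is needed.

## Synthetic data generator

The generator emulates the study conditions end to end without any
download. Defaults: 4 modules × 25 proteins × 5 drugs; within-module PPI
edge probability 0.3 against 0.01 across modules (stochastic block model),
confidence scores uniform on 801–999 so all edges survive the default
filter; per drug, 3 training targets and 2 held-out targets drawn from the
drug's module, with one module **hub** protein targeted by every drug of the
module — this guarantees the shared-target DDI cliques whose contraction the
weighting exploits; 1024-bit fingerprints built from a per-module template
(bit density 0.1, roughly a hundred set bits, typical of substructure
fingerprints) with 5% per-bit flip noise; random sequences of length
120–300 over the 20-letter alphabet. Everything derives from one integer
seed, and the written files round-trip exactly through the package readers.

Module and noise parameters not fixed by the design were chosen once as
field-realistic values and are recorded in `params.json` with every world.

What the planted world does **not** emulate: real fingerprint chemistry and
bit correlations, real interactome degree distributions (hubs, scale-free
tails), sequence homology between interacting proteins, and any relation
between sequence and module membership — sequences are deliberately random
so that every protein-side signal must flow through the network. Passing the
synthetic benchmark therefore demonstrates that the implementation extracts
exactly the network-topology signal the method is designed to extract; it
does not certify performance on real DrugBank/HIPPIE-scale data, whose
headline numbers depend on those databases' actual content. The pipeline
accepts such exports unchanged when users supply them.

On the default world the RWR-weighted model reaches a held-out AUC of about
0.64 ± 0.05 over 20 replicate negative sets against 0.50 ± 0.06 unweighted
(paired p ≈ 2e-8), and weighting at c = 0.25 roughly halves the mean
within-clique fingerprint distance — the numbers printed by the README
example and recomputed by the test suite. Problem sizes throughout the tests
(100 proteins, 20 drugs, 20 replicates) are the package's chosen desk-scale
conditions; they keep the full suite in the tens of seconds while leaving
every statistical conclusion comfortably significant.

## Repository shape

The library modules (`io`, `descriptors`, `propagation`, `dti_model`,
`evaluation`, `synthetic`) are stateless building blocks;
`DTIPropagationModel` / `DTIPropagationResults` compose them into the
statsmodels-style fit/results surface that the CLI wraps. The `sweep-c`
operation re-runs the whole pipeline per restart probability; its c = 1 row
is exactly the unweighted model, which the tests assert bit-for-bit.

## Known limitations

* Column-stochastic normalization is asserted, not derived: with symmetric
  normalization the affinity rows are no longer distributions and the
  convex-combination interpretation of weighting is lost.
* The kNN is O(n_train × n_query) per scoring call; interactome-scale
  training sets (~10⁴ pairs) are fine, but far larger corpora would need a
  metric index.
* Negative "non-interactions" are unverified absences, as in all DTI
  work of this kind; replicate negative sets quantify, but cannot remove,
  that sampling noise.
* FASTA identifiers must match the PPI/DTI protein identifiers exactly; no
  UniProt/DrugBank namespace mapping is attempted.
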