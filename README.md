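# netfas

Network-aware similarity for sparse binary profiles, applied to cancer
subtype discovery from somatic mutations.

Somatic mutation profiles are extreme: hundreds of patients, ~18,000
genes, a handful of mutations per patient, and clinically identical
patients often share *no* mutated gene. Direct similarity measures
(cosine, Jaccard, Pearson) collapse on such data. `netfas` instead scores
two patients by how close their mutated genes sit in a gene interaction
network: the **Feature Alignment Similarity (FAS)**

    s(P, Q) = max_{f ≥ 0} Σᵢⱼ f_ij s(pᵢ, qⱼ)
              s.t.  Σⱼ f_ij = w(pᵢ),   Σᵢ f_ij = w(qⱼ),

a transportation (earth-mover's-style) optimum whose ground similarities
`s(·,·)` are derived from the network: adjacent genes score
`1/|Edges(i) ∪ Edges(j)|`, distant genes score the maximal product of
those values along a connecting path (a max-product Floyd–Warshall
closure), and each gene's self-similarity becomes the sum of its
similarities to its neighbors. The resulting patient similarity is a true
similarity metric, comes with cheap nearest-neighbor relaxation upper
bounds for pruning, and feeds affinity propagation to produce subtypes
(**NetAP**). A planted-module cohort simulator and the standard
clustering scores (NMI, Rand, adjusted Rand, chi-square) round out the
package.

Intended users: computational biologists stratifying mutation (or other
sparse binary) profiles with a feature network in hand, and methods
researchers who need a clean, tested reference implementation of
network-propagated optimal-transport similarity.

## Worked example

```python
from netfas import (FeatureNetwork, WeightedFeatureProfile,
                    compute_feature_similarity, fas_exact)

# two 4-cliques bridged by one edge
left, right = ["L1","L2","L3","L4"], ["R1","R2","R3","R4"]
edges = [(a, b) for grp in (left, right)
         for i, a in enumerate(grp) for b in grp[i+1:]] + [("L4", "R1")]
net = FeatureNetwork.from_edge_list(edges)
sims = compute_feature_similarity(net)

A = WeightedFeatureProfile.from_indices([net.index_of("L1"), net.index_of("L2")])
B = WeightedFeatureProfile.from_indices([net.index_of("L3"), net.index_of("L4")])
C = WeightedFeatureProfile.from_indices([net.index_of("R2"), net.index_of("R3")])
print(fas_exact(A, B, sims).similarity)   # 0.1833
print(fas_exact(A, C, sims).similarity)   # 0.0040
```

A and B share no gene, yet score ~45× higher than A vs C because their
genes occupy the same dense network region — exactly the behaviour that
rescues similarity estimation on non-overlapping mutation profiles.

The full pipeline on a simulated cohort
(`python examples/03_netap_pipeline.py`):

```
cohort: 60 patients x 200 genes, mean 31 mutations/patient, 822 network edges
clustered 58 retained patients into 3 subtypes
  nmi            0.8768
  rand_index     0.9583
  adjusted_rand  0.9065
  chi_square     103.2015
  p_value        0.0000
```

An adjusted Rand index of 0.91 against the planted truth means the three
subtypes were recovered almost perfectly; the chi-square p-value rejects
independence between clusters and true labels.

More narrative scripts live in `examples/` (feature similarity and the
published path products, FAS vs its relaxation bounds, the end-to-end
pipeline). The same stages are scriptable from the shell:

```sh
netfas simulate --seed 7 --out-prefix cohort
netfas featuresim --network cohort.edges.tsv --knn 11 --out fsim.tsv
netfas similarity --profiles cohort.mut.tsv --featuresim fsim.tsv --out psim.tsv
netfas cluster --profiles cohort.mut.tsv --network cohort.edges.tsv --k 4 --out clusters.tsv
netfas evaluate --pred clusters.tsv --truth cohort.labels.tsv --out metrics.json
# or everything at once:
netfas run-all --simulate --seed 7 --k 4 --f 0.15 --out-dir run/
```

Accepted formats: 2/3-column edge lists or SIF for networks; TSV
matrices or 2-column gene–sample pair lists for profiles. See
`docs/methods.md` for the model, parameter defaults, and what the
synthetic benchmark does and does not emulate.

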