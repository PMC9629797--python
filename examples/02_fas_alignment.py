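"""Feature Alignment Similarity between two patients.

Two mutation profiles that share no gene can still be similar when their
genes occupy the same network region. This example aligns two disjoint
profiles over a two-community network and compares the exact
transportation optimum with the cheap relaxation bounds used for pruning.
"""

from netfas import (
    FeatureNetwork,
    WeightedFeatureProfile,
    compute_feature_similarity,
    fas_combined_bound,
    fas_exact,
    fas_relaxed_bound,
)

# two 4-cliques joined by one bridge edge
edges = []
left = ["L1", "L2", "L3", "L4"]
right = ["R1", "R2", "R3", "R4"]
for grp in (left, right):
    edges += [(a, b) for i, a in enumerate(grp) for b in grp[i + 1:]]
edges.append(("L4", "R1"))
net = FeatureNetwork.from_edge_list(edges)
sims = compute_feature_similarity(net)

idx = net.index_of
pA = WeightedFeatureProfile.from_indices([idx("L1"), idx("L2")], sample_id="A")
pB = WeightedFeatureProfile.from_indices([idx("L3"), idx("L4")], sample_id="B")
pC = WeightedFeatureProfile.from_indices([idx("R2"), idx("R3")], sample_id="C")

for other, name in [(pB, "B (same community)"), (pC, "C (other community)")]:
    exact = fas_exact(pA, other, sims).similarity
    b1 = fas_relaxed_bound(pA, other, sims, drop="target").similarity
    comb = fas_combined_bound(pA, other, sims)
    print(f"A vs {name:22s} exact={exact:.4f}  one-sided bound={b1:.4f}  "
          f"combined bound={comb:.4f}")

# A shares no gene with either B or C, yet scores several-fold higher
# against B because L-genes sit in the same dense network region; the
# bounds never fall below the exact optimum.
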