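"""Synthetic somatic-mutation cohorts with planted network modules.

The generator emulates TCGA-like mutation data at desk scale: a modular
(planted-partition) gene network, k latent subtypes each tied to one
connected network module, and per-patient mutation counts drawn from a
right-skewed log-normal law so the cohort is sparse and heterogeneous. A
fraction f of each patient's mutations ("driver" frequency) is placed
uniformly inside the subtype's module; the rest fall uniformly over the
remaining genes.

Defaults: M=100 patients, N=500 genes, k=4 subtypes, module sizes 10-50,
log-normal counts with mean-log 3.0 and sd-log 0.8 (median ~20 mutated
genes, ~4% density — the density of real uterine cohorts scaled to N=500).
All randomness flows from a single integer seed through named sub-streams,
so the same seed reproduces the same cohort bitwise and the network does
not change when only f changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .network import FeatureNetwork, InvalidInputError
from .stratify import MutationProfileSet


@dataclass
class SimulationConfig:
    """Parameters of the planted-module cohort generator."""

    n_samples: int = 100
    n_features: int = 500
    n_subtypes: int = 4
    driver_fraction: float = 0.15
    module_size_range: tuple[int, int] = (10, 50)
    count_mean_log: float = 3.0
    count_sd_log: float = 0.8
    p_within: float = 0.3
    p_between: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if not (0.0 < self.driver_fraction < 1.0):
            raise InvalidInputError("driver_fraction must be in (0, 1)")
        if lo < 2 or hi > self.n_features or lo > hi:
            raise InvalidInputError("invalid module_size_range")
        if self.n_subtypes < 2:
            raise InvalidInputError("need at least 2 subtypes")
        if self.n_samples < 1 or self.n_features < 2:
            raise InvalidInputError("cohort dimensions too small")


@dataclass
class CohortSimulation:
    """A generated cohort with its ground truth."""

    data: MutationProfileSet
    network: FeatureNetwork
    labels: list[int]
    modules: list[list[int]]
    config: SimulationConfig = field(repr=False)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("network", "modules", "labels", "counts", "placement")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_network(config: SimulationConfig) -> FeatureNetwork:
    """Modular random graph: communities with sizes drawn uniformly from
    ``module_size_range``, dense within (``p_within``), sparse between
    (``p_between``); extra spanning edges guarantee connectivity.

    The planted communities are attached to the returned network so that
    module sampling can use them as ground truth.
    """
    rng = _streams(config.seed)["network"]
    lo, hi = config.module_size_range
    sizes: list[int] = []
    remaining = config.n_features
    while remaining > 0:
        s = int(rng.integers(lo, hi + 1))
        if s >= remaining:
            s = remaining
        sizes.append(s)
        remaining -= s
    if sizes[-1] < 2 and len(sizes) > 1:
        leftover = sizes.pop()
        sizes[-1] += leftover

    nx_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.random_partition_graph(sizes, config.p_within, config.p_between, seed=nx_seed)
    # connect components deterministically via lowest-index representatives
    comps = sorted(nx.connected_components(g), key=min)
    for a, b in zip(comps[:-1], comps[1:]):
        g.add_edge(min(a), min(b))

    ids = [f"g{i:04d}" for i in range(config.n_features)]
    edges = {(min(u, v), max(u, v)) for u, v in g.edges()}
    communities = []
    start = 0
    for s in sizes:
        communities.append(list(range(start, start + s)))
        start += s
    return FeatureNetwork(
        vertex_ids=ids, edges=edges, communities=communities
    )


def sample_modules(
    network: FeatureNetwork, config: SimulationConfig
) -> list[list[int]]:
    """Pick k distinct communities whose size lies in the configured range,
    uniformly at random, as the subtype modules."""
    if network.communities is None:
        raise InvalidInputError("network carries no community structure")
    rng = _streams(config.seed)["modules"]
    lo, hi = config.module_size_range
    eligible = [c for c in network.communities if lo <= len(c) <= hi]
    k = config.n_subtypes
    if len(eligible) < k:
        raise InvalidInputError(
            f"only {len(eligible)} communities in size range, need {k}"
        )
    chosen = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[int(i)] for i in chosen]


def generate_cohort(config: SimulationConfig) -> CohortSimulation:
    """Full cohort: network, modules, subtype labels, mutation matrix.

    Per patient: subtype uniform over k; total count c log-normal truncated
    to [1, N]; round(f*c) mutations uniform without replacement inside the
    subtype module (capped at module size, excess returned to background);
    the remainder uniform over the other genes.
    """
    streams = _streams(config.seed)
    network = generate_network(config)
    modules = sample_modules(network, config)
    k, n = config.n_subtypes, config.n_features

    labels = streams["labels"].integers(0, k, size=config.n_samples)
    counts = np.exp(
        streams["counts"].normal(
            config.count_mean_log, config.count_sd_log, size=config.n_samples
        )
    )
    counts = np.clip(np.round(counts).astype(int), 1, n)

    placement = streams["placement"]
    matrix = np.zeros((config.n_samples, n), dtype=np.uint8)
    module_arrays = [np.asarray(m, dtype=np.int64) for m in modules]
    background = [
        np.setdiff1d(np.arange(n), m, assume_unique=False) for m in module_arrays
    ]
    for s in range(config.n_samples):
        mod = module_arrays[labels[s]]
        c = int(counts[s])
        d = min(int(round(config.driver_fraction * c)), len(mod), c)
        drivers = placement.choice(mod, size=d, replace=False)
        rest = min(c - d, len(background[labels[s]]))
        passengers = placement.choice(background[labels[s]], size=rest, replace=False)
        matrix[s, drivers] = 1
        matrix[s, passengers] = 1

    data = MutationProfileSet(
        sample_ids=[f"P{s:04d}" for s in range(config.n_samples)],
        feature_ids=list(network.vertex_ids),
        matrix=matrix,
    )
    return CohortSimulation(
        data=data,
        network=network,
        labels=[int(x) for x in labels],
        modules=[list(map(int, m)) for m in modules],
        config=replace(config),
    )
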