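"""Clustering-agreement metrics: NMI, Rand index, adjusted Rand index, and
the Pearson chi-square test, all computed from a predicted-vs-true
contingency table."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .network import InvalidInputError
from .stratify import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise InvalidInputError("counts shape does not match labels")
        if (c < 0).any():
            raise InvalidInputError("negative cell count")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency(
    pred: ClusterAssignment | Sequence[int],
    truth: Mapping[str, object] | Sequence[object],
) -> ContingencyTable:
    """Cross-tabulate predicted clusters against ground-truth labels.

    ``truth`` may be a mapping from sample id to label (the intersection
    of sample universes is taken, mismatches logged) or a sequence aligned
    with the predictions.
    """
    if isinstance(pred, ClusterAssignment):
        pred_ids, pred_labels = pred.sample_ids, pred.labels
    else:
        pred_labels = list(pred)
        pred_ids = [str(i) for i in range(len(pred_labels))]
    if isinstance(truth, Mapping):
        shared = [i for i, s in enumerate(pred_ids) if s in truth]
        if len(shared) < len(pred_ids):
            logger.warning(
                "%d predicted samples missing from truth", len(pred_ids) - len(shared)
            )
        p = [pred_labels[i] for i in shared]
        t = [truth[pred_ids[i]] for i in shared]
    else:
        if len(truth) != len(pred_labels):
            raise InvalidInputError("truth length does not match predictions")
        p, t = list(pred_labels), list(truth)
    if not p:
        raise InvalidInputError("no samples shared between prediction and truth")
    rows = sorted(set(p), key=str)
    cols = sorted(set(t), key=str)
    r_idx = {v: i for i, v in enumerate(rows)}
    c_idx = {v: i for i, v in enumerate(cols)}
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for a, b in zip(p, t):
        counts[r_idx[a], c_idx[b]] += 1
    return ContingencyTable(rows, cols, counts)


def nmi(table: ContingencyTable, average: str = "arithmetic") -> float:
    """Normalized mutual information from a contingency table.

    MI is normalized by the ``average`` ("arithmetic", "geometric" or
    "min") of the two marginal entropies. The degenerate one-cluster vs
    one-class case (both entropies zero) is defined as 0.
    """
    n = table.total
    if n <= 0:
        raise InvalidInputError("empty contingency table")
    pij = table.counts / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])).sum())
    hi = float(stats.entropy(pi))
    hj = float(stats.entropy(pj))
    if hi == 0.0 and hj == 0.0:
        logger.warning("degenerate single-cluster vs single-class input; NMI := 0")
        return 0.0
    if average == "arithmetic":
        denom = 0.5 * (hi + hj)
    elif average == "geometric":
        denom = float(np.sqrt(hi * hj))
    elif average == "min":
        denom = min(hi, hj)
    else:
        raise InvalidInputError(f"unknown normalization {average!r}")
    if denom == 0.0:
        return 0.0
    return float(np.clip(mi / denom, 0.0, 1.0))


def _pair_counts(table: ContingencyTable) -> tuple[float, float, float, float]:
    n = table.total
    if n < 2:
        raise InvalidInputError("need at least two samples")
    comb2 = lambda x: x * (x - 1) / 2.0
    sum_ij = comb2(table.counts.astype(float)).sum()
    sum_a = comb2(table.counts.sum(axis=1).astype(float)).sum()
    sum_b = comb2(table.counts.sum(axis=0).astype(float)).sum()
    return sum_ij, sum_a, sum_b, comb2(float(n))


def rand_index(table: ContingencyTable) -> float:
    """Fraction of sample pairs on which the two partitions agree."""
    sum_ij, sum_a, sum_b, total = _pair_counts(table)
    return float((total + 2 * sum_ij - sum_a - sum_b) / total)


def adjusted_rand(table: ContingencyTable) -> float:
    """Chance-corrected Rand index (permutation-model expectation)."""
    sum_ij, sum_a, sum_b, total = _pair_counts(table)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square against independence, no continuity correction.

    Zero marginal rows/columns are dropped (with a warning) before the
    test; df = (r-1)(c-1) on the reduced table.
    """
    counts = table.counts
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if (~row_ok).any() or (~col_ok).any():
        logger.warning(
            "dropping %d empty rows and %d empty columns before chi-square",
            int((~row_ok).sum()),
            int((~col_ok).sum()),
        )
        counts = counts[row_ok][:, col_ok]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InvalidInputError("chi-square needs >= 2 non-empty rows and columns")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), float(res.pvalue)


def score_all(
    pred: ClusterAssignment | Sequence[int],
    truth: Mapping[str, object] | Sequence[object],
) -> dict[str, float]:
    """All five agreement scores in one call."""
    table = contingency(pred, truth)
    stat, p = chi_square(table)
    return {
        "nmi": nmi(table),
        "rand_index": rand_index(table),
        "adjusted_rand": adjusted_rand(table),
        "chi_square": stat,
        "p_value": p,
    }
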