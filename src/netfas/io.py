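"""Readers and writers for the on-disk formats.

Networks: 2/3-column whitespace- or tab-separated edge lists
(``source target [weight]``) and the SIF dialect
(``source interaction-type target``; the interaction token is ignored).
Profiles: samples-by-genes TSV with a header row, or a 2-column
gene/sample pair list of mutation calls. Matrices: full symmetric TSV with
header and id column, round-tripping at 17 significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .fas import SampleSimilarityMatrix
from .feature_similarity import FeatureSimilarityMatrix
from .network import FeatureNetwork, InvalidInputError
from .stratify import ClusterAssignment, MutationProfileSet

logger = logging.getLogger(__name__)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_network(path: str | Path) -> FeatureNetwork:
    """Parse an edge-list or SIF file into a FeatureNetwork.

    Three-column lines are weighted edges when the third token is numeric,
    otherwise SIF records (middle token = interaction type, ignored).
    Duplicate and reversed edges are merged, keeping the maximum weight.
    Comment lines start with '#'.
    """
    path = Path(path)
    pairs: list[tuple] = []
    sif_noted = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) == 2:
                pairs.append((toks[0], toks[1]))
            elif len(toks) == 3:
                if _is_number(toks[2]) and path.suffix.lower() != ".sif":
                    pairs.append((toks[0], toks[1], float(toks[2])))
                else:
                    if not sif_noted:
                        logger.info(
                            "%s: SIF dialect, ignoring interaction-type column", path
                        )
                        sif_noted = True
                    pairs.append((toks[0], toks[2]))
            else:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(toks)}"
                )
    if not pairs:
        raise InvalidInputError(f"{path}: no edges found")
    try:
        return FeatureNetwork.from_edge_list(pairs)
    except InvalidInputError as e:
        raise InvalidInputError(f"{path}: {e}")


def write_network(network: FeatureNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tweight\n")
        for i, j in sorted(network.edges):
            w = network.weights.get((i, j), 1.0)
            fh.write(f"{network.vertex_ids[i]}\t{network.vertex_ids[j]}\t{w:.17g}\n")


def read_profiles(path: str | Path) -> MutationProfileSet:
    """Load a binary mutation matrix.

    A file whose rows all have exactly two columns is read as a gene/sample
    pair list (one mutation call per line); anything else is a TSV matrix
    with gene symbols in the header and sample ids in the first column.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if len(first.rstrip("\n").split("\t")) == 2 and not first.startswith("#"):
        calls: list[tuple[str, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                toks = line.split("\t")
                if len(toks) != 2:
                    raise InvalidInputError(
                        f"{path}:{lineno}: pair list needs 2 columns"
                    )
                calls.append((toks[0], toks[1]))
        genes = sorted({g for g, _ in calls})
        samples = sorted({s for _, s in calls})
        gi = {g: i for i, g in enumerate(genes)}
        si = {s: i for i, s in enumerate(samples)}
        mat = np.zeros((len(samples), len(genes)), dtype=np.uint8)
        for g, s in calls:
            mat[si[s], gi[g]] = 1
        return MutationProfileSet(samples, genes, mat)

    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidInputError(
            f"{path}: non-binary value {values[r, c]!r} at data line {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    return MutationProfileSet(
        [str(s) for s in df.index], [str(g) for g in df.columns], values
    )


def write_profiles(data: MutationProfileSet, path: str | Path) -> None:
    df = pd.DataFrame(data.matrix, index=data.sample_ids, columns=data.feature_ids)
    df.to_csv(path, sep="\t", index_label="sample")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample id, label. Returns a mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) != 2:
                raise InvalidInputError(f"{path}:{lineno}: expected 2 columns")
            if toks[0] in out:
                raise InvalidInputError(f"{path}:{lineno}: duplicate sample {toks[0]!r}")
            out[toks[0]] = toks[1]
    if not out:
        raise InvalidInputError(f"{path}: no labels found")
    return out


def write_labels(labels: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, l in labels.items():
            fh.write(f"{s}\t{l}\n")


def _write_matrix(ids: list[str], values: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def write_feature_similarity(
    sims: FeatureSimilarityMatrix, path: str | Path
) -> None:
    _write_matrix(sims.vertex_ids, sims.values, path)


def read_feature_similarity(
    path: str | Path, self_updated: bool = True
) -> FeatureSimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureSimilarityMatrix(
        [str(v) for v in df.columns], df.to_numpy(dtype=float), self_updated
    )


def write_sample_similarity(sim: SampleSimilarityMatrix, path: str | Path) -> None:
    _write_matrix(sim.sample_ids, sim.values, path)


def read_sample_similarity(path: str | Path) -> SampleSimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleSimilarityMatrix([str(v) for v in df.columns], df.to_numpy(dtype=float))


def write_assignment(assignment: ClusterAssignment, path: str | Path) -> None:
    ex = set(assignment.exemplars)
    with open(path, "w") as fh:
        fh.write("sample_id\tcluster\tis_exemplar\n")
        for s, l in zip(assignment.sample_ids, assignment.labels):
            fh.write(f"{s}\t{l}\t{int(s in ex)}\n")


def read_assignment(path: str | Path) -> ClusterAssignment:
    df = pd.read_csv(path, sep="\t")
    ids = [str(s) for s in df["sample_id"]]
    labels = [int(x) for x in df["cluster"]]
    exemplars = [str(s) for s, e in zip(ids, df["is_exemplar"]) if int(e) == 1]
    return ClusterAssignment(
        sample_ids=ids,
        labels=labels,
        exemplars=exemplars,
        achieved_k=len(set(labels)),
    )


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
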