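"""Dataset unification and leakage-safe splitting.

Targets are clustered by global (Needleman-Wunsch) sequence identity so
that any two proteins sharing more than the identity threshold (80% by
default) land in the same cross-validation fold; folds are assigned at the
cluster level, so no protein ever appears in two folds.  Also provides
negative:positive ratio enforcement, affinity binarization at a pK
threshold (6 by default, i.e. IC50 = 1 uM), and a floor-value filter for
datasets whose affinities pile up at an assay floor.

Identity is matches / alignment length (gaps included) * 100 — the most
conservative denominator for leakage control.  Default alignment scores:
match +1, mismatch 0, linear gap -1.  Ties in the dynamic program are
broken diagonal > up > left, which makes the reported identity
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MANIFEST_COLUMNS",
    "TargetClustering",
    "global_identity",
    "cluster_targets",
    "make_folds",
    "add_fold_column",
    "enforce_ratio",
    "binarize_affinity",
    "drop_floor_values",
    "check_manifest",
]

MANIFEST_COLUMNS = ["protein_id", "ligand_id", "dataset", "task", "label"]


def check_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Validate an interaction manifest (registry of protein/ligand pairs)."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    keys = manifest[["protein_id", "ligand_id", "dataset"]]
    if keys.duplicated().any():
        raise ValueError("manifest has duplicate (protein_id, ligand_id, dataset) records")
    bad_task = set(manifest["task"]) - {"classification", "regression"}
    if bad_task:
        raise ValueError(f"manifest has unknown task values: {bad_task}")
    cls = manifest.loc[manifest["task"] == "classification", "label"]
    if len(cls) and not cls.isin((0, 1)).all():
        raise ValueError("classification labels must be 0/1")
    return manifest


def _nw_matrices(a: str, b: str, match: float, mismatch: float, gap: float):
    """Row-vectorised Needleman-Wunsch score and pointer matrices."""
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    S = np.empty((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    S[0] = gap * np.arange(m + 1)
    S[:, 0] = gap * np.arange(n + 1)
    P[0, 1:] = 2
    P[1:, 0] = 1
    j = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(bb == aa[i - 1], match, mismatch)
        diag = S[i - 1, :-1] + sub
        up = S[i - 1, 1:] + gap
        cand = np.maximum(diag, up)
        # left moves form a running max: S[i,j] = max_{t<=j} cand'[t] + gap*(j-t)
        vals = np.empty(m + 1)
        vals[0] = S[i, 0]
        vals[1:] = cand
        row = np.maximum.accumulate(vals - gap * j) + gap * j
        S[i] = row
        # pointer priority: diagonal, then up, then left
        P[i, 1:] = np.where(np.isclose(row[1:], diag), 0,
                            np.where(np.isclose(row[1:], up), 1, 2))
    return S, P


def global_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Percent identity along the optimal global alignment.

    identity = matched positions / alignment length (gaps included) * 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    _, P = _nw_matrices(seq_a, seq_b, match, mismatch, gap)
    i, j = len(seq_a), len(seq_b)
    matches = 0
    length = 0
    while i > 0 or j > 0:
        move = P[i, j]
        if move == 0:
            matches += seq_a[i - 1] == seq_b[j - 1]
            i -= 1
            j -= 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
        length += 1
    return 100.0 * matches / length


@dataclass
class TargetClustering:
    """Protein -> cluster assignment at a given identity threshold.

    Clusters are single-linkage connected components of the graph whose
    edges join pairs with identity strictly greater than the threshold, so
    the closure property holds: any such pair shares a cluster.
    """

    assignments: dict
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self) -> dict:
        out: dict = {}
        for pid, cid in self.assignments.items():
            out.setdefault(cid, []).append(pid)
        return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_targets(
    sequences: Mapping[str, str],
    threshold: float = 80.0,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> TargetClustering:
    """Single-linkage clustering by pairwise global identity.

    An edge joins two proteins when identity > ``threshold`` (strict, per
    the 'greater than 80%' rule); components are the clusters.  Threshold 0
    merges everything; any threshold >= 100 leaves singletons.
    """
    ids = list(sequences)
    uf = _UnionFind(ids)
    for i, pa in enumerate(ids):
        for pb in ids[i + 1 :]:
            if global_identity(sequences[pa], sequences[pb], match, mismatch, gap) > threshold:
                uf.union(pa, pb)
    roots = {pid: uf.find(pid) for pid in ids}
    order: dict = {}
    assignments = {}
    for pid in ids:  # stable, insertion-ordered cluster ids
        root = roots[pid]
        if root not in order:
            order[root] = len(order)
        assignments[pid] = order[root]
    return TargetClustering(assignments=assignments, threshold=threshold)


def make_folds(
    clustering: TargetClustering,
    k: int,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
) -> dict:
    """Assign whole clusters to ``k`` folds, greedily balancing weight.

    ``weights`` maps protein_id to its interaction count (default 1 each).
    Clusters are taken in decreasing weight order (ties broken by a seeded
    shuffle) and added to the currently lightest fold.  Returns
    protein_id -> fold index; clusters never straddle folds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    members = clustering.members()
    rng = np.random.default_rng(seed)
    cluster_ids = list(members)
    rng.shuffle(cluster_ids)

    def cluster_weight(cid) -> float:
        return sum((weights or {}).get(pid, 1.0) for pid in members[cid])

    cluster_ids.sort(key=cluster_weight, reverse=True)
    fold_load = np.zeros(k)
    folds: dict = {}
    for cid in cluster_ids:
        fold = int(np.argmin(fold_load))
        fold_load[fold] += cluster_weight(cid)
        for pid in members[cid]:
            folds[pid] = fold
    return folds


def add_fold_column(manifest: pd.DataFrame, protein_folds: Mapping[str, int]) -> pd.DataFrame:
    """Annotate a manifest with each record's protein fold."""
    out = manifest.copy()
    out["fold"] = out["protein_id"].map(protein_folds)
    if out["fold"].isna().any():
        missing = sorted(out.loc[out["fold"].isna(), "protein_id"].unique())
        raise ValueError(f"proteins without a fold assignment: {missing[:5]} ...")
    out["fold"] = out["fold"].astype(int)
    return out


def enforce_ratio(manifest: pd.DataFrame, ratio_neg_to_pos: float, seed: int = 0) -> pd.DataFrame:
    """Downsample negatives per dataset to at most ``ratio * positives``.

    Positives are never touched and no records are fabricated; when a
    dataset has fewer negatives than the ratio allows it is left unchanged
    with a warning.  Only classification rows are affected.
    """
    if ratio_neg_to_pos <= 0:
        raise ValueError("ratio must be positive")
    rng = np.random.default_rng(seed)
    keep = []
    for dataset, group in manifest.groupby("dataset", sort=False):
        cls = group[group["task"] == "classification"]
        if cls.empty:
            keep.append(group)
            continue
        pos = cls[cls["label"] == 1]
        neg = cls[cls["label"] == 0]
        target = int(np.floor(ratio_neg_to_pos * len(pos)))
        if len(neg) <= target:
            if len(neg) < target:
                warnings.warn(
                    f"dataset {dataset!r}: only {len(neg)} negatives for target "
                    f"{target}; left unchanged")
            keep.append(group)
            continue
        chosen = rng.choice(neg.index.to_numpy(), size=target, replace=False)
        keep.append(group.loc[group.index.isin(chosen) | (group["label"] == 1)
                              | (group["task"] != "classification")])
    return pd.concat(keep).sort_index()


def binarize_affinity(values, threshold: float = 6.0) -> np.ndarray:
    """Binarize pK affinities: label 1 iff value strictly above threshold.

    The default threshold 6 corresponds to IC50 = 1 uM
    (-log10(1e-6) = 6); ties at the threshold are negative.  Kinase-style
    transformed scores use their own threshold (e.g. 12.1).
    """
    values = np.asarray(values, dtype=float)
    return (values > threshold).astype(int)


def drop_floor_values(manifest: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Remove regression records whose label equals an assay floor value.

    Mirrors the exclusion of pile-up samples at the lowest measurable
    affinity that would otherwise dominate a skewed dataset.
    """
    mask = (manifest["task"] == "regression") & (manifest["label"].astype(float) == floor)
    return manifest.loc[~mask].copy()
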