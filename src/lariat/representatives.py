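"""Representative-set selection for phylogenetic marker proteins.

To place intron-containing phages on a tree without inflating it with
redundant taxa, marker proteins (e.g. the terminase large subunit, TerL)
are reduced to representatives three ways: direct inclusion of the
intron-positive genomes' markers, capped random sampling within annotated
families, and single-linkage clustering of unannotated sequences by
pairwise percent identity at a threshold searched to give an exact
cluster count, taking one random sequence per cluster.

Percent identity uses the shorter of the two unaligned sequence lengths
as denominator (so a perfect substring scores 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from lariat.boundaries import percent_identity


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix over named sequences."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")


@dataclass(frozen=True)
class Clustering:
    """A partition of sequence ids produced at a given identity threshold."""

    threshold: float
    clusters: tuple[tuple[str, ...], ...]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def identity_matrix(
    seqs: Mapping[str, str] | Sequence[tuple[str, str]],
    mode: str = "semi_global",
) -> IdentityMatrix:
    """All-pairs percent identity (shorter-sequence denominator).

    Pairs are aligned shorter-against-longer semi-globally by default so
    that the shorter-denominator convention is honoured when lengths
    differ substantially.
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i][1], items[j][1]
            if len(a) > len(b):
                a, b = b, a
            values[i, j] = values[j, i] = percent_identity(a, b, mode=mode)
    return IdentityMatrix(ids=tuple(ids), values=values)


def single_linkage(matrix: IdentityMatrix, threshold: float) -> Clustering:
    """Connected components of the graph with edges at identity >= threshold."""
    adj = matrix.values >= threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for sid, lab in zip(matrix.ids, labels):
        clusters[lab].append(sid)
    clusters.sort(key=lambda c: c[0])
    return Clustering(threshold=float(threshold), clusters=tuple(tuple(c) for c in clusters))


def _candidate_thresholds(matrix: IdentityMatrix) -> np.ndarray:
    n = len(matrix.ids)
    iu = np.triu_indices(n, k=1)
    vals = np.unique(matrix.values[iu])
    mids = (vals[:-1] + vals[1:]) / 2 if len(vals) > 1 else np.array([])
    cands = np.unique(np.concatenate([vals, mids, [vals[-1] + 1.0]]))
    return cands


def threshold_for_k(matrix: IdentityMatrix, k: int) -> float:
    """An identity threshold at which single linkage yields exactly k clusters.

    The cluster count is a non-decreasing step function of the
    threshold, changing only at observed identity values, so a binary
    search over the finite candidate set (distinct off-diagonal values,
    midpoints between consecutive values, and one value above the
    maximum) suffices. When several thresholds achieve k, the largest is
    returned. Raises ValueError with the bracketing achievable counts
    when k is unreachable.
    """
    n = len(matrix.ids)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    cands = _candidate_thresholds(matrix)
    counts_cache: dict[int, int] = {}

    def count(idx: int) -> int:
        if idx not in counts_cache:
            counts_cache[idx] = single_linkage(matrix, float(cands[idx])).n_clusters
        return counts_cache[idx]

    # smallest candidate index with count >= k
    lo, hi = 0, len(cands) - 1
    if count(hi) < k or count(0) > k:
        raise ValueError(
            f"no threshold yields exactly {k} clusters "
            f"(achievable range here: {count(0)}..{count(len(cands) - 1)})"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if count(mid) >= k:
            hi = mid
        else:
            lo = mid + 1
    first = lo
    if count(first) != k:
        below = count(first - 1) if first > 0 else None
        raise ValueError(
            f"no threshold yields exactly {k} clusters; "
            f"achievable counts bracket k: {below} and {count(first)}"
        )
    # largest candidate index still achieving k
    lo, hi = first, len(cands) - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if count(mid) == k:
            lo = mid
        else:
            hi = mid - 1
    return float(cands[lo])


def sample_capped(
    groups: Mapping[str, Sequence[str]], cap: int, seed: int
) -> list[str]:
    """Uniform without-replacement sample of at most ``cap`` ids per group.

    Deterministic for a given seed; groups are visited in sorted key
    order. Output size is sum(min(cap, |group|)).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    picked: list[str] = []
    for key in sorted(groups):
        members = sorted(groups[key])
        take = min(cap, len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        picked.extend(members[i] for i in sorted(idx))
    return picked


def one_per_cluster(clustering: Clustering, seed: int) -> list[str]:
    """One uniformly chosen id per cluster, deterministic for a seed."""
    rng = np.random.default_rng(seed)
    picked = []
    for cluster in clustering.clusters:
        members = sorted(cluster)
        picked.append(members[int(rng.integers(len(members)))])
    return picked


def assemble_representative_set(
    direct: Sequence[str],
    family_groups: Mapping[str, Sequence[str]],
    cap: int,
    clustering: Clustering,
    seed: int,
) -> list[str]:
    """Three-source marker set: direct + capped family sample + one per cluster."""
    out = list(direct)
    out += sample_capped(family_groups, cap=cap, seed=seed)
    out += one_per_cluster(clustering, seed=seed + 1)
    return out
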