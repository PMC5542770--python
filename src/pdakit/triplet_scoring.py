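"""Scoring of a single position triplet by phylogenetic mixing entropy.

For a triplet of alignment columns (i, j, k) the method builds the reduced
three-column alignment, one-hot encodes it, projects the sequences onto a
maximum-variance PCA subspace, clusters them hierarchically with a distance
cutoff equal to the average pairwise sequence distance, and scores the
clustering by the cluster-size-weighted Shannon entropy of phylogenetic
group labels:

    h(c) = -sum_i P(i|c) ln P(i|c)          (entropy of one cluster)
    H    =  sum_c w(c) h(c)                 (weighted average over clusters)

where P(i|c) is the fraction of sequences in cluster c belonging to group i
and w(c) the fraction of all sequences falling in cluster c.  Low H means
the clusters induced by the triplet are phylogenetically pure, i.e. the
triplet discriminates the groups well.

Natural logarithms are used throughout; triplet rankings and empirical
p-values are invariant under the choice of base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import pdist

from .alphabet import ENCODING_SIZE, encoding_indices
from .errors import DataError, SchemaError
from .msa_io import Alignment, AnnotationTable

__all__ = [
    "ScoringConfig",
    "ReducedEncoding",
    "Projection",
    "ClusterAssignment",
    "MixingScore",
    "encode_triplet",
    "project_pca",
    "cluster_sequences",
    "cluster_entropy",
    "mixing_score",
    "score_triplet",
]

_LINKAGE_METHODS = ("average", "ward", "complete", "single")


@dataclass(frozen=True)
class ScoringConfig:
    """Tunables of the per-triplet embedding/clustering pipeline.

    variance_kept
        Cumulative explained-variance fraction retained by the PCA
        projection (1.0 keeps every non-degenerate component).
    linkage
        Agglomeration rule for hierarchical clustering; Euclidean metric.
    """

    variance_kept: float = 0.95
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_kept <= 1.0:
            raise SchemaError("variance_kept must lie in (0, 1]")
        if self.linkage not in _LINKAGE_METHODS:
            raise SchemaError(f"linkage must be one of {_LINKAGE_METHODS}")


@dataclass(frozen=True)
class ReducedEncoding:
    """One-hot encoding of the reduced three-column alignment."""

    ids: tuple[str, ...]
    coordinates: np.ndarray  # n_seq x (3 * alphabet size)
    positions: tuple[int, int, int]


@dataclass(frozen=True)
class Projection:
    """PCA scores of the encoded sequences."""

    ids: tuple[str, ...]
    coordinates: np.ndarray  # n_seq x d'
    explained_variance_fraction: float


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering of sequences; labels contiguous from 0."""

    ids: tuple[str, ...]
    labels: np.ndarray
    n_clusters: int
    cluster_weights: np.ndarray  # fraction of sequences per cluster


@dataclass(frozen=True)
class MixingScore:
    """Weighted-entropy mixing score of a clustering."""

    H: float
    per_cluster_entropy: tuple[float, ...]


# ---------------------------------------------------------------------------
# numeric internals, shared with the scan fast path in pda_scan
# ---------------------------------------------------------------------------

def _pca_scores(X: np.ndarray, variance_kept: float) -> tuple[np.ndarray, float]:
    """Mean-centred PCA scores keeping the smallest subspace with cumulative
    explained variance >= variance_kept.  Component signs are fixed by making
    the largest-magnitude loading of each component positive.

    Degenerate input (zero total variance) yields a single all-zero column.
    """
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc  # unnormalized; ratios are scale-free
    evals, evecs = np.linalg.eigh(cov)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 1e-12 * max(1, X.shape[0]):
        return np.zeros((X.shape[0], 1)), 1.0
    ratios = evals / total
    cum = np.cumsum(ratios)
    k = int(np.argmax(cum >= variance_kept - 1e-12)) + 1
    W = evecs[:, :k]
    # sign convention: largest |loading| positive
    anchor = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[anchor, np.arange(k)])
    signs[signs == 0] = 1.0
    W = W * signs
    return Xc @ W, float(cum[k - 1])


def _cluster_labels(coords: np.ndarray, linkage: str) -> np.ndarray:
    """Hierarchical clustering cut at the mean pairwise distance.

    Merges at height equal to the cutoff are performed (ties merge), so two
    points at exactly the average distance form a single cluster.  Labels
    are relabelled contiguously from 0 in order of first appearance.
    """
    n = coords.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    dists = pdist(coords)
    cutoff = float(dists.mean())
    if cutoff == 0.0:
        return np.zeros(n, dtype=np.int64)
    Z = _scipy_linkage(dists, method=linkage)
    raw = fcluster(Z, t=cutoff, criterion="distance")
    _, labels = np.unique(raw, return_inverse=True)
    # order of first appearance
    order = np.full(labels.max() + 1, -1, dtype=np.int64)
    nxt = 0
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if order[lab] < 0:
            order[lab] = nxt
            nxt += 1
        out[i] = order[lab]
    return out


def _weighted_entropy(
    labels: np.ndarray, group_idx: np.ndarray, n_groups: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Return (H, per-cluster entropies, cluster weights)."""
    n_clusters = int(labels.max()) + 1
    cont = np.zeros((n_clusters, n_groups))
    np.add.at(cont, (labels, group_idx), 1.0)
    sizes = cont.sum(axis=1)
    P = cont / sizes[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    h = -(P * logP).sum(axis=1)
    h = np.clip(h, 0.0, None)
    w = sizes / sizes.sum()
    return float(w @ h), h, w


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def encode_triplet(aln: Alignment, positions: Sequence[int]) -> ReducedEncoding:
    """One-hot encode the reduced alignment restricted to three columns.

    Each row is the concatenation of three indicator vectors over the
    22-symbol alphabet (20 amino acids, 'X', gap); rows sum to 3.
    """
    pos = tuple(int(p) for p in positions)
    if len(pos) != 3 or len(set(pos)) != 3:
        raise SchemaError(f"positions must be three distinct indices, got {pos}")
    for p in pos:
        if not 0 <= p < aln.width:
            raise SchemaError(f"position {p} out of range [0, {aln.width})")
    idx = np.stack([encoding_indices(seq)[list(pos)] for seq in aln.sequences])
    eye = np.eye(ENCODING_SIZE)
    coords = eye[idx].reshape(len(aln), 3 * ENCODING_SIZE)
    return ReducedEncoding(aln.ids, coords, pos)  # type: ignore[arg-type]


def project_pca(enc: ReducedEncoding, variance_kept: float = 0.95) -> Projection:
    """Project the encoded sequences onto a maximum-variance PCA subspace."""
    if not 0.0 < variance_kept <= 1.0:
        raise SchemaError("variance_kept must lie in (0, 1]")
    if enc.coordinates.shape[0] < 2:
        raise DataError("PCA requires at least two sequences")
    scores, frac = _pca_scores(enc.coordinates, variance_kept)
    return Projection(enc.ids, scores, frac)


def cluster_sequences(proj: Projection, linkage: str = "average") -> ClusterAssignment:
    """Agglomerative clustering cut at the mean pairwise distance."""
    if linkage not in _LINKAGE_METHODS:
        raise SchemaError(f"linkage must be one of {_LINKAGE_METHODS}")
    labels = _cluster_labels(proj.coordinates, linkage)
    n_clusters = int(labels.max()) + 1
    weights = np.bincount(labels, minlength=n_clusters) / labels.size
    return ClusterAssignment(proj.ids, labels, n_clusters, weights)


def cluster_entropy(members_groups: Iterable[str]) -> float:
    """Shannon entropy (natural log) of a multiset of group labels."""
    labels = list(members_groups)
    if not labels:
        raise DataError("cluster_entropy requires a non-empty multiset")
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mixing_score(assign: ClusterAssignment, ann: AnnotationTable) -> MixingScore:
    """Weighted average entropy H = sum_c w(c) h(c) over all clusters."""
    groups = [ann.group_of(sid) for sid in assign.ids]
    uniq = sorted(set(groups))
    gidx = np.array([uniq.index(g) for g in groups], dtype=np.int64)
    H, h, _ = _weighted_entropy(assign.labels, gidx, len(uniq))
    return MixingScore(H, tuple(float(x) for x in h))


def score_triplet(
    aln: Alignment,
    ann: AnnotationTable,
    positions: Sequence[int],
    config: ScoringConfig | None = None,
) -> float:
    """Full per-triplet pipeline: encode -> PCA -> cluster -> mixing score."""
    cfg = config or ScoringConfig()
    enc = encode_triplet(aln, positions)
    proj = project_pca(enc, cfg.variance_kept)
    assign = cluster_sequences(proj, cfg.linkage)
    return mixing_score(assign, ann).H
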