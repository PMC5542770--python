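"""Ensemble direct coupling analysis with random paralog matching.

Inter-protein coevolution between two families requires knowing which
paralog of family A interacts with which paralog of family B in each
organism.  When that pairing is unknown (no operon structure, variable
paralog numbers), this module implements the randomized strategy: in every
organism each family-A sequence is matched one-to-one with a uniformly
random family-B sequence of the same organism, matched pairs are
concatenated into a joint alignment, couplings are scored, and the whole
procedure is repeated R times (default 300).  An inter-protein position
pair is recorded in a realization when its min-max-normalized coupling
score reaches ``score_threshold`` (default 0.8); pairs recorded in at least
``appearance_threshold`` (default 5%) of realizations are selected.

The built-in coupling scorer is mean-field DCA: sequence reweighting at 90%
identity, pseudocount-regularized pair frequencies, inversion of the
covariance matrix over the 20 non-gap states, zero-sum gauge, Frobenius
norm and average-product correction.  Any scorer with the same call
signature can be plugged in instead (e.g. a pseudo-likelihood
implementation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .alphabet import COUPLING_STATES, coupling_indices
from .errors import AnnotationLookupError, DataError, SchemaError
from .msa_io import Alignment, AnnotationTable

__all__ = [
    "PairedFamily",
    "Matching",
    "SequenceWeights",
    "EnsembleDCAResult",
    "sequence_weights",
    "random_matching",
    "concatenate",
    "mean_field_scores",
    "coupling_scores",
    "normalize_scores",
    "ensemble_run",
]

Scorer = Callable[[np.ndarray, np.ndarray], np.ndarray]
"""Pluggable coupling scorer: (n x L integer alignment in the 21-state
coupling alphabet, per-sequence weights) -> symmetric L x L score matrix."""


@dataclass(frozen=True)
class PairedFamily:
    """Two annotated alignments sharing an organism universe."""

    alignment_a: Alignment
    annotations_a: AnnotationTable
    alignment_b: Alignment
    annotations_b: AnnotationTable

    def __post_init__(self) -> None:
        for aln, ann, tag in (
            (self.alignment_a, self.annotations_a, "A"),
            (self.alignment_b, self.annotations_b, "B"),
        ):
            for sid in aln.ids:
                if sid not in ann:
                    raise AnnotationLookupError(
                        f"family {tag} sequence {sid!r} has no annotation"
                    )

    @property
    def organisms(self) -> tuple[str, ...]:
        orgs_a = {self.annotations_a.organism_of(s) for s in self.alignment_a.ids}
        orgs_b = {self.annotations_b.organism_of(s) for s in self.alignment_b.ids}
        return tuple(sorted(orgs_a | orgs_b))

    def by_organism(self) -> dict[str, tuple[list[str], list[str]]]:
        """Organism -> (family-A ids, family-B ids), in alignment order."""
        table: dict[str, tuple[list[str], list[str]]] = {}
        for sid in self.alignment_a.ids:
            table.setdefault(
                self.annotations_a.organism_of(sid), ([], [])
            )[0].append(sid)
        for sid in self.alignment_b.ids:
            table.setdefault(
                self.annotations_b.organism_of(sid), ([], [])
            )[1].append(sid)
        return table


@dataclass(frozen=True)
class Matching:
    """One-to-one per-organism pairing of family-A and family-B sequences."""

    pairs: tuple[tuple[str, str], ...]
    realization_seed: int


@dataclass(frozen=True)
class SequenceWeights:
    """Inverse-neighborhood sequence weights at an identity threshold."""

    ids: tuple[str, ...]
    weights: np.ndarray
    identity_threshold: float

    @property
    def effective_sequences(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class EnsembleDCAResult:
    """Aggregated inter-protein pair statistics over R matchings."""

    n_realizations: int
    appearance_fraction: np.ndarray  # N_a x N_b
    score_threshold: float
    appearance_threshold: float
    base_seed: int
    scorer_name: str
    n_a: int
    n_b: int

    @property
    def selected_pairs(self) -> tuple[tuple[int, int], ...]:
        idx = np.argwhere(self.appearance_fraction >= self.appearance_threshold)
        return tuple((int(i), int(j)) for i, j in idx)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table; positions are 1-based in the output."""
        ii, jj = np.meshgrid(
            np.arange(self.n_a), np.arange(self.n_b), indexing="ij"
        )
        frac = self.appearance_fraction.ravel()
        return pd.DataFrame(
            {
                "pos_a": ii.ravel() + 1,
                "pos_b": jj.ravel() + 1,
                "appearance_fraction": frac,
                "selected": frac >= self.appearance_threshold,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        return {
            "n_realizations": self.n_realizations,
            "score_threshold": self.score_threshold,
            "appearance_threshold": self.appearance_threshold,
            "base_seed": self.base_seed,
            "scorer": self.scorer_name,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_selected_pairs": len(self.selected_pairs),
        }

    def manifest_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _int_matrix(aln: Alignment) -> np.ndarray:
    return np.stack([coupling_indices(s) for s in aln.sequences])


def sequence_weights(
    aln: Alignment, identity_threshold: float = 0.90
) -> SequenceWeights:
    """Weight each sequence by 1 / (number of neighbors at >= threshold identity).

    Identity is the fraction of columns with identical symbols over the full
    alignment width (gap-gap columns count as matches); each sequence is its
    own neighbor, so weights lie in (0, 1].
    """
    if len(aln) == 0:
        raise DataError("cannot weight an empty alignment")
    X = _int_matrix(aln)
    n = X.shape[0]
    identity = (X[:, None, :] == X[None, :, :]).mean(axis=2)
    neighbors = (identity >= identity_threshold).sum(axis=1)
    return SequenceWeights(aln.ids, 1.0 / neighbors, identity_threshold)


def random_matching(pf: PairedFamily, seed: int) -> Matching:
    """Uniform one-to-one per-organism matching.

    Within each organism min(#A, #B) pairs are formed; each family-B
    sequence is used at most once, and when one family has excess paralogs a
    uniformly random subset of it is matched.  Organisms lacking either
    family contribute no pairs.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    table = pf.by_organism()
    for org in sorted(table):
        ids_a, ids_b = table[org]
        k = min(len(ids_a), len(ids_b))
        if k == 0:
            continue
        perm_a = [ids_a[i] for i in rng.permutation(len(ids_a))[:k]]
        perm_b = [ids_b[i] for i in rng.permutation(len(ids_b))[:k]]
        pairs.extend(zip(perm_a, perm_b))
    return Matching(tuple(pairs), seed)


def concatenate(pf: PairedFamily, matching: Matching) -> Alignment:
    """Concatenate matched A/B sequences into a joint alignment.

    Record ids are ``a_id|b_id``; width is N_a + N_b.  An empty matching
    yields an empty alignment of the joint width.
    """
    width = pf.alignment_a.width + pf.alignment_b.width
    lut_a = dict(pf.alignment_a.records)
    lut_b = dict(pf.alignment_b.records)
    records = []
    for a_id, b_id in matching.pairs:
        if a_id not in lut_a:
            raise AnnotationLookupError(f"matched id {a_id!r} missing in family A")
        if b_id not in lut_b:
            raise AnnotationLookupError(f"matched id {b_id!r} missing in family B")
        records.append((f"{a_id}|{b_id}", lut_a[a_id] + lut_b[b_id]))
    return Alignment.from_records(records, width=width)


def mean_field_scores(
    X: np.ndarray,
    weights: np.ndarray,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Mean-field DCA coupling scores for every column pair.

    The weighted connected-correlation matrix over the 21-state alphabet is
    regularized by a pseudocount applied at the covariance level: the
    empirical covariance is shrunk with relative weight lambda toward the
    covariance of the uniform residue profile, which is block-diagonal, so
    statistically independent columns keep zero expected cross-covariance
    regardless of their per-column entropies.  (A frequency-level uniform
    pseudocount mixture would instead manufacture systematic cross-column
    covariance for low-entropy columns, swamping the coupling signal.)  The
    matrix restricted to the 20 non-gap states is inverted and each 20 x 20
    coupling block is shifted to the zero-sum gauge.

    The reported score is the average-product-corrected *squared* Frobenius
    norm of the coupling blocks.  The square is deliberate: under the null
    the expected squared norm is proportional to the product of the two
    columns' effective state counts, so it factorizes over columns and the
    rank-one average-product correction removes it exactly even when column
    alphabets are heterogeneous (e.g. a near-binary column next to fully
    variable ones); correcting the unsquared norm systematically mis-centers
    low-diversity column pairs.  Higher = stronger direct coupling.
    Deterministic and invariant under sequence reordering.
    """
    n, L = X.shape
    q = COUPLING_STATES
    lam = pseudocount
    w = weights / weights.sum()

    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    flat = onehot.reshape(n, L * q)
    f1 = (w[:, None, None] * onehot).sum(axis=0)  # L x q
    f2 = (flat * w[:, None]).T @ flat  # (Lq) x (Lq)
    f2 = f2.reshape(L, q, L, q)
    for i in range(L):
        f2[i, :, i, :] = np.diag(f1[i])

    C = f2 - f1[:, :, None, None] * f1[None, None, :, :]
    C *= 1.0 - lam
    # uniform-profile covariance on the diagonal blocks
    unif = np.eye(q) / q - 1.0 / (q * q)
    for i in range(L):
        C[i, :, i, :] += lam * unif

    # drop the gap state (index q-1) to obtain an invertible system
    C = C[:, : q - 1, :, : q - 1]
    d = q - 1
    Cm = C.reshape(L * d, L * d)
    J = -np.linalg.inv(Cm)
    J = J.reshape(L, d, L, d)

    # zero-sum gauge per block, then squared Frobenius norm
    Jz = (
        J
        - J.mean(axis=1, keepdims=True)
        - J.mean(axis=3, keepdims=True)
        + J.mean(axis=(1, 3), keepdims=True)
    )
    FN2 = (Jz**2).sum(axis=(1, 3))
    np.fill_diagonal(FN2, 0.0)

    # average-product correction over off-diagonal entries
    row = FN2.sum(axis=1) / (L - 1)
    mean = FN2.sum() / (L * (L - 1))
    apc = np.outer(row, row) / mean
    scores = FN2 - apc
    np.fill_diagonal(scores, 0.0)
    return scores


def coupling_scores(
    joint: Alignment,
    weights: SequenceWeights,
    n_a: int,
    scorer: Scorer | None = None,
    min_sequences: int = 10,
) -> np.ndarray:
    """Inter-protein block (N_a x N_b) of the coupling score matrix.

    The full L x L matrix (including intra-protein couplings) is computed by
    the scorer; only the A-block x B-block is returned for thresholding.
    """
    if joint.width <= n_a:
        raise SchemaError("joint alignment width must exceed the family-A width")
    if len(joint) < min_sequences:
        raise DataError(
            f"coupling analysis requires >= {min_sequences} sequences, "
            f"got {len(joint)}"
        )
    fn = scorer or mean_field_scores
    full = fn(_int_matrix(joint), weights.weights)
    return full[:n_a, n_a:]


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Affine min-max normalization of inter-protein scores to [0, 1].

    The maximum maps to 1; invariant under positive affine transforms of
    the input.  Degenerate cases: a single pair maps to 1.0 by convention,
    all-equal scores map to 0; both emit a warning.
    """
    if scores.size == 0:
        raise DataError("no inter-protein pairs to normalize")
    lo, hi = float(scores.min()), float(scores.max())
    if scores.size == 1:
        warnings.warn("single inter-protein pair; normalized to 1.0", stacklevel=2)
        return np.ones_like(scores)
    if hi == lo:
        warnings.warn("all coupling scores equal; normalized to 0", stacklevel=2)
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def ensemble_run(
    pf: PairedFamily,
    n_realizations: int = 300,
    score_threshold: float = 0.8,
    appearance_threshold: float = 0.05,
    base_seed: int = 0,
    scorer: Scorer | None = None,
    identity_threshold: float = 0.90,
    min_sequences: int = 10,
) -> EnsembleDCAResult:
    """Random-matching ensemble: R realizations, per-pair appearance fractions.

    Realization r uses seed ``base_seed + r``.  Sequence reweighting is
    applied to each concatenated alignment.  Coupling scores are memoized on
    the realized pair set, so repeated matchings (e.g. single-paralog
    organisms, where the matching is forced) are not recomputed; results are
    identical with or without the cache.
    """
    if n_realizations < 1:
        raise SchemaError("at least one realization is required")
    n_a, n_b = pf.alignment_a.width, pf.alignment_b.width
    counts = np.zeros((n_a, n_b))
    cache: dict[tuple[tuple[str, str], ...], np.ndarray] = {}
    for r in range(n_realizations):
        matching = random_matching(pf, base_seed + r)
        key = tuple(sorted(matching.pairs))
        hits = cache.get(key)
        if hits is None:
            joint = concatenate(pf, matching)
            w = sequence_weights(joint, identity_threshold)
            inter = coupling_scores(joint, w, n_a, scorer, min_sequences)
            norm = normalize_scores(inter)
            hits = (norm >= score_threshold).astype(float)
            cache[key] = hits
        counts += hits
    return EnsembleDCAResult(
        n_realizations=n_realizations,
        appearance_fraction=counts / n_realizations,
        score_threshold=score_threshold,
        appearance_threshold=appearance_threshold,
        base_seed=base_seed,
        scorer_name=(scorer or mean_field_scores).__name__,
        n_a=n_a,
        n_b=n_b,
    )
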