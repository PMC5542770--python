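"""Phylogenetic discriminant analysis over position triplets.

The scan enumerates (or uniformly samples) position triplets of an annotated
alignment, scores each by the mixing entropy H of
:mod:`pdakit.triplet_scoring`, and derives:

* an empirical p-value for any score (fraction of scanned triplets with
  equal or lower H);
* a reference score, either the H of a designated reference triplet or a
  low percentile of the score distribution (default 5%) when no reference
  triplet is available;
* per-position selection frequencies — how often each position appears in
  the triplets scoring below the reference;
* a uniform-prior null model with expected frequency p_null = 3/N_pos and
  standard error sigma_p = sqrt(p_null (1 - p_null) / m) for m selected
  triplets, from which positions beyond a k-sigma threshold (default 3 and
  10) are called discriminating.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import ENCODING_SIZE, encoding_indices
from .errors import DataError, SchemaError
from .msa_io import Alignment, AnnotationTable
from .triplet_scoring import (
    ScoringConfig,
    _cluster_labels,
    _pca_scores,
    _weighted_entropy,
)

__all__ = [
    "PDAConfig",
    "TripletScoreTable",
    "NullModel",
    "PDAResult",
    "enumerate_triplets",
    "sample_triplets",
    "scan",
    "empirical_pvalue",
    "reference_threshold",
    "position_selection_frequency",
    "null_model",
    "select_positions",
    "run_pda",
    "regroup_and_rescan",
]


@dataclass(frozen=True)
class PDAConfig:
    """Resolved parameters of one PDA run."""

    scan_mode: str = "exhaustive"  # or "sampled"
    n_sample: int | None = None
    seed: int = 0
    reference_mode: str = "percentile"  # or "reference_triplet"
    reference_triplet: tuple[int, int, int] | None = None
    percentile: float = 5.0
    k_sigmas: tuple[float, ...] = (3.0, 10.0)
    variance_kept: float = 0.95
    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.scan_mode not in ("exhaustive", "sampled"):
            raise SchemaError("scan_mode must be 'exhaustive' or 'sampled'")
        if self.scan_mode == "sampled" and not self.n_sample:
            raise SchemaError("sampled mode requires n_sample")
        if self.reference_mode not in ("percentile", "reference_triplet"):
            raise SchemaError(
                "reference_mode must be 'percentile' or 'reference_triplet'"
            )
        if self.reference_mode == "reference_triplet" and self.reference_triplet is None:
            raise SchemaError("reference_triplet mode requires a triplet")
        if not 0.0 < self.percentile <= 100.0:
            raise SchemaError("percentile must lie in (0, 100]")

    def scoring(self) -> ScoringConfig:
        return ScoringConfig(self.variance_kept, self.linkage)

    def to_dict(self) -> dict:
        return {
            "scan_mode": self.scan_mode,
            "n_sample": self.n_sample,
            "seed": self.seed,
            "reference_mode": self.reference_mode,
            "reference_triplet": list(self.reference_triplet)
            if self.reference_triplet
            else None,
            "percentile": self.percentile,
            "k_sigmas": list(self.k_sigmas),
            "variance_kept": self.variance_kept,
            "linkage": self.linkage,
        }


@dataclass(frozen=True)
class TripletScoreTable:
    """Mixing scores H for a set of scanned triplets."""

    triplets: np.ndarray  # T x 3, strictly increasing rows
    H: np.ndarray  # T
    n_positions: int
    scan_mode: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.triplets.shape[0] != self.H.shape[0]:
            raise SchemaError("triplets and scores differ in length")

    @property
    def n_scanned(self) -> int:
        return int(self.triplets.shape[0])

    def score_of(self, triplet: Sequence[int]) -> float:
        t = tuple(sorted(int(x) for x in triplet))
        match = np.flatnonzero(
            (self.triplets[:, 0] == t[0])
            & (self.triplets[:, 1] == t[1])
            & (self.triplets[:, 2] == t[2])
        )
        if match.size == 0:
            raise DataError(f"triplet {t} was not scanned")
        return float(self.H[match[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": self.triplets[:, 0],
                "j": self.triplets[:, 1],
                "k": self.triplets[:, 2],
                "H": self.H,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class NullModel:
    """Uniform-prior null model for position selection frequencies."""

    n_positions: int
    m: int
    p_null: float
    sigma_p: float
    k_sigmas: tuple[float, ...]

    def threshold(self, k_sigma: float) -> float:
        return self.p_null + k_sigma * self.sigma_p

    @property
    def thresholds(self) -> dict[float, float]:
        return {k: self.threshold(k) for k in self.k_sigmas}

    def to_dict(self) -> dict:
        return {
            "n_positions": self.n_positions,
            "m": self.m,
            "p_null": self.p_null,
            "sigma_p": self.sigma_p,
            "thresholds": {str(k): v for k, v in self.thresholds.items()},
        }


@dataclass(frozen=True)
class PDAResult:
    """Full outcome of a PDA run."""

    score_table: TripletScoreTable
    reference_H: float
    reference_mode: str
    empirical_p: float
    selection_frequency: np.ndarray
    m_selected: int
    null: NullModel
    selected_positions: Mapping[float, tuple[int, ...]]
    config: PDAConfig
    grouping_name: str | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "grouping_name": self.grouping_name,
            "n_scanned": self.score_table.n_scanned,
            "reference_mode": self.reference_mode,
            "reference_H": self.reference_H,
            "empirical_p": self.empirical_p,
            "m_selected": self.m_selected,
            "selection_frequency": [float(x) for x in self.selection_frequency],
            "null_model": self.null.to_dict(),
            "selected_positions": {
                str(k): list(v) for k, v in self.selected_positions.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def enumerate_triplets(n_positions: int) -> np.ndarray:
    """All C(N, 3) strictly increasing triplets in lexicographic order."""
    if n_positions < 3:
        raise SchemaError("triplet enumeration requires at least 3 positions")
    return np.array(
        list(itertools.combinations(range(n_positions), 3)), dtype=np.int64
    )


def _unrank_triplet(rank: int, n: int) -> tuple[int, int, int]:
    """Triplet at a given lexicographic rank among C(n,3) combinations."""
    r = rank
    i = 0
    while True:
        c = math.comb(n - 1 - i, 2)
        if r < c:
            break
        r -= c
        i += 1
    j = i + 1
    while True:
        c = n - 1 - j
        if r < c:
            break
        r -= c
        j += 1
    return (i, j, j + 1 + r)


def sample_triplets(n_positions: int, m_sample: int, seed: int) -> np.ndarray:
    """Uniform sample of distinct triplets, without replacement.

    Output is sorted lexicographically; identical seeds give identical
    samples.  Sampling the full count returns exactly the exhaustive set.
    """
    total = math.comb(n_positions, 3)
    if not 1 <= m_sample <= total:
        raise SchemaError(
            f"m_sample must lie in [1, C({n_positions},3)={total}], got {m_sample}"
        )
    rng = np.random.default_rng(seed)
    ranks = np.sort(rng.choice(total, size=m_sample, replace=False))
    return np.array(
        [_unrank_triplet(int(r), n_positions) for r in ranks], dtype=np.int64
    )


def _group_indices(aln: Alignment, ann: AnnotationTable) -> tuple[np.ndarray, int]:
    groups = [ann.group_of(sid) for sid in aln.ids]
    uniq = sorted(set(groups))
    lut = {g: i for i, g in enumerate(uniq)}
    return np.array([lut[g] for g in groups], dtype=np.int64), len(uniq)


def scan(
    aln: Alignment,
    ann: AnnotationTable,
    triplets: np.ndarray | Sequence[Sequence[int]],
    config: ScoringConfig | None = None,
    scan_mode: str = "exhaustive",
    seed: int | None = None,
) -> TripletScoreTable:
    """Score every triplet in the list; deterministic given config.

    The per-triplet pipeline is identical to
    :func:`pdakit.triplet_scoring.score_triplet`; a shared one-hot encoding
    of the full alignment is computed once for speed.
    """
    cfg = config or ScoringConfig()
    trip = np.asarray(triplets, dtype=np.int64)
    if trip.ndim != 2 or trip.shape[1] != 3:
        raise SchemaError("triplets must be a T x 3 array")
    if trip.size and (trip.min() < 0 or trip.max() >= aln.width):
        raise SchemaError("triplet positions out of alignment range")
    if not (np.all(trip[:, 0] < trip[:, 1]) and np.all(trip[:, 1] < trip[:, 2])):
        raise SchemaError("triplets must be strictly increasing (i < j < k)")
    uniq = np.unique(trip, axis=0)
    if uniq.shape[0] != trip.shape[0]:
        raise DataError("duplicate triplets in scan input")

    gidx, n_groups = _group_indices(aln, ann)
    n = len(aln)
    sym = np.stack([encoding_indices(s) for s in aln.sequences])  # n x width
    eye = np.eye(ENCODING_SIZE)
    onehot = eye[sym].reshape(n, aln.width * ENCODING_SIZE)

    H = np.empty(trip.shape[0])
    base = np.arange(ENCODING_SIZE)
    for t, (i, j, k) in enumerate(trip):
        cols = np.concatenate((base + i * ENCODING_SIZE,
                               base + j * ENCODING_SIZE,
                               base + k * ENCODING_SIZE))
        X = onehot[:, cols]
        scores, _ = _pca_scores(X, cfg.variance_kept)
        labels = _cluster_labels(scores, cfg.linkage)
        H[t], _, _ = _weighted_entropy(labels, gidx, n_groups)
    return TripletScoreTable(trip, H, aln.width, scan_mode, seed)


def empirical_pvalue(table: TripletScoreTable, H_ref: float) -> float:
    """Fraction of scanned triplets with H equal to or lower than H_ref.

    Self-inclusive: the minimum attainable p-value for a scanned triplet is
    1 / T.
    """
    if table.n_scanned < 1:
        raise DataError("empirical p-value requires at least one scanned triplet")
    return float(np.count_nonzero(table.H <= H_ref) / table.n_scanned)


def reference_threshold(
    table: TripletScoreTable,
    mode: str,
    ref: Sequence[int] | float,
) -> float:
    """Reference mixing score used as selection cutoff.

    ``reference_triplet`` mode returns that triplet's H (it must have been
    scanned).  ``percentile`` mode returns the score delimiting the stated
    lower percentile of the empirical H distribution (no interpolation): the
    k-th smallest score with k = floor(percentile/100 * T), at least 1.
    """
    if mode == "reference_triplet":
        return table.score_of(ref)  # type: ignore[arg-type]
    if mode == "percentile":
        p = float(ref)  # type: ignore[arg-type]
        if not 0.0 < p <= 100.0:
            raise SchemaError("percentile must lie in (0, 100]")
        T = table.n_scanned
        k = max(1, int(math.floor(p * T / 100.0 + 1e-9)))
        return float(np.sort(table.H)[k - 1])
    raise SchemaError(f"unknown reference mode: {mode!r}")


def position_selection_frequency(
    table: TripletScoreTable,
    reference_H: float,
    inclusive: bool = False,
) -> tuple[np.ndarray, int]:
    """Per-position appearance frequency among triplets below the reference.

    With ``inclusive=False`` the selected set is {t : H(t) < reference_H}
    (the reference triplet itself is never selected); with
    ``inclusive=True`` ties at the reference value are included, the
    convention used for percentile cutoffs.  Frequencies are per-triplet
    fractions, so they sum to 3 whenever m > 0.  An empty selected set
    yields all-zero frequencies and a warning.
    """
    if inclusive:
        mask = table.H <= reference_H
    else:
        mask = table.H < reference_H
    m = int(np.count_nonzero(mask))
    freq = np.zeros(table.n_positions)
    if m == 0:
        warnings.warn(
            "no triplet scores below the reference; selection frequencies are 0",
            stacklevel=2,
        )
        return freq, 0
    counts = np.bincount(
        table.triplets[mask].ravel(), minlength=table.n_positions
    )
    return counts / m, m


def null_model(
    n_positions: int,
    m: int,
    k_sigmas: Sequence[float] = (3.0, 10.0),
) -> NullModel:
    """Uniform-prior null: p_null = 3/N_pos, sigma_p = sqrt(p(1-p)/m)."""
    if n_positions < 3:
        raise SchemaError("null model requires at least 3 positions")
    if m < 1:
        raise DataError("null model undefined for m = 0 selected triplets")
    p = 3.0 / n_positions
    sigma = math.sqrt(p * (1.0 - p) / m)
    return NullModel(n_positions, m, p, sigma, tuple(float(k) for k in k_sigmas))


def select_positions(
    frequencies: np.ndarray, null: NullModel, k_sigma: float
) -> tuple[int, ...]:
    """Positions whose selection frequency exceeds p_null + k_sigma * sigma_p."""
    if frequencies.shape[0] != null.n_positions:
        raise SchemaError("frequencies and null model disagree on N_pos")
    return tuple(int(i) for i in np.flatnonzero(frequencies > null.threshold(k_sigma)))


def run_pda(
    aln: Alignment,
    ann: AnnotationTable,
    config: PDAConfig | None = None,
    grouping_name: str | None = None,
) -> PDAResult:
    """Complete PDA pipeline on an annotated alignment."""
    cfg = config or PDAConfig()
    if cfg.scan_mode == "exhaustive":
        triplets = enumerate_triplets(aln.width)
    else:
        triplets = sample_triplets(aln.width, cfg.n_sample, cfg.seed)  # type: ignore[arg-type]
    table = scan(aln, ann, triplets, cfg.scoring(), cfg.scan_mode, cfg.seed)
    if cfg.reference_mode == "reference_triplet":
        ref_H = reference_threshold(table, "reference_triplet", cfg.reference_triplet)
        inclusive = False
    else:
        ref_H = reference_threshold(table, "percentile", cfg.percentile)
        inclusive = True
    p_emp = empirical_pvalue(table, ref_H)
    freq, m = position_selection_frequency(table, ref_H, inclusive=inclusive)
    if m >= 1:
        null = null_model(aln.width, m, cfg.k_sigmas)
        selected = {k: select_positions(freq, null, k) for k in cfg.k_sigmas}
    else:
        null = NullModel(aln.width, 0, 3.0 / aln.width, float("nan"), cfg.k_sigmas)
        selected = {k: () for k in cfg.k_sigmas}
    return PDAResult(
        score_table=table,
        reference_H=ref_H,
        reference_mode=cfg.reference_mode,
        empirical_p=p_emp,
        selection_frequency=freq,
        m_selected=m,
        null=null,
        selected_positions=selected,
        config=cfg,
        grouping_name=grouping_name,
    )


def regroup_and_rescan(
    aln: Alignment,
    ann: AnnotationTable,
    grouping_map: Mapping[str, str],
    config: PDAConfig | None = None,
    name: str | None = None,
) -> PDAResult:
    """Re-run the full PDA under a coarser/finer group partition.

    Used to check robustness of the selected positions against the chosen
    separation of phylogenetic classes.
    """
    relabeled = ann.relabel_groups(grouping_map)
    return run_pda(aln, relabeled, config, grouping_name=name)
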