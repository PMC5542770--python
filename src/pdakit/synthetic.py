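"""Synthetic alignment generators with planted, recorded ground truth.

Two generators cover the two analyses:

* :func:`make_grouped_msa` — an annotated alignment whose background
  columns are i.i.d. draws from a residue profile (uniform over the 20
  amino acids by default) and whose three planted columns carry a
  group-specific signature residue with probability ``purity`` (1.0 makes
  the planted triplet perfectly discriminating, 0.0 makes it pure
  background).
* :func:`make_paired_family` — two families over a shared organism set
  with per-organism paralog counts and a designated true partner map; at
  each planted (pos_A, pos_B) the columns are restricted to a two-residue
  alphabet and the coupled states co-occur in true partners with
  probability ``coupling_strength`` (non-partners are independent).

These emulate the statistical structure the analyses assume — group-
structured residue distributions and inter-family covariation — not
realistic phylogenies: there is no tree-based evolution, no indels, no
rate heterogeneity.  Every generator is deterministic per seed and
serializes its ground truth next to the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .alphabet import AMINO_ACIDS
from .dca_ensemble import PairedFamily
from .errors import SchemaError
from .msa_io import Alignment, AnnotationTable, write_alignment, write_annotations

__all__ = [
    "PlantedMSASpec",
    "PlantedPairedSpec",
    "make_grouped_msa",
    "make_paired_family",
    "write_msa_fixture",
    "write_paired_fixture",
]


@dataclass(frozen=True)
class PlantedMSASpec:
    """Recipe for a group-structured alignment with a planted triplet."""

    n_per_group: Mapping[str, int]
    n_positions: int
    planted_triplet: tuple[int, int, int]
    purity: float = 1.0
    background_profile: tuple[float, ...] | None = None  # over 20 amino acids
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group or any(n < 1 for n in self.n_per_group.values()):
            raise SchemaError("n_per_group must give a positive count per group")
        trip = tuple(self.planted_triplet)
        if len(set(trip)) != 3:
            raise SchemaError("planted triplet positions must be distinct")
        if any(not 0 <= p < self.n_positions for p in trip):
            raise SchemaError("planted triplet positions out of range")
        if not 0.0 <= self.purity <= 1.0:
            raise SchemaError("purity must lie in [0, 1]")
        if not 0.0 <= self.gap_rate < 1.0:
            raise SchemaError("gap_rate must lie in [0, 1)")
        if self.background_profile is not None:
            prof = np.asarray(self.background_profile)
            if prof.shape != (20,) or prof.min() < 0 or not np.isclose(prof.sum(), 1.0):
                raise SchemaError("background_profile must be a 20-simplex vector")
        if len(set(self.n_per_group)) > len(AMINO_ACIDS):
            raise SchemaError("at most 20 groups supported (one signature residue each)")


@dataclass(frozen=True)
class PlantedPairedSpec:
    """Recipe for a paired family with planted inter-protein covariation."""

    n_organisms: int
    paralogs_a: int
    paralogs_b: int
    n_positions_a: int
    n_positions_b: int
    planted_pairs: tuple[tuple[int, int], ...] = ((0, 0),)
    coupling_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organisms < 1:
            raise SchemaError("need at least one organism")
        if self.paralogs_a < 1 or self.paralogs_b < 1:
            raise SchemaError("paralog counts must be positive")
        for pa, pb in self.planted_pairs:
            if not 0 <= pa < self.n_positions_a:
                raise SchemaError(f"planted A-position {pa} out of range")
            if not 0 <= pb < self.n_positions_b:
                raise SchemaError(f"planted B-position {pb} out of range")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise SchemaError("coupling_strength must lie in [0, 1]")


def _draw_background(rng: np.random.Generator, shape, profile) -> np.ndarray:
    p = np.full(20, 0.05) if profile is None else np.asarray(profile, dtype=float)
    return rng.choice(20, size=shape, p=p / p.sum())


def make_grouped_msa(
    spec: PlantedMSASpec,
) -> tuple[Alignment, AnnotationTable, dict]:
    """Generate (alignment, annotations, ground-truth record).

    Signature residues are assigned deterministically: the g-th group (in
    sorted label order) carries the g-th amino acid of the alphabetical
    residue ordering at every planted position, so fixtures are stable
    across runs and versions.
    """
    rng = np.random.default_rng(spec.seed)
    groups = sorted(spec.n_per_group)
    signatures = {g: AMINO_ACIDS[i] for i, g in enumerate(groups)}
    n_total = sum(spec.n_per_group.values())

    codes = _draw_background(
        rng, (n_total, spec.n_positions), spec.background_profile
    )
    chars = np.array(list(AMINO_ACIDS))
    mat = chars[codes]

    labels: list[str] = []
    row = 0
    for g in groups:
        for _ in range(spec.n_per_group[g]):
            for p in spec.planted_triplet:
                if rng.random() < spec.purity:
                    mat[row, p] = signatures[g]
            labels.append(g)
            row += 1

    if spec.gap_rate > 0.0:
        gaps = rng.random(mat.shape) < spec.gap_rate
        mat[gaps] = "-"

    ids = []
    entries = {}
    counters: dict[str, int] = {}
    for i, g in enumerate(labels):
        counters[g] = counters.get(g, 0) + 1
        sid = f"{g}_{counters[g]:04d}"
        ids.append(sid)
        entries[sid] = (g, f"org{i:04d}")

    aln = Alignment(tuple(ids), tuple("".join(r) for r in mat))
    ann = AnnotationTable(entries)
    truth = {
        "kind": "planted_msa",
        "planted_triplet": list(spec.planted_triplet),
        "signatures": signatures,
        "purity": spec.purity,
        "n_positions": spec.n_positions,
        "n_per_group": dict(spec.n_per_group),
        "gap_rate": spec.gap_rate,
        "seed": spec.seed,
    }
    return aln, ann, truth


def _planted_letters(pair_index: int) -> tuple[str, str]:
    """Stable two-residue alphabet for the k-th planted pair."""
    a = AMINO_ACIDS[(2 * pair_index) % 20]
    b = AMINO_ACIDS[(2 * pair_index + 1) % 20]
    return a, b


def make_paired_family(
    spec: PlantedPairedSpec,
) -> tuple[PairedFamily, dict]:
    """Generate a paired family with planted covarying position pairs.

    Within each organism, the i-th family-A paralog is the true partner of
    the i-th family-B paralog (for i < min of the paralog counts).  At each
    planted (pos_A, pos_B), both columns use a two-residue alphabet; the
    true partner copies its A-side state with probability
    ``coupling_strength`` (otherwise flips it), while non-partner sequences
    draw independently.  Background columns are uniform over 20 residues.
    """
    rng = np.random.default_rng(spec.seed)
    chars = np.array(list(AMINO_ACIDS))

    ids_a, seqs_a, ann_a = [], [], {}
    ids_b, seqs_b, ann_b = [], [], {}
    partners: list[tuple[str, str]] = []

    planted_a = {pa for pa, _ in spec.planted_pairs}
    planted_b = {pb for _, pb in spec.planted_pairs}

    for o in range(spec.n_organisms):
        org = f"org{o:04d}"
        rows_a = chars[rng.choice(20, size=(spec.paralogs_a, spec.n_positions_a))]
        rows_b = chars[rng.choice(20, size=(spec.paralogs_b, spec.n_positions_b))]
        # planted-column states
        states_a = rng.integers(0, 2, size=(spec.paralogs_a, len(spec.planted_pairs)))
        states_b = rng.integers(0, 2, size=(spec.paralogs_b, len(spec.planted_pairs)))
        n_partners = min(spec.paralogs_a, spec.paralogs_b)
        for k in range(len(spec.planted_pairs)):
            for i in range(n_partners):
                if rng.random() < spec.coupling_strength:
                    states_b[i, k] = states_a[i, k]
                else:
                    states_b[i, k] = 1 - states_a[i, k]
        for k, (pa, pb) in enumerate(spec.planted_pairs):
            la, lb = _planted_letters(k)
            rows_a[:, pa] = np.where(states_a[:, k] == 0, la, lb)
            rows_b[:, pb] = np.where(states_b[:, k] == 0, la, lb)

        for i in range(spec.paralogs_a):
            sid = f"{org}_A{i}"
            ids_a.append(sid)
            seqs_a.append("".join(rows_a[i]))
            ann_a[sid] = ("A", org)
        for i in range(spec.paralogs_b):
            sid = f"{org}_B{i}"
            ids_b.append(sid)
            seqs_b.append("".join(rows_b[i]))
            ann_b[sid] = ("B", org)
        for i in range(n_partners):
            partners.append((f"{org}_A{i}", f"{org}_B{i}"))

    pf = PairedFamily(
        Alignment(tuple(ids_a), tuple(seqs_a)),
        AnnotationTable(ann_a),
        Alignment(tuple(ids_b), tuple(seqs_b)),
        AnnotationTable(ann_b),
    )
    truth = {
        "kind": "planted_paired_family",
        "planted_pairs": [list(p) for p in spec.planted_pairs],
        "planted_letters": [
            list(_planted_letters(k)) for k in range(len(spec.planted_pairs))
        ],
        "coupling_strength": spec.coupling_strength,
        "true_partners": [list(p) for p in partners],
        "n_organisms": spec.n_organisms,
        "paralogs_a": spec.paralogs_a,
        "paralogs_b": spec.paralogs_b,
        "n_positions_a": spec.n_positions_a,
        "n_positions_b": spec.n_positions_b,
        "seed": spec.seed,
    }
    return pf, truth


def write_msa_fixture(
    spec: PlantedMSASpec, outdir: str | Path, prefix: str = "planted_msa"
) -> dict[str, Path]:
    """Write alignment FASTA, annotation TSV and ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, ann, truth = make_grouped_msa(spec)
    paths = {
        "alignment": outdir / f"{prefix}.fasta",
        "annotations": outdir / f"{prefix}.annotations.tsv",
        "ground_truth": outdir / f"{prefix}.truth.json",
    }
    write_alignment(aln, paths["alignment"])
    write_annotations(ann, paths["annotations"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def write_paired_fixture(
    spec: PlantedPairedSpec, outdir: str | Path, prefix: str = "planted_pair"
) -> dict[str, Path]:
    """Write the two family FASTA/TSV pairs and the ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pf, truth = make_paired_family(spec)
    paths = {
        "alignment_a": outdir / f"{prefix}.familyA.fasta",
        "annotations_a": outdir / f"{prefix}.familyA.annotations.tsv",
        "alignment_b": outdir / f"{prefix}.familyB.fasta",
        "annotations_b": outdir / f"{prefix}.familyB.annotations.tsv",
        "ground_truth": outdir / f"{prefix}.truth.json",
    }
    write_alignment(pf.alignment_a, paths["alignment_a"])
    write_annotations(pf.annotations_a, paths["annotations_a"])
    write_alignment(pf.alignment_b, paths["alignment_b"])
    write_annotations(pf.annotations_b, paths["annotations_b"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
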