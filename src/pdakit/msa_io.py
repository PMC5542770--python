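"""Alignment and annotation I/O plus sequence-level filters.

This module provides the data containers shared by the whole package
(:class:`Alignment`, :class:`AnnotationTable`, :class:`UnalignedSequenceSet`)
and the pre-processing rules applied before any analysis:

* a gap-fraction filter that drops alignment rows with more than a given
  fraction of gap characters (default: more than 20%);
* counting of the zinc-finger ``CxxCxGxG`` motif on complete, unaligned
  sequences, and the motif-based partition that separates class A J-protein
  sequences (at least two motifs) from class B (no motif) — the rule used to
  disambiguate the two J-protein sub-families.

File formats go through Biopython (FASTA, Stockholm) and pandas (TSV).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentFormatError,
    AnnotationLookupError,
    DataError,
    DuplicateIdError,
    EmptyInputError,
    SchemaError,
)

__all__ = [
    "Alignment",
    "AnnotationTable",
    "UnalignedSequenceSet",
    "read_alignment",
    "write_alignment",
    "read_annotations",
    "write_annotations",
    "read_sequences",
    "filter_by_gap_fraction",
    "count_zf_motifs",
    "partition_by_motif",
    "ZF_MOTIF_PATTERN",
]

_GAP_CHARS = ("-", ".")


@dataclass(frozen=True)
class Alignment:
    """An aligned set of sequences over {20 amino acids, 'X', '-'}.

    All sequences have identical length ``width``; ids are unique.  An
    empty alignment (zero records) is permitted only when ``width`` is
    given explicitly, so that filters may legitimately remove every row.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    explicit_width: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentFormatError("ids and sequences differ in number")
        if not self.ids and self.explicit_width is None:
            raise EmptyInputError("empty alignment requires an explicit width")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise DuplicateIdError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
        width = self.explicit_width if not self.sequences else len(self.sequences[0])
        if width is not None and width < 1:
            raise AlignmentFormatError("alignment width must be >= 1")
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != width:
                raise AlignmentFormatError(
                    f"sequence {sid!r} has length {len(seq)}, expected {width}"
                )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]], width: int | None = None
    ) -> "Alignment":
        ids, seqs = [], []
        for sid, seq in records:
            ids.append(sid)
            seqs.append(_normalize(seq))
        return cls(tuple(ids), tuple(seqs), explicit_width=width)

    @property
    def width(self) -> int:
        if self.sequences:
            return len(self.sequences[0])
        assert self.explicit_width is not None
        return self.explicit_width

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def records(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.ids, self.sequences))

    def gap_counts(self) -> np.ndarray:
        """Number of gap characters per record."""
        return np.array([s.count("-") for s in self.sequences], dtype=np.int64)

    def sequence(self, sid: str) -> str:
        try:
            return self.sequences[self.ids.index(sid)]
        except ValueError:
            raise AnnotationLookupError(f"no sequence with id {sid!r}") from None

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        wanted = set(keep_ids)
        recs = [(i, s) for i, s in self.records if i in wanted]
        return Alignment.from_records(recs, width=self.width)


@dataclass(frozen=True)
class AnnotationTable:
    """Per-sequence phylogenetic group label and organism id."""

    entries: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sid: str) -> bool:
        return sid in self.entries

    def group_of(self, sid: str) -> str:
        try:
            return self.entries[sid][0]
        except KeyError:
            raise AnnotationLookupError(f"sequence {sid!r} has no annotation") from None

    def organism_of(self, sid: str) -> str:
        try:
            return self.entries[sid][1]
        except KeyError:
            raise AnnotationLookupError(f"sequence {sid!r} has no annotation") from None

    def groups(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, _ in self.entries.values()}))

    def relabel_groups(self, mapping: Mapping[str, str]) -> "AnnotationTable":
        """Map group labels to a coarser/finer partition; must cover all groups."""
        missing = [g for g in self.groups() if g not in mapping]
        if missing:
            raise SchemaError(f"grouping map does not cover groups: {missing}")
        return AnnotationTable(
            {sid: (mapping[g], org) for sid, (g, org) in self.entries.items()}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": sid, "group": g, "organism": org}
            for sid, (g, org) in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["id", "group", "organism"])


@dataclass(frozen=True)
class UnalignedSequenceSet:
    """Complete (gap-free) sequences, e.g. full-length proteins."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sid, seq in self.records:
            if sid in seen:
                raise DuplicateIdError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
            if any(c in seq for c in _GAP_CHARS):
                raise DataError(f"sequence {sid!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    Residues are upper-cased and ``.`` gaps normalized to ``-``.  Unequal
    sequence lengths raise :class:`AlignmentFormatError` naming the first
    offending id; an empty file raises :class:`EmptyInputError`.
    """
    if fmt not in ("fasta", "stockholm"):
        raise SchemaError(f"unsupported alignment format: {fmt!r}")
    path = Path(path)
    records = [(rec.id, _normalize(str(rec.seq))) for rec in SeqIO.parse(path, fmt)]
    if not records:
        raise EmptyInputError(f"no sequences found in {path}")
    width = len(records[0][1])
    for sid, seq in records:
        if len(seq) != width:
            raise AlignmentFormatError(
                f"sequence {sid!r} has length {len(seq)}, expected {width} "
                f"(first sequence {records[0][0]!r})"
            )
    return Alignment.from_records(records)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as single-line-per-sequence FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")


def read_sequences(path: str | Path) -> UnalignedSequenceSet:
    """Read complete, unaligned sequences from FASTA."""
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(Path(path), "fasta")
    )
    if not records:
        raise EmptyInputError(f"no sequences found in {path}")
    return UnalignedSequenceSet(records)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a tab-delimited annotation table with columns id, group, organism."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("id", "group", "organism") if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing columns: {missing}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise DuplicateIdError(f"duplicate annotation id: {dup!r}")
    entries = {
        row.id: (row.group, row.organism)
        for row in df.itertuples(index=False)
    }
    return AnnotationTable(entries)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    ann.to_frame().to_csv(path, sep="\t", index=False)


def filter_by_gap_fraction(aln: Alignment, max_gap_fraction: float = 0.20) -> Alignment:
    """Drop records with strictly more than ``max_gap_fraction`` gaps.

    A record with gap fraction exactly equal to the threshold is retained
    (removal requires "more than" the threshold).  Order is preserved; the
    result may be empty.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise SchemaError("max_gap_fraction must lie in [0, 1]")
    width = aln.width
    kept = [
        (sid, seq)
        for sid, seq in aln.records
        if seq.count("-") / width <= max_gap_fraction
    ]
    return Alignment.from_records(kept, width=width)


#: Zinc-finger signature: C, any, any, C, any, G, any, G.  The literal C/G
#: positions must match exactly (``X`` does not satisfy them); wildcard
#: positions accept any residue.  Lookahead makes matches overlapping.
ZF_MOTIF_PATTERN = re.compile(r"(?=C..C.G.G)")


def count_zf_motifs(seq: str) -> int:
    """Count (possibly overlapping) CxxCxGxG zinc-finger motif windows."""
    if any(c in seq for c in _GAP_CHARS):
        raise DataError("motif counting requires a gap-free sequence")
    return len(ZF_MOTIF_PATTERN.findall(seq.upper()))


def partition_by_motif(
    seqs: UnalignedSequenceSet,
    class_a_min: int = 2,
    class_b_max: int = 0,
) -> tuple[set[str], set[str], set[str]]:
    """Partition sequence ids by zinc-finger motif count.

    Ids with at least ``class_a_min`` motifs go to class A, ids with at most
    ``class_b_max`` motifs to class B, the rest are unassigned.  The default
    thresholds implement the J-protein rule: class A keeps sequences with at
    least two motifs, class B discards any sequence containing the motif.
    """
    if class_a_min <= class_b_max:
        raise SchemaError("class_a_min must exceed class_b_max")
    class_a: set[str] = set()
    class_b: set[str] = set()
    unassigned: set[str] = set()
    for sid, seq in seqs.records:
        n = count_zf_motifs(seq)
        if n >= class_a_min:
            class_a.add(sid)
        elif n <= class_b_max:
            class_b.add(sid)
        else:
            unassigned.add(sid)
    return class_a, class_b, unassigned
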