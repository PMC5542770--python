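"""Pre-processing: gap filtering and zinc-finger class disambiguation.

Builds a toy alignment plus the corresponding complete (unaligned)
sequences, removes rows with more than 20% gaps, and splits the remaining
ids into class A (at least two CxxCxGxG motifs in the full-length
sequence), class B (no motif) and an unassigned middle ground — the rule
used to keep class A and class B J-protein alignments free of each other's
members.
"""

from pdakit import (
    Alignment,
    UnalignedSequenceSet,
    count_zf_motifs,
    filter_by_gap_fraction,
    partition_by_motif,
)

aligned = Alignment.from_records(
    [
        ("seq1", "ACDEFGHIKL"),
        ("seq2", "AC---GH--L"),  # 50% gaps: dropped
        ("seq3", "ACDE-GHIKL"),  # 10% gaps: kept
        ("seq4", "ACDEFGHIK-"),
    ]
)
kept = filter_by_gap_fraction(aligned, max_gap_fraction=0.20)
print(f"gap filter: kept {len(kept)} of {len(aligned)} rows -> {kept.ids}")

full_length = UnalignedSequenceSet(
    (
        ("seq1", "MKCPTCSGSGAKCEHCNGSGMV"),  # two motifs -> class A
        ("seq3", "MKAAAAAAAAAAAAAAAAAAMV"),  # no motif  -> class B
        ("seq4", "MKCPTCSGSGAAAAAAAAAAMV"),  # one motif -> unassigned
    )
)
for sid, seq in full_length.records:
    print(f"  {sid}: {count_zf_motifs(seq)} zinc-finger motif(s)")

class_a, class_b, unassigned = partition_by_motif(full_length)
print(f"class A {sorted(class_a)}, class B {sorted(class_b)}, "
      f"unassigned {sorted(unassigned)}")
# Class A keeps only confident zinc-finger carriers; class B excludes any
# sequence containing the motif, so the two alignments cannot overlap.
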