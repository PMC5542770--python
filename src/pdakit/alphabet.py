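"""Residue alphabets.

Two alphabets are used in the package:

* the *encoding* alphabet for triplet analysis — the 20 standard amino
  acids, the ambiguity symbol ``X`` and the gap ``-`` (22 symbols).  Any
  non-standard residue code (B, Z, U, O, J, ...) is folded into ``X``.
* the *coupling* alphabet for direct coupling analysis — the 20 standard
  amino acids plus a single gap/unknown state (21 states, the common DCA
  convention).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: 22-symbol alphabet used for one-hot encoding of reduced alignments.
ENCODING_ALPHABET = AMINO_ACIDS + UNKNOWN + GAP
ENCODING_SIZE = len(ENCODING_ALPHABET)

#: number of states for coupling analysis: 20 amino acids + gap/unknown.
COUPLING_STATES = 21
COUPLING_GAP_STATE = 20

_ENC_LOOKUP = np.full(128, ENCODING_ALPHABET.index(UNKNOWN), dtype=np.int64)
for _i, _s in enumerate(ENCODING_ALPHABET):
    _ENC_LOOKUP[ord(_s)] = _i
_ENC_LOOKUP[ord(".")] = ENCODING_ALPHABET.index(GAP)

_DCA_LOOKUP = np.full(128, COUPLING_GAP_STATE, dtype=np.int64)
for _i, _s in enumerate(AMINO_ACIDS):
    _DCA_LOOKUP[ord(_s)] = _i


def _to_codepoints(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("latin-1", errors="replace"), dtype=np.uint8)
    return np.minimum(arr, 127).astype(np.int64)


def encoding_indices(seq: str) -> np.ndarray:
    """Map a residue string to indices in the 22-symbol encoding alphabet."""
    return _ENC_LOOKUP[_to_codepoints(seq)]


def coupling_indices(seq: str) -> np.ndarray:
    """Map a residue string to the 21-state coupling alphabet (gap/unknown = 20)."""
    return _DCA_LOOKUP[_to_codepoints(seq)]
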