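"""DNA alphabet encoding shared by the index and the matchers.

The indexed text is drawn from ``$ACGTX`` where ``$`` is the unique
lexicographically-smallest sentinel and ``X`` is a reserved fifth character
that every non-ACGT reference base (N and IUPAC ambiguity codes) is replaced
with.  ``X`` matches nothing -- not even another ``X`` -- so any alignment
across such a base is forced to spend an error there.  This keeps the
"report everything within distance k" guarantee well defined in the presence
of ambiguous bases.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "$ACGTX"
SENTINEL = 0
#: codes that index-space extension may try (everything except the sentinel)
EXTENDABLE = (1, 2, 3, 4, 5)
#: codes that can ever match a pattern character (A, C, G, T)
MATCHABLE = frozenset((1, 2, 3, 4))

_ENCODE = np.full(256, 5, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "X": "X"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes; unknown characters become X (5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = _ENCODE[raw]
    # '$' may only be introduced by the index builder itself
    if seq and SENTINEL in out and "$" in seq:
        raise ValueError("'$' is reserved for the index sentinel")
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c.upper(), "N") for c in reversed(seq))
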