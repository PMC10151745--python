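"""Semi-global pairwise alignment shared by clustering and taxonomy search.

The aligner scores match +1 / mismatch -1 / gap -2 in a fitting (semi-global)
alignment: the first sequence (the query) is aligned end to end, while end
gaps on the second sequence (the subject) are free and excluded from the
identity denominator.  Identity is matching columns over alignment columns,
internal gaps included.  Aligning the query globally keeps identity
meaningful between unrelated sequences (an overlap alignment with free end
gaps on both sides would happily report a perfect one-column overlap).

Ties are broken deterministically: diagonal over up over left during the
dynamic program, and the endpoint is the first maximum scanning the last row
left-to-right.  Any independent re-implementation using the same tie-break
rules reproduces the exact (matches, columns) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

IUPAC_DNA = frozenset(b"ACGTURYSWKMBDHVN")


def encode_seq(seq: str) -> np.ndarray:
    """Validate a DNA string against the IUPAC alphabet and encode it as uint8."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        data = seq.upper().encode("ascii")
    except UnicodeEncodeError as exc:  # pragma: no cover - exotic input
        raise ValueError(f"non-ASCII character in sequence: {seq!r}") from exc
    bad = set(data) - IUPAC_DNA
    if bad:
        raise ValueError(
            "non-IUPAC characters in sequence: " + ", ".join(chr(b) for b in sorted(bad))
        )
    return np.frombuffer(data, dtype=np.uint8).copy()


@njit(cache=True)
def _sg_core(a, b, match, mismatch, gap):  # pragma: no cover - numba-compiled
    n = a.size
    m = b.size
    S = np.zeros((n + 1, m + 1), np.int32)
    P = np.zeros((n + 1, m + 1), np.uint8)  # 1=diag, 2=up, 3=left
    for i in range(1, n + 1):  # query end gaps are penalised
        S[i, 0] = S[i - 1, 0] + gap
        P[i, 0] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if ai == b[j - 1] else mismatch
            best = S[i - 1, j - 1] + sub
            ptr = 1
            up = S[i - 1, j] + gap
            if up > best:
                best = up
                ptr = 2
            left = S[i, j - 1] + gap
            if left > best:
                best = left
                ptr = 3
            S[i, j] = best
            P[i, j] = ptr
    # endpoint: first maximum over the last row, scanning left to right
    bs = np.int32(-2147483648)
    bj = 0
    for j in range(m + 1):
        if S[n, j] > bs:
            bs = S[n, j]
            bj = j
    matches = 0
    cols = 0
    prof = np.zeros(n, np.uint8)
    i = n
    j = bj
    while i > 0:
        p = P[i, j]
        if p == 1:
            cols += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
                prof[i - 1] = 1
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return bs, matches, cols, prof


@dataclass(frozen=True)
class Alignment:
    """Summary of one semi-global alignment."""

    score: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def semi_global(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> Alignment:
    """Fitting alignment of query `a` against subject `b` (free subject end gaps)."""
    ea = encode_seq(a)
    eb = encode_seq(b)
    score, matches, cols, _ = _sg_core(ea, eb, match, mismatch, gap)
    return Alignment(int(score), int(matches), int(cols))


def match_profile(candidate: str, other: str, match: int = 1, mismatch: int = -1,
                  gap: int = -2) -> np.ndarray:
    """Per-position match mask over `candidate` from its alignment to `other`.

    Entry i is 1 iff candidate position i sits in a match column.  Used by the
    two-parent chimera scan, which combines prefix/suffix profiles from two
    putative parents via cumulative sums.
    """
    ea = encode_seq(candidate)
    eb = encode_seq(other)
    _, _, _, prof = _sg_core(ea, eb, match, mismatch, gap)
    return prof
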