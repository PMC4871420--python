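"""Global and semi-global nucleotide alignment with BLAST-style identity.

Scoring is fixed unit-cost: match +1, mismatch -1, gap -2 per gap column
(linear). By default N matches nothing, including another N (the semantics
behind the 97% reference-identity rule); clustering requests plain letter
equality instead so identical N padding compares as equal. Identity is
reported as identical columns over alignment columns — gap columns count —
because the 97/98/99/100% scoring bands downstream depend on exactly this
definition.

The dynamic program fills the full matrix (vectorised along anti-diagonals,
whose cells are mutually independent under a linear gap penalty), so the
reported identity is that of a true optimum, not of a banded approximation.
Traceback prefers diagonal over up (gap in b) over left (gap in a); this
makes the reported alignment, and hence the identity, deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MATCH = 1
MISMATCH = -1
GAP = -2

_CODE = np.full(256, 4, dtype=np.uint8)  # everything unknown -> N
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, else N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Alignment:
    """Result of a pairwise alignment."""

    score: int
    matches: int
    columns: int

    @property
    def identity_pct(self) -> float:
        return round(100.0 * self.matches / self.columns, 2)


def _match_mask(a: np.ndarray, b: np.ndarray, nn_match: bool) -> np.ndarray:
    eq = a[:, None] == b[None, :]
    if not nn_match:
        eq &= a[:, None] != N_CODE
    return eq


def _fill(a: np.ndarray, b: np.ndarray, free_b_ends: bool, nn_match: bool) -> np.ndarray:
    m, n = len(a), len(b)
    # substitution scores S[i, j] for a[i] vs b[j]
    S = np.where(_match_mask(a, b, nn_match), MATCH, MISMATCH).astype(np.int32)
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    H[:, 0] = GAP * np.arange(m + 1)
    H[0, :] = 0 if free_b_ends else GAP * np.arange(n + 1)
    # Row-wise fill. With a linear gap penalty the left-gap recurrence
    # H[i,j] = max(c[j], H[i,j-1] + GAP) unrolls to a running maximum:
    # H[i,j] = max_{k<=j} (c[k] + GAP*(j-k)), computed with one
    # maximum.accumulate over c[k] - GAP*k.
    offs = (-GAP) * np.arange(n + 1)
    c = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        prev = H[i - 1]
        c[0] = H[i, 0]
        np.maximum(prev[:-1] + S[i - 1], prev[1:] + GAP, out=c[1:])
        np.maximum.accumulate(c + offs, out=c)
        H[i] = c - offs
    return H


def _traceback(
    H: np.ndarray, a: np.ndarray, b: np.ndarray, i: int, j: int,
    free_b_ends: bool, nn_match: bool,
) -> Alignment:
    def is_match(x, y):
        return x == y and (nn_match or x != N_CODE)

    matches = columns = 0
    while i > 0 or j > 0:
        if free_b_ends and i == 0:
            break  # remaining b prefix is a free end gap, not part of the alignment
        if (
            i > 0
            and j > 0
            and H[i, j]
            == H[i - 1, j - 1]
            + (MATCH if is_match(a[i - 1], b[j - 1]) else MISMATCH)
        ):
            matches += int(is_match(a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    return Alignment(score=0, matches=matches, columns=columns)


def align_global(a: np.ndarray, b: np.ndarray, nn_match: bool = False) -> Alignment:
    """Needleman-Wunsch global alignment of two encoded sequences.

    With ``nn_match`` True, N is scored by plain letter equality (N matches
    N), the convention greedy clustering uses for N-padded fragments.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty sequence")
    H = _fill(a, b, free_b_ends=False, nn_match=nn_match)
    res = _traceback(H, a, b, len(a), len(b), free_b_ends=False, nn_match=nn_match)
    return Alignment(int(H[len(a), len(b)]), res.matches, res.columns)


def align_glocal(a: np.ndarray, b: np.ndarray) -> Alignment:
    """Semi-global alignment: ``a`` aligned end to end, end gaps in ``b`` free.

    Used for querying a (possibly short) sequence against a full-length
    reference: the unaligned reference overhangs cost nothing and are not
    counted as alignment columns, mirroring how BLAST reports identity over
    the aligned span only.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty sequence")
    H = _fill(a, b, free_b_ends=True, nn_match=False)
    m = len(a)
    jend = int(np.argmax(H[m, :]))
    res = _traceback(H, a, b, m, jend, free_b_ends=True, nn_match=False)
    return Alignment(int(H[m, jend]), res.matches, res.columns)
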