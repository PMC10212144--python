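"""Global pairwise alignment used to anchor motif transfer.

Implements affine-gap global alignment (Gotoh) with BLOSUM62 and the
EMBOSS-style gap cost ``open + extend * (L - 1)`` for a gap of length L.
Tie-breaking is fixed (diagonal over up over left; match state over
query-gap over reference-gap) so alignments are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_NEG = -1e30


class AlignmentInputError(ValueError):
    """Raised for empty sequences or non-amino-acid characters."""


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    reference_id: str
    aligned_query: str
    aligned_reference: str
    score: float

    def __post_init__(self):
        assert len(self.aligned_query) == len(self.aligned_reference)

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def reference(self) -> str:
        return self.aligned_reference.replace("-", "")

    def reference_to_query_map(self) -> dict[int, int]:
        """1-based reference position -> 1-based query position.

        Reference columns aligned to a gap in the query are absent.
        """
        out: dict[int, int] = {}
        qi = ri = 0
        for qc, rc in zip(self.aligned_query, self.aligned_reference):
            if qc != "-":
                qi += 1
            if rc != "-":
                ri += 1
                if qc != "-":
                    out[ri] = qi
        return out


@lru_cache(maxsize=1)
def _blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    n = len(_ALPHABET)
    out = np.zeros((n, n))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            out[i, j] = mat[a, b]
    return out


def _encode(seq: str, label: str) -> np.ndarray:
    idx = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, a in enumerate(_ALPHABET):
        lut[ord(a)] = i
    enc = lut[idx]
    if (enc < 0).any():
        bad = sorted({c for c in seq if c not in _ALPHABET})
        raise AlignmentInputError(
            f"{label}: non-amino-acid characters {bad} (X is permitted)")
    return enc


def global_align(query: str, reference: str, *,
                 query_id: str = "query", reference_id: str = "reference",
                 gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND) -> PairwiseAlignment:
    """Optimal global alignment of two amino-acid sequences.

    Raises :class:`AlignmentInputError` on empty input or characters
    outside the 20 standard residues plus ``X``.
    """
    query = query.upper()
    reference = reference.upper()
    if not query or not reference:
        raise AlignmentInputError("sequences must be non-empty")
    q = _encode(query, "query")
    r = _encode(reference, "reference")
    sub = _blosum62()[np.ix_(q, r)]  # (n, m) substitution scores
    n, m = len(q), len(r)
    op, ex = float(gap_open), float(gap_extend)

    # state rows for i-1 and pointers (0=M, 1=Ix "up", 2=Iy "left")
    M = np.full(m + 1, _NEG)
    Ix = np.full(m + 1, _NEG)
    Iy = np.full(m + 1, _NEG)
    M[0] = 0.0
    if m:
        Iy[1:] = -(op + ex * np.arange(m))
    pm = np.zeros((n + 1, m + 1), dtype=np.int8)
    px = np.zeros((n + 1, m + 1), dtype=np.int8)
    py = np.full((n + 1, m + 1), 2, dtype=np.int8)
    py[0, 1] = 0
    jj = np.arange(m)

    for i in range(1, n + 1):
        prev_best = np.maximum(M, np.maximum(Ix, Iy))
        new_M = np.full(m + 1, _NEG)
        new_M[1:] = sub[i - 1] + prev_best[:-1]
        # pointer for M: predecessor state at (i-1, j-1); prefer M>Ix>Iy
        pm[i, 1:] = np.where(M[:-1] >= prev_best[:-1], 0,
                             np.where(Ix[:-1] >= prev_best[:-1], 1, 2))
        # Ix: consume query residue (gap in reference)
        cand_open = np.maximum(M, Iy) - op
        new_Ix = np.maximum(cand_open, Ix - ex)
        px[i] = np.where(M - op >= new_Ix, 0,
                         np.where(Ix - ex >= new_Ix, 1, 2))
        # Iy: consume reference residue (gap in query); running-max trick
        new_Iy = np.full(m + 1, _NEG)
        if m:
            c = np.maximum(new_M[:-1], new_Ix[:-1]) - op  # open at column k
            t = c + ex * jj
            run = np.maximum.accumulate(t)
            new_Iy[1:] = run - ex * jj
            py[i, 1:] = np.where(
                new_M[:-1] - op >= new_Iy[1:], 0,
                np.where(new_Ix[:-1] - op >= new_Iy[1:], 1, 2))
        M, Ix, Iy = new_M, new_Ix, new_Iy

    order = (M[m], Ix[m], Iy[m])
    # preference M > Ix > Iy on exact ties
    best = max(order)
    if order[0] >= best:
        state = 0
    elif order[1] >= best:
        state = 1
    else:
        state = 2
    score = float(order[state])

    aq: list[str] = []
    ar: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            aq.append(query[i - 1])
            ar.append(reference[j - 1])
            state = int(pm[i, j])
            i -= 1
            j -= 1
        elif state == 1:
            aq.append(query[i - 1])
            ar.append("-")
            state = int(px[i, j])
            i -= 1
        else:
            aq.append("-")
            ar.append(reference[j - 1])
            state = int(py[i, j])
            j -= 1
    return PairwiseAlignment(query_id=query_id, reference_id=reference_id,
                             aligned_query="".join(reversed(aq)),
                             aligned_reference="".join(reversed(ar)),
                             score=score)
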