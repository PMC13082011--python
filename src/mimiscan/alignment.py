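"""Local protein alignment with BLOSUM62, affine gaps, and Karlin-Altschul
expect values.

The aligner is a three-state (match / gap-in-subject / gap-in-query)
Smith-Waterman with a deterministic traceback (tie order: diagonal, then up,
then left), so repeated runs on the same pair return the same alignment.  A
gap of length k costs ``gap_open + k * gap_extend`` (defaults 11 + k).

Each aligned column is flagged:

* ``identity``  — equal residues,
* ``conserved`` — different residues with BLOSUM62 score > 0
  (the conserved-substitution convention),
* ``mismatch``  — different residues with score <= 0,
* ``gap``       — a gap in either sequence.

The expect value uses the Karlin-Altschul formula E = K * m * n * exp(-lambda * S)
with standard gapped-BLOSUM62 constants (K = 0.041, lambda = 0.267) and
m, n the query and subject lengths — suitable for ranking candidates, not for
database-corrected significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentReport",
    "smith_waterman",
    "blosum62_score",
    "CANONICAL_AA",
    "KA_K",
    "KA_LAMBDA",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
KA_K = 0.041
KA_LAMBDA = 0.267

COL_IDENTITY = "identity"
COL_CONSERVED = "conserved"
COL_MISMATCH = "mismatch"
COL_GAP = "gap"


@lru_cache(maxsize=1)
def _blosum62():
    return substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> int:
    """BLOSUM62 substitution score for a residue pair."""
    return int(_blosum62()[a, b])


def _validate_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    for pos, res in enumerate(seq, start=1):
        if res not in CANONICAL_AA:
            raise ValueError(
                f"{name} sequence: non-canonical residue {res!r} at position {pos}"
            )


@dataclass(frozen=True)
class AlignmentReport:
    """A local alignment of a query epitope against a candidate protein."""

    candidate_id: str
    raw_score: int
    bit_score: float
    expect: float
    query_aligned: str
    subject_aligned: str
    column_flags: tuple[str, ...]
    query_interval: tuple[int, int]    # 1-based inclusive, 0,0 when empty
    subject_interval: tuple[int, int]

    @property
    def n_identity(self) -> int:
        return sum(f == COL_IDENTITY for f in self.column_flags)

    @property
    def n_conserved(self) -> int:
        return sum(f == COL_CONSERVED for f in self.column_flags)

    def match_line(self) -> str:
        """Pairwise display glyphs: '|' identity, '+' conserved, ' ' otherwise."""
        glyph = {COL_IDENTITY: "|", COL_CONSERVED: "+"}
        return "".join(glyph.get(f, " ") for f in self.column_flags)

    def pretty(self) -> str:
        qs, qe = self.query_interval
        ss, se = self.subject_interval
        return (
            f"Query   {qs:>5} {self.query_aligned} {qe}\n"
            f"              {self.match_line()}\n"
            f"Sbjct   {ss:>5} {self.subject_aligned} {se}"
        )


def _expect(raw_score: int, m: int, n: int, k: float, lam: float) -> float:
    return k * m * n * math.exp(-lam * raw_score)


def smith_waterman(
    query: str,
    subject: str,
    *,
    candidate_id: str = "",
    gap_open: int = 11,
    gap_extend: int = 1,
    ka_k: float = KA_K,
    ka_lambda: float = KA_LAMBDA,
) -> AlignmentReport:
    """Optimal local alignment of ``query`` vs ``subject`` under BLOSUM62.

    Affine gap penalty: a run of k gap columns costs ``gap_open +
    k * gap_extend``.  Traceback starts from the highest-scoring cell
    (earliest (i, j) on ties) and prefers diagonal over up (gap in subject
    track, i.e. consuming query) over left.  An all-negative scoring pair
    yields the empty alignment with raw score 0.
    """
    _validate_seq(query, "query")
    _validate_seq(subject, "subject")
    m, n = len(query), len(subject)
    mat = _blosum62()
    qi = np.array([mat.alphabet.index(c) for c in query])
    si = np.array([mat.alphabet.index(c) for c in subject])
    sub = np.asarray(mat)
    NEG = -10**9

    # H: best alignment ending at (i, j) in a match/mismatch column
    # E: ... ending in a gap run in the subject row (consuming query, "up")
    # F: ... ending in a gap run in the query row (consuming subject, "left")
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), float(NEG))
    F = np.full((m + 1, n + 1), float(NEG))
    for i in range(1, m + 1):
        srow = sub[qi[i - 1]]
        for j in range(1, n + 1):
            E[i, j] = max(H[i - 1, j] - gap_open - gap_extend,
                          E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - gap_open - gap_extend,
                          F[i, j - 1] - gap_extend)
            diag = max(H[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1], 0.0)
            H[i, j] = diag + srow[si[j - 1]]

    best = 0.0
    best_ij = (0, 0)
    best_state = "H"
    for i in range(m + 1):
        for j in range(n + 1):
            for state, val in (("H", H[i, j]), ("E", E[i, j]), ("F", F[i, j])):
                if val > best:
                    best = val
                    best_ij = (i, j)
                    best_state = state

    raw = int(round(best))
    if raw <= 0:
        return AlignmentReport(
            candidate_id=candidate_id, raw_score=0,
            bit_score=0.0, expect=_expect(0, m, n, ka_k, ka_lambda),
            query_aligned="", subject_aligned="", column_flags=(),
            query_interval=(0, 0), subject_interval=(0, 0),
        )

    # traceback: tie order diagonal > up (E) > left (F)
    q_out: list[str] = []
    s_out: list[str] = []
    flags: list[str] = []
    i, j = best_ij
    state = best_state
    end_q, end_s = i, j
    eps = 1e-9
    while True:
        if state == "H":
            if H[i, j] <= eps:
                break
            score = sub[qi[i - 1], si[j - 1]]
            prev = H[i, j] - score
            a, b = query[i - 1], subject[j - 1]
            q_out.append(a)
            s_out.append(b)
            if a == b:
                flags.append(COL_IDENTITY)
            elif score > 0:
                flags.append(COL_CONSERVED)
            else:
                flags.append(COL_MISMATCH)
            if prev <= eps:
                # diag source was the 0 floor: local alignment starts here
                i, j = i - 1, j - 1
                break
            if abs(H[i - 1, j - 1] - prev) <= eps:
                state = "H"
            elif abs(E[i - 1, j - 1] - prev) <= eps:
                state = "E"
            else:
                state = "F"
            i, j = i - 1, j - 1
        elif state == "E":
            q_out.append(query[i - 1])
            s_out.append("-")
            flags.append(COL_GAP)
            if abs(H[i - 1, j] - gap_open - gap_extend - E[i, j]) <= eps:
                state = "H"
            else:
                state = "E"
            i -= 1
        else:  # F
            q_out.append("-")
            s_out.append(subject[j - 1])
            flags.append(COL_GAP)
            if abs(H[i, j - 1] - gap_open - gap_extend - F[i, j]) <= eps:
                state = "H"
            else:
                state = "F"
            j -= 1

    q_out.reverse()
    s_out.reverse()
    flags.reverse()
    start_q, start_s = i + 1, j + 1
    bit = (ka_lambda * raw - math.log(ka_k)) / math.log(2.0)
    return AlignmentReport(
        candidate_id=candidate_id,
        raw_score=raw,
        bit_score=bit,
        expect=_expect(raw, m, n, ka_k, ka_lambda),
        query_aligned="".join(q_out),
        subject_aligned="".join(s_out),
        column_flags=tuple(flags),
        query_interval=(start_q, end_q),
        subject_interval=(start_s, end_s),
    )
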