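"""Local protein alignment with affine gaps (Smith-Waterman).

This is the scoring engine behind every per-code comparison: each translated
reading frame is aligned against reference proteins and the raw score,
identities and positives are what distinguish one genetic code from another.
It deliberately mirrors translated-search (BLASTx-style) conventions:

* BLOSUM62 with the extended ``*`` and ``X`` rows, so a standard-code
  translation containing in-frame stops still aligns (``score('*', aa) = -4``,
  ``score('*','*') = +1``).  This is what makes per-code score deltas well
  defined.
* affine gap cost ``open + k*extend`` for a gap of length k (defaults 11/1).
* identities = exact residue matches; positives = identities plus pairs with
  a strictly positive substitution score; gap columns count in neither.
* E-values are Karlin-Altschul ``K*m*n*exp(-lambda*S)`` with fixed gapped
  BLOSUM62 constants — an approximation used only for thresholding.

The dynamic programme is exact (no seeding or X-drop); traceback ties break
diagonal > up > left, and the traceback starts from the first maximal cell
in row-major order, so results are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit


@dataclass(frozen=True)
class ScoringMatrix:
    """Residue-pair substitution scores over a fixed alphabet."""

    name: str
    alphabet: str
    matrix: np.ndarray  # (len(alphabet), len(alphabet)) int32, symmetric
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index",
                           {ch: i for i, ch in enumerate(self.alphabet)})

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self.index[a], self.index[b]])

    def encode(self, seq: str) -> np.ndarray:
        """Map a protein string to alphabet indices (raises on unknown chars)."""
        try:
            return np.fromiter((self.index[c] for c in seq), dtype=np.int8,
                               count=len(seq))
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} outside matrix alphabet") from exc


def blosum62() -> ScoringMatrix:
    """BLOSUM62 with the extended B/Z/X/* columns, loaded from Biopython."""
    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    arr = np.asarray(m, dtype=np.int32)
    return ScoringMatrix(name="BLOSUM62", alphabet=alphabet, matrix=arr)


_DEFAULT_MATRIX: ScoringMatrix | None = None


def default_matrix() -> ScoringMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = blosum62()
    return _DEFAULT_MATRIX


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap cost: a gap of length k costs ``open + k * extend``."""

    open: int = 11
    extend: int = 1

    def __post_init__(self) -> None:
        if not (self.open >= self.extend >= 1):
            raise ValueError("require open >= extend >= 1")


@dataclass(frozen=True)
class EvalueParams:
    """Karlin-Altschul parameters for gapped BLOSUM62 (lambda in nats)."""

    lambda_nats: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.lambda_nats <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass
class AlignmentResult:
    """One local alignment with BLAST-style summary statistics.

    ``pairs`` holds one ``(query_char, subject_char)`` tuple per alignment
    column, with ``'-'`` marking a gap.  Coordinates are 1-based inclusive
    positions in the protein sequences.
    """

    raw_score: int
    identities: int
    positives: int
    gaps: int
    aligned_length: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    pairs: list[tuple[str, str]]

    @property
    def is_empty(self) -> bool:
        return self.aligned_length == 0


_GAP_STATE_H, _GAP_STATE_E, _GAP_STATE_F = 0, 1, 2


@njit(cache=True)
def _sw_score_only(q, s, mat, gap_open, gap_ext):  # pragma: no cover - jitted
    n, m = len(q), len(s)
    h_prev = np.zeros(m + 1, dtype=np.int32)
    h_cur = np.zeros(m + 1, dtype=np.int32)
    f = np.full(m + 1, -1_000_000, dtype=np.int32)
    best = 0
    for i in range(1, n + 1):
        e = -1_000_000
        h_cur[0] = 0
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(e - gap_ext, h_cur[j - 1] - gap_open - gap_ext)
            f[j] = max(f[j] - gap_ext, h_prev[j] - gap_open - gap_ext)
            h = h_prev[j - 1] + mat[qi, s[j - 1]]
            if e > h:
                h = e
            if f[j] > h:
                h = f[j]
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
    return best


@njit(cache=True)
def _sw_full(q, s, mat, gap_open, gap_ext):  # pragma: no cover - jitted
    """Full DP with traceback.

    Returns (score, path_q, path_s) where path arrays hold 0-based residue
    indices per column, -1 marking a gap.  Traceback tie-break priority in H:
    diagonal > up (gap in subject, consumes query) > left (gap in query).
    """
    n, m = len(q), len(s)
    NEG = -1_000_000
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    # pointers: for H, 0=stop, 1=diag, 2=from F (up), 3=from E (left)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    # for E/F: 1 = opened from H, 0 = extended
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            # E: gap in query (move left), F: gap in subject (move up)
            e_ext = E[i, j - 1] - gap_ext
            e_open = H[i, j - 1] - gap_open - gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_ext = F[i - 1, j] - gap_ext
            f_open = H[i - 1, j] - gap_open - gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            # priority: diag > up (F) > left (E) on equal scores
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    max_cols = n + m
    path_q = np.full(max_cols, -2, dtype=np.int64)
    path_s = np.full(max_cols, -2, dtype=np.int64)
    k = max_cols
    i, j = bi, bj
    state = _GAP_STATE_H
    while i > 0 and j > 0:
        if state == _GAP_STATE_H:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                k -= 1
                path_q[k] = i - 1
                path_s[k] = j - 1
                i -= 1
                j -= 1
            elif p == 2:
                state = _GAP_STATE_F
            else:
                state = _GAP_STATE_E
        elif state == _GAP_STATE_F:
            k -= 1
            path_q[k] = i - 1
            path_s[k] = -1
            opened = ptrF[i, j] == 1
            i -= 1
            if opened:
                state = _GAP_STATE_H
        else:  # E
            k -= 1
            path_q[k] = -1
            path_s[k] = j - 1
            opened = ptrE[i, j] == 1
            j -= 1
            if opened:
                state = _GAP_STATE_H
    return best, path_q[k:], path_s[k:]


def local_align(query: str, subject: str,
                matrix: ScoringMatrix | None = None,
                gaps: GapPenalties = GapPenalties()) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein strings.

    Raises ``ValueError`` for empty sequences or characters outside the
    matrix alphabet.  A pair with no positively scoring local alignment
    returns an empty result with ``raw_score`` 0.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    matrix = matrix or default_matrix()
    q = matrix.encode(query.upper())
    s = matrix.encode(subject.upper())
    score, path_q, path_s = _sw_full(q, s, matrix.matrix, gaps.open, gaps.extend)
    if score <= 0 or len(path_q) == 0:
        return AlignmentResult(0, 0, 0, 0, 0, 0, 0, 0, 0, [])
    pairs: list[tuple[str, str]] = []
    identities = positives = gap_cols = 0
    q_idx = [int(x) for x in path_q]
    s_idx = [int(x) for x in path_s]
    for qi, sj in zip(q_idx, s_idx):
        qc = query[qi].upper() if qi >= 0 else "-"
        sc = subject[sj].upper() if sj >= 0 else "-"
        pairs.append((qc, sc))
        if qi < 0 or sj < 0:
            gap_cols += 1
        else:
            if qc == sc:
                identities += 1
                positives += 1
            elif matrix.score(qc, sc) > 0:
                positives += 1
    q_res = [i for i in q_idx if i >= 0]
    s_res = [j for j in s_idx if j >= 0]
    return AlignmentResult(
        raw_score=int(score),
        identities=identities,
        positives=positives,
        gaps=gap_cols,
        aligned_length=len(pairs),
        query_start=q_res[0] + 1, query_end=q_res[-1] + 1,
        subject_start=s_res[0] + 1, subject_end=s_res[-1] + 1,
        pairs=pairs,
    )


def local_align_score(query: str, subject: str,
                      matrix: ScoringMatrix | None = None,
                      gaps: GapPenalties = GapPenalties()) -> int:
    """Raw Smith-Waterman score only (linear memory; used for best-hit scans)."""
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    matrix = matrix or default_matrix()
    q = matrix.encode(query.upper())
    s = matrix.encode(subject.upper())
    return int(_sw_score_only(q, s, matrix.matrix, gaps.open, gaps.extend))


def count_identities_positives(a: AlignmentResult,
                               matrix: ScoringMatrix | None = None) -> tuple[int, int]:
    """Recount identities/positives from the alignment columns.

    Identities are exact matches; positives additionally include pairs whose
    substitution score is strictly positive.  Gap columns count in neither.
    """
    matrix = matrix or default_matrix()
    identities = positives = 0
    for qc, sc in a.pairs:
        if qc == "-" or sc == "-":
            continue
        if qc == sc:
            identities += 1
            positives += 1
        elif matrix.score(qc, sc) > 0:
            positives += 1
    return identities, positives


def approximate_evalue(raw_score: int, query_len: int, db_len: int,
                       params: EvalueParams = EvalueParams()) -> float:
    """Karlin-Altschul expect value ``K*m*n*exp(-lambda*S)``.

    No edge-length correction is applied; the value is meant for threshold
    filtering, not reporting as a statistic.
    """
    if raw_score < 0 or query_len < 1 or db_len < 1:
        raise ValueError("raw_score must be >= 0 and lengths >= 1")
    return params.K * query_len * db_len * math.exp(-params.lambda_nats * raw_score)


def tabular_report(rows: list[dict]) -> str:
    """BLAST-tabular-like TSV text for a list of hit dicts."""
    cols = ["qid", "sid", "pident", "length", "identities", "positives", "gaps",
            "qstart", "qend", "sstart", "send", "raw_score", "evalue"]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r.get(c, "")) for c in cols))
    return "\n".join(lines) + "\n"
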