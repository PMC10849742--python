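"""Pairwise protein alignment and e-value statistics.

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment with affine
gaps, implemented as the standard three-state (M / Ix / Iy) recursion and
jit-compiled with numba.  A gap of length L costs ``gap_open + L*gap_extend``
(the NCBI-BLAST parameterisation, so the default Karlin–Altschul constants
for BLOSUM62 with gaps 11/1 apply unchanged).

E-values follow the Karlin–Altschul form  E = K*m*n*exp(-lambda*S)  with no
finite-size edge or composition corrections; this is a deliberate,
documented approximation of BLAST-style statistics that needs no database.

Traceback is deterministic: ties are broken diagonal > up > left, where
"up" consumes a query residue against a gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from numba import njit

from .records import ProteinRecord

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "align_global",
    "align_local",
    "evalue",
    "log_evalue",
    "percent_identity",
    "alignments_to_tsv",
]

_NEG = -(1 << 40)  # -infinity sentinel; int64 arithmetic never overflows from it


# ---------------------------------------------------------------------------
# scoring scheme

@lru_cache(maxsize=None)
def _load_named_matrix(name: str):
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load(name)
    return str(m.alphabet), np.asarray(m, dtype=np.int64)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap and Karlin–Altschul parameters."""

    name: str
    alphabet: str
    matrix: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.int64)
        if mat.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet length")
        if not np.array_equal(mat, mat.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive integers")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin parameters must be positive")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.alphabet)}
        )

    @classmethod
    def load(cls, name: str = "BLOSUM62", **kwargs) -> "ScoringScheme":
        """Load a named matrix shipped in NCBI text format (via Biopython)."""
        alphabet, matrix = _load_named_matrix(name)
        return cls(name=name, alphabet=alphabet, matrix=matrix, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "ScoringScheme":
        """Read a substitution matrix from an NCBI-format text file."""
        from Bio.Align import substitution_matrices

        m = substitution_matrices.read(str(path))
        return cls(
            name=Path(path).stem,
            alphabet=str(m.alphabet),
            matrix=np.asarray(m, dtype=np.int64),
            **kwargs,
        )

    def encode(self, seq: str) -> np.ndarray:
        idx = self._index  # type: ignore[attr-defined]
        try:
            return np.fromiter((idx[c] for c in seq), dtype=np.int64, count=len(seq))
        except KeyError as exc:
            raise ValueError(
                f"sequence contains character {exc.args[0]!r} not in the "
                f"{self.name} alphabet"
            ) from None

    def pair_score(self, a: str, b: str) -> int:
        idx = self._index  # type: ignore[attr-defined]
        return int(self.matrix[idx[a], idx[b]])


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _fill_global(a, b, sub, go, ge):
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), _NEG, np.int64)
    X = np.full((m + 1, n + 1), _NEG, np.int64)  # gap in subject (up)
    Y = np.full((m + 1, n + 1), _NEG, np.int64)  # gap in query (left)
    M[0, 0] = 0
    for i in range(1, m + 1):
        X[i, 0] = -(go + i * ge)
    for j in range(1, n + 1):
        Y[0, j] = -(go + j * ge)
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = sub[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge,
                          Y[i - 1, j] - go - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge,
                          X[i, j - 1] - go - ge)
    return M, X, Y


@njit(cache=True)
def _fill_local(a, b, sub, go, ge):
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), _NEG, np.int64)
    X = np.full((m + 1, n + 1), _NEG, np.int64)
    Y = np.full((m + 1, n + 1), _NEG, np.int64)
    best = np.int64(0)
    bi, bj = 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = sub[ai, b[j - 1]]
            prev = np.int64(0)  # a local alignment may start anywhere
            if M[i - 1, j - 1] > prev:
                prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            M[i, j] = prev + s
            X[i, j] = max(M[i - 1, j] - go - ge, X[i - 1, j] - ge,
                          Y[i - 1, j] - go - ge)
            Y[i, j] = max(M[i, j - 1] - go - ge, Y[i, j - 1] - ge,
                          X[i, j - 1] - go - ge)
            if M[i, j] > best:
                best = M[i, j]
                bi, bj = i, j
    return M, X, Y, best, bi, bj


@njit(cache=True)
def _local_score_only(a, b, sub, go, ge):
    """Rolling-row Smith–Waterman score; used for all-vs-all SSN scoring."""
    m, n = a.shape[0], b.shape[0]
    Mp = np.full(n + 1, _NEG, np.int64)
    Xp = np.full(n + 1, _NEG, np.int64)
    Yp = np.full(n + 1, _NEG, np.int64)
    Mc = np.full(n + 1, _NEG, np.int64)
    Xc = np.full(n + 1, _NEG, np.int64)
    Yc = np.full(n + 1, _NEG, np.int64)
    best = np.int64(0)
    for i in range(1, m + 1):
        ai = a[i - 1]
        Mc[0] = _NEG
        Xc[0] = _NEG
        Yc[0] = _NEG
        for j in range(1, n + 1):
            s = sub[ai, b[j - 1]]
            prev = np.int64(0)
            if Mp[j - 1] > prev:
                prev = Mp[j - 1]
            if Xp[j - 1] > prev:
                prev = Xp[j - 1]
            if Yp[j - 1] > prev:
                prev = Yp[j - 1]
            Mc[j] = prev + s
            Xc[j] = max(Mp[j] - go - ge, Xp[j] - ge, Yp[j] - go - ge)
            Yc[j] = max(Mc[j - 1] - go - ge, Yc[j - 1] - ge, Xc[j - 1] - go - ge)
            if Mc[j] > best:
                best = Mc[j]
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
    return best


def local_score(a_enc: np.ndarray, b_enc: np.ndarray, scheme: ScoringScheme) -> int:
    """Smith–Waterman score of two pre-encoded sequences (no traceback)."""
    return int(
        _local_score_only(a_enc, b_enc, scheme.matrix,
                          scheme.gap_open, scheme.gap_extend)
    )


# ---------------------------------------------------------------------------
# traceback (python; matrices come from the kernels)

_M, _X, _Y = 0, 1, 2


def _prefer(vm: int, vx: int, vy: int) -> int:
    """Tie-break: diagonal (M) > up (X) > left (Y)."""
    best = max(vm, vx, vy)
    if vm == best:
        return _M
    if vx == best:
        return _X
    return _Y


def _traceback_global(a: str, b: str, M, X, Y, go: int, ge: int):
    i, j = len(a), len(b)
    state = _prefer(M[i, j], X[i, j], Y[i, j])
    qa: list[str] = []
    qb: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            qa.append(a[i - 1])
            qb.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _prefer(M[i, j], X[i, j], Y[i, j])
        elif state == _X:
            qa.append(a[i - 1])
            qb.append("-")
            vm = M[i - 1, j] - go - ge
            vx = X[i - 1, j] - ge
            vy = Y[i - 1, j] - go - ge
            i -= 1
            state = _prefer(vm, vx, vy)
        else:
            qa.append("-")
            qb.append(b[j - 1])
            vm = M[i, j - 1] - go - ge
            vy = Y[i, j - 1] - ge
            vx = X[i, j - 1] - go - ge
            j -= 1
            state = _prefer(vm, vx, vy)
    return "".join(reversed(qa)), "".join(reversed(qb))


def _traceback_local(a: str, b: str, M, X, Y, bi: int, bj: int, go: int, ge: int):
    i, j = bi, bj
    qa: list[str] = []
    qb: list[str] = []
    state = _M  # an optimal local alignment ends on a match/mismatch column
    while True:
        if state == _M:
            qa.append(a[i - 1])
            qb.append(b[j - 1])
            vm, vx, vy = M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            i, j = i - 1, j - 1
            if max(vm, vx, vy) <= 0:  # the fill started the alignment here
                break
            state = _prefer(vm, vx, vy)
        elif state == _X:
            qa.append(a[i - 1])
            qb.append("-")
            vm = M[i - 1, j] - go - ge
            vx = X[i - 1, j] - ge
            vy = Y[i - 1, j] - go - ge
            i -= 1
            state = _prefer(vm, vx, vy)
        else:
            qa.append("-")
            qb.append(b[j - 1])
            vm = M[i, j - 1] - go - ge
            vy = Y[i, j - 1] - ge
            vx = X[i, j - 1] - go - ge
            j -= 1
            state = _prefer(vm, vx, vy)
    return "".join(reversed(qa)), "".join(reversed(qb)), i, j


# ---------------------------------------------------------------------------
# statistics

def log_evalue(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Natural log of the Karlin–Altschul e-value (never underflows)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if score < 0:
        raise ValueError("e-values are defined for nonnegative scores")
    return (
        math.log(scheme.karlin_K)
        + math.log(m)
        + math.log(n)
        - scheme.karlin_lambda * score
    )


def evalue(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expect value  E = K*m*n*exp(-lambda*S).

    Strictly positive and monotone decreasing in the score; floored at the
    smallest positive double where exp() would underflow (use
    :func:`log_evalue` when comparing astronomically small values).
    """
    e = math.exp(log_evalue(score, m, n, scheme))
    return e if e > 0.0 else 5e-324


# ---------------------------------------------------------------------------
# public alignment API

@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: int
    mode: str  # "global" | "local"
    identity_pct: float
    evalue: float
    query_start: int = 1  # 1-based position of the first aligned residue
    subject_start: int = 1

    def format(self) -> str:
        """Two-row text dump of the alignment."""
        marks = "".join(
            "|" if x == y and x != "-" else " "
            for x, y in zip(self.aligned_query, self.aligned_subject)
        )
        return (
            f"{self.query_id}\t{self.aligned_query}\n"
            f"\t{marks}\n"
            f"{self.subject_id}\t{self.aligned_subject}\n"
        )


def _identity_from_strings(qa: str, qb: str, mode: str) -> float:
    if not qa:
        raise ValueError("cannot compute identity of an empty alignment")
    matches = sum(1 for x, y in zip(qa, qb) if x == y and x != "-")
    if mode == "global":
        denom = len(qa)
    else:  # local convention: gap columns excluded from the denominator
        denom = sum(1 for x, y in zip(qa, qb) if x != "-" and y != "-")
    if denom == 0:
        raise ValueError("alignment has no aligned columns")
    return 100.0 * matches / denom


def percent_identity(aln: PairwiseAlignment) -> float:
    """Percent amino-acid identity of an alignment ("aa ID").

    Global mode counts every aligned column (gaps included) in the
    denominator; local mode counts only residue-residue columns.  The two
    conventions can differ and both are exposed because reported "aa ID"
    values are method-dependent.
    """
    return _identity_from_strings(aln.aligned_query, aln.aligned_subject, aln.mode)


def _evalue_field(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    return evalue(max(score, 0), m, n, scheme)


def align_global(a: ProteinRecord, b: ProteinRecord,
                 scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch alignment with affine gaps."""
    scheme = scheme or ScoringScheme.load()
    ea, eb = scheme.encode(a.sequence), scheme.encode(b.sequence)
    M, X, Y = _fill_global(ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    score = int(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    qa, qb = _traceback_global(a.sequence, b.sequence, M, X, Y,
                               scheme.gap_open, scheme.gap_extend)
    return PairwiseAlignment(
        query_id=a.id,
        subject_id=b.id,
        aligned_query=qa,
        aligned_subject=qb,
        score=score,
        mode="global",
        identity_pct=_identity_from_strings(qa, qb, "global"),
        evalue=_evalue_field(score, len(a), len(b), scheme),
    )


def align_local(a: ProteinRecord, b: ProteinRecord,
                scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal Smith–Waterman alignment with affine gaps.

    When no positive-scoring residue pair exists the empty alignment with
    score 0 is returned.
    """
    scheme = scheme or ScoringScheme.load()
    ea, eb = scheme.encode(a.sequence), scheme.encode(b.sequence)
    M, X, Y, best, bi, bj = _fill_local(
        ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    score = int(best)
    if score <= 0:
        return PairwiseAlignment(
            query_id=a.id, subject_id=b.id, aligned_query="", aligned_subject="",
            score=0, mode="local", identity_pct=0.0,
            evalue=_evalue_field(0, len(a), len(b), scheme),
            query_start=0, subject_start=0,
        )
    qa, qb, qi, qj = _traceback_local(
        a.sequence, b.sequence, M, X, Y, int(bi), int(bj),
        scheme.gap_open, scheme.gap_extend,
    )
    return PairwiseAlignment(
        query_id=a.id,
        subject_id=b.id,
        aligned_query=qa,
        aligned_subject=qb,
        score=score,
        mode="local",
        identity_pct=_identity_from_strings(qa, qb, "local"),
        evalue=_evalue_field(score, len(a), len(b), scheme),
        query_start=qi + 1,
        subject_start=qj + 1,
    )


def alignments_to_tsv(alns: list[PairwiseAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tidentity_pct\tevalue\n")
        for aln in alns:
            fh.write(
                f"{aln.query_id}\t{aln.subject_id}\t{aln.score}"
                f"\t{aln.identity_pct:.4f}\t{aln.evalue:.6g}\n"
            )
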