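"""Affine-gap local and glocal alignment kernels.

These kernels define score(s) for the whole package: HSR scores, junction
realignment, expected-support comparisons and duplication-vs-insertion
matching all use the same machinery, under one default scoring scheme
(+1 match, -4 mismatch, -6 gap open, -1 gap extend; the first gap base
costs -7). ``N`` never matches anything, including another ``N``.

Three entry points:

``local_align``
    Smith-Waterman with affine gaps. Co-optimal alignments are resolved
    deterministically: smallest reference start, then smallest query start,
    then smallest endpoints.
``split_totals``
    For a query of length n, returns T[i] = best local score of q[:i] plus
    best local score of q[i:] for every split point i, computed with one
    forward and one reverse pass (prefix/suffix running maxima of the DP
    row maxima) instead of n separate alignments.
``glocal_align``
    Query-global, target-local alignment: the entire query is aligned
    (internal gaps allowed), the target endpoints are free. Used to model
    an aligner's preferred full placement of a read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import DEFAULT_SCHEME, AlignmentScheme, LocalAlignmentResult

_NEG = np.int32(-(10**8))
_PACK = 1 << 20  # start/end packing base; supports sequences < 2^20 bp

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sub(a, b, ma, mm):
    if a == b and a < 4:
        return ma
    return mm


@njit(cache=True)
def _sw_kernel(q, t, ma, mm, go, ge):
    """Full SW with start propagation and traceback pointers.

    Returns (score, qs, qe, ts, te, ops, lens, nops). ops: 0=M, 1=I
    (consumes query), 2=D (consumes target).
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    SH = np.zeros((n + 1, m + 1), dtype=np.int64)
    SE = np.zeros((n + 1, m + 1), dtype=np.int64)
    SF = np.zeros((n + 1, m + 1), dtype=np.int64)
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 empty, 1 diag, 2 E, 3 F
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 open, 1 extend
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    best = np.int32(0)
    best_start = np.int64(0)
    best_end = np.int64(0)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # E: gap consuming target
            e_open = H[i, j - 1] + go + ge
            e_ext = E[i, j - 1] + ge
            if e_open > e_ext or (e_open == e_ext and SH[i, j - 1] <= SE[i, j - 1]):
                E[i, j] = e_open
                SE[i, j] = SH[i, j - 1]
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                SE[i, j] = SE[i, j - 1]
                PE[i, j] = 1
            # F: gap consuming query
            f_open = H[i - 1, j] + go + ge
            f_ext = F[i - 1, j] + ge
            if f_open > f_ext or (f_open == f_ext and SH[i - 1, j] <= SF[i - 1, j]):
                F[i, j] = f_open
                SF[i, j] = SH[i - 1, j]
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                SF[i, j] = SF[i - 1, j]
                PF[i, j] = 1
            # H
            s = _sub(q[i - 1], t[j - 1], ma, mm)
            diag = H[i - 1, j - 1] + s
            if H[i - 1, j - 1] == 0 and PH[i - 1, j - 1] == 0:
                dstart = np.int64(j - 1) * _PACK + (i - 1)
            else:
                dstart = SH[i - 1, j - 1]
            val = diag
            start = dstart
            ptr = np.uint8(1)
            if E[i, j] > val or (E[i, j] == val and SE[i, j] < start):
                val = E[i, j]
                start = SE[i, j]
                ptr = np.uint8(2)
            if F[i, j] > val or (F[i, j] == val and SF[i, j] < start):
                val = F[i, j]
                start = SF[i, j]
                ptr = np.uint8(3)
            if val <= 0:
                H[i, j] = 0
                SH[i, j] = 0
                PH[i, j] = 0
            else:
                H[i, j] = val
                SH[i, j] = start
                PH[i, j] = ptr
                end = np.int64(j) * _PACK + i
                if val > best or (
                    val == best
                    and (start < best_start or (start == best_start and end < best_end))
                ):
                    best = val
                    best_start = start
                    best_end = end

    ops = np.zeros(n + m + 2, dtype=np.int32)
    lens = np.zeros(n + m + 2, dtype=np.int32)
    if best == 0:
        return 0, 0, 0, 0, 0, ops, lens, 0

    j = int(best_end // _PACK)
    i = int(best_end % _PACK)
    qe = i
    te = j
    nops = 0

    def _push(ops, lens, nops, op):
        if nops > 0 and ops[nops - 1] == op:
            lens[nops - 1] += 1
            return nops
        ops[nops] = op
        lens[nops] = 1
        return nops + 1

    while True:
        p = PH[i, j]
        if p == 0:
            break
        if p == 1:
            nops = _push(ops, lens, nops, 0)
            i -= 1
            j -= 1
            if PH[i, j] == 0:
                break
        elif p == 2:
            while PE[i, j] == 1:
                nops = _push(ops, lens, nops, 2)
                j -= 1
            nops = _push(ops, lens, nops, 2)
            j -= 1
        else:
            while PF[i, j] == 1:
                nops = _push(ops, lens, nops, 1)
                i -= 1
            nops = _push(ops, lens, nops, 1)
            i -= 1
    # reverse op runs in place
    for k in range(nops // 2):
        ops[k], ops[nops - 1 - k] = ops[nops - 1 - k], ops[k]
        lens[k], lens[nops - 1 - k] = lens[nops - 1 - k], lens[k]
    qs = i
    ts = j
    return int(best), qs, qe, ts, te, ops, lens, nops


@njit(cache=True)
def _prefix_best(q, t, ma, mm, go, ge):
    """P[i] = best local-alignment score using only the first i query bases."""
    n = q.shape[0]
    m = t.shape[0]
    P = np.zeros(n + 1, dtype=np.int32)
    Hprev = np.zeros(m + 1, dtype=np.int32)
    Hcur = np.zeros(m + 1, dtype=np.int32)
    Fprev = np.full(m + 1, _NEG, dtype=np.int32)
    Fcur = np.full(m + 1, _NEG, dtype=np.int32)
    for i in range(1, n + 1):
        rowmax = np.int32(0)
        e = _NEG
        for j in range(1, m + 1):
            e_open = Hcur[j - 1] + go + ge
            e_ext = e + ge
            e = e_open if e_open > e_ext else e_ext
            f_open = Hprev[j] + go + ge
            f_ext = Fprev[j] + ge
            f = f_open if f_open > f_ext else f_ext
            Fcur[j] = f
            s = _sub(q[i - 1], t[j - 1], ma, mm)
            val = Hprev[j - 1] + s
            if e > val:
                val = e
            if f > val:
                val = f
            if val < 0:
                val = 0
            Hcur[j] = val
            if val > rowmax:
                rowmax = val
        P[i] = P[i - 1] if P[i - 1] > rowmax else rowmax
        Hprev, Hcur = Hcur, Hprev
        Fprev, Fcur = Fcur, Fprev
    return P


@njit(cache=True)
def _glocal_kernel(q, t, ma, mm, go, ge):
    """Query-global, target-local alignment with traceback.

    Returns (score, ts, te, ops, lens, nops).
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 diag, 2 E, 3 F, 4 row0
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for j in range(m + 1):
        H[0, j] = 0
        PH[0, j] = 4
    for i in range(1, n + 1):
        H[i, 0] = go + i * ge
        F[i, 0] = H[i, 0]
        PH[i, 0] = 3
        PF[i, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + go + ge
            e_ext = E[i, j - 1] + ge
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 0
            else:
                E[i, j] = e_ext
                PE[i, j] = 1
            f_open = H[i - 1, j] + go + ge
            f_ext = F[i - 1, j] + ge
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 0
            else:
                F[i, j] = f_ext
                PF[i, j] = 1
            s = _sub(q[i - 1], t[j - 1], ma, mm)
            val = H[i - 1, j - 1] + s
            ptr = np.uint8(1)
            if E[i, j] > val:
                val = E[i, j]
                ptr = np.uint8(2)
            if F[i, j] > val:
                val = F[i, j]
                ptr = np.uint8(3)
            H[i, j] = val
            PH[i, j] = ptr
    best = H[n, 0]
    bj = 0
    for j in range(1, m + 1):
        if H[n, j] > best:
            best = H[n, j]
            bj = j
    ops = np.zeros(2 * (n + m) + 2, dtype=np.int32)
    lens = np.zeros(2 * (n + m) + 2, dtype=np.int32)
    nops = 0
    i = n
    j = bj
    te = bj

    def _push(ops, lens, nops, op):
        if nops > 0 and ops[nops - 1] == op:
            lens[nops - 1] += 1
            return nops
        ops[nops] = op
        lens[nops] = 1
        return nops + 1

    while i > 0:
        p = PH[i, j]
        if p == 1:
            nops = _push(ops, lens, nops, 0)
            i -= 1
            j -= 1
        elif p == 2:
            while PE[i, j] == 1:
                nops = _push(ops, lens, nops, 2)
                j -= 1
            nops = _push(ops, lens, nops, 2)
            j -= 1
        else:
            while PF[i, j] == 1 and i > 1:
                nops = _push(ops, lens, nops, 1)
                i -= 1
            nops = _push(ops, lens, nops, 1)
            i -= 1
    for k in range(nops // 2):
        ops[k], ops[nops - 1 - k] = ops[nops - 1 - k], ops[k]
        lens[k], lens[nops - 1 - k] = lens[nops - 1 - k], lens[k]
    return int(best), j, te, ops, lens, nops


_OPCHARS = "MID"


def _decode_cigar(ops, lens, nops) -> tuple[tuple[str, int], ...]:
    return tuple((_OPCHARS[int(ops[k])], int(lens[k])) for k in range(nops))


def _check(query: str, target: str) -> None:
    if not query or not target:
        raise ValueError("query and target must be non-empty")


def local_align(
    query: str, target: str, scheme: AlignmentScheme = DEFAULT_SCHEME
) -> LocalAlignmentResult:
    """Optimal affine-gap local alignment of ``query`` against ``target``."""
    _check(query, target)
    score, qs, qe, ts, te, ops, lens, nops = _sw_kernel(
        encode(query), encode(target), scheme.match, scheme.mismatch,
        scheme.gap_open, scheme.gap_extend,
    )
    return LocalAlignmentResult(score, qs, qe, ts, te, _decode_cigar(ops, lens, nops))


def local_score(query: str, target: str, scheme: AlignmentScheme = DEFAULT_SCHEME) -> int:
    """Best local alignment score only (cheaper than ``local_align``)."""
    _check(query, target)
    P = _prefix_best(
        encode(query), encode(target), scheme.match, scheme.mismatch,
        scheme.gap_open, scheme.gap_extend,
    )
    return int(P[len(query)])


def split_totals(
    query: str, target: str, scheme: AlignmentScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """T[i] = local_score(query[:i]) + local_score(query[i:]) for i in 0..n.

    Two DP passes: a forward pass over the query and a reverse pass over the
    reversed query/target, then prefix/suffix running maxima.
    """
    _check(query, target)
    q = encode(query)
    t = encode(target)
    args = (scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    P = _prefix_best(q, t, *args)
    S = _prefix_best(q[::-1].copy(), t[::-1].copy(), *args)
    n = len(query)
    return P + S[n - np.arange(n + 1)]


@dataclass(frozen=True)
class GlocalResult:
    score: int
    ref_start: int
    ref_end: int
    cigar: tuple[tuple[str, int], ...]


def glocal_align(
    query: str, target: str, scheme: AlignmentScheme = DEFAULT_SCHEME
) -> GlocalResult:
    """Align the full query (internal gaps allowed) to a free target span."""
    _check(query, target)
    score, ts, te, ops, lens, nops = _glocal_kernel(
        encode(query), encode(target), scheme.match, scheme.mismatch,
        scheme.gap_open, scheme.gap_extend,
    )
    return GlocalResult(score, ts, te, _decode_cigar(ops, lens, nops))
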