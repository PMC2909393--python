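"""Low-level affine-gap Needleman-Wunsch kernels.

The dynamic program is written as numba ``@njit`` functions operating on
uint8-encoded sequences so that the all-pairs sparse-distance computation
stays tractable on a single CPU.  When numba is unavailable the same
functions run as pure Python (slowly, but identically).

State codes: 0 = diagonal (match/mismatch column), 1 = up (gap in the
second sequence, consuming the first), 2 = left (gap in the first,
consuming the second).  Ties during traceback prefer diagonal, then up,
then left, so results are deterministic.

Gap cost convention: a run of L gap columns costs
``gap_open + (L - 1) * gap_extend``.  With ``end_free`` set, gap columns
in terminal runs (leading/trailing) are free, i.e. the alignment is
semi-global.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_NEG = -1e30

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _CODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) == 255:
        raise ValueError(f"sequence contains non-ACGTN characters: {seq!r}")
    return arr


@njit(cache=False)
def _nw_fill_traceback(a, b, match, mismatch, gap_open, gap_extend, end_free,
                       M, X, Y, PM, PX, PY, ops):
    """Fill the three-state DP and trace back one optimal alignment.

    Returns (score, n_ops); ``ops[:n_ops]`` holds the column operations in
    alignment order (0 diag, 1 up, 2 left).
    """
    n = a.shape[0]
    m = b.shape[0]
    M[0, 0] = 0.0
    X[0, 0] = _NEG
    Y[0, 0] = _NEG
    for i in range(1, n + 1):
        M[i, 0] = _NEG
        Y[i, 0] = _NEG
        if end_free:
            X[i, 0] = 0.0
        else:
            X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        PX[i, 0] = 1
    for j in range(1, m + 1):
        M[0, j] = _NEG
        X[0, j] = _NEG
        if end_free:
            Y[0, j] = 0.0
        else:
            Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        PY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            # diagonal state
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            PM[i, j] = p
            # up state: gap in b, consumes a[i-1]; free when b is exhausted
            if end_free and j == m:
                go = 0.0
                ge = 0.0
            else:
                go = gap_open
                ge = gap_extend
            best = M[i - 1, j] - go
            p = 0
            v = X[i - 1, j] - ge
            if v > best:
                best = v
                p = 1
            v = Y[i - 1, j] - go
            if v > best:
                best = v
                p = 2
            X[i, j] = best
            PX[i, j] = p
            # left state: gap in a, consumes b[j-1]; free when a is exhausted
            if end_free and i == n:
                go = 0.0
                ge = 0.0
            else:
                go = gap_open
                ge = gap_extend
            best = M[i, j - 1] - go
            p = 0
            v = X[i, j - 1] - go
            if v > best:
                best = v
                p = 1
            v = Y[i, j - 1] - ge
            if v > best:
                best = v
                p = 2
            Y[i, j] = best
            PY[i, j] = p
    # terminal state: prefer diagonal, then up, then left
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    i = n
    j = m
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            nxt = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            nxt = PX[i, j]
            i -= 1
        else:
            ops[k] = 2
            nxt = PY[i, j]
            j -= 1
        state = nxt
        k += 1
    # reverse into alignment order
    for t in range(k // 2):
        tmp = ops[t]
        ops[t] = ops[k - 1 - t]
        ops[k - 1 - t] = tmp
    return score, k


@njit(cache=False)
def _ops_stats(a, b, ops, nops):
    """Column statistics of an alignment given its op string.

    Returns (columns, substitutions, gap_events, gap_columns,
    int_columns, int_gap_events, int_gap_columns) where the ``int_``
    variants exclude terminal (leading/trailing) gap runs.  Substitutions
    can only occur in non-gap columns and are therefore never terminal.
    """
    # terminal run extents
    lead = 0
    while lead < nops and ops[lead] != 0:
        lead += 1
    trail = 0
    while trail < nops - lead and ops[nops - 1 - trail] != 0:
        trail += 1
    subs = 0
    gap_events = 0
    gap_cols = 0
    int_gap_events = 0
    int_gap_cols = 0
    ai = 0
    bi = 0
    prev = 0
    for t in range(nops):
        op = ops[t]
        if op == 0:
            if a[ai] != b[bi]:
                subs += 1
            ai += 1
            bi += 1
        else:
            gap_cols += 1
            if op != prev:
                gap_events += 1
            # ops[lead] is diagonal by maximality of the leading run, so
            # every internal gap run begins strictly inside the window
            if lead <= t < nops - trail:
                int_gap_cols += 1
                if op != prev:
                    int_gap_events += 1
            if op == 1:
                ai += 1
            else:
                bi += 1
        prev = op
    int_cols = nops - lead - trail
    return nops, subs, gap_events, gap_cols, int_cols, int_gap_events, int_gap_cols


@njit(cache=False)
def _quickdist_from_stats(subs, gap_events, gap_cols, cols,
                          int_gap_events, int_gap_cols, int_cols,
                          end_free, gap_per_column):
    if end_free:
        cols_eff = int_cols
        gaps_eff = int_gap_cols if gap_per_column else int_gap_events
    else:
        cols_eff = cols
        gaps_eff = gap_cols if gap_per_column else gap_events
    if cols_eff == 0:
        return 1.0
    return (subs + gaps_eff) / cols_eff


@njit(cache=False)
def _pair_quickdist(a, b, match, mismatch, gap_open, gap_extend,
                    end_free, gap_per_column, M, X, Y, PM, PX, PY, ops):
    score, k = _nw_fill_traceback(a, b, match, mismatch, gap_open,
                                  gap_extend, end_free, M, X, Y, PM, PX, PY, ops)
    cols, subs, ge, gc, ic, ige, igc = _ops_stats(a, b, ops, k)
    return _quickdist_from_stats(subs, ge, gc, cols, ige, igc, ic,
                                 end_free, gap_per_column)


@njit(cache=False)
def _seq_less(a, na, b, nb):
    """Lexicographic comparison of two encoded sequences."""
    n = min(na, nb)
    for t in range(n):
        if a[t] < b[t]:
            return True
        if a[t] > b[t]:
            return False
    return na < nb


@njit(cache=False)
def _kmer_codes(seq, k, out):
    """Base-4 codes of all k-mers (N treated as A); returns count, sorted."""
    n = seq.shape[0] - k + 1
    for i in range(n):
        code = 0
        for t in range(k):
            c = seq[i + t]
            if c > 3:
                c = 0
            code = code * 4 + c
        out[i] = code
    out[:n].sort()
    return n


@njit(cache=False)
def _shared_kmers(ka, na, kb, nb):
    """Multiset intersection size of two sorted k-mer code arrays."""
    i = 0
    j = 0
    shared = 0
    while i < na and j < nb:
        if ka[i] == kb[j]:
            shared += 1
            i += 1
            j += 1
        elif ka[i] < kb[j]:
            i += 1
        else:
            j += 1
    return shared


@njit(cache=False)
def _sparse_kernel(seqs, lengths, kcodes, kcounts, cutoff, kmer_cutoff,
                   use_prescreen, match, mismatch, gap_open, gap_extend,
                   end_free, gap_per_column):
    """All candidate pairwise quickdists below ``cutoff``.

    ``seqs`` is an (n, Lmax) uint8 matrix padded arbitrarily beyond each
    row's length; ``kcodes``/``kcounts`` hold per-sequence sorted k-mer
    codes for the prescreen.  Pairs are aligned in canonical (lexicographic)
    order so the resulting distance is symmetric by construction.
    Returns (ii, jj, dd) arrays with i < j in input order.
    """
    n = seqs.shape[0]
    lmax = seqs.shape[1]
    M = np.empty((lmax + 1, lmax + 1), dtype=np.float64)
    X = np.empty((lmax + 1, lmax + 1), dtype=np.float64)
    Y = np.empty((lmax + 1, lmax + 1), dtype=np.float64)
    PM = np.empty((lmax + 1, lmax + 1), dtype=np.int8)
    PX = np.empty((lmax + 1, lmax + 1), dtype=np.int8)
    PY = np.empty((lmax + 1, lmax + 1), dtype=np.int8)
    ops = np.empty(2 * lmax + 2, dtype=np.int8)
    cap = 1024
    ii = np.empty(cap, dtype=np.int64)
    jj = np.empty(cap, dtype=np.int64)
    dd = np.empty(cap, dtype=np.float64)
    cnt = 0
    for i in range(n):
        ai = seqs[i, : lengths[i]]
        for j in range(i + 1, n):
            bj = seqs[j, : lengths[j]]
            if use_prescreen:
                na = kcounts[i]
                nb = kcounts[j]
                mn = na if na < nb else nb
                if mn > 0:
                    shared = _shared_kmers(kcodes[i], na, kcodes[j], nb)
                    kd = 1.0 - shared / mn
                    if kd > kmer_cutoff:
                        continue
            if _seq_less(ai, lengths[i], bj, lengths[j]):
                d = _pair_quickdist(ai, bj, match, mismatch, gap_open,
                                    gap_extend, end_free, gap_per_column,
                                    M, X, Y, PM, PX, PY, ops)
            else:
                d = _pair_quickdist(bj, ai, match, mismatch, gap_open,
                                    gap_extend, end_free, gap_per_column,
                                    M, X, Y, PM, PX, PY, ops)
            if d <= cutoff:
                if cnt == cap:
                    cap *= 2
                    ii2 = np.empty(cap, dtype=np.int64)
                    jj2 = np.empty(cap, dtype=np.int64)
                    dd2 = np.empty(cap, dtype=np.float64)
                    ii2[:cnt] = ii[:cnt]
                    jj2[:cnt] = jj[:cnt]
                    dd2[:cnt] = dd[:cnt]
                    ii = ii2
                    jj = jj2
                    dd = dd2
                ii[cnt] = i
                jj[cnt] = j
                dd[cnt] = d
                cnt += 1
    return ii[:cnt], jj[:cnt], dd[:cnt]


@njit(cache=False)
def _error_count_vs_templates(read, tlens, tmat, match, mismatch,
                              gap_open, gap_extend, end_free,
                              M, X, Y, PM, PX, PY, ops):
    """Align a read to every template; return (best_index, n_errors).

    Errors = substitutions + maximal gap runs (one event each, terminal
    runs excluded when ``end_free``).  Ties on the error count keep the
    lowest template index.
    """
    nt = tmat.shape[0]
    best_t = -1
    best_e = -1
    for t in range(nt):
        tpl = tmat[t, : tlens[t]]
        score, k = _nw_fill_traceback(read, tpl, match, mismatch, gap_open,
                                      gap_extend, end_free,
                                      M, X, Y, PM, PX, PY, ops)
        cols, subs, ge, gc, ic, ige, igc = _ops_stats(read, tpl, ops, k)
        if end_free:
            e = subs + ige
        else:
            e = subs + ge
        if best_e < 0 or e < best_e:
            best_e = e
            best_t = t
    return best_t, best_e
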