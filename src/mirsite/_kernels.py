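"""Numba kernels for the duplex dynamic program and the partition function.

Everything here works on integer-coded sequences (A=0, C=1, G=2, U=3) and the
flat parameter arrays produced by :mod:`mirsite.params`.  The Python-facing
wrappers live in :mod:`mirsite.duplex` and :mod:`mirsite.structure`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e30


@njit(cache=True)
def duplex_fill(mir, tgt, stack, pairable, init, bulge, internal, cap,
                forced_j, span_lo, span_hi):
    """Fill the intermolecular duplex DP matrix.

    ``B[i, j]`` is the minimum free energy of a monotone duplex whose 3'-most
    miRNA pair is (miRNA position ``i``, target position ``j``), including the
    initiation term.  ``pred[i, j]`` packs the predecessor pair as
    ``pi * len(tgt) + pj`` (-1 for a duplex-opening pair).

    ``forced_j[i] >= 0`` pins miRNA position ``i`` to that target position;
    positions in ``[span_lo, span_hi)`` may never be skipped by a loop, so a
    forced seed block is paired consecutively or not at all.
    """
    m = mir.shape[0]
    t = tgt.shape[0]
    B = np.full((m, t), INF)
    pred = np.full((m, t), -1, dtype=np.int64)
    for i in range(m):
        fj = forced_j[i]
        for j in range(t):
            if fj >= 0:
                if j != fj:
                    continue
            elif not pairable[mir[i], tgt[j]]:
                continue
            # open a new duplex here (allowed only 5' of a forced span)
            best = INF
            bp = -1
            if span_hi <= span_lo or i <= span_lo:
                best = init
            lo = i - 1 - cap
            if lo < 0:
                lo = 0
            for pi in range(lo, i):
                ga = i - pi - 1
                if ga > 0 and span_hi > span_lo:
                    # would skip miRNA positions pi+1..i-1: banned if any
                    # forced-span position falls in that gap
                    a = pi + 1
                    if a < span_lo:
                        a = span_lo
                    b = i - 1
                    if b > span_hi - 1:
                        b = span_hi - 1
                    if a <= b:
                        continue
                hi = j + 2 + cap
                if hi > t:
                    hi = t
                for pj in range(j + 1, hi):
                    if B[pi, pj] >= INF:
                        continue
                    gb = pj - j - 1
                    if ga == 0 and gb == 0:
                        cost = stack[4 * mir[pi] + tgt[pj], 4 * mir[i] + tgt[j]]
                    elif ga == 0 or gb == 0:
                        cost = bulge * (ga + gb)
                    else:
                        cost = internal * (ga + gb)
                    cand = B[pi, pj] + cost
                    if cand < best:
                        best = cand
                        bp = pi * t + pj
            if best < INF:
                B[i, j] = best
                pred[i, j] = bp
    return B, pred


@njit(cache=True)
def pf_inside(codes, wstack, wpair, pairable, min_hairpin, inv_sigma, banned):
    """Inside recursion of the scaled partition function.

    ``q[i, j]`` / ``qb[i, j]`` are the partition functions over interval
    ``[i, j]`` (any structure / structures pairing i with j), each multiplied
    by ``inv_sigma**(j - i + 1)`` to avoid overflow.  ``banned[k]`` forces
    position ``k`` single-stranded.
    """
    n = codes.shape[0]
    q = np.zeros((n, n))
    qb = np.zeros((n, n))
    for i in range(n):
        q[i, i] = inv_sigma
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            # structures pairing (i, j)
            if (d - 1 >= min_hairpin and pairable[codes[i], codes[j]]
                    and not banned[i] and not banned[j]):
                inner = q[i + 1, j - 1]
                v = inner
                if d - 3 >= min_hairpin and pairable[codes[i + 1], codes[j - 1]]:
                    ws = wstack[4 * codes[i] + codes[j],
                                4 * codes[i + 1] + codes[j - 1]]
                    v += (ws - 1.0) * qb[i + 1, j - 1]
                qb[i, j] = wpair * inv_sigma * inv_sigma * v
            # all structures on [i, j]: decompose on the partner of j
            acc = q[i, j - 1] * inv_sigma + qb[i, j]
            for k in range(i + 1, j - min_hairpin):
                if qb[k, j] > 0.0:
                    acc += q[i, k - 1] * qb[k, j]
            q[i, j] = acc
    return q, qb


@njit(cache=True)
def pf_outside(codes, q, qb, wstack, wpair, pairable, min_hairpin, inv_sigma):
    """Outside recursion: exterior partition function ``qc[i, j]`` per pair.

    The base-pair probability is ``qb * qc / q[0, n-1]``.  Processing runs
    from long spans to short; ``T[k, jp]`` accumulates, for every already
    processed enclosing pair (k, l), its weight times the partition function
    of the gap between jp and l.
    """
    n = codes.shape[0]
    qc = np.zeros((n, n))
    T = np.zeros((n, n))
    wp = wpair * inv_sigma * inv_sigma
    for d in range(n - 1, min_hairpin, -1):
        for i in range(n - d):
            j = i + d
            if qb[i, j] <= 0.0:
                continue
            left = q[0, i - 1] if i > 0 else 1.0
            right = q[j + 1, n - 1] if j < n - 1 else 1.0
            v = left * right
            for k in range(i):
                if T[k, j] > 0.0:
                    gap = q[k + 1, i - 1] if k + 1 <= i - 1 else 1.0
                    v += T[k, j] * gap
            if i >= 1 and j + 1 < n and qb[i - 1, j + 1] > 0.0:
                ws = wstack[4 * codes[i - 1] + codes[j + 1],
                            4 * codes[i] + codes[j]]
                v += qc[i - 1, j + 1] * wp * (ws - 1.0)
            qc[i, j] = v
            # publish this pair as a potential enclosing pair
            w = wp * v
            for jp in range(i + 1, j):
                gap = q[jp + 1, j - 1] if jp + 1 <= j - 1 else 1.0
                T[i, jp] += w * gap
    return qc


@njit(cache=True)
def pair_probabilities(q, qb, qc):
    n = q.shape[0]
    p = np.zeros((n, n))
    z = q[0, n - 1]
    for i in range(n):
        for j in range(i + 1, n):
            if qb[i, j] > 0.0:
                p[i, j] = qb[i, j] * qc[i, j] / z
    return p
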