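"""Numba kernels for the local-alignment scorer and background emission.

Kept separate so the rest of the package stays importable and testable
without triggering JIT compilation until a kernel is actually used.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def local_align_ends(logodds, seq, gap_open, gap_extend):
    """Position-specific local alignment, affine gaps, forward strand.

    logodds: (L, 4) match-state scores in bits; seq: int8 codes 0..3, 4=N
    (N scores 0 bits). Returns, for every sequence position j (1-based),
    the best score of a local alignment ending in a match state at j and
    the 1-based start position of that alignment.
    """
    L = logodds.shape[0]
    N = seq.shape[0]
    ends = np.full(N, NEG)
    starts = np.zeros(N, dtype=np.int64)

    M_prev = np.full(L + 1, NEG)
    Ix_prev = np.full(L + 1, NEG)
    Iy_prev = np.full(L + 1, NEG)
    SM_prev = np.zeros(L + 1, dtype=np.int64)
    SIx_prev = np.zeros(L + 1, dtype=np.int64)
    SIy_prev = np.zeros(L + 1, dtype=np.int64)
    M_cur = np.full(L + 1, NEG)
    Ix_cur = np.full(L + 1, NEG)
    Iy_cur = np.full(L + 1, NEG)
    SM_cur = np.zeros(L + 1, dtype=np.int64)
    SIx_cur = np.zeros(L + 1, dtype=np.int64)
    SIy_cur = np.zeros(L + 1, dtype=np.int64)

    for j in range(1, N + 1):
        x = seq[j - 1]
        M_cur[0] = NEG
        Ix_cur[0] = NEG
        Iy_cur[0] = NEG
        best_j = NEG
        best_s = 0
        for i in range(1, L + 1):
            e = 0.0 if x == 4 else logodds[i - 1, x]
            # best predecessor on the diagonal (previous column, i-1)
            b = 0.0
            s = j
            if M_prev[i - 1] > b:
                b = M_prev[i - 1]
                s = SM_prev[i - 1]
            if Ix_prev[i - 1] > b:
                b = Ix_prev[i - 1]
                s = SIx_prev[i - 1]
            if Iy_prev[i - 1] > b:
                b = Iy_prev[i - 1]
                s = SIy_prev[i - 1]
            M_cur[i] = e + b
            SM_cur[i] = s
            # gap in model (extra sequence residue): previous column, same i
            a1 = M_prev[i] - gap_open
            a2 = Ix_prev[i] - gap_extend
            if a1 >= a2:
                Ix_cur[i] = a1
                SIx_cur[i] = SM_prev[i]
            else:
                Ix_cur[i] = a2
                SIx_cur[i] = SIx_prev[i]
            # gap in sequence (model deletion): current column, i-1
            b1 = M_cur[i - 1] - gap_open
            b2 = Iy_cur[i - 1] - gap_extend
            if b1 >= b2:
                Iy_cur[i] = b1
                SIy_cur[i] = SM_cur[i - 1]
            else:
                Iy_cur[i] = b2
                SIy_cur[i] = SIy_cur[i - 1]
            if M_cur[i] > best_j:
                best_j = M_cur[i]
                best_s = SM_cur[i]
        ends[j - 1] = best_j
        starts[j - 1] = best_s
        M_prev, M_cur = M_cur, M_prev
        Ix_prev, Ix_cur = Ix_cur, Ix_prev
        Iy_prev, Iy_cur = Iy_cur, Iy_prev
        SM_prev, SM_cur = SM_cur, SM_prev
        SIx_prev, SIx_cur = SIx_cur, SIx_prev
        SIy_prev, SIy_cur = SIy_cur, SIy_prev
    return ends, starts


@njit(cache=True)
def emit_markov(bin_per_pos, cdf, context_len, init_ctx, uniforms):
    """Emit letters from per-bin fixed-order context tables.

    bin_per_pos: int64 (length,) bin index per position; cdf:
    (n_bins, 4**context_len, 4) cumulative emission probabilities;
    uniforms: (length,) uniform variates. Returns int8 letter codes.
    """
    n = bin_per_pos.shape[0]
    mask = 4 ** context_len - 1
    out = np.empty(n, dtype=np.int8)
    ctx = init_ctx
    for t in range(n):
        row = cdf[bin_per_pos[t], ctx]
        u = uniforms[t]
        x = 0
        while x < 3 and u > row[x]:
            x += 1
        out[t] = x
        ctx = ((ctx << 2) | x) & mask
    return out
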