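"""Numba dynamic-programming kernels for PSSM-to-sequence alignment.

Scores arrive as a (profile_width, sequence_length) matrix of per-cell
match scores, so the kernels are agnostic of alphabet and scoring system.
Affine gap costs: a gap of length g costs open + (g-1)*extend.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def sw_profile(cell: np.ndarray, gap_open: float, gap_extend: float):
    """Smith-Waterman local alignment of a profile (rows) to a sequence
    (columns). Returns (score, prof_start, prof_end, seq_start, seq_end)
    with 0-based inclusive coordinates; spans are empty if score <= 0."""
    W, L = cell.shape
    H = np.zeros((W + 1, L + 1))
    E = np.full((W + 1, L + 1), NEG)   # gap in profile (consume sequence)
    F = np.full((W + 1, L + 1), NEG)   # gap in sequence (skip column)
    ptr = np.zeros((W + 1, L + 1), np.uint8)   # 0 stop, 1 diag, 2 E, 3 F
    eptr = np.zeros((W + 1, L + 1), np.uint8)  # 1 = opened from H
    fptr = np.zeros((W + 1, L + 1), np.uint8)
    best = 0.0
    bi = bj = 0
    for i in range(1, W + 1):
        for j in range(1, L + 1):
            eo = H[i, j - 1] - gap_open
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                eptr[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] - gap_open
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                fptr[i, j] = 1
            else:
                F[i, j] = fe
            d = H[i - 1, j - 1] + cell[i - 1, j - 1]
            h = 0.0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi, bj = i, j
    # traceback for the start of the optimal local path
    i, j = bi, bj
    state = 0  # in H
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            opened = eptr[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            opened = fptr[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return best, i, bi - 1, j, bj - 1


@njit(cache=True)
def nw_profile(cell: np.ndarray, gap_open: float, gap_extend: float):
    """Global alignment of a profile to a sequence with affine end-charged
    gaps. Returns (score, path) where path is an (n,2) array of
    (profile_col, seq_pos) with -1 marking a gap on that side."""
    W, L = cell.shape
    H = np.full((W + 1, L + 1), NEG)
    E = np.full((W + 1, L + 1), NEG)
    F = np.full((W + 1, L + 1), NEG)
    ptr = np.zeros((W + 1, L + 1), np.uint8)
    eptr = np.zeros((W + 1, L + 1), np.uint8)
    fptr = np.zeros((W + 1, L + 1), np.uint8)
    H[0, 0] = 0.0
    for j in range(1, L + 1):
        E[0, j] = -gap_open - (j - 1) * gap_extend
        H[0, j] = E[0, j]
        ptr[0, j] = 2
        eptr[0, j] = 1 if j == 1 else 0
    for i in range(1, W + 1):
        F[i, 0] = -gap_open - (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
        ptr[i, 0] = 3
        fptr[i, 0] = 1 if i == 1 else 0
    for i in range(1, W + 1):
        for j in range(1, L + 1):
            eo = H[i, j - 1] - gap_open
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                eptr[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] - gap_open
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                fptr[i, j] = 1
            else:
                F[i, j] = fe
            d = H[i - 1, j - 1] + cell[i - 1, j - 1]
            h = d
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
    # traceback
    path = np.empty((W + L, 2), np.int64)
    k = W + L
    i, j = W, L
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptr[i, j]
        else:
            p = state
        if p == 1:
            k -= 1
            path[k, 0] = i - 1
            path[k, 1] = j - 1
            i -= 1
            j -= 1
            state = 0
        elif p == 2:
            k -= 1
            path[k, 0] = -1
            path[k, 1] = j - 1
            opened = eptr[i, j]
            j -= 1
            state = 0 if opened == 1 else 2
        else:
            k -= 1
            path[k, 0] = i - 1
            path[k, 1] = -1
            opened = fptr[i, j]
            i -= 1
            state = 0 if opened == 1 else 3
    return H[W, L], path[k:]
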