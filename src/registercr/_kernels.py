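"""Numba inner loops for the marginal likelihood and state smoothing.

The forward recursion is carried in scaled probability space: the state
vector is renormalised every year and the log-normalisers accumulated,
which is numerically equivalent to a log-space recursion while handling
exact-zero emission probabilities without special cases.

State coding: 0 = PRESENT, 1 = ABSENT, 2 = DEAD.
Mask coding:  0 = FREE, 1 = FORCED_PRESENT, 2 = FORCED_ABSENT,
              3 = FORCED_DEAD.
"""

import numpy as np
from numba import njit

FREE = 0
FORCED_PRESENT = 1
FORCED_ABSENT = 2
FORCED_DEAD = 3


@njit(cache=True, inline="always")
def _step_matrix(M, phi, psi, eta, lam, em_p, o_any, e, d, m):
    """Fill M[s_prev, s_now] = P(s_now | s_prev) * P(record | s_prev, s_now)."""
    for a in range(3):
        for b in range(3):
            M[a, b] = 0.0
    # into PRESENT: record must show no event; detection product em_p applies
    if e == 0 and d == 0:
        M[0, 0] = phi * psi * em_p
        M[1, 0] = phi * eta * em_p
    # into ABSENT: no detections, no death record
    if o_any == 0 and d == 0:
        lam_term = lam if e == 1 else 1.0 - lam
        M[0, 1] = phi * (1.0 - psi) * lam_term
        if e == 0:
            M[1, 1] = phi * (1.0 - eta)
    # into DEAD: no detections, no de-registration; death recorded iff from PRESENT
    if o_any == 0 and e == 0:
        if d == 1:
            M[0, 2] = 1.0 - phi
        else:
            M[1, 2] = 1.0 - phi
            M[2, 2] = 1.0
    # known-state mask: forbidden destination states carry zero mass
    if m == FORCED_PRESENT:
        for a in range(3):
            M[a, 1] = 0.0
            M[a, 2] = 0.0
    elif m == FORCED_ABSENT:
        for a in range(3):
            M[a, 0] = 0.0
            M[a, 2] = 0.0
    elif m == FORCED_DEAD:
        for a in range(3):
            M[a, 0] = 0.0
            M[a, 1] = 0.0


@njit(cache=True)
def forward_loglik(start, obs_any, e_flag, d_flag, mask,
                   phi, psi, eta, lam, em_p, out):
    """Per-individual marginal log-likelihood by the scaled forward recursion.

    All probability arrays are (n, Y); ``em_p`` is the detection-product
    emission probability of the year's list record given presence.  Writes
    log P(record_i) into ``out[i]`` (-inf for impossible records).
    """
    n, Y = obs_any.shape
    M = np.empty((3, 3))
    for i in range(n):
        y0 = start[i]
        # registration year: state PRESENT with certainty, no events possible
        if e_flag[i, y0] != 0 or d_flag[i, y0] != 0:
            out[i] = -np.inf
            continue
        aP = em_p[i, y0]
        aA = 0.0
        aD = 0.0
        if aP <= 0.0:
            out[i] = -np.inf
            continue
        ll = np.log(aP)
        aP = 1.0
        ok = True
        for y in range(y0 + 1, Y):
            _step_matrix(M, phi[i, y], psi[i, y], eta[i, y], lam[i, y],
                         em_p[i, y], obs_any[i, y], e_flag[i, y],
                         d_flag[i, y], mask[i, y])
            nP = aP * M[0, 0] + aA * M[1, 0] + aD * M[2, 0]
            nA = aP * M[0, 1] + aA * M[1, 1] + aD * M[2, 1]
            nD = aP * M[0, 2] + aA * M[1, 2] + aD * M[2, 2]
            c = nP + nA + nD
            if c <= 0.0:
                ll = -np.inf
                ok = False
                break
            ll += np.log(c)
            aP = nP / c
            aA = nA / c
            aD = nD / c
        out[i] = ll if ok else -np.inf


@njit(cache=True)
def forward_backward_weights(start, obs_any, e_flag, d_flag, mask,
                             phi, psi, eta, lam, em_p,
                             gphi, gpsi, geta, glam, gmP):
    """Score weights of the marginal log-likelihood per individual-year.

    Writes, for each (i, y), the derivative of log L_i with respect to the
    *linear predictor* of each transition probability (phi, psi, eta,
    lambda) and the smoothed presence probability ``gmP`` (the weight of
    the detection-score terms), using pairwise transition posteriors
    xi(a, b) from a forward-backward pass.  The coefficient gradient is
    then X^T times these weights.  Individuals with impossible records are
    left at zero weight.
    """
    n, Y = obs_any.shape
    M = np.empty((3, 3))
    alpha = np.empty((Y, 3))
    beta = np.empty((Y, 3))
    for i in range(n):
        y0 = start[i]
        if e_flag[i, y0] != 0 or d_flag[i, y0] != 0 or em_p[i, y0] <= 0.0:
            continue
        alpha[y0, 0] = 1.0
        alpha[y0, 1] = 0.0
        alpha[y0, 2] = 0.0
        ok = True
        for y in range(y0 + 1, Y):
            _step_matrix(M, phi[i, y], psi[i, y], eta[i, y], lam[i, y],
                         em_p[i, y], obs_any[i, y], e_flag[i, y],
                         d_flag[i, y], mask[i, y])
            c = 0.0
            for b in range(3):
                v = (alpha[y - 1, 0] * M[0, b] + alpha[y - 1, 1] * M[1, b]
                     + alpha[y - 1, 2] * M[2, b])
                alpha[y, b] = v
                c += v
            if c <= 0.0:
                ok = False
                break
            for b in range(3):
                alpha[y, b] /= c
        if not ok:
            continue
        for b in range(3):
            beta[Y - 1, b] = 1.0
        for y in range(Y - 2, y0 - 1, -1):
            _step_matrix(M, phi[i, y + 1], psi[i, y + 1], eta[i, y + 1],
                         lam[i, y + 1], em_p[i, y + 1], obs_any[i, y + 1],
                         e_flag[i, y + 1], d_flag[i, y + 1], mask[i, y + 1])
            c = 0.0
            for a in range(3):
                v = (M[a, 0] * beta[y + 1, 0] + M[a, 1] * beta[y + 1, 1]
                     + M[a, 2] * beta[y + 1, 2])
                beta[y, a] = v
                c += v
            if c <= 0.0:
                c = 1.0
            for a in range(3):
                beta[y, a] /= c
        gmP[i, y0] = 1.0
        for y in range(y0 + 1, Y):
            _step_matrix(M, phi[i, y], psi[i, y], eta[i, y], lam[i, y],
                         em_p[i, y], obs_any[i, y], e_flag[i, y],
                         d_flag[i, y], mask[i, y])
            norm = 0.0
            for a in range(3):
                for b in range(3):
                    M[a, b] = alpha[y - 1, a] * M[a, b] * beta[y, b]
                    norm += M[a, b]
            if norm <= 0.0:
                continue
            xiPP = M[0, 0] / norm
            xiPA = M[0, 1] / norm
            xiPD = M[0, 2] / norm
            xiAP = M[1, 0] / norm
            xiAA = M[1, 1] / norm
            xiAD = M[1, 2] / norm
            alive = xiPP + xiPA + xiAP + xiAA
            dead_new = xiPD + xiAD
            gphi[i, y] = alive * (1.0 - phi[i, y]) - dead_new * phi[i, y]
            gpsi[i, y] = xiPP * (1.0 - psi[i, y]) - xiPA * psi[i, y]
            geta[i, y] = xiAP * (1.0 - eta[i, y]) - xiAA * eta[i, y]
            if e_flag[i, y] == 1:
                glam[i, y] = xiPA * (1.0 - lam[i, y])
            else:
                glam[i, y] = -xiPA * lam[i, y]
            gmP[i, y] = xiPP + xiAP


@njit(cache=True)
def forward_backward(start, obs_any, e_flag, d_flag, mask,
                     phi, psi, eta, lam, em_p, zhat):
    """Smoothed P(state_y = PRESENT | full record) per individual-year.

    Writes into ``zhat`` (n, Y); years before registration are set to NaN,
    impossible records give NaN throughout.
    """
    n, Y = obs_any.shape
    M = np.empty((3, 3))
    alpha = np.empty((Y, 3))
    beta = np.empty((Y, 3))
    for i in range(n):
        y0 = start[i]
        for y in range(Y):
            zhat[i, y] = np.nan
        if e_flag[i, y0] != 0 or d_flag[i, y0] != 0 or em_p[i, y0] <= 0.0:
            continue
        alpha[y0, 0] = 1.0
        alpha[y0, 1] = 0.0
        alpha[y0, 2] = 0.0
        ok = True
        for y in range(y0 + 1, Y):
            _step_matrix(M, phi[i, y], psi[i, y], eta[i, y], lam[i, y],
                         em_p[i, y], obs_any[i, y], e_flag[i, y],
                         d_flag[i, y], mask[i, y])
            c = 0.0
            for b in range(3):
                v = (alpha[y - 1, 0] * M[0, b] + alpha[y - 1, 1] * M[1, b]
                     + alpha[y - 1, 2] * M[2, b])
                alpha[y, b] = v
                c += v
            if c <= 0.0:
                ok = False
                break
            for b in range(3):
                alpha[y, b] /= c
        if not ok:
            continue
        for b in range(3):
            beta[Y - 1, b] = 1.0
        for y in range(Y - 2, y0 - 1, -1):
            _step_matrix(M, phi[i, y + 1], psi[i, y + 1], eta[i, y + 1],
                         lam[i, y + 1], em_p[i, y + 1], obs_any[i, y + 1],
                         e_flag[i, y + 1], d_flag[i, y + 1], mask[i, y + 1])
            c = 0.0
            for a in range(3):
                v = (M[a, 0] * beta[y + 1, 0] + M[a, 1] * beta[y + 1, 1]
                     + M[a, 2] * beta[y + 1, 2])
                beta[y, a] = v
                c += v
            if c <= 0.0:
                c = 1.0  # dead-end mass already excluded by forward pass
            for a in range(3):
                beta[y, a] /= c
        for y in range(y0, Y):
            g0 = alpha[y, 0] * beta[y, 0]
            g1 = alpha[y, 1] * beta[y, 1]
            g2 = alpha[y, 2] * beta[y, 2]
            tot = g0 + g1 + g2
            if tot > 0.0:
                zhat[i, y] = g0 / tot
            else:
                zhat[i, y] = np.nan
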