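"""Compiled sampler core.

A numba translation of the Metropolis-within-Gibbs sweep. The model maths
is identical to the reference implementation in :mod:`apedyn.inference`;
latent states are updated in a sequential single-site scan (which needs no
grid colouring), and randomness comes from numba's Mersenne-Twister seeded
per chain, so runs are reproducible for a given seed but follow a
different stream than the pure-python engine. The enumeration-oracle tests
exercise both engines against the same exact conditionals.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# parameter-vector layout (mirrors apedyn.inference)
_A0, _B0, _E0 = 0, 11, 22
_CHI = 33
_U0 = 34
_G0 = 36
_MU0 = 42
_ZETA = 44
_NP = 45


@njit(cache=True)
def _log_pois(k, mu):
    if mu <= 0.0:
        return 0.0 if k == 0 else -np.inf
    return k * math.log(mu) - mu - math.lgamma(k + 1.0)


@njit(cache=True)
def _log_binom(k, n, p):
    if k > n or k < 0 or n < 0:
        return -np.inf
    if p <= 0.0:
        return 0.0 if k == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return (math.lgamma(n + 1.0) - math.lgamma(k + 1.0)
            - math.lgamma(n - k + 1.0)
            + k * math.log(p) + (n - k) * math.log1p(-p))


@njit(cache=True)
def _xlogy(x, y):
    if x == 0.0:
        return 0.0
    if y <= 0.0:
        return -np.inf
    return x * math.log(y)


@njit(cache=True)
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# rate fields


@njit(cache=True)
def _lam_vec(X, alpha, out):
    C = X.shape[0]
    for i in range(C):
        s = 0.0
        for k in range(11):
            s += X[i, 0, k] * alpha[k]
        out[i] = math.exp(s)


@njit(cache=True)
def _logistic_field(X, coef, t0, out):
    C, T = X.shape[0], X.shape[1]
    for i in range(C):
        for t in range(t0, T):
            s = 0.0
            for k in range(11):
                s += X[i, t, k] * coef[k]
            out[i, t - t0] = _expit(s)


@njit(cache=True)
def _psi_field(ind, gamma, out):
    C, T = ind.shape[0], ind.shape[1]
    for i in range(C):
        for t in range(T):
            s = gamma[0]
            for k in range(5):
                s += ind[i, t, k] * gamma[1 + k]
            out[i, t] = 100.0 * s


# ---------------------------------------------------------------------------
# likelihood blocks


@njit(cache=True)
def _ll_init(lam, O, Nou):
    s = 0.0
    for i in range(lam.size):
        s += _log_pois(Nou[i, 0], lam[i] * O[i, 0])
    return s


@njit(cache=True)
def _ll_occ(phi, O):
    C, T = phi.shape
    s = 0.0
    for i in range(C):
        for t in range(T):
            p = phi[i, t]
            if O[i, t] == 1:
                s += math.log(p) if p > 0 else -np.inf
            else:
                s += math.log1p(-p) if p < 1 else -np.inf
    return s


@njit(cache=True)
def _ll_surv(theta, Nou, S):
    C, Tm1 = theta.shape
    s = 0.0
    for i in range(C):
        for t in range(Tm1):
            s += _log_binom(S[i, t], Nou[i, t], theta[i, t])
    return s


@njit(cache=True)
def _ll_rec(exp_chi, WS, deg1, R):
    C, Tm1 = WS.shape
    s = 0.0
    for i in range(C):
        for t in range(Tm1):
            s += _log_pois(R[i, t], exp_chi * WS[i, t] / deg1[i])
    return s


@njit(cache=True)
def _ll_thin(O, Nou, S, R):
    C, Tm1 = S.shape
    s = 0.0
    for i in range(C):
        for t in range(Tm1):
            s += _log_pois(Nou[i, t + 1],
                           float(S[i, t] + R[i, t]) * O[i, t + 1])
    return s


@njit(cache=True)
def _ll_counts_j(Yobs, Yval, Nnest, xi_j, j):
    C, _, T = Yobs.shape
    s = 0.0
    for i in range(C):
        for t in range(T):
            if Yobs[i, j, t]:
                s += _log_binom(Yval[i, j, t], Nnest[i, t], xi_j)
    return s


@njit(cache=True)
def _ll_zn(rho, Nnest, zn_pos, zn_neg):
    C, T = zn_pos.shape
    s = 0.0
    for i in range(C):
        for t in range(T):
            p = rho if Nnest[i, t] > 0 else 0.0
            s += _xlogy(zn_pos[i, t], p) + _xlogy(zn_neg[i, t], 1.0 - p)
    return s


@njit(cache=True)
def _ll_zo(rho1, rho0, O, zo_pos1, zo_neg1, zo_pos0, zo_neg0):
    C, T = zo_pos1.shape
    s = 0.0
    for i in range(C):
        for t in range(T):
            o = float(O[i, t])
            s += (_xlogy(zo_pos1[i, t], rho1 * o)
                  + _xlogy(zo_neg1[i, t], 1.0 - rho1 * o)
                  + _xlogy(zo_pos0[i, t], rho0 * o)
                  + _xlogy(zo_neg0[i, t], 1.0 - rho0 * o))
    return s


@njit(cache=True)
def _obs_ll_cell(i, t, nn, xi, rho_nest, Yobs, Yval, zn_pos, zn_neg):
    s = 0.0
    for j in range(2):
        if Yobs[i, j, t]:
            s += _log_binom(Yval[i, j, t], nn, xi[j])
    p = rho_nest if nn > 0 else 0.0
    s += _xlogy(zn_pos[i, t], p) + _xlogy(zn_neg[i, t], 1.0 - p)
    return s


@njit(cache=True)
def _ridge_block(u, slope, vec, psi, Nou, xi_buf, nn_buf,
                 Yobs, Yval, zn_pos, zn_neg, lower, upper, zeta_unused):
    """Block ll at offset u along the (gamma0, mu) ridge; fills buffers.
    Returns -inf when out of bounds or psi <= 0."""
    g0 = vec[_G0] + u
    if g0 < lower[_G0] or g0 > upper[_G0]:
        return -np.inf
    for j in range(2):
        m = vec[_MU0 + j] - slope * u
        if m < lower[_MU0 + j] or m > upper[_MU0 + j]:
            return -np.inf
        xi_buf[j] = _expit(m)
    C, T = psi.shape
    for i in range(C):
        for t in range(T):
            p = psi[i, t] + 100.0 * u
            if p <= 0.0:
                return -np.inf
    s = 0.0
    rho = xi_buf[2]   # rho_nest carried in slot 2
    for i in range(C):
        for t in range(T):
            nn = int(round((psi[i, t] + 100.0 * u) * Nou[i, t]))
            nn_buf[i, t] = nn
            s += _obs_ll_cell(i, t, nn, xi_buf, rho, Yobs, Yval,
                              zn_pos, zn_neg)
    return s


# ---------------------------------------------------------------------------
# the chain


@njit(cache=True)
def _chol11(A, n, out):
    """In-place Cholesky of the leading n x n block; False if not PD."""
    for i in range(n):
        for j in range(n):
            out[i, j] = 0.0
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= out[i, k] * out[j, k]
            if i == j:
                if s <= 1e-12:
                    return False
                out[i, i] = math.sqrt(s)
            else:
                out[i, j] = s / out[j, j]
    return True


# multi-parameter blocks proposed jointly with adapted covariance; the
# ridge-coupled parameters (gamma0, mu_aerial, mu_ground) are deliberately
# excluded and handled by scalar moves plus the slice along the ridge
_BLK_START = np.array([0, 11, 22, 34], dtype=np.int64)
_BLK_LEN = np.array([11, 11, 11, 2], dtype=np.int64)
_NBLK = 4


@njit(cache=True)
def run_chain(X, ind, nbr, wgt, deg1,
              Yobs, Yval, zn_pos, zn_neg,
              zo_pos1, zo_neg1, zo_pos0, zo_neg0,
              lower, upper, vec_init, O, Nou, S, R,
              sample_mask, ridge_on, update_latents, adapt,
              n_iter, n_burn, latent_thin, seed):
    np.random.seed(seed)
    C = X.shape[0]
    T = X.shape[1]
    Tm1 = T - 1

    vec = vec_init.copy()
    steps = np.full(_NP + 1, 0.1)
    acc_count = np.zeros(_NP + 1)
    acc_batch = np.zeros(_NP + 1)
    prop_count = np.zeros(_NP + 1)

    # adaptive block-proposal state (alpha/beta/eta/upsilon/gamma/mu blocks
    # proposed jointly once their members are all being sampled)
    blk_on = np.zeros(_NBLK, dtype=np.bool_)
    in_block = np.zeros(_NP, dtype=np.bool_)
    for b in range(_NBLK):
        full = True
        for k in range(_BLK_START[b], _BLK_START[b] + _BLK_LEN[b]):
            if not sample_mask[k]:
                full = False
        blk_on[b] = full
        if full:
            for k in range(_BLK_START[b], _BLK_START[b] + _BLK_LEN[b]):
                in_block[k] = True
    blk_scale = np.full(_NBLK, 0.1)
    blk_acc = np.zeros(_NBLK)
    blk_prop = np.zeros(_NBLK)
    blk_acc_batch = np.zeros(_NBLK)
    blk_seeded = np.zeros(_NBLK, dtype=np.bool_)
    mean_acc = np.zeros((_NBLK, 11))
    outer_acc = np.zeros((_NBLK, 11, 11))
    n_acc = 0
    chol = np.zeros((_NBLK, 11, 11))
    for b in range(_NBLK):
        for k in range(11):
            chol[b, k, k] = 1.0
    cov_tmp = np.zeros((11, 11))
    chol_tmp = np.zeros((11, 11))
    znorm = np.zeros(11)
    dx = np.zeros(11)
    old_blk = np.zeros(11)

    lam = np.empty(C)
    phi = np.empty((C, T))
    theta = np.empty((C, max(Tm1, 1)))
    psi = np.empty((C, T))
    Nnest = np.empty((C, T), dtype=np.int64)
    WS = np.zeros((C, max(Tm1, 1)))
    xi = np.empty(2)
    xi_buf = np.empty(3)
    nn_buf = np.empty((C, T), dtype=np.int64)
    nn_best = np.empty((C, T), dtype=np.int64)

    n_kept = n_iter - n_burn
    n_stored = (n_kept + latent_thin - 1) // latent_thin
    draws = np.empty((n_kept, _NP))
    Nou_draws = np.empty((n_stored, C, T), dtype=np.int32)
    O_sum = np.zeros((C, T))
    stored = 0
    batch = 0

    for it in range(n_iter):
        # ---- rate fields -------------------------------------------------
        _lam_vec(X, vec[_A0:_A0 + 11], lam)
        _logistic_field(X, vec[_B0:_B0 + 11], 0, phi)
        if Tm1 > 0:
            _logistic_field(X, vec[_E0:_E0 + 11], 1, theta)
        _psi_field(ind, vec[_G0:_G0 + 6], psi)
        exp_chi = math.exp(vec[_CHI])
        rho1 = _expit(vec[_U0] + vec[_U0 + 1])
        rho0 = _expit(vec[_U0])
        xi[0] = _expit(vec[_MU0])
        xi[1] = _expit(vec[_MU0 + 1])
        rho_nest = _expit(vec[_ZETA])
        for i in range(C):
            for t in range(T):
                Nnest[i, t] = int(round(psi[i, t] * Nou[i, t]))
        for t in range(Tm1):
            for i in range(C):
                s = float(Nou[i, t])
                for k in range(8):
                    j = nbr[i, k]
                    if j >= 0:
                        s += wgt[i, k] * Nou[j, t]
                WS[i, t] = s

        # ---- block log-likelihoods --------------------------------------
        b_init = _ll_init(lam, O, Nou)
        b_occ = _ll_occ(phi, O)
        b_surv = _ll_surv(theta, Nou, S) if Tm1 > 0 else 0.0
        b_rec = _ll_rec(exp_chi, WS, deg1, R) if Tm1 > 0 else 0.0
        b_y0 = _ll_counts_j(Yobs, Yval, Nnest, xi[0], 0)
        b_y1 = _ll_counts_j(Yobs, Yval, Nnest, xi[1], 1)
        b_zn = _ll_zn(rho_nest, Nnest, zn_pos, zn_neg)
        b_zo = _ll_zo(rho1, rho0, O, zo_pos1, zo_neg1, zo_pos0, zo_neg0)

        # ---- scalar parameter updates (blocks handled jointly below) ----
        for k in range(_NP):
            if not sample_mask[k] or in_block[k]:
                continue
            prop_count[k] += 1.0
            scale = 10.0 if np.random.random() < 0.1 else 1.0
            old = vec[k]
            new = old + scale * steps[k] * np.random.normal()
            if new < lower[k] or new > upper[k]:
                continue
            vec[k] = new
            delta = 0.0
            accept_extra = 0   # 1: lam, 2: phi, 3: theta, 4: chi, 5: psi,
            #                    6: upsilon, 7: mu0, 8: mu1, 9: zeta
            if k < _B0:                                   # alpha
                _lam_vec(X, vec[_A0:_A0 + 11], lam)
                nb = _ll_init(lam, O, Nou)
                delta = nb - b_init
                accept_extra = 1
            elif k < _E0:                                 # beta
                _logistic_field(X, vec[_B0:_B0 + 11], 0, phi)
                nb = _ll_occ(phi, O)
                delta = nb - b_occ
                accept_extra = 2
            elif k < _CHI:                                # eta
                if Tm1 > 0:
                    _logistic_field(X, vec[_E0:_E0 + 11], 1, theta)
                    nb = _ll_surv(theta, Nou, S)
                    delta = nb - b_surv
                else:
                    nb = 0.0
                accept_extra = 3
            elif k == _CHI:
                ec = math.exp(vec[_CHI])
                nb = _ll_rec(ec, WS, deg1, R) if Tm1 > 0 else 0.0
                delta = nb - b_rec
                accept_extra = 4
            elif k < _G0:                                 # upsilon
                r1 = _expit(vec[_U0] + vec[_U0 + 1])
                r0 = _expit(vec[_U0])
                nb = _ll_zo(r1, r0, O, zo_pos1, zo_neg1, zo_pos0, zo_neg0)
                delta = nb - b_zo
                accept_extra = 6
            elif k < _MU0:                                # gamma
                _psi_field(ind, vec[_G0:_G0 + 6], psi)
                bad = False
                for i in range(C):
                    for t in range(T):
                        if psi[i, t] <= 0.0:
                            bad = True
                if bad:
                    vec[k] = old
                    _psi_field(ind, vec[_G0:_G0 + 6], psi)
                    continue
                for i in range(C):
                    for t in range(T):
                        nn_buf[i, t] = int(round(psi[i, t] * Nou[i, t]))
                ny0 = _ll_counts_j(Yobs, Yval, nn_buf, xi[0], 0)
                ny1 = _ll_counts_j(Yobs, Yval, nn_buf, xi[1], 1)
                nzn = _ll_zn(rho_nest, nn_buf, zn_pos, zn_neg)
                delta = ny0 - b_y0 + ny1 - b_y1 + nzn - b_zn
                accept_extra = 5
            elif k < _ZETA:                               # mu_j
                j = k - _MU0
                xj = _expit(vec[k])
                nb = _ll_counts_j(Yobs, Yval, Nnest, xj, j)
                delta = nb - (b_y0 if j == 0 else b_y1)
                accept_extra = 7 + j
            else:                                         # zeta
                rn = _expit(vec[_ZETA])
                nb = _ll_zn(rn, Nnest, zn_pos, zn_neg)
                delta = nb - b_zn
                accept_extra = 9

            if delta > -np.inf and math.log(np.random.random() + 1e-300) < delta:
                acc_count[k] += 1.0
                acc_batch[k] += 1.0
                if accept_extra == 1:
                    b_init = nb
                elif accept_extra == 2:
                    b_occ = nb
                elif accept_extra == 3:
                    b_surv = nb
                elif accept_extra == 4:
                    b_rec = nb
                    exp_chi = math.exp(vec[_CHI])
                elif accept_extra == 5:
                    b_y0, b_y1, b_zn = ny0, ny1, nzn
                    for i in range(C):
                        for t in range(T):
                            Nnest[i, t] = nn_buf[i, t]
                elif accept_extra == 6:
                    b_zo = nb
                    rho1 = _expit(vec[_U0] + vec[_U0 + 1])
                    rho0 = _expit(vec[_U0])
                elif accept_extra == 7:
                    b_y0 = nb
                    xi[0] = _expit(vec[_MU0])
                elif accept_extra == 8:
                    b_y1 = nb
                    xi[1] = _expit(vec[_MU0 + 1])
                elif accept_extra == 9:
                    b_zn = nb
                    rho_nest = _expit(vec[_ZETA])
            else:
                vec[k] = old
                # restore cached fields touched by the rejected proposal
                if accept_extra == 1:
                    _lam_vec(X, vec[_A0:_A0 + 11], lam)
                elif accept_extra == 2:
                    _logistic_field(X, vec[_B0:_B0 + 11], 0, phi)
                elif accept_extra == 3:
                    if Tm1 > 0:
                        _logistic_field(X, vec[_E0:_E0 + 11], 1, theta)
                elif accept_extra == 5:
                    _psi_field(ind, vec[_G0:_G0 + 6], psi)

        # ---- adaptive joint block proposals -----------------------------
        ny0 = ny1 = nzn = 0.0
        for b in range(_NBLK):
            if not blk_on[b]:
                continue
            L = _BLK_LEN[b]
            st = _BLK_START[b]
            blk_prop[b] += 1.0
            hv = 10.0 if np.random.random() < 0.05 else 1.0
            for k in range(L):
                znorm[k] = np.random.normal()
            ok = True
            for ri in range(L):
                s = 0.0
                for k in range(ri + 1):
                    s += chol[b, ri, k] * znorm[k]
                dx[ri] = hv * blk_scale[b] * s
                nv = vec[st + ri] + dx[ri]
                if nv < lower[st + ri] or nv > upper[st + ri]:
                    ok = False
            if not ok:
                continue
            for k in range(L):
                old_blk[k] = vec[st + k]
                vec[st + k] += dx[k]
            delta = -np.inf
            nb = 0.0
            if b == 0:                                    # alpha
                _lam_vec(X, vec[_A0:_A0 + 11], lam)
                nb = _ll_init(lam, O, Nou)
                delta = nb - b_init
            elif b == 1:                                  # beta
                _logistic_field(X, vec[_B0:_B0 + 11], 0, phi)
                nb = _ll_occ(phi, O)
                delta = nb - b_occ
            elif b == 2:                                  # eta
                if Tm1 > 0:
                    _logistic_field(X, vec[_E0:_E0 + 11], 1, theta)
                    nb = _ll_surv(theta, Nou, S)
                    delta = nb - b_surv
                else:
                    delta = 0.0
            else:                                         # upsilon
                r1n = _expit(vec[_U0] + vec[_U0 + 1])
                r0n = _expit(vec[_U0])
                nb = _ll_zo(r1n, r0n, O, zo_pos1, zo_neg1, zo_pos0, zo_neg0)
                delta = nb - b_zo
            if delta > -np.inf and math.log(np.random.random() + 1e-300) < delta:
                blk_acc[b] += 1.0
                blk_acc_batch[b] += 1.0
                if b == 0:
                    b_init = nb
                elif b == 1:
                    b_occ = nb
                elif b == 2:
                    b_surv = nb
                else:
                    b_zo = nb
                    rho1 = _expit(vec[_U0] + vec[_U0 + 1])
                    rho0 = _expit(vec[_U0])
            else:
                for k in range(L):
                    vec[st + k] = old_blk[k]
                if b == 0:
                    _lam_vec(X, vec[_A0:_A0 + 11], lam)
                elif b == 1:
                    _logistic_field(X, vec[_B0:_B0 + 11], 0, phi)
                elif b == 2:
                    if Tm1 > 0:
                        _logistic_field(X, vec[_E0:_E0 + 11], 1, theta)

        # ---- slice move along the psi/detection ridge -------------------
        if ridge_on:
            slope = float(np.random.randint(1, 4))
            f0 = b_y0 + b_y1 + b_zn
            logy = f0 - np.random.exponential()
            width = 0.5
            lo = -width * np.random.random()
            hi = lo + width
            xi_buf[2] = rho_nest
            for _ in range(6):
                fl = _ridge_block(lo, slope, vec, psi, Nou, xi_buf, nn_buf,
                                  Yobs, Yval, zn_pos, zn_neg, lower, upper, 0.0)
                if fl <= logy:
                    break
                lo -= width
            for _ in range(6):
                fh = _ridge_block(hi, slope, vec, psi, Nou, xi_buf, nn_buf,
                                  Yobs, Yval, zn_pos, zn_neg, lower, upper, 0.0)
                if fh <= logy:
                    break
                hi += width
            for _ in range(30):
                u = lo + (hi - lo) * np.random.random()
                fu = _ridge_block(u, slope, vec, psi, Nou, xi_buf, nn_buf,
                                  Yobs, Yval, zn_pos, zn_neg, lower, upper, 0.0)
                if fu > logy:
                    vec[_G0] += u
                    vec[_MU0] -= slope * u
                    vec[_MU0 + 1] -= slope * u
                    _psi_field(ind, vec[_G0:_G0 + 6], psi)
                    xi[0] = _expit(vec[_MU0])
                    xi[1] = _expit(vec[_MU0 + 1])
                    for i in range(C):
                        for t in range(T):
                            Nnest[i, t] = nn_buf[i, t]
                    b_y0 = _ll_counts_j(Yobs, Yval, Nnest, xi[0], 0)
                    b_y1 = _ll_counts_j(Yobs, Yval, Nnest, xi[1], 1)
                    b_zn = _ll_zn(rho_nest, Nnest, zn_pos, zn_neg)
                    break
                if u < 0:
                    lo = u
                else:
                    hi = u

        # ---- latent updates (sequential single-site scan) ---------------
        if update_latents:
            for i in range(C):
                for t in range(T):
                    # -- occupancy flip
                    cur = O[i, t]
                    new = 1 - cur
                    p = phi[i, t]
                    d = ((math.log(p) if p > 0 else -np.inf)
                         - (math.log1p(-p) if p < 1 else -np.inf))
                    if new == 0:
                        d = -d
                    o_new = float(new)
                    o_cur = float(cur)
                    d += (_xlogy(zo_pos1[i, t], rho1 * o_new)
                          + _xlogy(zo_neg1[i, t], 1.0 - rho1 * o_new)
                          + _xlogy(zo_pos0[i, t], rho0 * o_new)
                          + _xlogy(zo_neg0[i, t], 1.0 - rho0 * o_new)
                          - _xlogy(zo_pos1[i, t], rho1 * o_cur)
                          - _xlogy(zo_neg1[i, t], 1.0 - rho1 * o_cur)
                          - _xlogy(zo_pos0[i, t], rho0 * o_cur)
                          - _xlogy(zo_neg0[i, t], 1.0 - rho0 * o_cur))
                    rate = lam[i] if t == 0 else float(S[i, t - 1] + R[i, t - 1])
                    d += (_log_pois(Nou[i, t], rate * o_new)
                          - _log_pois(Nou[i, t], rate * o_cur))
                    if d > -np.inf and math.log(np.random.random() + 1e-300) < d:
                        O[i, t] = new

                    # -- abundance +/-1
                    step = 1 if np.random.random() < 0.5 else -1
                    curN = Nou[i, t]
                    newN = curN + step
                    if newN >= 0:
                        rate = (lam[i] if t == 0
                                else float(S[i, t - 1] + R[i, t - 1])) * O[i, t]
                        if step > 0:
                            d = ((math.log(rate) if rate > 0 else -np.inf)
                                 - math.log(curN + 1.0))
                        else:
                            d = ((math.log(float(curN)) if curN > 0 else -np.inf)
                                 - (math.log(rate) if rate > 0 else np.inf))
                        nn_new = int(round(psi[i, t] * newN))
                        d += (_obs_ll_cell(i, t, nn_new, xi, rho_nest, Yobs,
                                           Yval, zn_pos, zn_neg)
                              - _obs_ll_cell(i, t, Nnest[i, t], xi, rho_nest,
                                             Yobs, Yval, zn_pos, zn_neg))
                        if t < Tm1:
                            th = theta[i, t]
                            kS = S[i, t]
                            if step > 0:
                                d += (math.log(curN + 1.0)
                                      - (math.log(curN + 1.0 - kS)
                                         if curN + 1 - kS > 0 else np.inf)
                                      + (math.log1p(-th) if th < 1 else -np.inf))
                            else:
                                if kS > newN:
                                    d = -np.inf
                                else:
                                    d += ((math.log(float(curN - kS))
                                           if curN - kS > 0 else -np.inf)
                                          - math.log(float(curN))
                                          - (math.log1p(-th) if th < 1 else -np.inf))
                            if d > -np.inf:
                                # recruitment of self and neighbours
                                ws = WS[i, t]
                                d += (_log_pois(R[i, t],
                                                exp_chi * (ws + step) / deg1[i])
                                      - _log_pois(R[i, t], exp_chi * ws / deg1[i]))
                                for k in range(8):
                                    j = nbr[i, k]
                                    if j >= 0 and wgt[i, k] > 0.0:
                                        wsj = WS[j, t]
                                        d += (_log_pois(
                                            R[j, t],
                                            exp_chi * (wsj + step * wgt[i, k]) / deg1[j])
                                            - _log_pois(
                                                R[j, t], exp_chi * wsj / deg1[j]))
                        if d > -np.inf and math.log(np.random.random() + 1e-300) < d:
                            Nou[i, t] = newN
                            Nnest[i, t] = nn_new
                            if t < Tm1:
                                WS[i, t] += step
                                for k in range(8):
                                    j = nbr[i, k]
                                    if j >= 0 and wgt[i, k] > 0.0:
                                        WS[j, t] += step * wgt[i, k]

                    if t < Tm1:
                        # -- survivors +/-1
                        step = 1 if np.random.random() < 0.5 else -1
                        kS = S[i, t]
                        nS = kS + step
                        nmax = Nou[i, t]
                        if 0 <= nS <= nmax:
                            th = theta[i, t]
                            if step > 0:
                                d = ((math.log(float(nmax - kS))
                                      if nmax - kS > 0 else -np.inf)
                                     - math.log(kS + 1.0)
                                     + (math.log(th) if th > 0 else -np.inf)
                                     - (math.log1p(-th) if th < 1 else np.inf))
                            else:
                                d = ((math.log(float(kS)) if kS > 0 else -np.inf)
                                     - math.log(float(nmax - kS + 1))
                                     - (math.log(th) if th > 0 else -np.inf)
                                     + (math.log1p(-th) if th < 1 else -np.inf))
                            rate_old = float(kS + R[i, t]) * O[i, t + 1]
                            rate_new = float(nS + R[i, t]) * O[i, t + 1]
                            d += (_log_pois(Nou[i, t + 1], rate_new)
                                  - _log_pois(Nou[i, t + 1], rate_old))
                            if d > -np.inf and math.log(np.random.random() + 1e-300) < d:
                                S[i, t] = nS

                        # -- recruits +/-1
                        step = 1 if np.random.random() < 0.5 else -1
                        kR = R[i, t]
                        nR = kR + step
                        if nR >= 0:
                            delta_r = exp_chi * WS[i, t] / deg1[i]
                            if step > 0:
                                d = ((math.log(delta_r) if delta_r > 0 else -np.inf)
                                     - math.log(kR + 1.0))
                            else:
                                d = ((math.log(float(kR)) if kR > 0 else -np.inf)
                                     - (math.log(delta_r) if delta_r > 0 else np.inf))
                            rate_old = float(S[i, t] + kR) * O[i, t + 1]
                            rate_new = float(S[i, t] + nR) * O[i, t + 1]
                            d += (_log_pois(Nou[i, t + 1], rate_new)
                                  - _log_pois(Nou[i, t + 1], rate_old))
                            if d > -np.inf and math.log(np.random.random() + 1e-300) < d:
                                R[i, t] = nR

                        # -- S/R exchange keeping Ntilde
                        step = 1 if np.random.random() < 0.5 else -1
                        nS = S[i, t] + step
                        nR = R[i, t] - step
                        if 0 <= nS <= Nou[i, t] and nR >= 0:
                            th = theta[i, t]
                            delta_r = exp_chi * WS[i, t] / deg1[i]
                            d = (_log_binom(nS, Nou[i, t], th)
                                 - _log_binom(S[i, t], Nou[i, t], th)
                                 + _log_pois(nR, delta_r)
                                 - _log_pois(R[i, t], delta_r))
                            if d > -np.inf and math.log(np.random.random() + 1e-300) < d:
                                S[i, t] = nS
                                R[i, t] = nR

        # ---- adaptation -------------------------------------------------
        if adapt and it < n_burn:
            if it >= n_burn // 2:
                for b in range(_NBLK):
                    if blk_on[b]:
                        st = _BLK_START[b]
                        L = _BLK_LEN[b]
                        for ai in range(L):
                            xa = vec[st + ai]
                            mean_acc[b, ai] += xa
                            for ci in range(L):
                                outer_acc[b, ai, ci] += xa * vec[st + ci]
                n_acc += 1
            if n_acc >= 300 and (it + 1) % 200 == 0:
                for b in range(_NBLK):
                    if not blk_on[b]:
                        continue
                    L = _BLK_LEN[b]
                    for ai in range(L):
                        ma = mean_acc[b, ai] / n_acc
                        for ci in range(L):
                            cov_tmp[ai, ci] = (outer_acc[b, ai, ci] / n_acc
                                               - ma * mean_acc[b, ci] / n_acc)
                    jit = 0.0
                    for ai in range(L):
                        if cov_tmp[ai, ai] > jit:
                            jit = cov_tmp[ai, ai]
                    jit = 1e-6 * (jit if jit > 0.0 else 1.0)
                    for ai in range(L):
                        cov_tmp[ai, ai] += jit
                    if _chol11(cov_tmp, L, chol_tmp):
                        sc = 2.38 / math.sqrt(L)
                        for ai in range(L):
                            for ci in range(L):
                                chol[b, ai, ci] = sc * chol_tmp[ai, ci]
                        if not blk_seeded[b]:
                            blk_scale[b] = 1.0
                            blk_seeded[b] = True
        if adapt and it < n_burn and (it + 1) % 50 == 0:
            batch += 1
            sq = math.sqrt(batch)
            for k in range(_NP):
                rate = acc_batch[k] / 50.0
                steps[k] *= math.exp((rate - 0.44) / sq)
                if steps[k] < 1e-4:
                    steps[k] = 1e-4
                elif steps[k] > 10.0:
                    steps[k] = 10.0
                acc_batch[k] = 0.0
            for b in range(_NBLK):
                br = blk_acc_batch[b] / 50.0
                target = 0.28 if _BLK_LEN[b] > 1 else 0.44
                blk_scale[b] *= math.exp((br - target) / sq)
                if blk_scale[b] < 1e-4:
                    blk_scale[b] = 1e-4
                elif blk_scale[b] > 10.0:
                    blk_scale[b] = 10.0
                blk_acc_batch[b] = 0.0

        # ---- storage ----------------------------------------------------
        if it >= n_burn:
            row = it - n_burn
            for k in range(_NP):
                draws[row, k] = vec[k]
            for i in range(C):
                for t in range(T):
                    O_sum[i, t] += O[i, t]
            if row % latent_thin == 0:
                for i in range(C):
                    for t in range(T):
                        Nou_draws[stored, i, t] = Nou[i, t]
                stored += 1

    acc = np.zeros(_NP + 1)
    for k in range(_NP + 1):
        if prop_count[k] > 0:
            acc[k] = acc_count[k] / prop_count[k]
    return draws, Nou_draws, O_sum, acc
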