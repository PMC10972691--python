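"""Monte-Carlo genealogy sampler for the 4-lineage structured coalescent.

Independent of the matrix-exponential likelihood in :mod:`invcoal.likelihood`
(shares only the model definition): genealogies are sampled with a Gillespie
algorithm, tracking the total branch length in each of the four folded
mutation-type classes.  Used as the test oracle for the exact probabilities
and as the fast simulator of independent blocks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# class of a lineage subtending i A-leaves, j B-leaves (folded); -1 = none
_CLS = np.array([-2, 1, 3, 0, 2, 0, 3, 1, -1], dtype=np.int64)  # index i*3+j


@njit(cache=True)
def _simulate(R, ne_a, ne_b, ne_anc, t_split, m, mig_deme, seed):
    np.random.seed(seed)
    L = np.zeros((R, 4))
    i_ = np.empty(4, np.int64)
    j_ = np.empty(4, np.int64)
    d_ = np.empty(4, np.int64)
    start_deme = 1 if t_split > 0.0 else 0
    for r in range(R):
        i_[0] = 1; j_[0] = 0; d_[0] = 0
        i_[1] = 1; j_[1] = 0; d_[1] = 0
        i_[2] = 0; j_[2] = 1; d_[2] = start_deme
        i_[3] = 0; j_[3] = 1; d_[3] = start_deme
        n = 4
        tnow = 0.0
        phase1 = t_split > 0.0
        while n > 1:
            c0 = 0
            for a in range(n):
                if d_[a] == 0:
                    c0 += 1
            c1 = n - c0
            if phase1:
                r0 = c0 * (c0 - 1) * 0.5 / (2.0 * ne_a)
                r1 = c1 * (c1 - 1) * 0.5 / (2.0 * ne_b)
                if mig_deme == 0:
                    rm = c0 * m
                elif mig_deme == 1:
                    rm = c1 * m
                else:
                    rm = 0.0
            else:
                r0 = n * (n - 1) * 0.5 / (2.0 * ne_anc)
                r1 = 0.0
                rm = 0.0
            tot = r0 + r1 + rm
            if tot > 0.0:
                dt = np.random.exponential(1.0 / tot)
            else:
                dt = np.inf
            if phase1 and tnow + dt >= t_split:
                dt = t_split - tnow
                for a in range(n):
                    cl = _CLS[i_[a] * 3 + j_[a]]
                    if cl >= 0:
                        L[r, cl] += dt
                tnow = t_split
                phase1 = False
                for a in range(n):
                    d_[a] = 0
                continue
            for a in range(n):
                cl = _CLS[i_[a] * 3 + j_[a]]
                if cl >= 0:
                    L[r, cl] += dt
            tnow += dt
            u = np.random.random() * tot
            if u < r0 + r1:
                deme = 0 if u < r0 else 1
                npair = 0
                for a in range(n):
                    if d_[a] != deme:
                        continue
                    for b in range(a + 1, n):
                        if d_[b] == deme:
                            npair += 1
                pick = int(np.random.random() * npair)
                if pick >= npair:
                    pick = npair - 1
                cnt = 0
                pa = -1
                pb = -1
                for a in range(n):
                    if d_[a] != deme:
                        continue
                    for b in range(a + 1, n):
                        if d_[b] == deme:
                            if cnt == pick:
                                pa = a
                                pb = b
                            cnt += 1
                i_[pa] += i_[pb]
                j_[pa] += j_[pb]
                i_[pb] = i_[n - 1]
                j_[pb] = j_[n - 1]
                d_[pb] = d_[n - 1]
                n -= 1
            else:
                nm = 0
                for a in range(n):
                    if d_[a] == mig_deme:
                        nm += 1
                pick = int(np.random.random() * nm)
                if pick >= nm:
                    pick = nm - 1
                cnt = 0
                for a in range(n):
                    if d_[a] == mig_deme:
                        if cnt == pick:
                            d_[a] = 1 - mig_deme
                            break
                        cnt += 1
    return L


@njit(cache=True)
def _poisson_table(L, lam, kmax):
    R = L.shape[0]
    K = kmax + 2
    acc = np.zeros((K, K, K, K))
    acc2 = np.zeros((K, K, K, K))
    pv = np.empty((4, K))
    for r in range(R):
        for k in range(4):
            x = lam * L[r, k]
            p = np.exp(-x)
            s = p
            pv[k, 0] = p
            for c in range(1, kmax + 1):
                p = p * x / c
                pv[k, c] = p
                s += p
            resid = 1.0 - s
            pv[k, kmax + 1] = resid if resid > 0.0 else 0.0
        for a in range(K):
            pa = pv[0, a]
            for b in range(K):
                pab = pa * pv[1, b]
                for c in range(K):
                    pabc = pab * pv[2, c]
                    for d in range(K):
                        v = pabc * pv[3, d]
                        acc[a, b, c, d] += v
                        acc2[a, b, c, d] += v * v
    mean = acc / R
    var = acc2 / R - mean * mean
    se = np.sqrt(np.where(var > 0.0, var, 0.0) / R)
    return mean, se


@njit(cache=True)
def _poisson_counts(L, lam, seed):
    np.random.seed(seed)
    R = L.shape[0]
    out = np.empty((R, 4), np.int64)
    for r in range(R):
        for k in range(4):
            out[r, k] = np.random.poisson(lam * L[r, k])
    return out


def _mig_deme(params):
    if params.model == "DIV" or params.m == 0:
        return -1
    return 1 if params.model == "IM_AB" else 0


def sample_class_lengths(params, n_genealogies: int, seed: int) -> np.ndarray:
    """Sample per-genealogy total branch lengths (generations) in the four
    mutation-type classes (hetA, hetB, hetAB, fixed); shape (n, 4)."""
    if n_genealogies < 1:
        raise ValueError("need at least one genealogy")
    return _simulate(
        int(n_genealogies),
        float(params.ne_a),
        float(params.ne_b),
        float(params.ne_anc),
        float(params.t),
        float(params.m),
        _mig_deme(params),
        int(seed) % (2**31),
    )


def poisson_table(L: np.ndarray, lam: float, kmax: int):
    """Rao-Blackwellised table estimate: mean over genealogies of the exact
    Poisson product, with per-cell Monte-Carlo standard errors."""
    return _poisson_table(np.ascontiguousarray(L, dtype=np.float64), float(lam), int(kmax))


def sample_block_counts(params, n_blocks: int, block_length: int, mu: float, seed: int) -> np.ndarray:
    """Simulate mutation-type counts for independent blocks: one genealogy
    per block, Poisson mutation counts per class; shape (n_blocks, 4)."""
    L = sample_class_lengths(params, n_blocks, seed)
    return _poisson_counts(L, mu * block_length, (int(seed) + 1) % (2**31))
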