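"""Numba Gibbs-sweep kernel for the admixture model.

Kept separate from the user-facing module so the JIT surface is a single
self-contained function of plain arrays.  The sampler state is (Q, P):
per-individual ancestry proportions and per-cluster alternate-allele
frequencies.  One sweep (i) assigns every observed allele copy a cluster
of origin z with probability proportional to q_ik p_kl (alternate copies)
or q_ik (1 - p_kl) (reference copies), (ii) redraws each q_i from
Dirichlet(alpha + copy counts), and (iii) redraws each p_kl from
Beta(lambda + alternate copies in k, lambda + reference copies in k).
Post-burn-in sweeps record the observed-data log-likelihood
ln P(X|P,Q) = Σ copies ln Σ_k q_ik (p_kl or 1-p_kl) and accumulate Q and P
posterior means.

Performance notes: the per-copy categorical draws dominate the cost, so
they use an inline xorshift64* generator (seeded from the numba Mersenne
Twister stream, which still drives the Dirichlet/Beta conjugate updates),
the reference-copy weights reuse q_ik - q_ik p_kl, the likelihood uses
s0 = 1 - s1 (Q rows sum to one), and per-copy log terms are accumulated
as batched products flushed through a single log every 64 cells.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_XM = np.uint64(2685821657736338717)  # xorshift64* multiplier
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, fastmath=True)
def gibbs_admixture(G, K, burn_in, sweeps, alpha, lam, seed):
    """Run burn_in + sweeps Gibbs sweeps; returns (q_mean, pt_mean, lnl).

    G : (N, L) int8 dosage matrix, -1 for missing.
    Returns q_mean (N, K), pt_mean (L, K) and the post-burn-in
    log-likelihood trace lnl (sweeps,).
    """
    np.random.seed(seed)
    N, L = G.shape
    state = np.uint64(np.random.randint(1, 2**62) * 2 + 1)

    Q = np.empty((N, K))
    Pt = np.empty((L, K))  # P transposed for contiguous k-access
    for i in range(N):
        s = 0.0
        for k in range(K):
            g = np.random.gamma(alpha, 1.0)
            Q[i, k] = g
            s += g
        for k in range(K):
            Q[i, k] /= s
    for l in range(L):
        for k in range(K):
            Pt[l, k] = np.random.beta(lam, lam)

    q_mean = np.zeros((N, K))
    pt_mean = np.zeros((L, K))
    lnl = np.zeros(sweeps)

    n_ik = np.zeros((N, K))
    c_alt = np.zeros((L, K))
    c_ref = np.zeros((L, K))
    w1 = np.empty(K)
    qrow = np.empty(K)

    total = burn_in + sweeps
    for t in range(total):
        record = t >= burn_in
        ll = 0.0
        prod = 1.0
        nprod = 0
        n_ik[:, :] = 0.0
        c_alt[:, :] = 0.0
        c_ref[:, :] = 0.0
        for i in range(N):
            for k in range(K):
                qrow[k] = Q[i, k]
            for l in range(L):
                g = G[i, l]
                if g < 0:
                    continue
                s1 = 0.0
                for k in range(K):
                    v = qrow[k] * Pt[l, k]
                    w1[k] = v
                    s1 += v
                s0 = 1.0 - s1
                if K == 1:
                    k1 = 0
                    k2 = 0
                else:
                    # first allele copy
                    state ^= state << np.uint64(13)
                    state ^= state >> np.uint64(7)
                    state ^= state << np.uint64(17)
                    u = float((state * _XM) >> np.uint64(11)) * _INV53
                    acc = 0.0
                    k1 = K - 1
                    if g >= 1:
                        u *= s1
                        for k in range(K):
                            acc += w1[k]
                            if u < acc:
                                k1 = k
                                break
                    else:
                        u *= s0
                        for k in range(K):
                            acc += qrow[k] - w1[k]
                            if u < acc:
                                k1 = k
                                break
                    # second allele copy
                    state ^= state << np.uint64(13)
                    state ^= state >> np.uint64(7)
                    state ^= state << np.uint64(17)
                    u = float((state * _XM) >> np.uint64(11)) * _INV53
                    acc = 0.0
                    k2 = K - 1
                    if g == 2:
                        u *= s1
                        for k in range(K):
                            acc += w1[k]
                            if u < acc:
                                k2 = k
                                break
                    else:
                        u *= s0
                        for k in range(K):
                            acc += qrow[k] - w1[k]
                            if u < acc:
                                k2 = k
                                break
                if g >= 1:
                    c_alt[l, k1] += 1.0
                else:
                    c_ref[l, k1] += 1.0
                if g == 2:
                    c_alt[l, k2] += 1.0
                else:
                    c_ref[l, k2] += 1.0
                n_ik[i, k1] += 1.0
                n_ik[i, k2] += 1.0
                if record:
                    pa = s1 if g >= 1 else s0
                    pb = s1 if g == 2 else s0
                    prod *= pa * pb
                    nprod += 1
                    if nprod == 64:
                        ll += np.log(prod)
                        prod = 1.0
                        nprod = 0
        if record and nprod > 0:
            ll += np.log(prod)
        # update Q | z
        for i in range(N):
            s = 0.0
            for k in range(K):
                gd = np.random.gamma(alpha + n_ik[i, k], 1.0)
                Q[i, k] = gd
                s += gd
            for k in range(K):
                Q[i, k] /= s
        # update P | z
        for l in range(L):
            for k in range(K):
                Pt[l, k] = np.random.beta(lam + c_alt[l, k], lam + c_ref[l, k])
        if record:
            lnl[t - burn_in] = ll
            q_mean += Q
            pt_mean += Pt

    q_mean /= sweeps
    pt_mean /= sweeps
    return q_mean, pt_mean, lnl
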