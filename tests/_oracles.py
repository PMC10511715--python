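"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written by enumeration / first principles,
separate from the library code paths it is used to check.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import expit


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x > r2 or c1 - x < 0:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * Fraction(10**7 + 1, 10**7):  # relative float-tie slack
            total += px
    return float(total)


def ranksum_oracle(x, y):
    """Two-sided rank-sum p by enumeration over all C(n+m, n) assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    W_obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        W = ranks[list(comb)].sum()
        total += 1
        if abs(W - mu) >= abs(W_obs - mu) - 1e-9:
            count += 1
    return count / total


def signed_rank_oracle(d):
    """Two-sided signed-rank p by enumeration over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    W_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    count = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        W = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if abs(W - mu) >= abs(W_obs - mu) - 1e-9:
            count += 1
    return count / total


def permanova_oracle(Y, labels):
    """Exact PERMANOVA p over all distinct label permutations (small N)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    labels = np.asarray(labels)
    D2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)

    def F_of(lab):
        N = len(lab)
        ss_total = D2.sum() / (2 * N)
        ss_within = 0.0
        for g in np.unique(lab):
            idx = np.flatnonzero(lab == g)
            ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        k = len(np.unique(lab))
        ss_among = ss_total - ss_within
        if ss_within <= 1e-300:
            return np.inf
        return (ss_among / (k - 1)) / (ss_within / (N - k))

    F_obs = F_of(labels)
    perms = set(itertools.permutations(labels))
    count = sum(1 for p in perms if F_of(np.array(p)) >= F_obs - 1e-9)
    return count / len(perms), F_obs


def all_states(n):
    """Every binary vector of length n (2^n rows)."""
    return np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)


def exact_loglik_gradient(W, a, c, data):
    """Exact gradient of the binary-RBM data log-likelihood via brute force
    over every (v, h) state pair (independent of any CD code path)."""
    nv, nh = W.shape
    V = all_states(nv)
    H = all_states(nh)
    energy = V @ a[:, None] + (H @ c)[None, :] + V @ W @ H.T  # -E(v, h)
    joint = np.exp(energy)
    p_joint = joint / joint.sum()
    E_vh_model = np.einsum("ij,ik,jl->kl", p_joint, V, H)
    E_v_model = p_joint.sum(axis=1) @ V
    E_h_model = p_joint.sum(axis=0) @ H
    ph = expit(c + data @ W)
    E_vh_data = data.T @ ph / len(data)
    E_v_data = data.mean(axis=0)
    E_h_data = ph.mean(axis=0)
    return E_vh_data - E_vh_model, E_v_data - E_v_model, E_h_data - E_h_model


def cosine(u, v):
    u, v = np.ravel(u), np.ravel(v)
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
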