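"""Independent scalar oracles for the core equations.

Everything here is a deliberately naive double-loop evaluation, kept free
of any code path from the package so that agreement is meaningful.
"""

import numpy as np


def bandwidth_oracle(profiles, gamma_prime=1.0):
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    mean_sq = sum(float(np.dot(p, p)) for p in profiles) / n
    return gamma_prime / mean_sq


def kernel_oracle(profiles, gamma):
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = profiles[i] - profiles[j]
            K[i, j] = np.exp(-gamma * float(np.dot(d, d)))
    return K


def ncp_d_oracle(KD, A):
    KD, A = np.asarray(KD, float), np.asarray(A, float)
    nd, nm = A.shape
    out = np.zeros((nd, nm))
    for i in range(nd):
        for j in range(nm):
            col = A[:, j]
            norm = np.sqrt(float(np.dot(col, col)))
            if norm > 0:
                out[i, j] = float(np.dot(KD[i], col)) / norm
    return out


def ncp_m_oracle(A, KM):
    KM, A = np.asarray(KM, float), np.asarray(A, float)
    nd, nm = A.shape
    out = np.zeros((nd, nm))
    for i in range(nd):
        for j in range(nm):
            row = A[i]
            norm = np.sqrt(float(np.dot(row, row)))
            if norm > 0:
                out[i, j] = float(np.dot(row, KM[:, j])) / norm
    return out


def ncp_combine_oracle(ncp_d, ncp_m, KD, KM):
    ncp_d, ncp_m = np.asarray(ncp_d, float), np.asarray(ncp_m, float)
    KD, KM = np.asarray(KD, float), np.asarray(KM, float)
    nd, nm = ncp_d.shape
    out = np.empty((nd, nm))
    for i in range(nd):
        for j in range(nm):
            denom = np.sqrt(float(np.dot(KD[i], KD[i]))) + np.sqrt(
                float(np.dot(KM[:, j], KM[:, j]))
            )
            out[i, j] = (ncp_d[i, j] + ncp_m[i, j]) / denom
    return out


def predict_oracle(A, gamma_prime_d=1.0, gamma_prime_m=1.0):
    """Full scoring pipeline by scalar evaluation only."""
    A = np.asarray(A, dtype=float)
    KD = kernel_oracle(A, bandwidth_oracle(A, gamma_prime_d))
    KM = kernel_oracle(A.T, bandwidth_oracle(A.T, gamma_prime_m))
    return ncp_combine_oracle(
        ncp_d_oracle(KD, A), ncp_m_oracle(A, KM), KD, KM
    )


def auc_oracle(test_scores, candidate_scores):
    """Exhaustive pairwise Mann-Whitney statistic, ties count one half."""
    wins = 0.0
    for t in test_scores:
        for c in candidate_scores:
            if t > c:
                wins += 1.0
            elif t == c:
                wins += 0.5
    return wins / (len(test_scores) * len(candidate_scores))


def global_loocv_oracle(A, gamma_prime_d=1.0, gamma_prime_m=1.0):
    """From-scratch scripted leave-one-association-out evaluation."""
    A = np.asarray(A, dtype=float)
    tests, cands = [], []
    zeros = np.argwhere(A == 0)
    for i, j in np.argwhere(A == 1):
        B = A.copy()
        B[i, j] = 0.0
        S = predict_oracle(B, gamma_prime_d, gamma_prime_m)
        tests.append(S[i, j])
        cands.extend(S[a, b] for a, b in zeros)
    return auc_oracle(tests, cands)


def random_binary_matrix(rng, max_rows=15, max_cols=20):
    """Random 0/1 matrix with at least one 1."""
    while True:
        nd = int(rng.integers(1, max_rows + 1))
        nm = int(rng.integers(1, max_cols + 1))
        A = (rng.random((nd, nm)) < rng.uniform(0.1, 0.6)).astype(np.int8)
        if A.any():
            return A
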