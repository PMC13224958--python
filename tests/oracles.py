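"""Independent dense, loop-based oracles for the closed-form block updates.

Everything here is written directly from the normal equations with plain
loops / dense algebra, deliberately sharing no code path with the package.
"""
import numpy as np


def dense_residual(Y, o, s, Z, delta, sample_of_cell):
    """Y - o 1^T - 1 s^T - (Z + dZ_i) B-part left out: residual before factors."""
    R = np.asarray(Y, dtype=float).copy()
    R -= o[:, None]
    R -= s[None, :]
    return R


def oracle_reconstruct(Z, delta_i, b, o, s_n):
    g, K = Z.shape
    out = np.empty(g)
    for gi in range(g):
        acc = o[gi] + s_n
        for k in range(K):
            acc += (Z[gi, k] + delta_i[gi, k]) * b[k]
        out[gi] = acc
    return out


def oracle_loss(Y, o, s, Z, delta, B, sample_of_cell, hp, X=None, D=None, W=None):
    Y = np.asarray(Y, dtype=float)
    g, n = Y.shape
    total = 0.0
    for c in range(n):
        i = sample_of_cell[c]
        pred = o + s[c] + (Z + delta[i]) @ B[:, c]
        total += float(((Y[:, c] - pred) ** 2).sum())
    total += hp.lambda_b * float((B ** 2).sum())
    n_samples = len(delta)
    for i in range(n_samples):
        Dx = np.zeros_like(Z)
        if D is not None and X is not None:
            for t in range(X.shape[1]):
                Dx += X[i, t] * D[t]
        total += hp.lambda_delta * float(((delta[i] - Dx) ** 2).sum())
    if D is not None:
        total += hp.lambda_d * float((D ** 2).sum())
    if W is not None:
        total += hp.lambda_w * float((W ** 2).sum())
    return total


def oracle_embeddings(Y, o, s, Z, delta, sample_of_cell, lam):
    """Per-cell ridge solve b = (M^T M + lam I)^-1 M^T (y - o - s 1)."""
    Y = np.asarray(Y, dtype=float)
    g, n = Y.shape
    K = Z.shape[1]
    B = np.empty((K, n))
    for c in range(n):
        M = Z + delta[sample_of_cell[c]]
        r = Y[:, c] - o - s[c]
        B[:, c] = np.linalg.solve(M.T @ M + lam * np.eye(K), M.T @ r)
    return B


def oracle_distortions(Y, o, s, Z, B, sample_of_cell, n_samples, lam, X=None, D=None):
    """Per-sample ridge: dZ = (R B^T + lam Dx)(B B^T + lam I)^-1 with dense R."""
    Y = np.asarray(Y, dtype=float)
    K = Z.shape[1]
    out = []
    for i in range(n_samples):
        idx = np.flatnonzero(sample_of_cell == i)
        Dx = np.zeros_like(Z)
        if D is not None and X is not None:
            for t in range(X.shape[1]):
                Dx += X[i, t] * D[t]
        if len(idx) == 0:
            out.append(Dx.copy())
            continue
        Bi = B[:, idx]
        R = Y[:, idx] - o[:, None] - s[idx][None, :] - Z @ Bi
        lhs = Bi @ Bi.T + lam * np.eye(K)
        out.append(np.linalg.solve(lhs.T, (R @ Bi.T + lam * Dx).T).T)
    return out


def oracle_covariate_map(delta, X, lam_ratio):
    """Ridge regression of each (g,k) distortion entry on the covariates."""
    S, T = X.shape
    g, K = delta[0].shape
    V = np.stack([d.ravel() for d in delta])          # S x (g*K)
    G = X.T @ X + lam_ratio * np.eye(T)
    sol = np.linalg.solve(G, X.T @ V)
    return sol.reshape(T, g, K)


def oracle_reference(Y, o, s, delta, B, sample_of_cell):
    """Z* = C_yb C_bb^-1 accumulated cell by cell."""
    Y = np.asarray(Y, dtype=float)
    g, n = Y.shape
    K = B.shape[0]
    Cyb = np.zeros((g, K))
    Cbb = np.zeros((K, K))
    for c in range(n):
        b = B[:, c]
        r = Y[:, c] - o - s[c] - delta[sample_of_cell[c]] @ b
        Cyb += np.outer(r, b)
        Cbb += np.outer(b, b)
    return np.linalg.solve(Cbb.T, Cyb.T).T


def oracle_offsets(Y, o, s, Z, delta, B, sample_of_cell):
    """Joint (o, s) minimizer after B row-centering, built cell by cell.

    Least squares over (o, s) given the factor part: o gets the per-gene
    residual means (including the grand mean), s the per-cell residual
    means minus the grand mean.
    """
    Y = np.asarray(Y, dtype=float)
    g, n = Y.shape
    bbar = B.mean(axis=1)
    B_c = B - bbar[:, None]
    F = np.empty_like(Y)
    for c in range(n):
        F[:, c] = (Z + delta[sample_of_cell[c]]) @ B_c[:, c]
    R = Y - F
    o_new = R.mean(axis=1)
    s_new = R.mean(axis=0) - R.mean()
    return o_new, s_new, B_c


def auroc(scores_pos, scores_neg):
    """Rank-based AUROC (probability a planted gene outranks a background gene)."""
    pooled = np.concatenate([scores_pos, scores_neg])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(pooled) + 1)
    # midranks for ties
    sorted_vals = pooled[order]
    start = 0
    for end in range(1, len(pooled) + 1):
        if end == len(pooled) or sorted_vals[end] != sorted_vals[start]:
            ranks[order[start:end]] = 0.5 * (start + 1 + end)
            start = end
    n1, n2 = len(scores_pos), len(scores_neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)
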