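"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles with elementary numpy
(recursive kinship instead of the tabular loop, explicit dense inversions
instead of Cholesky solves, per-marker loops instead of einsum) so it can
serve as an oracle for the package's optimized paths.
"""

from __future__ import annotations

import sys

import numpy as np

from ssgwas.relmat import UNKNOWN, GenotypeMatrix, PedigreeTable


def kinship_matrix(ped: PedigreeTable) -> np.ndarray:
    """Additive relationship matrix from the Malecot kinship recursion.

    phi(i, i) = 0.5 * (1 + phi(s_i, d_i)); for j earlier than i,
    phi(i, j) = 0.5 * (phi(s_i, j) + phi(d_i, j)); unknown parents
    contribute 0.  A = 2 * phi.
    """
    sys.setrecursionlimit(10000)
    s, d = ped.sire_idx, ped.dam_idx
    memo: dict[tuple[int, int], float] = {}

    def phi(i: int, j: int) -> float:
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        if j > i:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + phi(int(s[i]), int(d[i])))
        else:
            # i is the later-born animal, recurse on its parents
            val = 0.5 * (phi(int(s[i]), j) + phi(int(d[i]), j))
        memo[key] = val
        return val

    n = ped.n_animals
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * phi(i, j)
    return A


def projection_absorption(phen, animal_ids) -> np.ndarray:
    """Diagonal of W'(I - X (X'X)^-1 X') W formed explicitly."""
    cgs = sorted(phen["cg"].astype(str).unique())
    cg_pos = {c: i for i, c in enumerate(cgs)}
    an_pos = {a: i for i, a in enumerate(animal_ids)}
    n_rec = len(phen)
    X = np.zeros((n_rec, len(cgs)))
    W = np.zeros((n_rec, len(animal_ids)))
    for r, (_, rec) in enumerate(phen.iterrows()):
        X[r, cg_pos[str(rec["cg"])]] = 1.0
        if rec["animal_id"] in an_pos:
            W[r, an_pos[rec["animal_id"]]] = 1.0
    P = np.eye(n_rec) - X @ np.linalg.inv(X.T @ X) @ X.T
    return np.diag(W.T @ P @ W)


def dense_pipeline_variances(
    ped: PedigreeTable,
    geno: GenotypeMatrix,
    phen,
    sigma_u2: float,
    sigma_e2: float,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """From-scratch exact-route SNP effects and variances.

    Builds every matrix densely and explicitly: recursive-kinship A,
    np.linalg.inv everywhere, dense one-hot incidence matrices, a
    per-marker loop for the quadratic forms.  Returns (effects, variances).
    """
    A = kinship_matrix(ped)
    gidx = ped.index_of(geno.animal_ids)
    A22 = A[np.ix_(gidx, gidx)]

    counts = geno.counts
    p = counts.mean(axis=0) / 2.0
    Z = counts - 2.0 * p
    k = float(2.0 * np.sum(p * (1.0 - p)))
    G_raw = Z @ Z.T / k

    n_g = len(gidx)
    off = ~np.eye(n_g, dtype=bool)
    coef = np.array([[np.mean(np.diag(G_raw)), 1.0], [np.mean(G_raw[off]), 1.0]])
    targ = np.array([np.mean(np.diag(A22)), np.mean(A22[off])])
    b, alpha = np.linalg.solve(coef, targ)
    G = (1.0 - beta) * (alpha + b * G_raw) + beta * A22

    G_inv = np.linalg.inv(G)
    H_inv = np.linalg.inv(A)
    adj = G_inv - np.linalg.inv(A22)
    H_inv[np.ix_(gidx, gidx)] += adj

    cgs = sorted(phen["cg"].astype(str).unique())
    cg_pos = {c: i for i, c in enumerate(cgs)}
    an_pos = {a: i for i, a in enumerate(ped.ids)}
    n_rec, n_anim = len(phen), ped.n_animals
    X = np.zeros((n_rec, len(cgs)))
    W = np.zeros((n_rec, n_anim))
    y = phen["value"].to_numpy(dtype=float)
    for r, (_, rec) in enumerate(phen.iterrows()):
        X[r, cg_pos[str(rec["cg"])]] = 1.0
        W[r, an_pos[rec["animal_id"]]] = 1.0

    lam = sigma_e2 / sigma_u2
    lhs = np.block([[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + lam * H_inv]])
    rhs = np.concatenate([X.T @ y, W.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    u_hat = sol[len(cgs) :][gidx]

    lhs_inv = np.linalg.inv(lhs)
    anim_block = lhs_inv[len(cgs) :, len(cgs) :]
    C = sigma_e2 * anim_block[np.ix_(gidx, gidx)]

    c = (1.0 - beta) * b / k
    effects = c * (Z.T @ (G_inv @ u_hat))
    mid = G_inv @ (G * sigma_u2 - C) @ G_inv
    variances = np.empty(Z.shape[1])
    for i in range(Z.shape[1]):
        zi = Z[:, i]
        variances[i] = c * c * float(zi @ mid @ zi)
    return effects, variances
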