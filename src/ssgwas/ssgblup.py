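"""Single-trait single-step GBLUP mixed-model equations.

Assembles the normal equations of the animal model

    y = X beta + W u + e,   u ~ N(0, H sigma_u^2),  e ~ N(0, I sigma_e^2)

where H^-1 combines the pedigree inverse A^-1 with a genomic adjustment
(T^-1 - A22^-1) over genotyped animals, T^-1 being the exact G^-1 or its
sparse APY counterpart.  Solved either densely or with Jacobi-preconditioned
conjugate gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .relmat import PedigreeTable

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """PCG failed to reach the requested residual within max_iter."""

    def __init__(self, message: str, residuals: list[float] | None = None):
        super().__init__(message)
        self.residuals = residuals or []


@dataclass
class HInverseBlocks:
    """H^-1 = A^-1 + scatter(T^-1 - A22^-1) over genotyped animals."""

    matrix: sp.csr_matrix  # full pedigree-dimension H^-1
    genotyped_index: np.ndarray  # pedigree positions of genotyped animals


@dataclass
class MmeSystem:
    """Sparse mixed-model equations, ordered [CG levels | pedigree animals]."""

    lhs: sp.csr_matrix
    rhs: np.ndarray
    lambda_ratio: float
    cg_levels: list[str]
    animal_ids: list[str]
    mode: str = "exact-G"
    solution: np.ndarray | None = None

    @property
    def n_fixed(self) -> int:
        return len(self.cg_levels)

    @property
    def gebv(self) -> np.ndarray:
        if self.solution is None:
            raise SolverError("system not solved yet")
        return self.solution[self.n_fixed :]

    @property
    def fixed_effects(self) -> np.ndarray:
        if self.solution is None:
            raise SolverError("system not solved yet")
        return self.solution[: self.n_fixed]

    def gebv_for(self, ids: list[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        return self.gebv[[lookup[a] for a in ids]]


def build_H_inverse(
    a_inv: sp.spmatrix,
    A22_inv: np.ndarray,
    T_inv: np.ndarray | sp.spmatrix,
    genotyped_index: np.ndarray,
) -> HInverseBlocks:
    """Scatter the genomic adjustment onto the pedigree-wide A^-1.

    ``genotyped_index`` maps rows of T_inv/A22_inv to pedigree positions.
    """
    n = a_inv.shape[0]
    g = np.asarray(genotyped_index, dtype=np.int64)
    m = len(g)
    if A22_inv.shape != (m, m) or T_inv.shape != (m, m):
        raise ValueError("genomic blocks do not match the genotyped index map")
    adj = (sp.csr_matrix(T_inv) - sp.csr_matrix(A22_inv)).tocoo()
    scat = sp.coo_matrix(
        (adj.data, (g[adj.row], g[adj.col])), shape=(n, n)
    ).tocsr()
    H_inv = (sp.csr_matrix(a_inv) + scat).tocsr()
    return HInverseBlocks(matrix=H_inv, genotyped_index=g)


def assemble_mme(
    phenotypes: pd.DataFrame,
    ped: PedigreeTable,
    h_inv: HInverseBlocks | sp.spmatrix,
    lambda_ratio: float,
    mode: str = "exact-G",
) -> MmeSystem:
    """Normal equations [[X'X, X'W], [W'X, W'W + lambda H^-1]].

    Fixed effects are contemporary-group levels found in the records; empty
    levels cannot arise since levels are taken from the data.  Animals enter
    in pedigree order.
    """
    H = h_inv.matrix if isinstance(h_inv, HInverseBlocks) else sp.csr_matrix(h_inv)
    n_anim = ped.n_animals
    if H.shape != (n_anim, n_anim):
        raise ValueError("H^-1 dimension does not match pedigree")
    recs = phenotypes
    cg_levels = sorted(recs["cg"].astype(str).unique())
    cg_pos = {c: i for i, c in enumerate(cg_levels)}
    nf = len(cg_levels)
    n_rec = len(recs)

    anim_idx = ped.index_of(recs["animal_id"].tolist())
    cg_idx = np.array([cg_pos[str(c)] for c in recs["cg"]], dtype=np.int64)
    y = recs["value"].to_numpy(dtype=np.float64)

    ones = np.ones(n_rec)
    X = sp.coo_matrix((ones, (np.arange(n_rec), cg_idx)), shape=(n_rec, nf)).tocsr()
    W = sp.coo_matrix(
        (ones, (np.arange(n_rec), anim_idx)), shape=(n_rec, n_anim)
    ).tocsr()

    XtX = (X.T @ X).tocsr()
    XtW = (X.T @ W).tocsr()
    WtW = (W.T @ W).tocsr()
    lhs = sp.bmat(
        [[XtX, XtW], [XtW.T, WtW + lambda_ratio * H]], format="csr"
    )
    rhs = np.concatenate([X.T @ y, W.T @ y])
    logger.info(
        "assembled MME: %d CG levels + %d animals, %d records, lambda=%.4f",
        nf, n_anim, n_rec, lambda_ratio,
    )
    return MmeSystem(
        lhs=lhs,
        rhs=rhs,
        lambda_ratio=lambda_ratio,
        cg_levels=cg_levels,
        animal_ids=list(ped.ids),
        mode=mode,
    )


def solve_pcg(
    system: MmeSystem,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> np.ndarray:
    """Jacobi-preconditioned conjugate gradients on the assembled MME.

    Iterates until the relative residual ||lhs x - rhs|| / ||rhs|| drops
    below ``tol``.  Raises SolverError with the residual history on
    non-convergence.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    A = system.lhs
    b = system.rhs
    d = A.diagonal()
    if np.any(d <= 0):
        raise SolverError("nonpositive diagonal in LHS; system not SPD")
    minv = 1.0 / d
    x = np.zeros_like(b)
    r = b - A @ x
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        system.solution = x
        return x
    z = minv * r
    p = z.copy()
    rz = r @ z
    residuals: list[float] = []
    for it in range(1, max_iter + 1):
        Ap = A @ p
        pAp = p @ Ap
        if pAp <= 0:
            raise SolverError(
                f"direction of nonpositive curvature at iter {it}; "
                "LHS is singular or indefinite", residuals,
            )
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        res = np.linalg.norm(r) / bnorm
        residuals.append(res)
        if res <= tol:
            logger.info("PCG converged in %d iterations (rel res %.2e)", it, res)
            system.solution = x
            return x
        z = minv * r
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise SolverError(
        f"PCG did not converge in {max_iter} iterations "
        f"(last rel res {residuals[-1]:.2e})", residuals,
    )


def solve_dense(system: MmeSystem) -> np.ndarray:
    """Direct dense solve; reference path for small systems."""
    x = np.linalg.solve(system.lhs.toarray(), system.rhs)
    system.solution = x
    return x


def ebv_reliability_pedigree(
    phenotypes: pd.DataFrame,
    ped: PedigreeTable,
    a_inv: sp.spmatrix,
    lambda_ratio: float,
    sigma_u2: float,
    sigma_e2: float,
) -> dict[str, float]:
    """Pedigree-only EBV reliabilities, r^2_i = 1 - PEV_i / sigma_u2.

    Assembles the MME with H^-1 = A^-1 (no genomic information), inverts the
    left-hand side densely, and reads prediction error variances off the
    animal-block diagonal.  Desk-scale only.
    """
    system = assemble_mme(phenotypes, ped, a_inv, lambda_ratio, mode="pedigree")
    inv = np.linalg.inv(system.lhs.toarray())
    nf = system.n_fixed
    pev = sigma_e2 * np.diag(inv)[nf:]
    rel = np.clip(1.0 - pev / sigma_u2, 0.0, 1.0)
    return dict(zip(ped.ids, rel))
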