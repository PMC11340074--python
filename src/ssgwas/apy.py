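"""APY sparse inverse of the genomic relationship matrix.

The algorithm for proven and young (APY) splits genotyped animals into a
core set, whose genomic relationships are inverted directly, and a noncore
set whose breeding values are treated as recursions on the core.  The
resulting inverse keeps the noncore-noncore block strictly diagonal:

    G_APY^-1 = [[Gcc^-1 + Gcc^-1 Gcn Mnn^-1 Gnc Gcc^-1,  -Gcc^-1 Gcn Mnn^-1],
                [-Mnn^-1 Gnc Gcc^-1,                       Mnn^-1          ]]

with m_nn,j = g_jj - g_jc' Gcc^-1 g_cj, the variance of noncore animal j's
breeding value conditional on the core.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .relmat import BlendedG, GenotypeMatrix


class ConditioningError(ValueError):
    """A conditional variance collapsed; the core does not span the animal."""


class ApyPartition:
    """Core/noncore split with the stored blocks of G_APY^-1.

    Blocks follow core-first ordering.  ``Gcc_inv`` and ``Gcn`` are dense;
    ``mnn`` holds the noncore conditional variances, so the noncore-noncore
    block of the inverse is diag(1/mnn).
    """

    def __init__(
        self,
        core_ids: list[str],
        noncore_ids: list[str],
        Gcc: np.ndarray | None = None,
        Gcc_inv: np.ndarray | None = None,
        Gcn: np.ndarray | None = None,
        mnn: np.ndarray | None = None,
    ) -> None:
        if set(core_ids) & set(noncore_ids):
            raise ValueError("core and noncore sets overlap")
        self.core_ids = list(core_ids)
        self.noncore_ids = list(noncore_ids)
        self.Gcc = Gcc
        self.Gcc_inv = Gcc_inv
        self.Gcn = Gcn
        self.mnn = mnn

    @property
    def n_core(self) -> int:
        return len(self.core_ids)

    @property
    def n_noncore(self) -> int:
        return len(self.noncore_ids)

    @property
    def ordered_ids(self) -> list[str]:
        return self.core_ids + self.noncore_ids

    # --- blocks of the assembled inverse (Gcc_inv etc. must be built) ---

    def upper_left(self) -> np.ndarray:
        """G^cc = Gcc^-1 + Gcc^-1 Gcn Mnn^-1 Gnc Gcc^-1."""
        if self.n_noncore == 0:
            return self.Gcc_inv
        B = self.Gcc_inv @ self.Gcn  # core x noncore
        return self.Gcc_inv + (B / self.mnn) @ B.T

    def upper_right(self) -> np.ndarray:
        """G^cn = -Gcc^-1 Gcn Mnn^-1."""
        return -(self.Gcc_inv @ self.Gcn) / self.mnn

    def assemble(self) -> sp.csr_matrix:
        """Full sparse G_APY^-1 in core-first order."""
        nc, nn = self.n_core, self.n_noncore
        if nn == 0:
            return sp.csr_matrix(self.Gcc_inv)
        ur = self.upper_right()
        top = sp.hstack([sp.csr_matrix(self.upper_left()), sp.csr_matrix(ur)])
        bot = sp.hstack([sp.csr_matrix(ur.T), sp.diags(1.0 / self.mnn)])
        out = sp.vstack([top, bot]).tocsr()
        return out

    def assemble_ordered(self, animal_ids: list[str]) -> np.ndarray:
        """Dense G_APY^-1 with rows/columns in the given animal order
        (e.g. the genotype-file order expected by the mixed-model builder)."""
        order = {a: i for i, a in enumerate(animal_ids)}
        perm = np.array([order[a] for a in self.ordered_ids])
        M = self.assemble().toarray()
        out = np.empty_like(M)
        out[np.ix_(perm, perm)] = M
        return out

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """G_APY^-1 @ v without assembling the full matrix."""
        nc = self.n_core
        vc, vn = v[:nc], v[nc:]
        if self.n_noncore == 0:
            return self.Gcc_inv @ vc
        w = (self.Gcn @ (vn / self.mnn)) if self.n_noncore else 0.0
        t = self.Gcc_inv @ (self.Gcn @ ((self.Gcn.T @ (self.Gcc_inv @ vc)) / self.mnn))
        out_c = self.Gcc_inv @ vc + t - self.Gcc_inv @ w
        out_n = vn / self.mnn - (self.Gcn.T @ (self.Gcc_inv @ vc)) / self.mnn
        return np.concatenate([out_c, out_n])


def core_size_from_eigenvalues(geno: GenotypeMatrix, var_fraction: float = 0.98) -> int:
    """Number of principal dimensions explaining a fraction of genomic variance.

    Smallest r such that the top-r squared singular values of the centered
    genotype matrix Z account for at least ``var_fraction`` of their total.
    """
    if not 0.0 < var_fraction < 1.0:
        raise ValueError("var_fraction must be in (0, 1)")
    Z = geno.Z
    if Z.size == 0:
        raise ValueError("empty genotype matrix")
    sv = np.linalg.svd(Z, compute_uv=False)
    ev = sv**2
    total = ev.sum()
    if total == 0.0:
        raise ValueError("genotype matrix has no variation")
    cum = np.cumsum(ev) / total
    return int(np.searchsorted(cum, var_fraction) + 1)


def select_core_random(
    genotyped_ids: list[str], n_core: int, seed: int = 0
) -> ApyPartition:
    """Uniform random core of size ``n_core`` (skeleton, no blocks yet)."""
    n = len(genotyped_ids)
    if not 0 < n_core <= n:
        raise ValueError(f"n_core must be in (0, {n}], got {n_core}")
    rng = np.random.default_rng(seed)
    core_pos = np.sort(rng.choice(n, size=n_core, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[core_pos] = True
    core = [genotyped_ids[i] for i in range(n) if mask[i]]
    noncore = [genotyped_ids[i] for i in range(n) if not mask[i]]
    return ApyPartition(core, noncore)


def select_core_high_accuracy(
    genotyped_ids: list[str], accuracies: dict[str, float], n_core: int
) -> ApyPartition:
    """Core = genotyped animals with the highest pedigree-EBV reliabilities.

    Ties break by the stable order of ``genotyped_ids``.
    """
    n = len(genotyped_ids)
    if not 0 < n_core <= n:
        raise ValueError(f"n_core must be in (0, {n}], got {n_core}")
    missing = [a for a in genotyped_ids if a not in accuracies]
    if missing:
        raise KeyError(f"no accuracy for animals {missing[:5]}")
    acc = np.array([accuracies[a] for a in genotyped_ids])
    order = np.argsort(-acc, kind="stable")
    core_pos = np.sort(order[:n_core])
    mask = np.zeros(n, dtype=bool)
    mask[core_pos] = True
    core = [genotyped_ids[i] for i in range(n) if mask[i]]
    noncore = [genotyped_ids[i] for i in range(n) if not mask[i]]
    return ApyPartition(core, noncore)


def build_gapy_inverse(
    G: BlendedG, partition: ApyPartition, genotyped_ids: list[str],
    mnn_floor_factor: float = 1e-8,
) -> ApyPartition:
    """Fill an ApyPartition skeleton with the blocks of G_APY^-1.

    Conditional variances m_nn are computed one noncore animal at a time
    against a shared Cholesky factor of the core block; the dense noncore
    block of G is never formed as a whole.
    """
    lookup = {a: i for i, a in enumerate(genotyped_ids)}
    cidx = np.array([lookup[a] for a in partition.core_ids], dtype=np.int64)
    nidx = np.array([lookup[a] for a in partition.noncore_ids], dtype=np.int64)
    Gm = G.matrix
    Gcc = Gm[np.ix_(cidx, cidx)]
    c, low = cho_factor(Gcc, lower=True)
    Gcc_inv = cho_solve((c, low), np.eye(len(cidx)))
    Gcc_inv = 0.5 * (Gcc_inv + Gcc_inv.T)
    if len(nidx):
        Gcn = Gm[np.ix_(cidx, nidx)]
        # m_j = g_jj - g_jc' Gcc^-1 g_cj via triangular solves on the shared factor
        gjj = np.diag(Gm)[nidx]
        from scipy.linalg import solve_triangular

        V = solve_triangular(c, Gcn, lower=low)
        mnn = gjj - np.einsum("ij,ij->j", V, V)
        floor = mnn_floor_factor * float(np.mean(np.diag(Gm)))
        bad = mnn <= floor
        if bad.any():
            j = int(np.nonzero(bad)[0][0])
            raise ConditioningError(
                f"conditional variance {mnn[j]:.3e} for noncore animal "
                f"{partition.noncore_ids[j]!r} is at or below the floor {floor:.3e}"
            )
    else:
        Gcn = np.zeros((len(cidx), 0))
        mnn = np.zeros(0)
    return ApyPartition(
        core_ids=partition.core_ids,
        noncore_ids=partition.noncore_ids,
        Gcc=Gcc,
        Gcc_inv=Gcc_inv,
        Gcn=Gcn,
        mnn=mnn,
    )


def write_partition(path, partition: ApyPartition) -> None:
    """Serialize the core/noncore split as two whitespace-separated columns."""
    with open(path, "w") as fh:
        for a in partition.core_ids:
            fh.write(f"{a} CORE\n")
        for a in partition.noncore_ids:
            fh.write(f"{a} NONCORE\n")


def read_partition(path) -> ApyPartition:
    core: list[str] = []
    noncore: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2 or parts[1] not in ("CORE", "NONCORE"):
                raise ValueError(f"{path}:{lineno}: expected 'id CORE|NONCORE'")
            (core if parts[1] == "CORE" else noncore).append(parts[0])
    return ApyPartition(core, noncore)
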