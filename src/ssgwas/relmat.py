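"""Pedigree and genomic relationship machinery.

Builds the numerator relationship matrix A (tabular method), its sparse
inverse via Henderson's rules with inbreeding, the genotyped-animal
submatrix A22, and the blended/tuned genomic relationship matrix G from
centered allele counts (VanRaden type I).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

UNKNOWN = -1  # internal index for an unknown parent


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown id, bad order)."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. all markers monomorphic)."""


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree with inbreeding coefficients.

    ``sire_idx``/``dam_idx`` hold positional indices into ``ids`` or
    ``UNKNOWN`` (-1).  Parents always precede offspring.
    """

    ids: list[str]
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    inbreeding: np.ndarray | None = None
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sire_idx = np.asarray(self.sire_idx, dtype=np.int64)
        self.dam_idx = np.asarray(self.dam_idx, dtype=np.int64)
        n = len(self.ids)
        if self.sire_idx.shape != (n,) or self.dam_idx.shape != (n,):
            raise PedigreeError("parent index arrays must match number of ids")
        for name, par in (("sire", self.sire_idx), ("dam", self.dam_idx)):
            bad = (par >= np.arange(n)) & (par != UNKNOWN)
            if bad.any():
                raise PedigreeError(
                    f"{name} index not earlier in order for animal "
                    f"{self.ids[int(np.nonzero(bad)[0][0])]}"
                )

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from exc


@dataclass
class GenotypeMatrix:
    """Allele-count matrix (animals x markers) with frequencies and Z.

    ``counts`` holds 0/1/2 copies of the counted allele; missing values
    must be imputed before construction.  ``allele_freq`` is the frequency
    of the counted allele per marker; by default it is computed from
    ``counts`` itself.
    """

    animal_ids: list[str]
    marker_ids: list[str]
    counts: np.ndarray
    allele_freq: np.ndarray = field(default=None)  # type: ignore[assignment]
    chromosome: np.ndarray | None = None
    position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError("counts shape does not match id lists")
        if self.allele_freq is None:
            self.allele_freq = self.counts.mean(axis=0) / 2.0
        self.allele_freq = np.asarray(self.allele_freq, dtype=np.float64)

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    @property
    def scale_k(self) -> float:
        """2 * sum_i p_i (1 - p_i), the polygenic-to-marker variance scale."""
        p = self.allele_freq
        return float(2.0 * np.sum(p * (1.0 - p)))

    @property
    def Z(self) -> np.ndarray:
        """Allele counts centered by twice the allele frequency."""
        return self.counts - 2.0 * self.allele_freq

    def drop_monomorphic(self, min_maf: float = 0.0) -> "GenotypeMatrix":
        """Remove monomorphic markers and, with ``min_maf`` > 0, markers
        below the minor-allele-frequency threshold (panel quality control)."""
        p = self.allele_freq
        maf = np.minimum(p, 1.0 - p)
        keep = (maf > 0.0) & (maf >= min_maf)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning(
                "dropping %d markers (monomorphic or MAF < %g)", n_drop, min_maf
            )
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            marker_ids=[m for m, k in zip(self.marker_ids, keep) if k],
            counts=self.counts[:, keep],
            allele_freq=None,
            chromosome=None if self.chromosome is None else self.chromosome[keep],
            position=None if self.position is None else self.position[keep],
        )

    def subset_animals(self, animal_ids, recompute_freq: bool = False) -> "GenotypeMatrix":
        """Restrict to a subset of animals, keeping the parent frequencies
        unless ``recompute_freq``; centering must stay consistent with the
        matrix G was built from."""
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([lookup[a] for a in animal_ids], dtype=np.int64)
        return GenotypeMatrix(
            animal_ids=list(animal_ids),
            marker_ids=self.marker_ids,
            counts=self.counts[idx],
            allele_freq=None if recompute_freq else self.allele_freq.copy(),
            chromosome=self.chromosome,
            position=self.position,
        )


@dataclass
class BlendedG:
    """Blended and tuned genomic relationship matrix.

    G = (1-beta) * (alpha * 11' + b * G_raw) + beta * A22.
    """

    matrix: np.ndarray
    beta: float
    b_tune: float
    alpha_tune: float
    _inverse: np.ndarray | None = None
    _chol: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def inverse(self) -> np.ndarray:
        if self._inverse is None:
            c = self.cholesky
            eye = np.eye(self.n)
            from scipy.linalg import cho_solve

            self._inverse = cho_solve((c, True), eye)
            self._inverse = 0.5 * (self._inverse + self._inverse.T)
        return self._inverse

    @property
    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            from scipy.linalg import cholesky

            self._chol = cholesky(self.matrix, lower=True)
        return self._chol

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        from scipy.linalg import cho_solve

        return cho_solve((self.cholesky, True), rhs)


# ---------------------------------------------------------------------------
# Pedigree relationship machinery


def build_A(ped: PedigreeTable) -> np.ndarray:
    """Numerator relationship matrix by the tabular method (dense).

    Suitable at desk scale; O(n^2) memory.
    """
    n = ped.n_animals
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if si != UNKNOWN and di != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        # relationship with all earlier animals
        row = np.zeros(i)
        if si != UNKNOWN:
            row += 0.5 * A[si, :i]
        if di != UNKNOWN:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients F_i = 0.5 * A(sire_i, dam_i).

    Uses the tabular A; founders and animals with an unknown parent get 0.
    """
    A = build_A(ped)
    return np.diag(A) - 1.0


def build_A_inverse(ped: PedigreeTable) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules, accounting for inbreeding.

    Each animal contributes at most nine entries.  The Mendelian sampling
    variance uses parental inbreeding:
      both parents known:  m = 0.5 - 0.25 (F_s + F_d)
      one parent known:    m = 0.75 - 0.25 F_p
      no parents known:    m = 1
    """
    if ped.inbreeding is None:
        ped.inbreeding = compute_inbreeding(ped)
    F = ped.inbreeding
    n = ped.n_animals
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        si, di = int(ped.sire_idx[i]), int(ped.dam_idx[i])
        if si != UNKNOWN and di != UNKNOWN:
            m = 0.5 - 0.25 * (F[si] + F[di])
        elif si != UNKNOWN or di != UNKNOWN:
            p = si if si != UNKNOWN else di
            m = 0.75 - 0.25 * F[p]
        else:
            m = 1.0
        b = 1.0 / m
        add(i, i, b)
        for p in (si, di):
            if p != UNKNOWN:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        known = [p for p in (si, di) if p != UNKNOWN]
        for p in known:
            for q in known:
                add(p, q, 0.25 * b)
    Ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Ainv.sum_duplicates()
    return Ainv


def build_A22(ped: PedigreeTable, genotyped_ids) -> np.ndarray:
    """Pedigree relationships among genotyped animals (dense submatrix)."""
    if len(genotyped_ids) == 0:
        raise ValueError("genotyped set is empty")
    idx = ped.index_of(genotyped_ids)
    A = build_A(ped)
    return A[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Genomic relationship machinery


def build_G_raw(geno: GenotypeMatrix) -> np.ndarray:
    """Raw VanRaden type-I genomic relationship matrix ZZ' / 2*sum p(1-p)."""
    k = geno.scale_k
    if k <= 0.0:
        raise DegenerateInputError("all markers monomorphic; G is undefined")
    Z = geno.Z
    G = Z @ Z.T / k
    return 0.5 * (G + G.T)


def tune_and_blend_G(
    G_raw: np.ndarray, A22: np.ndarray, beta: float = 0.05
) -> BlendedG:
    """Tune G_raw to A22 (two-moment matching) and blend with A22.

    Solves  b * mean(diag G_raw) + alpha = mean(diag A22)
            b * mean(offdiag G_raw) + alpha = mean(offdiag A22)
    then forms G = (1-beta)(alpha 11' + b G_raw) + beta A22.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must be in [0, 1), got {beta}")
    if G_raw.shape != A22.shape:
        raise ValueError("G_raw and A22 are not conformable")
    n = G_raw.shape[0]
    dg, da = float(np.mean(np.diag(G_raw))), float(np.mean(np.diag(A22)))
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        og, oa = float(G_raw[off].mean()), float(A22[off].mean())
    else:
        og, oa = 0.0, 0.0
    # 2x2 system [[dg, 1], [og, 1]] @ [b, alpha] = [da, oa]
    det = dg - og
    if abs(det) < 1e-12:
        raise ValueError("tuning system singular: G_raw has no diag/offdiag contrast")
    b = (da - oa) / det
    alpha = da - b * dg
    G = (1.0 - beta) * (alpha + b * G_raw) + beta * A22
    G = 0.5 * (G + G.T)
    logger.info("tuned G: b=%.6f alpha=%.6f beta=%.3f", b, alpha, beta)
    return BlendedG(matrix=G, beta=beta, b_tune=b, alpha_tune=alpha)
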