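"""Prediction-error (co)variance of GEBVs, exact and approximated.

Three routes to the GEBV prediction-error covariance used for SNP-effect
sampling variances:

* exact over all genotyped animals, by dense inversion of the mixed-model
  left-hand side;
* exact over the APY core set (the same inverse, sliced to core);
* approximated over the core set without touching the LHS inverse, using
  the APY inverse blocks plus a diagonal of fixed-effect-absorbed phenotype
  contributions

      C_approx = (D_c + lam G^cc - lam G^cn (lam Mnn^-1 + D_n)^-1 lam G^nc)^-1

  scaled by sigma_e^2 so its units match the exact routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apy import ApyPartition, ConditioningError
from .ssgblup import MmeSystem


@dataclass
class PevMatrix:
    """Dense symmetric PEV (co)variance over a stated animal set."""

    matrix: np.ndarray
    animal_set: list[str]
    method: str  # exact-full | exact-core | approx-core

    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


@dataclass
class AbsorptionDiagonal:
    """Per-animal phenotype contributions after absorbing fixed effects.

    d_i is the i-th diagonal of W'(I - X(X'X)^-1 X')W; for a single
    contemporary-group classification an animal with one record in a group
    of size s contributes 1 - 1/s.
    """

    d: np.ndarray  # aligned with ``animal_ids``
    animal_ids: list[str]

    def split(self, partition: ApyPartition) -> tuple[np.ndarray, np.ndarray]:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        dc = np.array([self.d[lookup[a]] for a in partition.core_ids])
        dn = np.array([self.d[lookup[a]] for a in partition.noncore_ids])
        return dc, dn


def pev_exact_from_lhs(
    system: MmeSystem, sigma_e2: float, animal_subset: list[str],
    lhs_inverse: np.ndarray | None = None,
) -> PevMatrix:
    """PEV = sigma_e^2 * (animal block of LHS^-1), sliced to a subset.

    Dense inversion of the full left-hand side; desk-scale reference route.
    A precomputed ``lhs_inverse`` may be passed to amortize the inversion
    across calls.
    """
    if lhs_inverse is None:
        lhs_inverse = np.linalg.inv(system.lhs.toarray())
    nf = system.n_fixed
    lookup = {a: i for i, a in enumerate(system.animal_ids)}
    try:
        idx = np.array([nf + lookup[a] for a in animal_subset], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"animal {exc.args[0]!r} not in the MME") from exc
    C = sigma_e2 * lhs_inverse[np.ix_(idx, idx)]
    return PevMatrix(matrix=0.5 * (C + C.T), animal_set=list(animal_subset),
                     method="exact-full")


def compute_absorption_diagonal(
    phenotypes: pd.DataFrame, animal_ids: list[str]
) -> AbsorptionDiagonal:
    """Diagonal of W'(I - X(X'X)^-1 X')W for the CG fixed-effect design.

    With a one-hot contemporary-group design X, X'X is diagonal with the
    group sizes, so d_i = n_i - sum_g c_gi^2 / n_g where c_gi counts records
    of animal i in group g.  Animals without records get 0.
    """
    d = np.zeros(len(animal_ids))
    pos = {a: i for i, a in enumerate(animal_ids)}
    recs = phenotypes
    group_sizes = recs.groupby("cg")["animal_id"].size()
    cell = recs.groupby(["cg", "animal_id"]).size()
    for (g, a), c in cell.items():
        if a in pos:
            d[pos[a]] += c - c * c / group_sizes[g]
        # records of animals outside the stated set contribute nothing here
    return AbsorptionDiagonal(d=d, animal_ids=list(animal_ids))


def pev_core_approx(
    partition: ApyPartition,
    absorption: AbsorptionDiagonal,
    lambda_ratio: float,
    sigma_e2: float,
) -> PevMatrix:
    """Approximated core PEV from the APY inverse blocks and the absorption
    diagonal; the noncore inner inverse stays diagonal (cost linear in the
    noncore count)."""
    dc, dn = absorption.split(partition)
    lam = lambda_ratio
    Gcc_up = partition.upper_left()  # G^cc
    M = np.diag(dc) + lam * Gcc_up
    if partition.n_noncore:
        inner = lam / partition.mnn + dn
        if np.any(inner <= 0):
            j = int(np.argmin(inner))
            raise ConditioningError(
                f"nonpositive inner diagonal for noncore animal "
                f"{partition.noncore_ids[j]!r}"
            )
        Gcn_up = partition.upper_right()  # G^cn
        M -= (lam * Gcn_up) * (1.0 / inner) @ (lam * Gcn_up.T)
    C = sigma_e2 * np.linalg.inv(M)
    return PevMatrix(matrix=0.5 * (C + C.T), animal_set=list(partition.core_ids),
                     method="approx-core")


def write_pev(path, pev: PevMatrix) -> None:
    """Whitespace-delimited (row_id, col_id, value) triplets."""
    ids = pev.animal_set
    with open(path, "w") as fh:
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if j < i:
                    continue
                fh.write(f"{a} {b} {pev.matrix[i, j]:.18g}\n")
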