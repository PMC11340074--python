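"""Text readers and writers for pedigree, genotype, map, and phenotype files.

Formats (whitespace-separated, one record per line):

* pedigree:  ``animal sire dam`` with 0 for an unknown parent;
* genotypes: ``animal_id genotype_string`` where each character is the
  allele count 0/1/2 and 5 marks a missing call (imputed to twice the
  observed allele frequency);
* map:       ``marker chromosome position``;
* phenotype: ``animal_id cg_id value``;
* config:    YAML ``key: value`` pairs (see RunConfig).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .relmat import UNKNOWN, GenotypeMatrix, PedigreeTable

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed or inconsistent input data; message names the line."""


VALID_METHODS = ("exact_ginv", "exact_ginv_apy", "approx_ginv_apy")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    pedigree: str
    genotypes: str
    snp_map: str
    phenotypes: str
    sigma_u2: float
    sigma_e2: float
    beta_blend: float = 0.05
    method: str = "exact_ginv"
    # core selection, required for the APY methods: exactly one of
    core_random: int | None = None
    core_high_accuracy: int | None = None
    core_file: str | None = None
    core_var_fraction: float | None = None
    min_maf: float = 0.05
    seed: int = 0
    solver_tol: float = 1e-12
    solver_max_iter: int = 5000
    alpha: float = 0.05
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(f"method must be one of {VALID_METHODS}")
        if self.sigma_u2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")
        specs = [
            s for s in (self.core_random, self.core_high_accuracy,
                        self.core_file, self.core_var_fraction)
            if s is not None
        ]
        if self.method != "exact_ginv" and len(specs) != 1:
            raise ValueError("APY methods need exactly one core specification")

    @property
    def lambda_ratio(self) -> float:
        return self.sigma_e2 / self.sigma_u2


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def write_config(path, config: RunConfig) -> None:
    payload = {k: getattr(config, k) for k in RunConfig.__dataclass_fields__}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Pedigree


def read_pedigree(path) -> PedigreeTable:
    """Read and topologically sort an animal/sire/dam file."""
    triples: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 'animal sire dam'")
            triples.append((parts[0], parts[1], parts[2]))
    ids = [t[0] for t in triples]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts().idxmax()
        raise DataError(f"{path}: duplicate animal id {dup!r}")
    parents = {t[0]: (t[1], t[2]) for t in triples}
    # parents that never get their own line become founders
    all_ids = list(ids)
    seen = set(ids)
    for s, d in parents.values():
        for p in (s, d):
            if p != "0" and p not in seen:
                all_ids.append(p)
                seen.add(p)
                parents[p] = ("0", "0")

    # Kahn-style topological sort, stable in file order
    order: list[str] = []
    placed: set[str] = set()
    remaining = list(all_ids)
    while remaining:
        progress = []
        for a in remaining:
            s, d = parents[a]
            if (s == "0" or s in placed) and (d == "0" or d in placed):
                order.append(a)
                placed.add(a)
            else:
                progress.append(a)
        if len(progress) == len(remaining):
            raise DataError(f"{path}: pedigree contains a cycle near {progress[0]!r}")
        remaining = progress

    pos = {a: i for i, a in enumerate(order)}
    sire = np.array(
        [UNKNOWN if parents[a][0] == "0" else pos[parents[a][0]] for a in order]
    )
    dam = np.array(
        [UNKNOWN if parents[a][1] == "0" else pos[parents[a][1]] for a in order]
    )
    return PedigreeTable(ids=order, sire_idx=sire, dam_idx=dam)


def write_pedigree(path, ped: PedigreeTable) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(ped.ids):
            s = "0" if ped.sire_idx[i] == UNKNOWN else ped.ids[ped.sire_idx[i]]
            d = "0" if ped.dam_idx[i] == UNKNOWN else ped.ids[ped.dam_idx[i]]
            fh.write(f"{a} {s} {d}\n")


# ---------------------------------------------------------------------------
# Genotypes and map


def read_snp_map(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 'marker chrom position'")
            rows.append((parts[0], parts[1], int(parts[2])))
    return pd.DataFrame(rows, columns=["marker", "chromosome", "position"])


def write_snp_map(path, snp_map: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for _, r in snp_map.iterrows():
            fh.write(f"{r['marker']} {r['chromosome']} {r['position']}\n")


def read_genotypes(path, snp_map: pd.DataFrame) -> GenotypeMatrix:
    """Read ``animal_id genotype_string`` lines against a marker map.

    Missing calls (character 5) are imputed to twice the allele frequency of
    the observed calls, i.e. they contribute 0 in the centered matrix Z.
    """
    n_markers = len(snp_map)
    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 'animal genotypes'")
            aid, gstr = parts
            if len(gstr) != n_markers:
                raise DataError(
                    f"{path}:{lineno}: genotype string of length {len(gstr)} "
                    f"does not match the {n_markers}-marker map"
                )
            codes = np.frombuffer(gstr.encode(), dtype=np.uint8) - ord("0")
            if not np.isin(codes, (0, 1, 2, 5)).all():
                raise DataError(f"{path}:{lineno}: genotype codes must be 0/1/2/5")
            animal_ids.append(aid)
            rows.append(codes.astype(np.float64))
    if not rows:
        raise DataError(f"{path}: no genotype records")
    counts = np.vstack(rows)
    missing = counts == 5.0
    if missing.any():
        counts[missing] = np.nan
        p = np.nanmean(counts, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.5, p)
        fill = np.broadcast_to(2.0 * p, counts.shape)
        counts = np.where(np.isnan(counts), fill, counts)
        logger.info("imputed %d missing genotype calls to 2p", int(missing.sum()))
    return GenotypeMatrix(
        animal_ids=animal_ids,
        marker_ids=snp_map["marker"].tolist(),
        counts=counts,
        chromosome=snp_map["chromosome"].to_numpy(),
        position=snp_map["position"].to_numpy(),
    )


def write_genotypes(path, geno: GenotypeMatrix) -> None:
    counts = np.rint(geno.counts).astype(int)
    with open(path, "w") as fh:
        for i, a in enumerate(geno.animal_ids):
            fh.write(f"{a} {''.join(map(str, counts[i]))}\n")


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 'animal cg value'")
            try:
                val = float(parts[2])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad trait value") from exc
            rows.append((parts[0], parts[1], val))
    if not rows:
        raise DataError(f"{path}: no phenotype records")
    return pd.DataFrame(rows, columns=["animal_id", "cg", "value"])


def write_phenotypes(path, phen: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for _, r in phen.iterrows():
            fh.write(f"{r['animal_id']} {r['cg']} {r['value']:.18g}\n")


# ---------------------------------------------------------------------------
# Cross-referenced loading and matrix persistence


def read_inputs(config: RunConfig) -> tuple[PedigreeTable, GenotypeMatrix, pd.DataFrame]:
    """Load and cross-validate the four input files of a run."""
    ped = read_pedigree(config.pedigree)
    snp_map = read_snp_map(config.snp_map)
    geno = read_genotypes(config.genotypes, snp_map)
    phen = read_phenotypes(config.phenotypes)
    known = set(ped.ids)
    for aid in geno.animal_ids:
        if aid not in known:
            raise DataError(f"genotyped animal {aid!r} missing from the pedigree")
    for aid in phen["animal_id"]:
        if aid not in known:
            raise DataError(f"phenotyped animal {aid!r} missing from the pedigree")
    logger.info(
        "loaded %d pedigree animals, %d genotyped, %d markers, %d records",
        ped.n_animals, geno.n_animals, geno.n_markers, len(phen),
    )
    return ped, geno, phen


def write_matrix_triplets(path, matrix, row_ids=None, col_ids=None) -> None:
    """Persist a (sparse or dense) matrix as ``row col value`` text triplets
    with 18 significant digits, so cross-run comparisons are bit-stable."""
    import scipy.sparse as sp

    M = sp.coo_matrix(matrix)
    with open(path, "w") as fh:
        for r, c, v in zip(M.row, M.col, M.data):
            rid = row_ids[r] if row_ids is not None else r
            cid = col_ids[c] if col_ids is not None else c
            fh.write(f"{rid} {cid} {v:.18g}\n")


def read_matrix_triplets(path, row_ids, col_ids) -> "np.ndarray":
    rpos = {a: i for i, a in enumerate(row_ids)}
    cpos = {a: i for i, a in enumerate(col_ids)}
    M = np.zeros((len(row_ids), len(col_ids)))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise DataError(f"{path}:{lineno}: expected 'row col value'")
            M[rpos[parts[0]], cpos[parts[1]]] = float(parts[2])
    return M
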