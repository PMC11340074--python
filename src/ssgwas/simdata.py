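"""Synthetic livestock populations for end-to-end testing.

Generates a multi-generation pedigree with overlapping generations,
biallelic SNP genotypes propagated by Mendelian gene-dropping, and a
single-trait phenotype

    y = contemporary-group effect + genomic breeding value + residual,

with breeding values defined through marker effects (u = Z a_true) so that
backsolved SNP effects have a known truth.  Partial genotyping and partial
phenotyping emulate populations where many phenotyped animals are
ungenotyped and many genotyped animals carry no record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import UNKNOWN, GenotypeMatrix, PedigreeTable


@dataclass
class LitterParams:
    """Mating design per generation."""

    n_matings: int = 50
    offspring_per_mating: int = 2
    # parents are drawn from all earlier generations (overlapping generations)


@dataclass
class TraitArchitecture:
    """A few large-effect QTN on a polygenic background.

    Every marker carries a small effect drawn from the polygenic prior
    N(0, sigma_u2 / k) with k = 2 sum p(1-p) — the distribution the
    mixed-model test assumes — and ``n_qtn`` randomly chosen markers get an
    extra large effect with standard deviation ``qtn_effect_sd`` (trait
    units).  With ``n_qtn = 0`` the trait is purely polygenic, i.e. null at
    every individual marker.

    sigma_u2 and sigma_e2 are the additive-genetic and residual variances of
    the simulated trait; h2 = sigma_u2 / (sigma_u2 + sigma_e2) must hold.
    """

    n_qtn: int
    qtn_effect_sd: float
    sigma_u2: float
    sigma_e2: float
    n_cg: int = 5
    cg_effect_sd: float = 1.0
    polygenic_background: bool = True
    # QTN are placed on markers at or above this realized MAF, so that the
    # planted peaks are segregating and recoverable by association
    qtn_min_maf: float = 0.10

    @property
    def h2(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else 0.0

    @classmethod
    def from_h2(
        cls,
        h2: float,
        n_qtn: int = 10,
        qtn_effect_sd: float = 0.5,
        total_var: float = 1.0,
        n_cg: int = 5,
        cg_effect_sd: float = 1.0,
    ) -> "TraitArchitecture":
        if not 0.0 <= h2 < 1.0:
            raise ValueError(f"h2 must be in [0, 1), got {h2}")
        return cls(
            n_qtn=n_qtn,
            qtn_effect_sd=qtn_effect_sd,
            sigma_u2=h2 * total_var,
            sigma_e2=(1.0 - h2) * total_var,
            n_cg=n_cg,
            cg_effect_sd=cg_effect_sd,
        )

    def validate(self, n_markers: int) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be positive")
        if self.n_qtn > n_markers:
            raise ValueError("more QTN than markers")
        expected = self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)
        if abs(self.h2 - expected) > 1e-12:
            raise ValueError("h2 inconsistent with variance components")


@dataclass
class SimulatedPopulation:
    """A pedigree, observed genotypes, phenotypes, and the simulation truth."""

    pedigree: PedigreeTable
    genotypes: GenotypeMatrix  # genotyped animals only
    true_breeding_values: np.ndarray  # all pedigree animals
    true_snp_effects: np.ndarray  # per marker (0 for non-QTN)
    qtn_indices: np.ndarray
    phenotypes: pd.DataFrame  # columns: animal_id, cg, value
    genotyped_ids: list[str]
    all_counts: np.ndarray = field(repr=False, default=None)  # full gene-drop matrix


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    litter_params: LitterParams | None = None,
    seed: int = 0,
) -> PedigreeTable:
    """Random-mating pedigree with overlapping generations.

    Founders have unknown parents (coded internally as -1, written as 0).
    Each subsequent generation mates sires and dams sampled from all earlier
    generations, so parents always precede offspring.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    lp = litter_params or LitterParams()
    rng = np.random.default_rng(seed)

    sires: list[int] = [UNKNOWN] * n_founders
    dams: list[int] = [UNKNOWN] * n_founders
    gen: list[int] = [0] * n_founders
    sex = list(rng.integers(0, 2, size=n_founders))  # 0 = male, 1 = female
    # guarantee both sexes among founders
    if sum(sex) == 0:
        sex[-1] = 1
    elif sum(sex) == len(sex):
        sex[-1] = 0

    for g in range(1, n_generations + 1):
        males = [i for i, s in enumerate(sex) if s == 0]
        females = [i for i, s in enumerate(sex) if s == 1]
        for _ in range(lp.n_matings):
            si = int(rng.choice(males))
            di = int(rng.choice(females))
            for _ in range(lp.offspring_per_mating):
                sires.append(si)
                dams.append(di)
                gen.append(g)
                sex.append(int(rng.integers(0, 2)))

    ids = [f"A{i + 1}" for i in range(len(sires))]
    return PedigreeTable(
        ids=ids,
        sire_idx=np.array(sires),
        dam_idx=np.array(dams),
        generation=np.array(gen),
    )


def _gamete(counts_row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per marker from a parent's genotype (Mendelian sampling)."""
    g = np.where(counts_row == 0, 0, np.where(counts_row == 2, 1, -1))
    het = g == -1
    if het.any():
        g = g.copy()
        g[het] = rng.integers(0, 2, size=int(het.sum()))
    return g.astype(np.int8)


def simulate_genotypes(
    ped: PedigreeTable,
    n_markers: int,
    founder_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> np.ndarray:
    """Gene-drop genotypes for every pedigree animal.

    Founders are drawn from Hardy-Weinberg proportions at frequencies
    sampled uniformly in ``founder_maf_range``; descendants inherit one
    Mendelian gamete from each parent.  A missing parent contributes a
    gamete drawn from the founder frequency.  Markers are independent.

    Returns the full (n_animals x n_markers) allele-count matrix.
    """
    lo, hi = founder_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("founder_maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n = ped.n_animals
    p = rng.uniform(lo, hi, size=n_markers)
    counts = np.zeros((n, n_markers), dtype=np.int8)
    for i in range(n):
        si, di = int(ped.sire_idx[i]), int(ped.dam_idx[i])
        gametes = []
        for par in (si, di):
            if par == UNKNOWN:
                gametes.append((rng.random(n_markers) < p).astype(np.int8))
            else:
                gametes.append(_gamete(counts[par], rng))
        counts[i] = gametes[0] + gametes[1]
    return counts


def simulate_phenotypes(
    ped: PedigreeTable,
    all_counts: np.ndarray,
    marker_ids: list[str],
    arch: TraitArchitecture,
    phenotyping_rate: float = 0.8,
    genotyping_rate: float = 0.5,
    genotyped_pool: str = "all",
    seed: int = 0,
) -> SimulatedPopulation:
    """Assign QTN effects, breeding values, records, and observation sets.

    ``genotyped_pool`` controls who can be genotyped: ``"all"`` samples from
    the whole pedigree, ``"phenotyped"`` restricts genotyping to animals
    with a record (so every genotyped animal is phenotyped).

    Breeding values are u = Z a_true with Z centered at the realized allele
    frequencies, rescaled so that var(u) among phenotyped animals equals
    sigma_u2 exactly.  Each record gets a contemporary-group effect drawn
    once per group and an independent residual with variance sigma_e2.
    """
    if not 0.0 < phenotyping_rate <= 1.0:
        raise ValueError("phenotyping_rate must be in (0, 1]")
    if not 0.0 < genotyping_rate <= 1.0:
        raise ValueError("genotyping_rate must be in (0, 1]")
    n_markers = all_counts.shape[1]
    arch.validate(n_markers)
    rng = np.random.default_rng(seed)
    n = ped.n_animals

    p = all_counts.mean(axis=0) / 2.0
    k = 2.0 * np.sum(p * (1.0 - p))
    common = np.nonzero(np.minimum(p, 1.0 - p) >= arch.qtn_min_maf)[0]
    if arch.n_qtn > len(common):
        raise ValueError(
            f"only {len(common)} markers at MAF >= {arch.qtn_min_maf} "
            f"for {arch.n_qtn} QTN"
        )
    qtn = np.sort(rng.choice(common, size=arch.n_qtn, replace=False))
    a_true = np.zeros(n_markers)
    if arch.polygenic_background and k > 0 and arch.sigma_u2 > 0:
        a_true += rng.normal(0.0, np.sqrt(arch.sigma_u2 / k), size=n_markers)
    a_true[qtn] += rng.normal(0.0, arch.qtn_effect_sd, size=arch.n_qtn)

    Z_all = all_counts - 2.0 * p
    u = Z_all @ a_true

    # observation sets: founders are never phenotyped (no CG of their own),
    # later animals phenotyped/genotyped independently at the given rates
    non_founders = np.arange(n)[(ped.sire_idx != UNKNOWN) | (ped.dam_idx != UNKNOWN)]
    eligible = non_founders if len(non_founders) else np.arange(n)
    n_ph = max(1, int(round(phenotyping_rate * len(eligible))))
    ph_idx = np.sort(rng.choice(eligible, size=n_ph, replace=False))
    if genotyped_pool == "phenotyped":
        pool = ph_idx
    elif genotyped_pool == "all":
        pool = np.arange(n)
    else:
        raise ValueError("genotyped_pool must be 'all' or 'phenotyped'")
    n_gt = min(len(pool), max(2, int(round(genotyping_rate * len(pool)))))
    gt_idx = np.sort(rng.choice(pool, size=n_gt, replace=False))

    if arch.n_cg > len(ph_idx):
        raise ValueError("more contemporary groups than phenotyped animals")

    # rescale u so empirical variance among phenotyped animals is sigma_u2
    v = float(np.var(u[ph_idx]))
    if arch.sigma_u2 == 0.0 or v == 0.0:
        scale = 0.0
    else:
        scale = np.sqrt(arch.sigma_u2 / v)
    u = u * scale
    a_true = a_true * scale

    # contemporary groups: split birth cohorts randomly into groups
    gen = ped.generation if ped.generation is not None else np.zeros(n, dtype=int)
    cg = np.empty(len(ph_idx), dtype=np.int64)
    order = np.lexsort((rng.random(len(ph_idx)), gen[ph_idx]))
    bounds = np.array_split(np.arange(len(ph_idx)), arch.n_cg)
    for g, chunk in enumerate(bounds):
        cg[order[chunk]] = g
    cg_effects = rng.normal(0.0, arch.cg_effect_sd, size=arch.n_cg)

    e = rng.normal(0.0, np.sqrt(arch.sigma_e2), size=len(ph_idx))
    y = cg_effects[cg] + u[ph_idx] + e

    phen = pd.DataFrame(
        {
            "animal_id": [ped.ids[i] for i in ph_idx],
            "cg": [f"CG{g + 1}" for g in cg],
            "value": y,
        }
    )
    genotyped_ids = [ped.ids[i] for i in gt_idx]
    geno = GenotypeMatrix(
        animal_ids=genotyped_ids,
        marker_ids=list(marker_ids),
        counts=all_counts[gt_idx].astype(np.float64),
    )
    return SimulatedPopulation(
        pedigree=ped,
        genotypes=geno,
        true_breeding_values=u,
        true_snp_effects=a_true,
        qtn_indices=qtn,
        phenotypes=phen,
        genotyped_ids=genotyped_ids,
        all_counts=all_counts,
    )


def simulate_population(
    n_founders: int = 60,
    n_generations: int = 3,
    n_markers: int = 1000,
    arch: TraitArchitecture | None = None,
    litter_params: LitterParams | None = None,
    founder_maf_range: tuple[float, float] = (0.05, 0.5),
    phenotyping_rate: float = 0.8,
    genotyping_rate: float = 0.5,
    genotyped_pool: str = "all",
    seed: int = 0,
) -> SimulatedPopulation:
    """Convenience wrapper: pedigree -> gene drop -> phenotypes."""
    arch = arch or TraitArchitecture.from_h2(0.3, n_qtn=10)
    ss = np.random.SeedSequence(seed)
    s_ped, s_geno, s_phen = [int(s) for s in ss.generate_state(3) >> np.uint32(1)]
    ped = simulate_pedigree(n_founders, n_generations, litter_params, seed=s_ped)
    counts = simulate_genotypes(ped, n_markers, founder_maf_range, seed=s_geno)
    marker_ids = [f"M{j + 1}" for j in range(n_markers)]
    return simulate_phenotypes(
        ped,
        counts,
        marker_ids,
        arch,
        phenotyping_rate=phenotyping_rate,
        genotyping_rate=genotyping_rate,
        genotyped_pool=genotyped_pool,
        seed=s_phen,
    )
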