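"""End-to-end orchestration of a single-step GWAS run.

The pipeline follows a five-stage procedure:

1. build the relationship machinery (A^-1, A22 and its inverse, blended G)
   and, for the APY methods, the sparse APY inverse of G, persisting it;
2. solve the single-step mixed-model equations for GEBVs;
3. obtain the GEBV prediction-error covariance by the configured route
   (full LHS inverse, LHS inverse sliced to the core, or the core
   approximation that never touches the LHS inverse);
4. turn it into per-marker sampling variances;
5. backsolve SNP effects from GEBVs, attach p-values, significance calls
   and diagnostics, and write the results.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import apy as apy_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import pev as pev_mod
from . import relmat, ssgblup
from .io import RunConfig

logger = logging.getLogger(__name__)

METHOD_TAGS = {
    "exact_ginv": "Exact_Ginv",
    "exact_ginv_apy": "Exact_GinvAPY",
    "approx_ginv_apy": "Approx_GinvAPY",
}


def _select_core(config: RunConfig, geno, ped, phen) -> apy_mod.ApyPartition:
    ids = geno.animal_ids
    if config.core_random is not None:
        return apy_mod.select_core_random(ids, config.core_random, seed=config.seed)
    if config.core_var_fraction is not None:
        n_core = apy_mod.core_size_from_eigenvalues(geno, config.core_var_fraction)
        return apy_mod.select_core_random(ids, n_core, seed=config.seed)
    if config.core_high_accuracy is not None:
        a_inv = relmat.build_A_inverse(ped)
        rel = ssgblup.ebv_reliability_pedigree(
            phen, ped, a_inv, config.lambda_ratio, config.sigma_u2, config.sigma_e2
        )
        return apy_mod.select_core_high_accuracy(ids, rel, config.core_high_accuracy)
    if config.core_file is not None:
        return apy_mod.read_partition(config.core_file)
    raise ValueError("no core specification for an APY method")


def run_pipeline(
    config: RunConfig,
    inputs: tuple | None = None,
) -> gwas_mod.GwasResult:
    """Run one method end to end; returns the GWAS result and writes
    the output table, diagnostics, and persisted matrices to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    ped, geno, phen = inputs if inputs is not None else io_mod.read_inputs(config)
    geno = geno.drop_monomorphic(min_maf=config.min_maf)

    # -- stage 1: relationship machinery ----------------------------------
    ped.inbreeding = relmat.compute_inbreeding(ped)
    a_inv = relmat.build_A_inverse(ped)
    A22 = relmat.build_A22(ped, geno.animal_ids)
    A22_inv = np.linalg.inv(A22)
    G_raw = relmat.build_G_raw(geno)
    G = relmat.tune_and_blend_G(G_raw, A22, beta=config.beta_blend)

    partition = None
    if config.method == "exact_ginv":
        T_inv = G.inverse
    else:
        skeleton = _select_core(config, geno, ped, phen)
        partition = apy_mod.build_gapy_inverse(G, skeleton, geno.animal_ids)
        apy_mod.write_partition(out / "apy_partition.txt", partition)
        T_inv = partition.assemble_ordered(geno.animal_ids)
        io_mod.write_matrix_triplets(
            out / "gapy_inverse.txt", T_inv,
            row_ids=geno.animal_ids, col_ids=geno.animal_ids,
        )
    logger.info("stage 1 (relationships) done in %.2fs", time.perf_counter() - t0)

    # -- stage 2: GEBVs -----------------------------------------------------
    t1 = time.perf_counter()
    genotyped_index = ped.index_of(geno.animal_ids)
    h_inv = ssgblup.build_H_inverse(a_inv, A22_inv, T_inv, genotyped_index)
    system = ssgblup.assemble_mme(
        phen, ped, h_inv, config.lambda_ratio, mode=config.method
    )
    ssgblup.solve_pcg(system, tol=config.solver_tol, max_iter=config.solver_max_iter)
    u_hat = system.gebv_for(geno.animal_ids)
    logger.info("stage 2 (GEBVs) done in %.2fs", time.perf_counter() - t1)

    # -- stages 3-4: PEV and marker variances ------------------------------
    t2 = time.perf_counter()
    if config.method == "exact_ginv":
        C = pev_mod.pev_exact_from_lhs(system, config.sigma_e2, geno.animal_ids)
        variances = gwas_mod.snp_variance_exact(G, C, geno, config.sigma_u2)
    else:
        if config.method == "exact_ginv_apy":
            C = pev_mod.pev_exact_from_lhs(
                system, config.sigma_e2, partition.core_ids
            )
            C.method = "exact-core"
        else:
            absorption = pev_mod.compute_absorption_diagonal(phen, geno.animal_ids)
            C = pev_mod.pev_core_approx(
                partition, absorption, config.lambda_ratio, config.sigma_e2
            )
        geno_core = geno.subset_animals(partition.core_ids)
        variances = gwas_mod.snp_variance_apy(
            partition, C, geno_core,
            beta=G.beta, b_tune=G.b_tune, scale_k=geno.scale_k,
            sigma_u2=config.sigma_u2,
        )
    logger.info("stages 3-4 (PEV, variances) done in %.2fs", time.perf_counter() - t2)

    # -- stage 5: backsolve, p-values, outputs -----------------------------
    t3 = time.perf_counter()
    effects = gwas_mod.backsolve_snp_effects(
        u_hat, G, geno, apy_partition=partition
    )
    result = gwas_mod.make_result(
        geno, effects, variances, METHOD_TAGS[config.method], alpha=config.alpha
    )
    tag = result.method
    result.table.to_csv(out / f"gwas_{tag}.tsv", sep="\t", index=False)
    with open(out / f"diagnostics_{tag}.json", "w") as fh:
        json.dump(result.diagnostics.to_dict(), fh, indent=2)
    io_mod.write_config(out / "config_effective.yaml", config)
    logger.info("stage 5 (GWAS outputs) done in %.2fs", time.perf_counter() - t3)
    return result


def run_comparison(
    base_config: RunConfig,
    methods: list[str],
    inputs: tuple | None = None,
    benchmark: str = "Exact_Ginv",
) -> tuple[list[gwas_mod.GwasResult], pd.DataFrame]:
    """Run several methods on the same inputs and correlate their outputs."""
    import dataclasses

    results = []
    for m in methods:
        cfg = dataclasses.replace(
            base_config, method=m, out_dir=str(Path(base_config.out_dir) / m)
        )
        results.append(run_pipeline(cfg, inputs=inputs))
    table = gwas_mod.compare_methods(results, benchmark=benchmark)
    table.to_csv(Path(base_config.out_dir) / "method_comparison.tsv",
                 sep="\t", index=False)
    return results, table
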