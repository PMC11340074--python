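"""SNP-effect backsolving, sampling variances, p-values, and diagnostics.

Marker effects are recovered from GEBVs of genotyped animals by the linear
transformation

    a_hat = (1 - beta) * b * (1 / k) * Z' G^-1 u_hat,    k = 2 sum p(1-p)

with G^-1 either the exact inverse of the blended genomic relationship
matrix or its sparse APY counterpart.  Their sampling variances come from
the GEBV prediction-error covariance C:

    var(a_hat_i) = c^2 * z_i' G^-1 (G sigma_u^2 - C) G^-1 z_i,
    c = (1 - beta) * b / k

over all genotyped animals (exact route) or restricted to the APY core with
either the exact-core or the approximated core C.  Each marker is then
tested with the two-sided standard-normal statistic a_hat / sd(a_hat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .apy import ApyPartition
from .pev import PevMatrix
from .relmat import BlendedG, GenotypeMatrix

LOG10 = np.log(10.0)
# median of the chi-square(1) distribution, the genomic-control normalizer
CHI2_1_MEDIAN = float(stats.chi2.median(1))


@dataclass
class GwasDiagnostics:
    qq_slope: float
    lambda_gc: float
    threshold_neglog10: float

    def to_dict(self) -> dict[str, float]:
        return {
            "qq_slope": self.qq_slope,
            "lambda_gc": self.lambda_gc,
            "threshold_neglog10": self.threshold_neglog10,
        }


@dataclass
class GwasResult:
    """Per-marker effects, variances, p-values, and significance calls."""

    table: pd.DataFrame  # marker, chromosome, position, allele_freq, effect,
    # se, pvalue, neglog10p, significant
    method: str  # Exact_Ginv | Exact_GinvAPY | Approx_GinvAPY
    diagnostics: GwasDiagnostics | None = None

    @property
    def effects(self) -> np.ndarray:
        return self.table["effect"].to_numpy()

    @property
    def variances(self) -> np.ndarray:
        return self.table["se"].to_numpy() ** 2

    @property
    def pvalues(self) -> np.ndarray:
        return self.table["pvalue"].to_numpy()

    @property
    def neglog10p(self) -> np.ndarray:
        return self.table["neglog10p"].to_numpy()

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy()


def backsolve_snp_effects(
    gebv_genotyped: np.ndarray,
    G: BlendedG,
    geno: GenotypeMatrix,
    apy_partition: ApyPartition | None = None,
) -> np.ndarray:
    """a_hat = (1-beta) b (1/k) Z' (G^-1 u_hat).

    When ``apy_partition`` is given the sparse APY inverse is applied (the
    GEBV vector must then be ordered like ``geno.animal_ids``); otherwise
    the exact inverse of the blended G is used via its Cholesky factor.
    One inverse-vector product, then one Z'-vector product.
    """
    u = np.asarray(gebv_genotyped, dtype=np.float64)
    if u.shape != (geno.n_animals,):
        raise ValueError("GEBV vector does not match the genotyped set")
    if apy_partition is not None:
        order = {a: i for i, a in enumerate(geno.animal_ids)}
        perm = np.array([order[a] for a in apy_partition.ordered_ids])
        w_perm = apy_partition.matvec(u[perm])
        w = np.empty_like(w_perm)
        w[perm] = w_perm
    else:
        w = G.solve(u)
    c = (1.0 - G.beta) * G.b_tune / geno.scale_k
    return c * (geno.Z.T @ w)


def snp_variance_exact(
    G: BlendedG,
    pev_full: PevMatrix,
    geno: GenotypeMatrix,
    sigma_u2: float,
) -> np.ndarray:
    """Sampling variance of each backsolved effect, exact route.

    var(a_hat_i) = c^2 z_i' G^-1 (G sigma_u2 - C) G^-1 z_i with the full
    genotyped-animal PEV matrix C.  The middle matrix is formed once and
    reused across markers.
    """
    if pev_full.animal_set != list(geno.animal_ids):
        raise ValueError("PEV animal set does not match genotype matrix")
    mid = G.matrix * sigma_u2 - pev_full.matrix
    S = G.solve(G.solve(mid).T)  # G^-1 mid G^-1 (mid symmetric)
    c = (1.0 - G.beta) * G.b_tune / geno.scale_k
    Z = geno.Z
    var = c * c * np.einsum("ij,jk,ik->i", Z.T, S, Z.T)
    return _sanitize_variances(var)


def snp_variance_apy(
    partition: ApyPartition,
    pev_core: PevMatrix,
    geno_core: GenotypeMatrix,
    beta: float,
    b_tune: float,
    scale_k: float,
    sigma_u2: float,
) -> np.ndarray:
    """Sampling variances restricted to the APY core.

    var(a_hat_i) = c^2 z_ci' Gcc^-1 (Gcc sigma_u2 - C_core) Gcc^-1 z_ci,
    identical code path whether C_core is the exact-core or the
    approximated core PEV.  ``geno_core`` must keep the centering
    frequencies of the full genotyped set.
    """
    if pev_core.animal_set != list(partition.core_ids):
        raise ValueError("core PEV does not match partition core")
    if geno_core.animal_ids != list(partition.core_ids):
        raise ValueError("core genotype rows do not match partition core")
    mid = partition.Gcc * sigma_u2 - pev_core.matrix
    S = partition.Gcc_inv @ mid @ partition.Gcc_inv
    c = (1.0 - beta) * b_tune / scale_k
    Zc = geno_core.Z
    var = c * c * np.einsum("ij,jk,ik->i", Zc.T, S, Zc.T)
    return _sanitize_variances(var)


def _sanitize_variances(var: np.ndarray, neg_tol: float = 1e-10) -> np.ndarray:
    """Clamp round-off negatives; real negatives are a numerical failure."""
    vmax = float(np.max(np.abs(var))) if var.size else 0.0
    if np.any(var < -neg_tol * max(vmax, 1.0)):
        raise FloatingPointError("negative SNP-effect variance beyond round-off")
    tiny = np.finfo(np.float64).tiny
    return np.maximum(var, tiny)


def snp_pvalues(
    effects: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal p-values and overflow-safe -log10 p.

    p_i = 2 (1 - Phi(|a_hat_i| / sd_i)); the -log10 uses the log survival
    function so extreme markers never underflow to p = 0.
    """
    effects = np.asarray(effects, dtype=np.float64)
    variances = np.asarray(variances, dtype=np.float64)
    if np.any(variances <= 0):
        raise ValueError("all variances must be positive")
    t = np.abs(effects) / np.sqrt(variances)
    pvals = 2.0 * stats.norm.sf(t)
    neglog10p = -(np.log(2.0) + stats.norm.logsf(t)) / LOG10
    return pvals, neglog10p


def bonferroni_threshold(n_markers: int, alpha: float = 0.05) -> float:
    """Family-wise rejection cutoff on the -log10 scale: -log10(alpha/m)."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    return float(-np.log10(alpha / n_markers))


def genomic_control(pvalues: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-control inflation factor and deflated p-values.

    lambda_GC is the median of the chi-square(1) statistics implied by the
    p-values divided by the null median 0.4549...; corrected p-values come
    from the statistics divided by lambda_GC.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    valid = np.isfinite(p) & (p > 0) & (p <= 1)
    if not valid.any():
        raise ValueError("no valid p-values for genomic control")
    chi2 = stats.chi2.isf(p[valid], df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    corrected = np.full_like(p, np.nan)
    corrected[valid] = stats.chi2.sf(chi2 / lam, df=1)
    return lam, corrected


def qq_slope(pvalues: np.ndarray) -> float:
    """Slope through the origin of observed vs expected -log10 p quantiles."""
    p = np.asarray(pvalues, dtype=np.float64)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    m = len(p)
    if m < 2:
        raise ValueError("need at least two valid p-values")
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return float((obs @ exp) / (exp @ exp))


def make_result(
    geno: GenotypeMatrix,
    effects: np.ndarray,
    variances: np.ndarray,
    method: str,
    alpha: float = 0.05,
    n_markers_panel: int | None = None,
) -> GwasResult:
    """Bundle per-marker statistics with significance calls and diagnostics."""
    pvals, nlp = snp_pvalues(effects, variances)
    m = n_markers_panel or geno.n_markers
    cutoff = bonferroni_threshold(m, alpha)
    lam, _ = genomic_control(pvals)
    slope = qq_slope(pvals)
    table = pd.DataFrame(
        {
            "marker": geno.marker_ids,
            "chromosome": geno.chromosome if geno.chromosome is not None
            else np.ones(geno.n_markers, dtype=int),
            "position": geno.position if geno.position is not None
            else np.arange(1, geno.n_markers + 1),
            "allele_freq": geno.allele_freq,
            "effect": effects,
            "se": np.sqrt(variances),
            "pvalue": pvals,
            "neglog10p": nlp,
            "significant": nlp >= cutoff,
        }
    )
    diag = GwasDiagnostics(qq_slope=slope, lambda_gc=lam, threshold_neglog10=cutoff)
    return GwasResult(table=table, method=method, diagnostics=diag)


def compare_methods(
    results: list[GwasResult], benchmark: str = "Exact_Ginv"
) -> pd.DataFrame:
    """Pearson correlations of p-values, effects, and variances across methods.

    Rows are method pairs; ``*_all`` columns use every shared marker,
    ``*_significant`` restrict to markers significant under the benchmark
    method.  All result sets must cover identical marker lists.
    """
    if len(results) < 2:
        raise ValueError("need at least two result sets to compare")
    markers = list(results[0].table["marker"])
    for r in results[1:]:
        if list(r.table["marker"]) != markers:
            raise ValueError("marker sets differ across results")
    by_name = {r.method: r for r in results}
    bench = by_name.get(benchmark, results[0])
    sig_mask = bench.significant

    rows = []
    for i, r1 in enumerate(results):
        for r2 in results[i + 1 :]:
            row: dict[str, object] = {"method_a": r1.method, "method_b": r2.method}
            for name, x, y in (
                ("pvalue", r1.pvalues, r2.pvalues),
                ("effect", r1.effects, r2.effects),
                ("variance", r1.variances, r2.variances),
            ):
                row[f"{name}_all"] = _pearson(x, y)
                row[f"{name}_significant"] = (
                    _pearson(x[sig_mask], y[sig_mask]) if sig_mask.sum() >= 2
                    else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
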