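# Methods

This note documents the statistical model, the approximations, the synthetic
data generator, and the numerical and design choices behind `ssgwas`.

## The evaluation model

All methods operate on a single-trait animal model with contemporary-group
(CG) fixed effects,

```
y = X b + W u + e,   u ~ N(0, H σ²_u),  e ~ N(0, I σ²_e),
```

solved through the standard normal equations

```
[ X'X      X'W          ] [ b̂ ]   [ X'y ]
[ W'X   W'W + λ H⁻¹     ] [ û ] = [ W'y ],    λ = σ²_e / σ²_u.
```

Variance components are inputs, not estimated. `H⁻¹` adds a genomic
adjustment `(T⁻¹ − A₂₂⁻¹)` over genotyped animals to the sparse pedigree
inverse `A⁻¹` (Henderson rules with inbreeding; inbreeding coefficients from
the tabular relationship matrix). `T⁻¹` is the exact inverse of the blended,
tuned genomic relationship matrix `G`, or its APY approximation.

**Blending and tuning.** `G_raw = ZZ'/k` with `Z` the allele counts centered
by twice the allele frequency and `k = 2Σp(1−p)`. Frequencies are computed
from the supplied genotype set (the base-population frequencies of real
evaluations are unavailable in general). Because `G_raw` is singular
(column-centering alone puts the ones vector in its null space), `G` is
formed as `(1−β)(α11' + b·G_raw) + βA₂₂` with β = 0.05 by default. The
tuning scalars solve the two-moment system

```
b · mean(diag G_raw) + α = mean(diag A₂₂)
b · mean(offdiag G_raw) + α = mean(offdiag A₂₂),
```

the standard compatibility condition between genomic and pedigree
relationships. Using off-diagonal means (rather than all-element means) is a
deliberate choice; the two differ only by O(1/n).

**APY.** Given a core/noncore split of the genotyped animals, the APY
inverse stores `Gcc⁻¹` (dense, core-sized), `Gcn` (core × noncore), and the
noncore conditional variances `m_nn,j = g_jj − g_jc' Gcc⁻¹ g_cj`, computed
one animal at a time against a shared Cholesky factor of `Gcc` so the dense
noncore block is never formed. The assembled inverse has no
noncore–noncore fill beyond the diagonal, hence at most
`n_core² + 2·n_core·n_noncore + n_noncore` stored entries. A conditional
variance at or below `1e-8 · mean(diag G)` raises a conditioning error
naming the offending animal — silent clamping would silently distort the
downstream prediction-error approximation. Core selection is uniform random
(the default), by highest pedigree-based EBV reliability, by an explicit
file, or sized by the number of eigenvalues explaining a given fraction of
the variance of `Z` (via SVD).

## The three p-value routes

Marker effects are backsolved as `â = (1−β) b (1/k) Z' T⁻¹ û` and tested
with `p = 2(1 − Φ(|â|/sd â))`. The sampling variance is the quadratic form

```
var(âᵢ) = c² zᵢ' T⁻¹ (T σ²_u − C) T⁻¹ zᵢ,   c = (1−β) b / k,
```

instantiated three ways:

1. **exact**: `T = G`, `C` = σ²_e × (genotyped block of the dense LHS
   inverse); the middle matrix `G⁻¹(Gσ²_u − C)G⁻¹` is formed once and the
   per-marker quadratic forms are a single einsum.
2. **exact core (APY)**: the same LHS inverse, sliced to the core; `z`
   restricted to core rows; `Gcc` blocks replace `G`.
3. **approximated core**: `C` replaced by
   `σ²_e (D_c + λG^cc − λG^cn (λM⁻¹ₙₙ + D_n)⁻¹ λG^nc)⁻¹` where
   `G^cc, G^cn, M⁻¹ₙₙ` are the APY inverse blocks and `D` is the diagonal
   of `W'(I − X(X'X)⁻¹X')W`. The inner noncore inverse is elementwise
   (cost linear in the noncore count). The leading σ²_e converts the
   inverse-information units of the expression into trait units², making it
   directly comparable with routes 1–2.

Two conventions in the variance/backsolve chain deserve a note. The
backsolve carries the factor `1/k` (i.e. σ²_a/σ²_u), matching the variance
formula; an alternative convention with the reciprocal factor exists in the
literature but is dimensionally inconsistent with the variance expression
used here. Likewise the weight multiplying the quadratic form is always the
blending complement `(1−β)`; the tuning intercept α plays no multiplicative
role.

**What the approximation ignores.** `D` contains phenotype contributions
only. The exact genotyped block of the absorbed LHS additionally carries
(i) the off-diagonal absorption terms within contemporary groups, and
(ii) pedigree information flowing through `A⁻¹` and `−A₂₂⁻¹`, including
records of non-genotyped relatives. On a fully genotyped, fully phenotyped
population the block algebra is exact up to (i) — the test suite verifies
machine-precision agreement when `D` is exactly diagonal — while with
partial genotyping the approximation degrades gracefully; its p-values stay
strongly correlated with the exact route even where the PEV level drifts.
Markers nearly monomorphic *within the core* are the known failure mode:
their core-restricted variance collapses and the statistic explodes, which
is the practical reason for the MAF filter below.

**Calibration caveat.** The statistic is calibrated under the fitted mixed
model, i.e. when marker effects are draws from the polygenic prior. The
core-restricted routes are over-dispersed at small core sizes (QQ slopes
around 2 at a 60/200 core, against ~1 for the exact route); this is a
property of the approximation at aggressive core reductions, and the
genomic-control factor λ_GC is reported so users can deflate if desired.

## Quality control

Markers that are monomorphic or below a minor-allele-frequency threshold
(pipeline default `min_maf = 0.05`) are dropped before `Z` is formed, with a
logged count. Besides being standard panel QC, the filter removes drifted
rare markers that would otherwise be monomorphic inside a small core and
trigger the failure mode above. Missing genotype calls (code 5 in the text
format) are imputed to twice the observed allele frequency, i.e. they are
exactly neutral in the centered matrix.

## Solver and numerics

The mixed-model equations are assembled sparsely (animals ordered after CG
levels) and solved with Jacobi-preconditioned conjugate gradients, default
relative-residual tolerance 1e-12 and 5,000 iterations — p-values are
sensitive to û precision, so the tolerance is deliberately strict. CG
levels are taken from the records, so empty levels cannot arise; X is full
rank whenever every level has a record, and a singular system surfaces as a
non-convergence/curvature error carrying the residual history. Exact PEVs
use a dense inversion of the LHS, acceptable at the desk scales this
package targets (a few hundred pedigree animals); `A` and `A₂₂` are built
by the tabular method for the same reason. Negative marker variances beyond
−1e-10 (relative) raise; round-off negatives are clamped to the smallest
positive float. `−log10 p` is evaluated through the normal log-survival
function, so extreme statistics (|t| > 8) never underflow to p = 0.

## Synthetic populations

The generator emulates the structure of a genotyped livestock evaluation:

- **Pedigree**: `n_founders` unrelated founders, then `n_generations`
  rounds of `n_matings` sire–dam pairs each producing
  `offspring_per_mating` offspring; parents are drawn from all earlier
  generations (overlapping generations, half/full-sib families). Unknown
  parents are coded 0 in files.
- **Genotypes**: founders drawn from Hardy–Weinberg proportions at
  frequencies uniform in `founder_maf_range` (default 0.05–0.5);
  descendants receive one Mendelian gamete per parent; markers are
  independent (no LD map). Relatedness still induces the low-rank structure
  APY exploits, but less of it than real LD-laden panels: at a 200-animal
  set, 60 dimensions capture ~70 % of the variance of `Z` versus 98 % for
  the core sizes used in large real evaluations. Passing tests therefore
  exercise the algebra and the approximation's behavior, not APY's best-case
  fidelity on real data.
- **Trait**: breeding values are defined through marker effects,
  `u = Z a_true`, so backsolved effects have a known truth. Every marker
  carries a polygenic effect `~ N(0, σ²_u/k)` — the prior under which the
  test statistic is calibrated — and `n_qtn` markers with realized MAF
  ≥ 0.10 receive an additional large effect with SD `qtn_effect_sd` (trait
  units). `u` is rescaled so its empirical variance among phenotyped
  animals equals σ²_u exactly. With `n_qtn = 0` the trait is a calibrated
  null: no marker is individually detectable. A trait with literally zero
  genetic variance is *not* a calibrated null for this statistic (the
  model-based variance then overstates the realized one and the test is
  conservative); the polygenic null is the correct reference.
- **Records**: founders are never phenotyped; other animals are phenotyped
  at `phenotyping_rate` and assigned to `n_cg` contemporary groups by
  randomly split birth cohorts, with group effects drawn once per group.
  Genotyped animals are sampled from the whole pedigree (default) or from
  the phenotyped set (`genotyped_pool="phenotyped"`), giving the partial
  overlap of real evaluations: some phenotyped animals contribute no
  genotype and vice versa.

Default study conditions used by the acceptance checks: h² = 0.3
(σ²_u = 0.3, σ²_e = 0.7), 3 QTN with SD 2.0, 5 contemporary groups,
family-structured pedigrees of 30–60 founders with 3 overlapping
generations, 1,000–2,000 markers, and 150–250 genotyped animals — sizes at
which the dense benchmark routes remain exact references while the full
three-method comparison runs in seconds.

Null-calibration diagnostics (rejection rate at 0.05, QQ slope, λ_GC) are
averaged over three replicate populations: within one population the 2,000
marker tests share a single realized pedigree and are positively dependent,
so single-population diagnostics are over-dispersed relative to independent
tests (observed single-population rejection rates range roughly 0.03–0.09
around a mean of 0.05).

## Known limitations

- Single trait, CG fixed effect only; no maternal, multi-trait, or
  random-regression models, and no variance-component estimation.
- Dense `A`/LHS algebra caps practical problem sizes at a few thousand
  pedigree animals; iteration-on-data and Colleau-style indirect products
  are noted scaling paths, not implemented.
- The absorption diagonal contains phenotype contributions only; pedigree
  contributions (as in fuller reliability-approximation algorithms) are a
  hook, not implemented.
- No metafounders, unknown-parent groups, or genomic-inbreeding
  adjustments; simulated markers carry no LD map and no genotyping error.
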