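# Methods

`wheatmt` implements a multi-trait association-mapping workflow for panels
of (near-)inbred crop varieties: two-stage phenotypic analysis, bivariate
mixed-model association scans, a two-dimensional likelihood-ratio scan that
separates pleiotropy from close linkage, and a simulation study of that
scan's power and Type I error.  This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic-data
based tests do and do not demonstrate.

## Phenotypic two-stage analysis

Stage 1 fits, per trait and environment, the alpha-lattice model

    value ~ genotype (fixed) + replicate (random)
            + block-within-replicate (random) + plot error,

by REML (through statsmodels' MixedLM) and carries the genotype BLUEs
forward; environments with a single replicate pass their raw plot values
through with a flag.  Stage 2 combines the per-environment BLUEs with
genotype fixed and environment random; a parallel random-genotype fit gives
the genotypic variance.  The stage-2 residual mixes genotype-by-environment
and error variance; the G×E component is obtained by subtracting the
stage-1 average plot-error variance, floored at zero with a warning when
the subtraction goes negative.  The pipeline is deliberately unweighted (no
stage-1 precision weights).

Two properties of this (conventional) procedure are worth stating plainly:

* Because stage-2 BLUEs average `nRep` plots, the stage-2 residual is
  approximately `σ²_GxE + σ²_Error / nRep`, so subtracting the full
  `σ²_Error` biases the G×E estimate downward by `σ²_Error (1 − 1/nRep)`.
  The subtraction is implemented exactly as defined; the recovery tests
  assert the procedure's actual estimand.
* The random-genotype variance treats genotypes as exchangeable.  In a
  panel with kinship `A = 2(J − RD)`, a large common component of `A` is
  absorbed by the intercept, so the ANOVA genotypic variance corresponds to
  `s·(mean diag A − mean offdiag A)`, not to the marginal `s·A_ii`.

Heritabilities: `h²_plot = σ²_G / (σ²_G + σ²_GxE + σ²_Error)` and
`h²_entry = σ²_G / (σ²_G + σ²_GxE/nEnv + σ²_Error/(nRep·nEnv))`.

## The multi-trait mixed model

The computational core is the t-trait linear mixed model

    y_kji = fixed effects + g_ki + e_kji,
    g ~ N(0, G0 ⊗ A),   e ~ N(0, R0 ⊗ I),

with `A = 2(J − RD)` from Rogers' distances (bent by adding
`−λ_min + 10⁻⁶` to the diagonal when indefinite).  Fixed effects cover
per-trait intercepts, environment effects, marker-dosage effects (possibly
a different marker per trait — the close-linkage model) and
marker-by-environment interactions.

Estimation maximizes the (restricted) likelihood over the log-Cholesky
parameterization of (G0, R0), profiling fixed effects by GLS inside every
evaluation.  Balanced layouts are rotated once — `A = U D U'` plus an
orthogonal environment basis whose first vector is `1/√J` — after which the
covariance is block diagonal with t×t blocks `d_m G0 + R0` and each
evaluation costs O(n t²).  Unbalanced trait-environment layouts fall back
to a dense multivariate-normal likelihood in which errors are shared across
traits only for jointly observed genotype-environment cells.  L-BFGS-B with
numerical gradients drives the optimization (Nelder-Mead polish on
failure); invalid covariances return a large finite penalty rather than
infinity, because an infinite objective silently breaks the L-BFGS-B line
search.  Convergence: relative objective tolerance 1e-11, projected
gradient 1e-6, 200 iterations.

Wald statistics use `θ' Var(θ)⁻¹ θ` with `Var(θ)` the corresponding
submatrix of the GLS fixed-effect covariance at the variance-component
estimates (the C11 block), referred to chi-square with df = rank.

The genetic correlation `r_g = s₁₂/√(s₁₁ s₂₂)` is tested by an LR against a
refit with the genetic covariance constrained to zero (same fixed effects,
so REML LRs are valid), referred to χ²₁ with the statistic floored at 0.
**Identifiability caveat:** with a single observation per genotype-trait,
only `c·s₁₂ + r₁₂` enters the likelihood (exactly so when A ∝ I), so the
genetic and error covariances are confounded and the LR collapses.  The
genetic-correlation model is therefore meant for per-environment data
(J ≥ 2), where the repeated structure identifies both components; the
calibration tests use J = 4.

## Association scan and multiplicity

The bivariate genome scan fits the marker model per marker on stage-1
BLUEs, with the hierarchy: global Wald test of both marker effects (df 2),
post-hoc per-trait tests (df 1, gate at nominal α = 0.05), and global /
per-trait marker-by-environment tests.  A marker counts as potentially
pleiotropic only if the global and both per-trait tests pass.
Benjamini–Hochberg q-values are computed on the global p-values within a
trait pair; Bonferroni and M_eff corrections adjust the per-test threshold.
M_eff of an r² matrix is the smallest number of leading eigenvalues
(negatives floored at 0, no re-centering) whose cumulative share reaches
95%; genome-wide M_eff sums per-chromosome values over markers with unique
mapped positions.  The same rule applied to the r² matrix of significant
markers gives the effective number of associations.  Sequential (Type-I) R²
partitions enter markers by ascending global p-value; dividing phenotypic
R² by `h²_entry` converts it to a share of genetic variance.

## Two-dimensional pleiotropy-vs-linkage scan

For a target marker, candidate positions are the target plus its r² > 0.5
window (same chromosome, unique mapped positions).  Every ordered candidate
pair (m₁ carries trait 1's QTL, m₂ trait 2's) is fitted by **maximum
likelihood** (the two models differ in fixed effects, so REML likelihoods
are not comparable); the diagonal of the grid is the pleiotropy model.  L0
is the best diagonal log-likelihood, L1 the best anywhere, so
`LR = 2(L1 − L0) ≥ 0` by construction; it is referred to χ²₁ at α = 0.05,
accepting the known caveat that the two models are not strictly nested.
Both trait-assignment directions of each pair are scanned and the maximum
taken.  Variance components are re-estimated at every grid point by
default; `fast=True` estimates them once under the no-marker null model and
re-solves only the GLS step — an approximation that agrees with the full
profile within binomial noise in side-by-side grid checks while being two
orders of magnitude faster.  An empty window makes the target untestable
(such targets are skipped, mirroring how markers without linked neighbours
must be discarded).

## Synthetic genotype panels

Lines are founder-haplotype mosaics: each inbred line follows a Markov
chain over a pool of founder haplotypes, switching founders at rate
`exp(−Δ cM / ld_decay_cM)`; a line copies its family's reference mosaic
with probability `kinship_strength`, which induces families and hence an
informative Rogers-distance kinship.  Founder haplotypes themselves are
Markov chains along the chromosome (ancestral haplotype sharing), which is
what creates marker-to-marker LD; target allele frequencies are
block-constant along the chromosome with an L-shaped spectrum, so rare- and
common-allele regions are coherent and every MAF class contains marker
pairs across the full r² range.  Realized MAFs are nudged into the
configured range by flipping single founder alleles (small perturbations
that leave the LD-block structure intact).

Engineered two-locus draws (`simulate_marker_pair`) use the standard
haplotype-frequency parameterization with positive D, rejection-sampled
until realized MAFs are within ±0.02 and realized r² within ±0.03 of the
request (default 200 attempts), with the feasibility bound
`r²_max = min(p(1−q), q(1−p))² / (p(1−p)q(1−q))` enforced.

Phenotypes are alpha-lattice plots: per-trait QTL effects plus a polygenic
term with covariance `genetic_corr`-structured G0 ⊗ A (scaled so the
marginal polygenic variance equals `var_G`), i.i.d. G×E per
genotype-environment cell, i.i.d. replicate and block effects (blocks are
random partitions of each replicate, default 10 plots), and plot error.

What the generator does **not** emulate: real wheat demography and
selection history, genotyping error, physical-coordinate structure, and —
most consequentially — the exact LD geometry and relatedness of a real
variety panel.  Tests passing on these panels show the machinery is
correct and calibrated under the stated covariance structure; they do not
certify numerical agreement with analyses of any particular real panel.

## Power / Type I simulation study

The study grid crosses MAF levels {~0.06, ~0.13, ~0.22, ~0.46} (band-
matched as 0.06–0.07, 0.11–0.14, 0.20–0.24, 0.44–0.48), QTL sizes {5, 10,
15}% of genetic variance, and — in linkage mode — r² levels {~0.55, ~0.70,
~0.91} (0.53–0.56, 0.68–0.72, 0.90–0.93), with 100 replicates per cell on a
panel of 372 genotypes.  Unbalanced (size₁, size₂) cells are supported.

Protocol choices, each fixed once and applied throughout:

* **Causal markers come from the panel itself** (band-matched pairs /
  windowed singles), not from independent engineered draws: only
  panel-embedded markers experience the kinship absorption and the
  surrounding-window competition that shape the test.  A finite panel can
  lack pairs in the rare-MAF × moderate-r² corner, in which case the grid
  runner regenerates the panel deterministically until every cell is
  feasible.
* **Variance scale.**  Everything sits on the REML component scale on which
  heritabilities are defined with `A = 2(J − RD)` (diagonal 2): trait
  genetic variance 1, QTL absolute variance `pct/100` (effect
  `α = √(pct/100 · V_G / 4p(1−p))` for 0/2 dosages), polygenic component
  `1 − pct/100`, residuals `1/h² − 1` with plot-basis h² of 0.44 (trait 1,
  yield-like) and 0.60 (trait 2, component-trait-like).
* **Scan protocol.**  The per-replicate scan runs in fast mode (null-model
  variance components reused across the candidate grid); candidate windows
  are capped at the 10 highest-r² neighbours.  The default panel
  (10 chromosomes × 800 markers, ~5.3 markers/cM, r² > 0.5 within ~1 cM)
  gives window sizes around ten markers.
* Rejection is `p < 0.05` against χ²₁; each cell reports the rejection
  proportion and its binomial standard error; cells with >20% failed
  replicates are flagged unreliable.

Under this protocol the test's Type I error is close to nominal (grand mean
≈ 0.05 over the pleiotropy grid) and power increases with MAF and QTL size
and decreases with r², with low-MAF and small-QTL cells in the 0.0–0.3
range.  Large-QTL cells at intermediate/common MAF reach substantially
higher power on these synthetic panels than on real variety panels: the
synthetic LD geometry offers fewer compromise positions and weaker
confounding than a real 19k-marker panel, and no reconstruction of the
(unavailable) original protocol that we examined — entry-mean vs plot-basis
residual scales, population vs component variance scales, causal markers
included in or excluded from the candidate set, full-profile vs null-reuse
variance estimation — removes this gap while keeping Type I error
calibrated.  The power numbers for those cells should therefore be read as
upper bounds specific to the synthetic panel geometry.

## Known limitations

* The 2D scan evaluates marker positions only (no interval mapping between
  markers) and at most two QTLs.
* REML/ML fits with more than three traits are untested territory; the
  3-trait path exists for the higher-order marker test.
* The dense (unbalanced) likelihood path is O(N³) per evaluation and meant
  for moderate data sizes.
* χ²₁ reference distributions are used exactly as in the underlying
  methodology despite the non-nested caveat for the 2D scan and the
  boundary caveat for variance-component LRs.
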