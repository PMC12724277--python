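# Methods

## Panel construction

Input is a CpG × sample matrix of beta values (methylation fractions in
[0, 1]) per cohort, with sample metadata (donor, cell type ∈ {NEU, MG,
OLIG, AST}, age, sex). The package consumes preprocessed, batch-corrected
matrices; array preprocessing (normalization, probe QC, batch adjustment)
is upstream and out of scope.

Per cohort, the per-cell-type **median profile** is computed (pandas
median; midpoint convention for even counts). A median is *intermediate*
when 0.1 < β < 0.9, with both inequalities strict — a median of exactly
0.1 or 0.9 is extreme. The three specificity levels:

* **high** — intermediate in exactly one cell type, and
  |median_target − median_other| ≥ 0.1 for all three others. The gap
  comparison uses an absolute tolerance of 1e-9 so that a gap of exactly
  0.1 passes despite binary-float rounding (0.15 − 0.05 ≠ 0.1 in
  float64). High sets are pairwise disjoint by construction.
* **medium** — intermediate in 1–3 cell types (so ≥ 1 extreme type);
  multi-annotation allowed. The 0.1 gap is *not* required at this level;
  a `require_gap` flag adds it against the extreme cell types only.
* **low** — intermediate in the cell type *and* all three pairwise
  contrasts involving it Bonferroni-significant (p_bonf < α, default
  0.05), plus all high/medium CpGs carried over unconditionally.

Contrasts come from a per-CpG linear mixed model on M-values
(M = log2(β′/(1−β′)), β clamped to [ε, 1−ε], ε = 1e-6): fixed effects
cell type, age, sex; random intercept per donor; REML via statsmodels
`MixedLM` with its default BFGS optimizer (the L-BFGS path proved
numerically fragile on this design). Age is standardized in the design
purely for conditioning; cell-type contrasts are unaffected. The six
pairwise cell-type differences are Wald-tested and Bonferroni-adjusted
within the CpG (factor 6 — the per-CpG family; a genome-wide factor can
be passed instead). If the mixed fit fails or yields non-finite standard
errors, an OLS fallback with donor as a fixed covariate is used and
flagged `ols_fixed_donor`; if that is also degenerate (e.g. a single
donor, zero residual df) the CpG is flagged `failed` and excluded from
the low-specificity statistical route.

Every criterion is evaluated within each cohort independently and
per-cohort results are intersected, so panels contain only CpGs passing
in both cohorts; the shared CpG universe is the index intersection of the
two matrices. All classification is deterministic.

## Enrichment (ORA)

For input set I, background U (I ⊆ U enforced; violations are an error,
or dropped with a warning on request) and panel set S (intersected with
U): a = |I∩S|, b = |I|−a, c = |S∩U|−a, d = |U|−|I|−c.

* **p-value**: one-sided exact hypergeometric tail P(X ≥ a) with all
  margins fixed (scipy `hypergeom.sf`); a two-sided Fisher option exists.
* **odds ratio**: ad/bc when all cells are positive; when any cell is
  zero, 0.5 is added to every cell (the Haldane–Anscombe correction,
  applied conditionally). When a = 0 the *reported* OR is 0 with a
  `zero_overlap` flag — a display convention, not an estimate — while the
  corrected OR is kept in a diagnostic field. The p-value never uses the
  correction.
* **FDR**: Benjamini–Hochberg across the four cell types within one
  specificity level (statsmodels `multipletests`), matching the
  per-level significance marking; pooling across levels is possible by
  adjusting the caller's p collection.
* Multi-annotated CpGs (medium/low) count toward every set they belong
  to; `overlap_decomposition` reports input counts per exact cell-type
  combination (shared vs unique).

The **matched permutation null** draws, per permutation, as many
background probes as the input holds within each joint stratum of probe
design type × island context × gene context, without replacement, and
records the HA odds ratio against the panel set. Because the input is a
subset of the annotated background, the exact joint stratum always holds
enough probes; if an inconsistent annotation leaves a stratum short,
matching coarsens deterministically (drop gene context, then island
context), with each step logged. The empirical p is
(1 + #{OR_perm ≥ OR_obs}) / (n_perm + 1), so it lies in (0, 1] and is
never exactly zero. A fixed seed reproduces the null exactly.

## Pseudo-bulk simulation

Each simulated CpG is a *set* CpG for one cell type or *background*:

* set CpG: target-cell mean µ ~ U(0.15, 0.85); each other cell type
  µ ~ U(0.01, 0.09) or U(0.91, 0.99) (fair coin per cell type);
* background CpG: all four µ ~ U(0.15, 0.85) independently;
* per-CpG SD ~ U(0, 0.1), shrunk per cell type as
  SD\* = SD · (1 − |0.5 − µ|/0.5), reproducing the boundary
  heteroskedasticity of beta values.

Values are drawn from N(µ, SD\*) truncated to [0, 1] by inverse-CDF
sampling (scipy `ndtr`/`ndtri`; fully vectorized; SD\* = 0 returns µ
exactly). Per-sample mixing weights are Dirichlet draws on the
4-simplex, and bulk β is the convex combination Σ_c w_c β_c.

Default set fractions are NEU 2.5%, MG 2.5%, OLIG 0.6%, AST 0.6% (≈ 6%
of CpGs in a set, with the oligodendrocyte/astrocyte sets several-fold
smaller than the neuron/microglia sets, mirroring the relative sizes of
real high-specificity panels; exact per-set sizes are a modeling choice).

**DMP calling** is a per-CpG OLS of bulk β on a disease indicator,
optionally with the mixing weights as covariates (three of four columns
— the last is dropped since rows sum to 1). Fitting is vectorized via a
shared QR decomposition; the group coefficient's two-sided t-test p-values
are BH-adjusted, DMPs = {adjusted p < 0.05}. Constant columns get p = 1.
Betas, not M-values, are regressed here.

**Weight perturbation.** The correction's sensitivity to composition
estimation error is modeled by corrupting the true weights before using
them as covariates. The default convention is noise *proportional to the
weight*: w′ = w·(1 + N(0, SD)), floored at 0 and renormalized to the
simplex (an all-zero row becomes uniform). Under the composition-shift
design this yields a mean per-sample RMSE of ≈ 0.12 at SD 0.6, the
calibration point that fixed the convention; plain additive noise
(w′ = w + N(0, SD), same floor/renormalize) is available via
`mode="additive"` and produces a much larger RMSE (≈ 0.25) at the same
SD. The RMSE is the per-sample root-mean-square deviation over the four
proportions, averaged over samples.

**Experiment 1 — composition shift.** Control weights ~ Dirichlet(1,1,1,1),
disease weights ~ Dirichlet(1,2,2,2): the three glial proportions rise
and the neuronal proportion falls (mean 1/4 → 1/7), while all CpG
generating distributions are identical between groups, so composition is
the only group difference. Per iteration DMPs are called uncorrected and
corrected-with-perturbed-weights across a noise grid (default 0–1.5),
each DMP list is scored by ORA against the simulated sets, and medians /
IQRs over iterations are reported with the mean RMSE per noise level.
*Which* cell types surface as spuriously enriched in the uncorrected
analysis depends on the interplay of set sizes and the weight shift and
varies between runs; the robust, tested property is that the uncorrected
analysis produces spurious set enrichment, exact correction removes it
entirely, and heavily noised correction (SD 1.5) drifts back toward the
uncorrected results.

**Experiment 2 — input size.** Both groups share Dirichlet(1,1,1,1)
weights. A known number of DMPs (grid 2, 4, …, 1024) is designated by
largest-remainder apportionment of the allocation 50% neuron set / 20%
microglia set / 0.1% each oligodendrocyte and astrocyte set / 29.8%
background (ties in the remainder broken in that fixed category order),
and the disease-group bulk at designated CpGs is shifted by
`effect_delta` (default 0.2; the validation runs use 0.3) and clamped to
[0, 1]. A `designate_only` mode skips the shift and feeds the designated
list directly, isolating ORA sensitivity from calling power. Only the
corrected analysis (true weights) is run.

## Synthetic purified cohorts (fixtures)

Two cohorts, one sample per donor × cell type, ages ~ N(82, 9) (clipped
to 60–105), balanced sexes, β ~ truncated-normal(µ + donor effect,
within-type SD 0.03); the donor effect is a per-(donor, CpG) intercept
of SD 0.02 on the beta scale, shared across the donor's four samples.
Planted categories are parameterized clear of the 0.1/0.9 thresholds
(high-specific targets in [0.2, 0.8], extremes ≤ 0.05 or ≥ 0.95) so that
recovery tests measure the classifier, not threshold knife-edges; a
separate borderline generator places noise-free medians exactly on the
thresholds to pin the strict-inequality tie behavior. "Low-only" CpGs
are intermediate in all four cell types with the target mean 0.3 above
the (equal) others, so only the mixed-model route can annotate them.

The generator emulates the *structure* of purified-nuclei array data —
cell-type-specific intermediate/extreme methylation, donor random
effects, two cohorts — not its full realism: no probe-type or batch
artifacts, no correlated CpGs, no cohort-specific universes, no
bimodal genome-wide beta distribution. Passing recovery tests therefore
demonstrates correctness of the classification logic under the stated
generative model, not performance on real arrays.

## Scales, seeds, numerical choices

* Test and validation runs use 20,000 simulated CpGs (the generating
  model is per-CpG independent, so behavior scales linearly); the
  package default of 200,000 CpGs and the full 2–1024 grid are available
  through `SimulationConfig`.
* All randomness flows through `numpy.random.default_rng` seeds;
  identical config + seed gives bit-identical datasets, experiment
  tables and permutation nulls.
* M-value clamp ε = 1e-6; gap tolerance 1e-9; hypergeometric p floored
  at the smallest positive double and capped at 1.
* The six-fold Bonferroni factor treats the six pairwise comparisons of
  one CpG as the family; genome-wide correction across CpGs is the
  caller's choice via the `bonferroni_factor` argument.

## Known limitations

* The mixed-model contrasts use a normal (Wald) reference distribution,
  as statsmodels provides; with 20 donors the difference from a
  t-reference is small but p-values near α can differ marginally from
  other software (e.g. nlme-based fits).
* Real panels cannot be reproduced without the original purified-cohort
  data; the package validates the algorithmic pipeline on synthetic
  cohorts only.
* The background universe retains all-hypo/all-hyper CpGs (they are
  ineligible for sets but remain valid background members).
* ORA treats the DMP list as binary; graded or rank-based enrichment is
  out of scope.
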