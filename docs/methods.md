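# Methods

## Deconvolution model

A bulk transcriptome is modelled as a mixture of cell types drawn from a
healthy bone-marrow reference. For shared genes `g` and reference types
`k`, with `θ_gk` the cross-donor mean relative expression of a single cell
(columns of θ sum to 1), `σ²_gk` the cross-donor variance of the
donor-level relative profiles, `S_k` the mean per-cell library size and
`p_k` the unknown cell-count proportions:

```
E[y_g] ∝ Σ_k p_k S_k θ_gk,     p ≥ 0, Σ p = 1
```

where `y` is the bulk sample's relative expression (counts divided by their
sum). The design matrix has columns `θ_k·S_k`, each rescaled to unit column
sum; on the full gene set that rescaling factor is exactly `S_k`, so the
fitted coefficients estimate mRNA-mass fractions `p_k·S_k` (up to a global
scale) and dividing by `S_k` before normalizing returns cell-count
proportions. Under partial gene overlap the rescaling additionally absorbs
each type's signature mass on the shared genes; this second-order
correction is deliberately left in the column rescaling rather than in the
final division, keeping the coefficient-to-proportion map the simple
`x_k / S_k`.

### Iterative re-weighting

Genes are not equally reliable: a gene whose relative expression varies
between reference donors, or which the current fit explains poorly, should
influence the solution less. Starting from an unweighted NNLS solution,
each iteration recomputes per-gene weights

```
w_g = 1 / (ν + r_g² + Σ_k c_k² σ²_gk)
```

with `r_g` the current residual and `c_k = x_k S_k / t_k` the current
coefficients mapped back to the unrescaled `θ·S` scale (`t_k` the design
column sum), then re-solves the weighted NNLS. The relative bulk vector is
multiplied by 100 before fitting so that the variance floor `ν = 1e-4`
sits on the conventional scale for this family of estimators. Iteration
stops when no proportion moves by more than `convergence_tol = 0.01`, or
after `max_iter = 1000` weighted solves; non-converged samples keep their
last iterate and are flagged, never dropped. `max_iter = 0` returns the
plain unweighted NNLS solution (the unweighted limit used for
cross-checking). The inner solver is the exact Lawson–Hanson active-set
NNLS (scipy), applied to the square-root-weighted system, so the whole
procedure is deterministic.

Counts enter non-log and no further normalization is applied beyond the
conversion to relative expression — consistent with the convention of
deconvolving raw count scale data with the engine's normalization option
off. The gene intersection between bulk and atlas is case-sensitive and
its size is logged and returned: with signature spaces of only a few
hundred genes, a silently small overlap is the dominant practical failure
mode, and `min_common_genes = 100` aborts clearly instead.

### Reference construction

Donor-level profiles, not pooled cells, define the signatures: for each
donor and type, the mean count vector over that donor's cells of the type
is converted to relative expression; `θ` is the across-donor mean and `σ²`
the across-donor variance (unbiased, ddof 1; zero with a single donor).
This weights each donor equally regardless of cell yield. A pooled-mean
mode exists behind a flag for comparison. Per-type cell size is the mean
total count of a cell of that type. Types with fewer than
`min_cells_per_type = 10` cells are dropped (variance estimates from a
handful of cells are degenerate); genes with zero expression in every type
carry no design information and are dropped. Cell-type and donor labels
are processed in sorted order, making the atlas invariant to the input
cell ordering.

Note one approximation this estimator implies: because each donor profile
is renormalized on the full gene set, restricting genes *before* building
the reference does not exactly equal restricting the built reference and
renormalizing — the two differ by the donor-to-donor spread of the
renormalization factors (exact equality holds with one donor). The test
suite checks the single-donor identity exactly and the multi-donor
agreement to 5%.

### Phenotype assignment

Each sample's phenotype is its most abundant estimated cell type (row
argmax). Exact ties take the first type in atlas column order and set a
tie flag.

## Synthetic atlas

The generator emulates a targeted-panel single-cell survey of healthy
marrow from a few donors. Per type, a log-normal baseline mean profile
(sdlog 1) is up-scaled by `2^f` on that type's `m` dedicated marker genes;
each donor contributes an independent log-normal multiplicative effect per
gene (`subject_sd = 0.25` on the natural-log scale, a moderate
inter-individual variability); each cell draws a log-normal library size
(median 2000 counts, sdlog 0.5 — typical for a few-hundred-gene panel) and
negative-binomial counts (dispersion 0.25, i.e. variance `μ + 0.25μ²`)
around the type/donor relative profile scaled to that library size.
Defaults are the benchmark conditions: K = 8 types, S = 3 donors, G = 400
genes, m = 10 markers/type at f = 3 (8-fold), 40 cells/type/donor.

What the generator does *not* emulate: malignant transcriptional programs
(the framework deliberately deconvolutes against healthy signatures only),
transcriptionally adjacent types with overlapping marker programs (real
erythro-myeloid progenitors blur into neighbouring stages; synthetic types
are cleanly separated), dropout structure beyond NB noise, batch effects,
and platform mixtures. Passing the recovery benchmark therefore
demonstrates correctness of the estimator under its own model assumptions
— not field performance on real marrow, where signature collinearity is
the binding constraint.

### Pseudobulk schemes

The overabundant scheme draws `round(frac·n)` cells of a target type with
replacement and distributes the remaining cells over the other types with
weights proportional to `1 / n_available(type)` (renormalized), so rare
types are deliberately over-represented in the minor fraction; fractional
allocations are resolved by largest-remainder rounding, which conserves
the total exactly (ties by position). The per-individual scheme simply
sums one donor's cells. Matrices flagged as log-scale integrated
expression are exponentiated with `expm1` before any sampling or summing
(natural-log1p convention; the base is configurable since conventions
differ between toolchains).

## Drug-resistance stage

Per drug, AUCs are min-max normalized to [0,1] (higher = more resistant)
and predicted from the K composition columns by a random-forest regressor
under leave-one-out cross-validation: 500 trees, `floor(K/3)` (at least 1)
features per split, unlimited depth — the conventional regression-forest
defaults. Each fold is seeded by a CRC-32 hash of `(global seed, held-out
sample id)` and samples are processed in sorted-id order, so predictions
are reproducible and invariant to input ordering. Performance is the
Spearman ρ (mid-rank ties, two-sided t-approximation p) between held-out
predictions and observations.

A caution on permutation nulls for LOOCV correlations: the n held-out
predictions share almost all their training data, so they are mutually
dependent, and the null spread of ρ is wider than the independent-sample
heuristic `1/√(n-3)` suggests. Null calibration checks in this package run
20 response permutations with 100-tree forests (the null width is a
property of the LOOCV dependence structure, not of forest size) and
report the 95th percentile of |ρ|; expect that percentile to land near or
above 0.2 at n = 100 even for a perfectly uninformative predictor.

Association utilities: per-class linear regression of observed on
predicted resistance (classes under 4 samples skipped); per-(type, drug)
univariate regressions of normalized AUC on a composition column with
Benjamini–Hochberg FDR across all pairs.

## Associations, signatures, batch correction, survival

* **Univariate / multivariate models** — ordinary least squares on a
  min-max-normalized response; slope t-test p-values; BH correction across
  attributes in the univariate ledger. The multivariate model refuses
  exactly collinear designs (rank check) and records excluded terms.
  Categorical attributes are expected one-hot encoded against a declared
  reference level by the caller.
* **Signature score** — `score_s = Σ_g w_g · log2(cpm_gs + 1)` over the
  signature genes present (missing genes warned, none present is an
  error). Weights are user-supplied configuration; log2(cpm+1) is the
  declared transform, making the score library-depth invariant.
* **Batch correction** — per feature, the per-batch mean deviation from
  the feature's grand mean is subtracted, preserving the grand mean and
  removing an additive batch shift exactly; intended for log-scale
  abundances.
* **Median split** — score > median → high, ≤ median → low (deterministic
  tie rule); constant scores are an error.
* **Survival** — product-limit Kaplan–Meier per group and the unstratified
  multi-group log-rank chi-square with (groups − 1) df (lifelines).
  Group selection (phenotype, median-split score, treatment subgroup) is
  an upstream metadata filter, not baked into the test.

## Bulk preprocessing

ERCC spike-ins and mitochondrial genes are removed (explicit flags, or the
conventional `ERCC-` / `MT-` prefixes case-insensitively), identifiers are
mapped to symbols by a user-supplied table (no annotation release is
assumed), and among rows sharing a symbol only the one with the largest
per-gene standard deviation across samples survives — the less variable
duplicates carry less information. The SD is computed on raw counts with
ddof 0 by default (configurable; the scale is a convention, not a result).
The operation is idempotent. CPM normalization scales each sample to one
million; signature scoring runs on cpm before symbol conversion matters.

## Problem sizes and numerical choices

The shipped validation drivers use: 1200 pseudobulks (50 per type × 8
types × fractions 0.2/0.5/0.8, 1000 cells each) for proportion recovery;
n = 100 samples, one-hot effect, 10%-of-signal-SD noise for the drug
stage, with a 20-permutation null; 100 replicates of n = 200/arm
exponential survival at hazard ratio 4 for log-rank power; 200 null drugs
× 5 types for association type-I calibration. Tolerances: ECC rows sum to
1 within 1e-6; library-scaling invariance to 1e-8; solver-vs-grid-oracle
agreement to 2e-3 at grid step 1e-3; statistics oracles to 1e-10.
Tabular output is TSV with 6 significant digits; the atlas file stores
full double precision for exact round trips.

## Known limitations

* Healthy-reference design: malignant programs not spanned by healthy
  signatures are absorbed into the nearest healthy types by construction.
* The weight update's functional form is pinned in code (above); other
  engines in this family differ in detail, and the unweighted limit is
  exposed precisely so the two can be compared on any dataset.
* Gene-ID mapping is a required user input; no annotation liftover is
  performed.
* Transcriptionally similar types (progenitor continua) are not
  resolvable in principle; expect shared mass among neighbours rather
  than a wrong dominant call.
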