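# Methods

## The problem

Case-control studies of a complex disease often produce several genomic data
types for the same genes — here, microarray gene-expression intensities and
SNP genotypes — but from cohorts that need not share subjects, scales, or
even formats. `srcshave` selects disease-associated genes by moving both
data types into a common *feature space* of per-variable statistics and
clustering those feature vectors with a sparse-representation method, so the
evidence from both types can be weighed jointly.

## Feature space

For each variable (an expression probe, or a SNP under additive 0/1/2
minor-allele coding) the pipeline computes five statistics against the
case/control labels:

    y = [ sd_control, sd_case, |mean_case − mean_control|, |corr|, a ]

where `corr` is the Pearson (point-biserial) correlation between the
variable's values and the 0/1 status and `a` is the L2 norm of the
variable's sample vector. Standard deviations use the n−1 denominator;
correlations of constant variables are defined as 0; `corr` is stored as an
absolute value because its sign only reflects arbitrary probe/allele
polarity. Each feature row is min-max scaled to [0, 1] across variables
(a constant row maps to 0.5), then *oriented*: the two spread entries are
flipped (x → 1 − x) so that larger uniformly means more disease-relevant.

For the integrative analysis, every probe of a gene is paired with every SNP
of that gene (cross combination); each pair contributes one 10-entry column
stacking the probe block over the SNP block. Genes present in only one data
type are excluded from the combined analysis. A combined column's selection
is attributed to its gene, and a gene's score is the maximum over its
combination columns.

## Sparse-representation clustering

Columns are clustered against a designed dictionary `A` (the characteristic
matrix) whose column groups encode cluster prototypes by direction and
amplitude: cluster `k` owns the columns `amp · t_k` for an amplitude grid
`{0.25, 0.5, 0.75, 1.0}` and template `t_k`. Columns are deliberately not
L2-normalized — amplitude carries information. A query `y` is sparse-coded
by basis pursuit denoising,

    min ‖x‖₁   s.t.   ‖A x − y‖₂ ≤ ε,

and assigned to the cluster whose own coefficients reconstruct it with the
smallest residual (ties to the lowest cluster index).

**Templates.** Only the two association entries (|Δμ|, |corr|) separate
signal from noise in oriented feature space: the within-group spreads and
the amplitude of a null variable carry no label information and, after
min-max scaling, scatter around 0.5 whether or not the variable is
disease-associated. The per-block templates therefore pin those three
entries at the null centroid 0.5 and discriminate on the association
entries: significant block `[0.5, 0.5, 1, 1, 0.5]`, background block
`[0.5, 0.5, 0.05, 0.05, 0.5]` (the 0.05 floor keeps the column nonzero; a
zero-association template would be a zero direction). An earlier design
with spread/amplitude entries pinned at 1 mis-assigned half-significant
combined columns and mid-range nulls to the significant cluster; the
centroid calibration fixed both failure modes on the synthetic benchmark.

For `b` stacked blocks the default dictionary takes every combination of
per-block patterns as a cluster (`c = 2^b`), ordered with the
all-significant cluster first. In the integrative analysis (b = 2) this
yields four clusters — significant in both, expression only, SNP only,
neither — and only the all-significant cluster is kept, which is what lets
the combined analysis demand joint evidence rather than a strong signal in
either type alone.

**Solver.** For ε > 0 the constrained problem is solved through its
penalized (lasso) form: the residual of the lasso path is nondecreasing in
the penalty λ, so a bisection on λ (55 steps, warm-started) finds the point
where the constraint is active; inner solves use FISTA (tolerance 1e-11,
≤1500 iterations), vectorized across the columns of a window. For ε = 0 the
problem is the basis pursuit linear program, solved exactly by HiGHS. The
default tolerance rule is ε = 0.05·‖y‖₂, clipped from below at the
attainable least-squares residual: a designed dictionary spans only `c`
directions, so a generic feature vector cannot be reconstructed to
arbitrary accuracy and an unclipped rule would be infeasible. An explicit
user-supplied ε is strict and raises an error when unreachable. The
classifier (below) uses a coarser solver budget (28 bisections, tolerance
1e-9); residual *comparisons* are insensitive at that level while objective
values, which the tests check against an independent solver to 1e-4, use
the full budget.

## Sliding-window shaving

One iteration slides a window (default 500 columns, step 250, plus a tail
window so every column is covered) across the feature matrix; within each
window the rows are re-scaled to the window's own min-max range (local
contrast), columns are sparse-coded, and every column assigned to a kept
cluster is marked selected. A column's frequency increases by one per
iteration if it was selected in at least one window of that sweep — counting
per window instead would reward interior positions, which fall in two
overlapping windows, over edge positions, which fall in one. Between
iterations the columns are reshuffled with an explicit Fisher-Yates pass
(swap schedule i = n−1…1, j ~ U{0..i}) so window composition is not tied to
input order.

After each iteration from the second onward, the cumulative top-k gene list
is compared with the previous iteration's by percentage similarity,
PS = 100·|a ∩ b| / max(|a|, |b|); the loop stops when PS reaches the
threshold (default 90%) or at the iteration cap (default 50). Ranking is by
frequency (descending), ties broken by oriented-feature sum (descending)
then key; gene-level scores are the maximum over the gene's columns. An
optional multi-round mode re-runs the loop on the surviving (ever-selected)
columns until a user floor is reached.

## Classification validation

Selected panels are validated with the sample-dictionary
sparse-representation classifier: training sample vectors (restricted to
the panel) form the dictionary columns, unit-normalized and grouped by
class; a test vector is sparse-coded and assigned to the class with the
smaller masked residual (ties to controls). All-zero training vectors are
dropped; a class left without columns is scored by the bare residual ‖y‖.
Accuracy is the classification ratio (CR), percent of correctly classified
samples, estimated by leave-one-out cross-validation. Selection is run once
on the full data set and *not* re-run inside folds; the resulting selection
bias is deliberate (it mirrors the common validation design this package
evaluates) and documented in the README. Baselines: Welch's unequal-variance
t-test for expression; two-sided Fisher exact tests on 2×2 allele-count
tables (each sample contributes two alleles) for SNPs; a nearest-centroid
classifier and random panels for ablation.

## Synthetic cohorts

The generator emulates a two-cohort integrative study at desk scale:
200 genes with 1-2 probes and 1-3 SNPs each, an expression cohort of
40 cases + 40 controls, a genotype cohort of 70 + 70 (disjoint subjects by
default; shared on request for combined classification). Expression is
Normal(0, σ) noise, genotypes are Binomial(2, f) with per-SNP MAF uniform
on [0.1, 0.4]. A planted risk gene shifts the case mean of all its probes by
`d·σ` and/or the case allele frequency of all its SNPs by Δf. The gene-map
layout is drawn from a fixed internal stream so different seeds change the
sampled values but never the shapes.

Two stock configurations drive the benchmark experiments:

* **benchmark**: 10 planted genes with d = 2 and Δf = 0.2 in both types —
  strong, jointly visible signals for recovery tests;
* **integration**: 14 genes with a strong expression-only effect (d = 2),
  14 with a strong genotype-only effect (Δf = 0.25), and one gene weak in
  both (d = 1.0, Δf = 0.15). The decoys are strong and numerous enough to
  saturate the single-type top-10 lists with margin for sampling noise, so
  the weak gene can only surface through the combined analysis — the
  designed, testable analogue of the integration-advantage claim.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, eQTL coupling between a gene's SNPs and its expression, batch or
array effects, non-Gaussian expression noise, and population structure.
Passing tests therefore demonstrate the machinery's behavior under clean
additive signals, not robustness to those real-data phenomena.

## Numerical and design notes

* Cluster-assignment ties and class ties break toward the lower index
  (cluster 1, class 0); ranking ties break by feature sum, then key, so all
  outputs are deterministic for a fixed seed.
* Whole-matrix row scaling precedes shaving; windows re-scale locally by
  default. In a window of near-identical columns local re-scaling amplifies
  measurement noise to full range — with the default large windows this is
  negligible, but very small windows on homogeneous data will produce
  spurious significant assignments.
* The frequency signal saturates quickly (most informative columns are
  selected every sweep once assignments are stable); the ranked list's
  tie-break then carries the remaining resolution. This is why the PS
  criterion typically stops after two or three sweeps on clean synthetic
  signals.
* Problem sizes in the test-suite experiments (200 genes, ≈600 combined
  columns, 5 seeds) were chosen as the smallest configurations at which the
  planted-recovery and integration properties are stable across seeds.
* Degenerate inputs: constant variables get corr 0 and p = 1 in baselines;
  constant feature rows scale to 0.5; empty gene maps yield empty combined
  matrices and empty selections; monomorphic SNPs get Fisher p = 1.

## Known limitations

* The characteristic-matrix templates are calibrated to min-max-scaled
  oriented features; feeding unscaled features produces meaningless
  assignments (the API enforces the scaled/oriented flags).
* With disjoint cohorts the combined *classification* is undefined (no
  subject has both data types); combined classification requires
  shared-sample data, as in the shared-samples generator mode.
* LOO after whole-data selection overstates absolute accuracy; comparisons
  *between* selectors evaluated the same way remain meaningful.
* The selection loop's stopping rule compares cumulative lists, so very
  long runs cannot oscillate, but an adversarial near-tie between two genes
  at the list boundary can delay convergence to the iteration cap.
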