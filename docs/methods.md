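# Methods

## The influence model

A miRNA represses its direct targets by binding miRNA response elements
in their 3'UTRs; because the encoded proteins act inside complexes and
functional modules, the perturbation reaches the interaction partners of
those targets as well.  `mircontext` encodes this *context-specific
effect* per miRNA as a column over a common gene universe: 1 for a
direct target, `w_indirect` for a gene that is only a one-hop
protein-interaction partner of a direct target, 0 otherwise.  A gene
that is both direct and indirect is recorded as direct — the stronger,
better-evidenced mode — so no cell is double-counted.

Expansion is deliberately one hop.  Multi-hop diffusion mixes in ever
more of the network and erases the distinction between miRNA columns;
the partners of the direct targets are the part of the footprint with a
concrete mechanistic reading (same complex or module as a repressed
protein).

The gene universe defaults to `ppi_restricted`: genes that are targeted
by at least one miRNA *and* appear in the protein network.  Genes with
no interaction data contribute no context signal and would only dilute
the response; the `union` mode (all targeted genes) is kept for
direct-targets-only baselines, which otherwise lose most of their rows.
miRNA columns and gene rows left without support are dropped and
logged, so the design matrix never contains all-zero rows or columns.

A gene signature is aligned to the universe as a 0/1 membership vector.
Membership is the minimal encoding that makes "these genes are of
interest" a regression response; genes of the signature outside the
universe are reported as dropped, and a coverage below 10% triggers a
warning because the fit then explains only a sliver of the list.

## Fitting and model selection

The response is regressed on the influence columns with the elastic
net under the glmnet objective convention,

    (1/2n)‖y − β0 − Xβ‖² + λ Σ_j [½(1−α)β_j² + α|β_j|],

with an unpenalized intercept.  The mixing value α trades off the
lasso's sparsity against the ridge's tolerance of correlated columns;
context target sets overlap heavily, so an intermediate α is essential —
pure lasso would arbitrarily pick one member of a family of related
miRNAs.  The default is α = 0.6; `alpha="auto"` scans a 20-point grid
and keeps the smallest α from which the cross-validated λ-min stays
within 5% relative change across all larger grid values (the point where
the selection has stabilized), falling back to 0.6 with a warning when
the curve never settles.

λ is selected on a 100-value log-spaced path from λ_max (the smallest
penalty that zeroes every coefficient, `max_j |⟨x_j, y−ȳ⟩|/(n·α)` with α
floored at 10⁻³ so the ridge limit keeps a finite anchor) down to
λ_max·10⁻⁴, by 10-fold cross-validation minimizing mean squared error.
λ-min, not λ-1se, is the target; ties prefer the larger (sparser) λ.
Folds are assigned deterministically from the seed and stratified on the
response so every fold contains signature members; a fold whose training
response is constant is skipped with a warning, and more than half the
folds skipped is an error.

Predictors are scaled to unit (population) variance before fitting and
coefficients reported back on the original scale; the binary response is
centered but not scaled.  Constant columns are dropped with a warning
and get coefficient zero.

The solver is cyclic coordinate descent with soft-thresholding, run on
precomputed Gram products (the gene dimension far exceeds the miRNA
dimension, so covariance updates are cheapest), warm-started from larger
to smaller λ, with an active-set inner loop.  Convergence is declared
when the largest coefficient change in a full sweep drops below `tol`
(default 10⁻⁷ on the standardized scale, `max_iter` 10,000 sweeps);
non-convergence raises a warning, never passes silently.  The inner
loops are JIT-compiled with numba.  Correctness is pinned by tests
against a bound-constrained L-BFGS-B minimizer of the identical
objective (split positive/negative parts), the ridge closed form, the
least-squares limit, the exact-zero property at λ ≥ λ_max, and
scikit-learn's implementation of the same objective.

## Ranking and the ORA baseline

miRNAs are ranked by signed β descending with lexicographic ties:
positive influence means enrichment, negative coefficients are reported
but rank below zero, and zero-coefficient miRNAs are still ranked so
every miRNA has a well-defined position.  The hypergeometric baseline
computes, per miRNA, the upper-tail probability of the observed overlap
between its (context or direct) target set and the signature, on exactly
the design-matrix universe — so the regression and the baseline are
compared on identical information, and the difference between them is
the joint, penalized fit, not the data.

## Batch associations and evaluation

Batch mode fits one signature at a time and keeps an edge for every
nonzero coefficient.  The 0.5-coefficient threshold (strictly greater)
is available where only strong associations are wanted, but counts and
AUC are computed on the unthresholded network.  Against a gold standard,
common/missed/novel are plain set arithmetic; AUC is the Mann–Whitney
statistic (ties ½) over an explicit candidate space — by default the
network's signatures crossed with a supplied miRNA universe — scoring
absent pairs 0.  The negative set is made explicit because association
gold standards define positives only.

## Synthetic data

The generator emulates the input layers at a configurable scale
(defaults: 305 miRNAs, 3,235 genes; the `small` preset is 100 × 1,500).
Choices and what they emulate:

- **Protein network**: Barabási–Albert preferential attachment (mean
  degree 6) by default, because protein interaction degree
  distributions are heavy-tailed; Erdős–Rényi is available as a null.
- **Targets per miRNA**: uniform in (60, 120) — prediction databases
  assign tens to a few hundred conserved targets per miRNA family.
- **Hub bias** (default 1.0): target-site sampling probability
  ∝ 1 + hub_bias · degree, reflecting the observation that highly
  connected proteins are targeted by more miRNAs; 0 gives uniform
  sampling, and the correlation it induces is itself under test.
- **Planted signatures**: 60 direct + 20 indirect + 20 noise genes by
  default, sampled without replacement from the planted miRNA's pools.
  Noise genes are drawn from in-universe genes outside the planted
  context — genes outside every context would be dropped by universe
  restriction and provide no interference.
- **Gold corruption**: each true edge dropped with `gold_fn_rate`;
  `round(|true|·gold_fp_rate)` spurious pairs added.

What the generator does *not* emulate: expression-derived signature
noise structure (signatures are exact gene sets, not thresholded
differential-expression calls), database-specific target-prediction
biases, direction of regulation, and any clinical covariates.  Passing
the planted-recovery tests therefore shows the machinery identifies the
responsible miRNA when the signature genuinely derives from its context
footprint — not that any particular prediction database is accurate.

All generated identifiers are zero-padded (`G0001`, `miR-0001`) so
lexicographic tie-breaks are deterministic.  In the recovery experiments
the planted miRNA is placed mid-list (`miR-0050`), so the tie-break
among zero coefficients can never hand it its rank for free.

## Problem sizes and determinism

The bundled experiments run at the reduced preset (100 miRNAs × 1,500
genes, 50 replicates in the test suite, 15–20 in the acceptance script),
which preserves the column-overlap regime of the full scale while
keeping a laptop run in minutes.  Every random draw — network, targets,
signature sampling, fold assignment, gold corruption — flows from one
root seed through named substreams, and the command-line pipeline is
byte-reproducible: two runs with the same seed produce identical files
(floats are written with a fixed 10-significant-digit format).

## Known limitations

- Symbol-level only: no identifier mapping; inputs must share a gene
  namespace.
- One-hop expansion with a single global `w_indirect`; no per-edge
  confidence weights from source databases.
- Squared-error loss on a binary response (the linear probability
  model), chosen for its direct coefficient interpretation and convex
  path structure; no logistic family.
- The α stabilization search is a heuristic on a discrete grid; on weak
  signals it falls back to the 0.6 default rather than failing.
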