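# mircontext

Protein-network-aware miRNA enrichment analysis.

Given a list of genes of interest — genes repressed after pre-miRNA
transfection, a disease signature, a pathway gene set — which miRNAs are
driving it?  Classical over-representation analysis (ORA) tests each
miRNA's direct target set against the list with a hypergeometric test,
one miRNA at a time.  `mircontext` instead models the *context-specific
effect* of each miRNA — its direct targets plus the one-hop
protein-interaction partners of those targets — and fits all miRNAs
jointly with a regularized regression, so that correlated, redundant
miRNA target sets compete for the signal instead of each being called
significant on its own.

## Model

Let X be the gene × miRNA influence matrix: `X[g, j] = 1` if gene *g* is
a direct target of miRNA *j*, `w` (default 1) if *g* is only a
protein-interaction partner of a direct target, 0 otherwise.  A gene
signature is encoded as the 0/1 membership vector *y* over the matrix's
gene universe.  The influence coefficients β solve the elastic net

    min_{β0, β}  (1/2n) ‖y − β0 − Xβ‖² + λ Σ_j [ ½(1−α)β_j² + α|β_j| ]

(α = 1 lasso, α = 0 ridge; the intercept β0 is unpenalized).  λ is
chosen by 10-fold cross-validation (minimum mean squared error over a
100-value log-spaced path); α defaults to 0.6 and can be selected
automatically by the λ-min stabilization rule over a 20-point grid.
miRNAs are ranked by β descending: a large positive coefficient means
the miRNA's context targets are enriched in the signature.

The solver is cyclic coordinate descent with soft-thresholding on
precomputed Gram products, warm-started along the λ path and verified in
the test suite against an independent convex optimizer, closed-form
ridge/least-squares limits, and scikit-learn.

## Worked example

Generate a synthetic dataset with a planted miRNA, build the influence
matrix, and recover the planted miRNA from the signature:

```sh
mircontext simulate --preset small --seed 42 --out-dir sim
mircontext build-net sim/targets.tsv sim/ppi.tsv --out-dir net
mircontext enrich net/matrix.tsv sim/signature.txt --alpha 0.6 --seed 42 --top 5 --out-dir enrich
```

which prints

```
n_genes=1500	n_mirnas=100	n_direct=9089	n_indirect=66932
# signature=signature alpha=0.6 lambda=0.0151606 nonzero=8 coverage=1.00
mirna_id	beta	rank	target_count_direct	target_count_context
miR-0001	0.0739284	1	73	658
miR-0005	0.0134476	2	61	597
miR-0019	0.0101652	3	62	610
miR-0090	0.0068192	4	109	847
miR-0003	0.00203874	5	93	777
```

The matrix covers 1,500 genes × 100 miRNAs with 9,089 direct and 66,932
indirect influence entries.  Cross-validation selected λ ≈ 0.015, leaving
8 miRNAs with nonzero influence; the top-ranked miRNA (β ≈ 0.074, an
order of magnitude above the runner-up) is exactly the planted one
recorded in `sim/truth.tsv`.  Batch mode (`mircontext associate`) runs
the same fit over a GMT collection to build a signature–miRNA
association network, which `mircontext evaluate` scores against a gold
standard (common / missed / novel edge counts and AUC).

Real data drop in the same way: a 2-column miRNA→gene TSV (e.g. cut from
TargetScan or miRTarBase exports), a 2-column protein-interaction TSV
(e.g. Reactome functional interactions), and gene lists or GMT files
with HGNC symbols.

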