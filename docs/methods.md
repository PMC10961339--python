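# Methods

## The model

`mpkit` studies transcriptional heterogeneity that recurs across
independent single-cell studies of related diseases. The unit of analysis
is the *gene program*: one factor of a non-negative matrix factorization
(NMF) of a gene × cell expression matrix, summarized by its 50
highest-coefficient genes and interpreted as a co-expressed gene module.
The pipeline has four stages.

**1. QC and normalization.** Per study, genes detected (count > 0) in 5 or
fewer cells are removed; cells whose expressed-gene count falls strictly
below the 2nd or strictly above the 98th percentile of the per-cell
distribution are removed; each surviving cell is scaled to a common total
(10,000 counts) and log(1+x)-transformed. The percentile rule is applied
per study, with linear interpolation, and cells exactly at a bound
survive. The 2%/98% rule is read as percentiles of the per-cell
expressed-gene-count distribution — the conventional QC reading — rather
than fractions of the gene universe.

**2. Program extraction.** Each study is factorized at every rank in
k = 4..9, giving 4+5+…+9 = 39 programs per study. The input to NMF is the
log-normalized matrix restricted to the most variable genes (default
3,000), centered per gene and clipped at zero — a non-negative
relative-expression representation in which factors capture co-varying
modules rather than baseline expression. Factorization uses coordinate
descent with deterministic NNDSVD initialization (scikit-learn), so the
grid is exactly reproducible under a fixed seed. Within a factor, the top
50 genes are selected by coefficient, ties broken lexicographically by
gene ID.

**3. Robust programs.** A program is *robust* when both hold:
(a) some program from the same study at a *different* rank shares ≥ 35 of
its 50 top genes (70% overlap) — same-rank duplicates do not count; and
(b) some program from a different study is more than 20% similar.
Cross-study similarity is the shared-top-gene fraction |A∩B|/50 (> 0.2
means more than 10 of 50 genes), consistent with the >10-gene clustering
threshold below; Jaccard similarity is available as a configuration
alternative. Witnesses for both criteria are recorded per retained
program. Comparing full coefficient vectors instead of top-gene sets was
the other defensible reading; sets were chosen because every downstream
threshold is stated in shared-gene counts.

**4. Meta programs.** Robust programs are clustered by greedy,
founder-based agglomeration. The founder of a new cluster is the
unclustered program with the greatest total top-gene intersection with all
other unclustered programs (ties: lexicographically smallest
(study, rank, factor)). The cluster grows by admitting the unclustered
program with maximal overlap to the cluster's *current consensus* — the 50
genes most commonly shared among members, ties broken by mean within-
member rank, then gene ID — as long as that overlap is strictly greater
than 10 genes; the consensus is recomputed after every admission.
Overlap-with-founder is available as a configuration alternative; overlap
with the consensus was chosen because it matches the "most commonly
shared" semantics of the MP gene set itself. Clusters with fewer than 2
members are not meta-programs (a cluster of one program is just a
program); their members are reported as unassigned. MPs are discovered
separately per disease entity and then compared across entities by shared
MP-gene counts: two MPs overlap by |A∩B| of 50 genes, reported as a
fraction of the MP gene-set size.

## Supporting statistics

**AUCell-style activity.** Per cell, genes are ranked by expression
(highest first; expression ties get average ranks by default, or a
seeded-random order). The score of a gene set is the area under its
recovery curve within the top `top_fraction` of ranks, normalized by the
maximal achievable area, giving a value in [0, 1] that depends only on
ranks — hence invariant to any monotone transformation of a cell's
expression. `top_fraction` defaults to 0.05, the upstream tool's
convention, and the integrated rank threshold is recorded in the output.

**Ro/e.** For a cell-group × condition contingency table, expected counts
are row_total × col_total / grand_total and Ro/e is observed/expected
elementwise; values above 1 indicate preference. Per-cell chi-square
contributions and Fisher exact tests on 2×2 collapses (group vs rest ×
condition vs rest) are reported alongside; the point estimate itself is
margin-based.

**Differential expression.** Per gene, a two-sided Wilcoxon rank-sum test
between two disjoint cell groups: exact null distribution when the number
of label arrangements C(na+nb, na) ≤ 10,000 and the combined values are
tie-free, otherwise the tie-corrected, continuity-corrected normal
approximation. Constant genes get p = 1 by convention. Log fold change is
the natural-log ratio of group means with a 1e-9 pseudocount; BH step-up
FDR across genes (the conventional reading of "FDR-adjusted"; the method
is configurable).

**Enrichment.** Upper-tail hypergeometric P(X ≥ k) for drawing k term
genes in an n-gene query from an N-gene universe containing K term genes,
BH-adjusted across terms, significant at FDR < 0.05. Query genes outside
the stated universe are warned about and dropped.

**Consensus malignancy.** A cell is malignant only when two independent
copy-number callers both say malignant, non-malignant only when both say
non-malignant, and ambiguous otherwise (disagreement or an uncallable
verdict). Ambiguous cells are always reported, never silently dropped;
"high-confidence" counts are the two concordant classes. The callers
themselves are inputs (TSV of cell → call), not reimplemented here.

## The synthetic generator

The generator emulates the statistical structure the inference assumes:
multiple studies per disease entity, cells that are non-negative mixtures
of sparse planted programs, and partial program sharing between entities.

Per entity it plants `n_programs_per_entity` programs of `program_size`
genes with log-normal(0, 1) coefficients (graded rankings, as NMF
coefficients would give). Each cell draws Dirichlet(α = 0.5) usage over
its entity's programs — sparse enough that most cells are dominated by one
program, as in real heterogeneous tissue — and its expected profile is
`library_size × [(1−b)·normalize(S·u) + b·uniform]` with background
fraction b = 0.05, so every gene has nonzero expected expression and the
QC stage has realistic work to do. Counts are negative binomial with
variance μ + μ²/φ, dispersion φ = 10 (moderate scRNA-seq overdispersion);
Poisson is available. Library size defaults to 2,000 counts; the default
recovery scenario uses 800 genes and 400 cells per study, sized so the
full three-entity, nine-study pipeline runs in well under a minute per
seed while leaving the factorization a genuinely noisy problem.

Cross-entity sharing: each configured entity pair is assigned one
dedicated program slot (round-robin over slots), and the two entities'
programs at that slot share exactly `round(fraction × program_size)`
genes. Hosting each pair's overlap on its own slot keeps arbitrary
overlap maps constructible — a single 50-gene program cannot simultaneously
owe 34 genes to one entity and 26 to another when those two entities share
nothing — and mirrors the situation the pipeline targets, where different
MPs carry different cross-entity relationships. The designated slots are
recorded in the truth, and recovered overlap is measured between the MPs
matched (best Jaccard) to planted programs, so leftover clusters of
residual factors do not contaminate the measurement.

Categorical labels (cell type, tissue, stage) are drawn per entity from
configurable distributions with built-in defaults (malignant entities
dominated by epithelial cells in tumor tissue, inflammatory entities by a
mixed epithelial/immune pool in inflamed tissue), so group-wise statistics
have structure to find. Randomness is a hierarchical stream keyed by
(entity index, study index) under one global seed: adding a study or an
entity never perturbs earlier studies' draws, and identical (config, seed)
pairs are byte-identical.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, gene-length or capture biases, realistic cohort compositions, or
correlated program usage. Passing recovery tests therefore shows the
inference machinery is correct under its own model assumptions — not that
the thresholds are optimal for any real cohort.

## Numerical choices and degenerate inputs

- NMF: `max_iter` 500, `tol` 1e-4; non-convergence emits a warning with
  the reconstruction error and the programs are still usable.
- All gene-ranking ties (top genes, MP consensus, founder selection) have
  documented deterministic tie-breaks, so every pipeline product is
  byte-identical across runs at a fixed seed.
- Degenerate inputs fail loudly: all genes filtered, zero-total cells
  (listed by ID), a contingency margin of zero, an empty gene-set/matrix
  intersection, overlapping DE groups, mismatched caller cell universes.
- A Dirichlet concentration of exactly 0 is treated as the one-hot limit
  (each cell uses a single uniformly drawn program).

## Known limitations

- The rank grid is fixed by configuration; there is no automatic rank
  selection or within-rank redundancy removal before robustness testing
  (the latter exists as an idea in consensus-NMF schemes but is
  deliberately not assumed here).
- Cross-study similarity and all clustering thresholds operate on top-gene
  sets; coefficient-level similarity is not implemented.
- The AUCell implementation densifies the matrix per scoring call; it is
  sized for tens of thousands of cells, not millions.
- Ro/e significance is reported via both per-cell Fisher 2×2 collapses and
  chi-square contributions without asserting either as canonical.
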