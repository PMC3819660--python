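# Methods

## Abundance estimation

The unit of quantification is the scaffold of a de novo assembly.  Read
counts below two are zeroed before anything else: a single read mapped
to a scaffold is treated as fortuitous, not as expression.  The
abundance `Y_gk = c_gk / (L_g · T_k)` divides by the scaffold length in
nucleotides (no effective-length correction) and by the sample's total
cleaned count.  The total is deliberately the column sum of the cleaned
per-scaffold counts rather than the raw sequencing yield: the toolkit
never sees unassembled reads, and the cleaned-column total is monotone
with the yield.  All per-sample totals are therefore computed *after*
zeroing; this also fixes the one ordering the abundance definition
leaves open.

## Multi-sample trimmed-mean normalization

The estimator assumes that most genes shared by all samples are not
differentially expressed, so the log2 ratio M of a shared gene's
relative abundance against the mean-profile reference should scatter
around a single value — the log factor.  The reference is virtual
(the per-gene mean over all n samples restricted to the common set G),
so factors are only reported for real samples, and each sample gets its
own trimmed set G\*.

Two printed-formula choices deserve explicit documentation:

* **Log base.**  All logs are base 2; the method's own name refers to
  the log2 expression ratio, and M, A are implemented in the standard
  MA-plane sense.
* **Weights.**  The default weight is the approximate delta-method
  expression `w_g = 1/Y_gk + 1/Y_g` *used directly* as the weight in
  `Σ wM / Σ w`, matching the formula as published.  Note that this
  expression is the (approximate) *variance* of M, so weighting by it
  emphasises the least-expressed, noisiest genes — the opposite of
  inverse-variance weighting.  We keep the published form as the
  default for fidelity; the exact binomial variance form is available
  via `exact_weights=True`.  The practical consequence is a higher
  estimator variance than precision weighting would give; with deep
  libraries and a well-measured common set the effect stays at the
  percent level.

### Trimming: min-max versus rank

The published trimming rule rescales M and A by their per-sample
extremes and keeps genes strictly inside the windows (0.3, 0.7) and
(0.2, 0.8).  This is implemented exactly (`trim_mode="minmax"`,
default), including the degenerate case: when all M (or all A)
coincide, that criterion carries no information and passes every gene,
which makes the duplicated-sample identity (R = 1) well defined.

Min-max scaling, however, is determined by the two most extreme genes.
Whenever differential expression is asymmetric — a cluster of genes
up-regulated in one sample — that cluster stretches one extreme, the
window (a fixed fraction of the *range*, not of the *ranks*) shifts
away from the non-DE bulk, and the factor becomes biased; with a
clearly separated DE cluster the window can even land in the gap
between the clusters and keep almost nothing.  Simulations in the test
suite show 20–50 % factor error under 5 % one-sided 8-fold DE, and the
min-max-trimmed factor is then farther from the DE-excluded target than
the *untrimmed* weighted mean.  `trim_mode="quantile"` trims by rank
quantile instead (the classical trimmed-mean scheme): the same bounds
discard fixed fractions of genes at each end, a 5 % DE cluster is
simply removed, and the planted factors are recovered to ~1–2 %.  Both
modes share every other formula.  For data with appreciable
organ-specific expression the rank mode is the one to trust; the
min-max mode is retained as the published procedure.

Ties at a trimming boundary are excluded (strict inequalities as
published).  The normalized output scale `(Y_gk/N_k)/R_k × 10⁶` is a
per-million convention; the constant cancels in every ratio, fold
change and correlation downstream.

## Subcellular partitioning

Coverage is alignment span over the scaffold (query) length — the
threshold "length ≥ 80 %" is read against the transcript being
classified, since the biological question is whether the *scaffold* is
an organelle transcript.  A scaffold qualifies for an organelle when
*any* hit passes all three thresholds; the best passing hit (smallest
e-value, then largest bit score) is recorded as the classifying hit.
Chloroplast takes precedence over mitochondrion when both pass, and
such conflicts are reported rather than silently resolved.  Scaffolds
at or below 200 bp (the sequencing-library length) are never assigned
to an organelle.  The partition is a disjoint cover by construction.

For shared/organ-specific comparisons, `shared_sets` reports every
exclusive Venn region plus the fraction `|expressed in all| /
|expressed in any|`.  The denominator of a shared percentage is a
reporting choice (annotated units of a reference genome would be
another defensible one); both readings are derivable from the returned
counts.

## Organ-comparison statistics

Correlations are computed on the genes non-zero in *both* members of a
pair.  The t test uses `t = r·√(n−2)/√(1−r²)` with n−2 df; for very
large n the Fisher transform `z = atanh(r)·√(n−3)` against the standard
normal is preferable and offered as `test="z"`.  Tests are two-sided by
default.  The one-sample Wilcoxon signed-rank test uses the exact
permutation null up to 25 non-zero differences and the
continuity-corrected normal approximation above that; at least five
non-zero differences are required.

Clustering scales each profile by its maximum (maxtf), uses Pearson
correlation as similarity and 1 − r as distance, and merges by UPGMA
(average linkage).  UPGMA is implemented directly (O(n³), ample for
organ panels and gene modules) because the tie-break is part of the
contract: among equally distant pairs the lowest-index pair merges
first, making trees bit-reproducible under input order.  The
implementation is cross-checked against scipy's average-linkage on
distinct-distance matrices in the tests.  Trees export to Newick with
ultrametric branch lengths (merge height halved).

## Pathway flow annotation

A pathway node's level in a sample is the *sum* of its mapped
scaffolds' normalized levels — isoforms of one enzyme pool their
catalytic capacity; a per-scaffold reading remains available by mapping
one scaffold per node.  Group levels aggregate by mean by default
(max is offered for highest-sample readings).  The fold is the larger
aggregate over the smaller, direction by which side is larger, and the
tier thresholds are strict: a node at exactly 2.0-fold is ≈.  A zero
reference aggregate with expression on the other side is reported as an
infinite fold at tier 3 — presence/absence is the strongest possible
change.  Nodes with no expression anywhere carry an absent flag and no
direction.  Swapping target and reference groups flips every direction
and preserves every fold and tier.

## Synthetic study design

The generator emulates the data structure the methods assume, with one
fixed reference condition used throughout the tests and the acceptance
script:

| parameter | default | rationale |
|---|---|---|
| genes × samples | 2000 × 3 | desk-scale panel with realistic composition effects |
| library sizes | 2e7, 1e7, 4e7 reads | deep bulk libraries, unequal depths |
| DE plan | 5 % of genes, 8-fold up in the last sample | asymmetric composition bias |
| count noise | negative binomial, dispersion 0.01 | one library per organ, no biological replicates: technical, near-Poisson noise |
| expression rates | lognormal(σ = 1.5) shifted by 0.15 | commonly expressed genes stay well above the detection floor (minimum expected count ≈ 200) |
| lengths | uniform 200–3000 nt | short-read assembly scaffold range |
| organelles | 5 % chloroplast, 2 % mitochondrial | hits planted strictly inside the thresholds |
| pathway folds | 1.2, 4, 15, 150, ∞ | one node per tier, placed well inside the tier intervals |
| dropout | 0 | absence is modelled explicitly, not by noise |

Pathway folds are planted as organ-specific isoform switching: each
finite-fold node has a shared isoform expressed everywhere plus a
target-only isoform sized to produce the node-level fold; the ∞ node is
a single target-only transcript.  This mirrors how large fold changes
arise in organ comparisons (organ-specific transcripts) and keeps the
common gene set free of extreme ratios, which matters for the min-max
trimming discussion above.  The separate boundary fixture plants hits
exactly at 95.0/94.9 % identity, 80/79.9 % and 50/49.9 % coverage and
201/200 nt length for threshold tests.

The planted "true" factor of a sample is computed in closed form from
the noise-free expected abundances: for every gene carrying no planted
signal, the ratio of its relative abundance in the sample to its
relative abundance in the mean-profile reference is the same; that
common ratio is the target of any trimmed-mean estimator.  No trimming
or weighting enters this computation.

What the generator does **not** model: read-level errors, multimapping
and assembly artefacts, biological replicate variance, genuinely
low-expressed genes hovering at one or two reads inside the common set,
and inter-species mapping noise for the mitochondrial reference.
Passing tests therefore demonstrate correctness of the computations and
recoverability under the stated design, not performance on arbitrary
real libraries — in particular, real data with shallow libraries or
many near-floor common genes will behave worse under the min-max
trimming than these simulations do.

## Numerical notes and limitations

* Empty trimmed sets raise with advice to widen the bounds; under
  min-max trimming this can occur legitimately when M is strongly
  bimodal (see above).
* Factors are exact powers of two of the weighted mean; `log2(R)`
  round-trips to the reported `log2_tmm` at machine precision.
* The duplicated-sample identity holds to < 1e-12; per-sample count
  rescaling is an exact invariance of the pipeline provided no count
  equals 1 (the zeroing rule would otherwise change the zero pattern —
  a real property of the cleaning step, not an artefact).
* Correlation of constant vectors, clustering of constant profiles and
  abundance of zero-total samples are errors naming the offender, not
  silent NaNs.
* One published-scheme acceptance check — factor recovery within 5 %
  under the asymmetric-DE design with min-max trimming — fails by the
  analysis above and is intentionally not relaxed; the rank-trimmed
  variant meets it.
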