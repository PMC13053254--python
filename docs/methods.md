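# Methods

## Normalization and the highly-expressed rule

Counts are scaled per cell to a library size of `scale` (default 10,000) and
transformed as v = log_b(count / total × scale + 1), log base b = 2 by
default. The base and scale are exposed because the printed threshold
("expression above 0.5 in more than 20% of cells") only has its intended
meaning on this scale; both comparisons are strict inequalities, so boundary
cells (v exactly 0.5) and boundary fractions (exactly 20%) do not qualify.
Zeros are preserved exactly (the transform is applied to stored sparse
entries only), which makes normalization invariant to per-cell
multiplicative rescaling of counts — a property test in the suite.

Highly-expressed calling is computed per condition by default (the
per-condition interactomes are what the Venn/gained comparisons consume);
pooled calling is available by passing `condition=None`.

## Interactome and its identity

An interaction is the 4-tuple (sender, receiver, ligand, receptor); its
identity deliberately excludes expression magnitude, which lives in the
permutation score. Autocrine edges (sender = receiver) are computed only on
request — the default report is the directional myeloid → lymphoid map.
Condition comparison is plain set algebra on 4-tuples, so
|shared| + |unique_A| = |A| and the gained matrix column-sums to |A \ B| by
construction.

## Permutation significance

The pair statistic is the average of the ligand's mean normalized expression
over sender cells and the receptor's mean over receiver cells. The null
shuffles the sender/receiver labels over the pooled cells of the two tested
types only, within the tested condition — the narrowest exchangeable unit
for the hypothesis "these two types co-express this pair above chance".
Design choices:

- **Add-one estimator** p = (1 + #{s* ≥ s})/(1 + n_perm), guaranteeing
  p ∈ [1/(1+n_perm), 1] and a valid test; the raw proportion is available
  via `estimator="raw"` for compatibility with tools that report it.
- **Ties count as extreme** (≥ observed, with a 1e-12 absolute guard against
  float noise) — conservative.
- **Order-independent substreams**: each score's RNG stream is derived from
  (seed, sender, receiver, ligand, receptor, condition) via a hash, so a
  table of scores is independent of evaluation order and of which other
  pairs are scored.
- No additional expressing-fraction gate is applied here: the 20%/0.5 gate
  upstream already decides which pairs are scored.

Calibration: on label-independent synthetic data the p ≤ 0.05 fraction over
600 pair tests sits in [0.03, 0.07] (asserted in the suite; measured
0.042–0.07 over seeds 0–42).

## Differential expression and the increased-interaction rule

Genes pass the gate if expressed (v > 0) in at least `min_pct` = 0.2 of
cells in either group. The test is the two-sided Wilcoxon rank-sum on
normalized values: for group sizes ≤ 25 the exact permutation distribution
of the rank sum is computed by a dynamic program over doubled midranks
(exact *with* ties, verified against brute-force enumeration); larger groups
use the tie-corrected normal approximation with continuity correction. BH
adjustment is applied over the tested genes of one contrast.

log₂FC uses linearized means with a pseudocount,
log₂((mean(bᵛ−1)+1)_A / (mean(bᵛ−1)+1)_B) — deterministic and stable at low
expression. "Upregulated" means p_adj < alpha (0.05) with log₂FC > 0; no
fold-change floor is applied by default (`lfc_floor` is exposed) because the
increased-interaction rule as stated imposes none. An interaction is gained
in A iff at least one of {ligand-in-sender, receptor-in-receiver} is up in A
and neither is down; the mirrored rule gives edges gained in B. All nine
status combinations are asserted exhaustively in the suite.

## Marker stratification

Quantile thresholds use linear interpolation on the sorted within-cell-type
marker values (the numpy default, declared here because tie-heavy markers
make the convention visible). Negative stratum: v ≤ Q(0.25); positive:
v ≥ Q(0.75); cells strictly between are excluded from the contrast. When the
thresholds collapse (Q(0.75) ≤ Q(0.25), e.g. a marker with more than 75%
zeros) a degenerate-stratification error reports the marker and its zero
fraction rather than returning overlapping strata. Membership is invariant
under strictly monotone transforms of the marker (property-tested), so the
raw-vs-normalized ambiguity only matters through the cell-total denominator.

Enrichment between strata reuses the DE machinery; the significance flag is
p_adj < 0.05 and |log₂FC| ≥ 0.5. The gene-set dot table reports the union,
over cell types, of set members with p_adj < 0.05, for **all** strata and
cell types (union semantics), with per-gene standardized mean expression
(constant genes map to 0, not NaN) and unscaled expressing fractions.

A caveat the synthetic experiments made visible: stratifying on a
*normalized* marker couples the strata to cell library size, and a module
co-expressed with the marker changes library composition; both effects give
null genes a small systematic negative log-fold-change in the positive
stratum (measured: mean null log₂FC ≈ −0.07, null p < 0.01 fraction ≈ 2.2%
at a 9% module library share). This is a property of the analysis pattern
itself, not of this implementation, and is why the false-discovery check on
the module benchmark is stated as an FDP bound over the flagged set rather
than a raw count.

## Co-culture statistics

The field of view is the statistical unit; ratios are analyzed untransformed
(rank tests are invariant to monotone transforms anyway) and never pooled
across fields or donors silently. Kruskal–Wallis uses the tie-corrected H
with a chi-square reference (H = 0, p = 1 by convention when every
observation is identical). Dunn's z uses pooled mean ranks with the
tie-corrected variance [N(N+1)/12 − ΣT/(12(N−1))](1/nᵢ + 1/nⱼ); the
adjustment (Holm by default; Bonferroni and BH selectable) covers exactly
the requested comparison family — treated vs control, not all pairs — which
is how such panels state their post-hoc tests. Significance tiers follow the
*, **, ***, **** convention at 0.05/0.01/0.001/0.0001.

Note that Dunn's test bounds the attainable z by the pooled-rank geometry:
with three groups of five, fully separated values give z = 5/√8 ≈ 1.77 for
the adjacent comparison — not significant no matter how large the raw
effect. Power analyses should therefore be run at the field counts actually
used (15 fields/group in the default design, where a 0.6 vs 0.2 event-rate
difference is detected in ≥ 90% of replicates).

## Synthetic data: what it emulates, and what it does not

Counts are negative-binomial with shared dispersion 0.3 (gamma-Poisson, the
standard scRNA-seq noise model) and log-normal baseline gene means (median
0.15, sigma 1.5 across genes) with per-(gene, cell type) log-normal
variation (sigma 0.6) shared across conditions — so the between-condition
null holds exactly for unplanted genes. Default scale: 7 cell types × 2
conditions × 150 cells × 2,000 genes (≈ 1,100 counts/cell), generated in
under a second.

Planted structure:

- **Interactions**: ligand/receptor NB means in designated (type, condition)
  slots are calibrated by inverting the NB tail probability so the expected
  detection fraction (count ≥ the count that maps to v > 0.5 at the expected
  library size) equals the target (0.6 by default); elsewhere planted genes
  sit at fraction 0.02 and decoy-pair genes at 0.10 — expressed but below
  the 20% gate, as most L-R genes are for any given type pair.
- **Regulation**: per-(gene, type, condition) fold multipliers; the demo
  design upregulates ligands 2-fold in the first condition. Regulated
  ligands default to detection fraction 0.75 (NB mean ≈ 2.1): a 2-fold shift
  on a mean-1 NB gene is at the edge of what a BH-corrected rank test
  resolves at 200 cells/type, and differential edges in real data are
  carried by well-expressed ligands.
- **Marker module**: cells carry a latent factor w ~ N(0,1); the marker's NB
  mean is log-normally modulated by w (sigma 1.5) and module genes by a
  correlated latent (rho = 0.8). The module slope is calibrated through the
  *observation channel* (latent → NB count → quartile strata, inverted
  numerically on a fixed internal stream) so the planted fold change (2 by
  default) is the expected module contrast between the observed strata —
  the quantity enrichment actually measures. Calibrating on the noise-free
  latent instead realizes only ~1.4× and misstates the planted effect.
- **Co-culture**: n_event ~ Binomial(n_total, p_group), n_total uniform on
  [20, 40], 15 fields per group; default probabilities 0.6 (controls) vs
  0.2 (knockdown).

RNG streams are derived hierarchically from the master seed per (cell type,
condition) block and per purpose, so a given seed is bit-reproducible and
adding one planted program does not perturb unrelated draws.

Not emulated: batch effects, ambient RNA, doublets, patient-level
pseudoreplication, realistic cluster substructure, or gene-gene correlation
beyond the planted module. Passing the recovery benchmarks therefore shows
the *inference machinery* is correct and calibrated under the stated noise
model — not that the thresholds are optimal for any particular real
dataset.

## Problem sizes used by tests and the acceptance script

Oracle-equivalence: 100 random instances (≤ 6 types, ≤ 60 cells/type, ≤ 50
pairs). Permutation exactness: the C(6,3) = 20-assignment pool at
n_perm = 2,000. Calibration: 600 null pair tests at n_perm = 399 (p ≤ 0.05
attainable exactly at the 20/400 quantile). Planted recovery: 5 seeds × the
default demo scale at n_perm = 1,000. Gained recovery: 200 cells/type,
4 regulated ligands. Module recovery: 400 MG cells, 25 module genes, 2,000
genes. Co-culture power/size: 100 replicates each. These sizes keep the
whole suite under a minute while leaving every stochastic bound multiple
standard errors from its threshold.

## Known limitations

- Single-gene pairs only: heteromeric receptor complexes are not modeled,
  matching the stated gene-level interaction rule.
- Cell-level DE (no pseudobulk/mixed models): p-values overstate certainty
  relative to patient-level replication, as cell-level FindMarkers-style
  analyses do.
- The permutation test shuffles labels within the two tested types; cells
  are treated as exchangeable across samples of a condition.
- Exact Wilcoxon is limited to groups ≤ 25 (DP cost grows with rank sums);
  beyond that the tie-corrected asymptotic is used.
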