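# lrcomm

Directional ligand–receptor (L-R) interactome inference for two-condition
single-cell RNA-seq data, with permutation significance, differential
("gained") interaction calling, quantile-based marker stratification, and
nonparametric co-culture statistics.

The package targets the analysis pattern of tumor-immunology studies that
ask which myeloid cell types (microglia, dendritic cells) signal to which
lymphoid cell types (CD4⁺ T, Treg, CD8⁺ T, NK, NKT) in a tumor
microenvironment, and how that communication map differs between two
patient strata (here labelled IDH-wt vs IDH-mut, after the glioma subtypes
that motivated it).

## The method

**Highly expressed genes.** Counts are library-size normalized,
v = log₂(UMI / cell_total × 10⁴ + 1). A gene is *highly expressed* in a cell
type when strictly more than 20% of that type's cells have v > 0.5.

**Interactome.** Given a directed L-R pair list, an interaction
sender → receiver exists for pair (L, R) when the sender highly expresses L
and the receiver highly expresses R. Per-condition interactomes are compared
by set algebra on the (sender, receiver, ligand, receptor) identity: shared
and condition-unique edges (Venn counts) and per-(sender, receiver) gained
counts.

**Significance.** Each interaction is scored with the CellPhoneDB-v2-style
statistic, s = ½(mean ligand expression in sender + mean receptor expression
in receiver), against a null built by shuffling the sender/receiver labels
over the pooled cells of the two types. The permutation-inclusive p-value is
(1 + #{s* ≥ s}) / (1 + n_perm); ties count as extreme.

**Differential interactome.** Per cell type, genes expressed in ≥ 20% of
cells of either condition (min.pct = 0.2) are tested with a two-sided
Wilcoxon rank-sum test (exact, tie-corrected, for small groups; tie-corrected
normal approximation otherwise) and BH-adjusted;
log₂FC = log₂((mean(2ᵛ−1)+1)_A / (mean(2ᵛ−1)+1)_B). An interaction is
*gained* in a condition when at least one of {ligand in sender, receptor in
receiver} is upregulated there and neither is downregulated.

**Marker stratification.** Cells of one type are split on a marker gene
(study default *LGALS9*/Galectin-9) at the 0.25 / 0.75 empirical quantiles
into marker⁻ and marker⁺ strata; enrichment between strata uses the same
Wilcoxon + BH machinery with significance at p_adj < 0.05 and |log₂FC| ≥ 0.5.

**Co-culture statistics.** Per microscope field, ratio = (phagocytes with an
adhesion/phagocytosis event) / (total phagocytes). Groups are compared with
the tie-corrected Kruskal–Wallis test followed by Dunn's post-hoc z tests
over the requested treated-vs-control family (Holm-adjusted by default).

A synthetic-data module generates negative-binomial count matrices with
planted highly-expressed L-R programs, condition-specific fold changes, a
marker-correlated gene module, and binomial co-culture event tables, so
every stage is exercised against known ground truth.

## Worked example

```python
from lrcomm import (demo_spec, generate_dataset, generate_lr_database, normalize,
                    call_highly_expressed, infer_interactions, compare_conditions,
                    score_all, generate_coculture, compute_ratios, dunn_posthoc)
from lrcomm.coculture import groups_from_frame

spec = demo_spec(seed=0)                      # 7 cell types x 2 conditions x 150 cells
ds, truth = generate_dataset(spec)
norm = normalize(ds)                          # log2(counts / total * 1e4 + 1)
db = generate_lr_database(spec)               # 10 planted + 90 decoy pairs

senders, receivers = ("MG", "DC"), ("CD4T", "Treg", "CD8T", "NK", "NKT")
interactomes = {}
for cond in spec.conditions:
    calls = call_highly_expressed(norm, condition=cond)   # >20% cells above 0.5
    interactomes[cond] = infer_interactions(calls, db, senders, receivers,
                                            condition=cond)
    print(f"{cond}: {len(interactomes[cond])} interactions")

venn = compare_conditions(interactomes["IDH-wt"], interactomes["IDH-mut"])
print(f"shared: {len(venn.shared)}  unique IDH-wt: {len(venn.unique_a)}"
      f"  unique IDH-mut: {len(venn.unique_b)}")

scores = score_all(interactomes["IDH-wt"], norm, n_perm=1000, seed=0)
print(scores.head(3)[["sender", "receiver", "ligand", "receptor",
                      "mean_statistic", "p_value"]].to_string(index=False))

events = generate_coculture({"untreated": 0.6, "siRNA-control": 0.6,
                             "Gal9-siRNA": 0.2}, seed=0)
posthoc = dunn_posthoc(groups_from_frame(compute_ratios(events)),
                       [("Gal9-siRNA", "siRNA-control"),
                        ("Gal9-siRNA", "untreated")])
print(posthoc[["group_a", "group_b", "z", "p_adj", "significance"]]
      .to_string(index=False))
```

which prints:

```
IDH-wt: 10 interactions
IDH-mut: 10 interactions
shared: 10  unique IDH-wt: 0  unique IDH-mut: 0
sender receiver ligand receptor  mean_statistic  p_value
    DC     CD4T PLG005   PRC005        2.291543 0.000999
    DC     CD8T PLG007   PRC007        2.388546 0.000999
    DC       NK PLG003   PRC003        2.308614 0.000999
   group_a       group_b         z        p_adj significance
Gal9-siRNA siRNA-control -5.047379 8.958245e-07         ****
Gal9-siRNA     untreated -4.338243 1.436262e-05         ****
```

All 10 planted L-R edges are recovered in each condition at the permutation
floor p = 1/1001 ≈ 0.001, none of the 90 decoys enter the interactome, and
the knockdown group's adhesion ratio (0.2 vs 0.6 in controls) is flagged at
the **** tier by Dunn's test.

The same stages are available from the shell via the `lrcomm` CLI
(`simulate`, `interactome`, `diff-interactome`, `stratify`, `coculture`,
`report`); each run writes TSV tables plus a JSON manifest with the config
echo and input/output checksums.

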