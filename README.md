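# drugcorr

Gene expression / drug sensitivity association mapping for cancer
cell-line panels.

Large public screens such as the Cancer Cell Line Encyclopedia (CCLE)
and the Genomics of Drug Sensitivity in Cancer (GDSC) measure, for more
than a thousand cell lines, both genome-wide expression and the
concentration of each drug needed to inhibit growth (IC50) or reach
half-maximal effect (EC50). A gene whose expression tracks a drug's
IC50 within a cancer lineage is a candidate resistance marker; a gene
whose expression runs opposite to IC50 marks sensitization. `drugcorr`
computes these associations and cross-validates them between two
independent panels, for researchers doing biomarker discovery or
combination-therapy hypothesis generation.

## Method

For each (gene *g*, drug *d*, lineage *l*) the tool takes the
pairwise-complete set of cell lines of lineage *l* and computes
Spearman's rank correlation

ρ = corr(rank(x_g), rank(y_d)),

i.e. the Pearson correlation of midranks (ties receive the mean of the
ranks they occupy). Significance is two-sided: for n ≤ 8 the p-value is
the exact permutation tail P(|ρ*| ≥ |ρ|) over all n! permutations; for
larger n it uses t = ρ·√((n−2)/(1−ρ²)) with n−2 degrees of freedom.
Only associations with p < 0.05 (strict) are retained by default;
optional Benjamini–Hochberg correction per drug, per lineage or global
is available. Because Spearman is invariant to strictly monotone
transformations, raw and log IC50 give identical results and units
never matter.

Sign semantics (IC50/EC50 are "higher = more resistant"):

* ρ > 0 — **resistance** association: the drug is less effective when
  the gene is highly expressed.
* ρ < 0 — **sensitizing** association: the drug works better when the
  gene is highly expressed.

A (gene, drug, lineage) triple is **confirmed** when it is significant
at the same α with the same sign in two independent panels.

A Gaussian-copula synthetic panel generator (`drugcorr simulate`)
plants effects with an exact target population Spearman
(latent Pearson r = 2·sin(πρ_s/6)), so every claim the tool makes can
be checked against known ground truth.

## Worked example

Simulate a three-lineage panel with three planted effects, then map all
gene-drug associations:

```sh
$ drugcorr simulate --spec spec.yaml --out panel
wrote panel (3 genes x 54 lines, 2 drugs) to panel

$ drugcorr associate --expression panel/expression.tsv \
    --response panel/response.tsv --annotation panel/annotation.tsv \
    --only-significant --matrix-gene G0001 --out assoc
wrote 3 association row(s) to assoc/associations.tsv
```

with `spec.yaml`:

```yaml
n_genes: 3
drugs: [HSP90i, MEKi]
lineages: [[melanoma, 20], [lung, 18], [liver, 16]]
planted_effects:
  - {gene: G0001, drug: HSP90i, lineage: melanoma, rho_s: -0.8}
  - {gene: G0001, drug: HSP90i, lineage: lung, rho_s: -0.8}
  - {gene: G0002, drug: MEKi, lineage: melanoma, rho_s: 0.7}
seed: 7
```

`assoc/associations.tsv` then holds exactly the three planted triples —
18 tests were run (3 genes × 2 drugs × 3 lineages) and only these pass
p < 0.05:

```
gene    drug    lineage   metric  n   rho      p         q         direction    method      dataset
G0001   HSP90i  lung      IC50    18  -0.7544  0.000298  0.000298  sensitizing  asymptotic  panel
G0001   HSP90i  melanoma  IC50    20  -0.7459  0.00016   0.00016   sensitizing  asymptotic  panel
G0002   MEKi    melanoma  IC50    20  0.6692   0.00125   0.00125   resistance   asymptotic  panel
```

Read: in melanoma, G0001 expression correlates ρ = −0.75 with HSP90i
IC50 over 20 lines — high G0001 predicts a lower IC50, i.e. the drug
is *more* effective (a sensitizing marker recovering the planted
ρ_s = −0.8). G0002 is a resistance marker for MEKi. The per-gene matrix
export (`matrix_G0001.tsv`) is the same result as a lineage × drug
table with non-significant cells masked to NA. `drugcorr concordance`
runs two panels and labels each shared triple confirmed /
discordant_sign / only_a / only_b / absent.

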