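# Methods

## Model and procedure

`drugcorr` treats a cell-line panel as three tables joined on a
normalized cell-line key (uppercased, non-alphanumerics stripped — the
only practical way to match lines across sources that spell
"SK-MEL-28" differently): a genes × lines expression matrix, a long
drug-response table (IC50 or EC50 per line and drug), and a line →
lineage annotation. After harmonization the three components cover the
identical intersection of cell lines.

For every (gene, drug, lineage) triple the engine forms the
pairwise-complete (expression, response) pairs within the lineage and
computes Spearman's ρ as the Pearson correlation of midranks. The
classical 1 − 6Σd²/(n³−n) shortcut is deliberately not used: it is
biased under ties, while Pearson-on-midranks is the tie-correct
definition. Missing values are dropped per pair, never imputed.

Two-sided p-values are dispatched on sample size:

* **n ≤ 8 (default `exact_threshold`)** — exact permutation test:
  p = #{π : |ρ(x, π(y))| ≥ |ρ_obs| − ε} / n!, with ε = 1e−12 absorbing
  float rounding (permutation ρ values are ratios of small integers, so
  1e−12 is orders of magnitude below the smallest genuine gap). The
  identity permutation always counts, so p > 0. The permutation index
  matrix is cached per n (40,320 × 8 at n = 8), making each test
  ~1 ms. `exact_threshold` is capped at 8; 9! enumeration would be
  50 times slower for negligible accuracy gain over the t
  approximation.
* **n > threshold** — t = ρ·√((n−2)/(1−ρ²)) referred to Student's t
  with n−2 df (scipy's t distribution). |ρ| = 1 is clamped to the
  smallest positive double rather than p = 0.

Constant (degenerate) variables have no defined rank correlation; such
triples are flagged and reported with p = 1 / skipped, never filtered
into results.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| `alpha` | 0.05, strict `<` | the conventional robust-correlation screen threshold |
| `min_n` | 5 lines/lineage | at n = 4 the smallest achievable two-sided exact p is 2/24 ≈ 0.083, so no result could ever be significant; 5 (p_min = 2/120) is the smallest informative group |
| `exact_threshold` | 8 | validity at small n, standard t practice above |
| metric preference | EC50, then IC50 | when both were screened, EC50 is kept; both are higher-equals-more-resistant so the sign semantics are identical |
| adjustment | none (BH opt-in, per-drug stratum) | the default pipeline reports raw p at a strict 0.05, mirroring common screening practice; BH (statsmodels) is offered for users wanting FDR control |
| pooled PAN rows | off | lineage stratification is the primary analysis; pooling across tissues confounds lineage-specific expression with lineage-specific sensitivity |

Replicate (line, drug, metric) response rows are averaged
(arithmetic mean — symmetric and standard for replicate screens);
duplicate gene rows keep the first occurrence with a warning
(deterministic and auditable). Units are carried through but never
converted: Spearman is invariant to any monotone rescaling, which the
test suite verifies end-to-end by re-running the engine on
log-transformed responses.

## Cross-panel concordance

Associations from two independently screened panels are joined on
(gene, drug, lineage) after optional injective drug/lineage rename
maps (vocabularies differ between sources). A triple is **confirmed**
only when significant at the same α in both panels with the same sign
— the strictest sensible reading of replication; both-significant with
opposite signs is `discordant_sign`, one-sided significance `only_a` /
`only_b`, neither `absent`. A metric mismatch (EC50 in one panel, IC50
in the other) is permitted and recorded, since both metrics order cell
lines the same way. No meta-analytic combined p (Fisher/Stouffer) is
computed; replication is reported, not pooled.

## Synthetic panels

The generator emulates the three input tables with known ground truth.
Within each lineage, expression values are independent standard
normals (shifted by +5 to a plausible log2-expression scale). A
planted (gene, drug, lineage, ρ_s) effect draws the drug's latent
log-response jointly with that gene's expression from a bivariate
normal with Pearson r = 2·sin(πρ_s/6) — the closed-form latent
correlation whose population Spearman is exactly ρ_s, which makes
"planted effect" a precise, testable statement. Responses are
exponentiated (log-normal, sd 1.5 dex) to positive, right-skewed
IC50-like values; by rank invariance this changes no statistic, and a
test asserts exactly that. Ties are injected by rounding a chosen
fraction of expression values to one decimal (deterministically
exercising the midrank path); missingness by dropping a fraction of
response rows. Everything derives from one `numpy` Generator seeded
from the spec, so identical specs give byte-identical TSVs.

What the generator does **not** emulate: correlated co-expression
between genes, panel-specific batch effects, shared cell lines with
correlated noise across the two panels, heteroscedastic or censored
IC50s (values truncated at the maximum tested concentration), or
lineage-specific expression baselines. Passing tests therefore
demonstrate the statistical machinery is correct under clean
exchangeable sampling, not that real CCLE/GDSC data meet those
assumptions.

## Problem sizes used in the checks

The null-calibration check uses 10,000 independent gene-drug pairs at
n = 8 (100 genes × 100 drugs, one lineage), large enough that the
Monte-Carlo standard error of the type-I fraction is ~0.002 while the
full run stays around fifteen seconds. Sign-recovery uses 500
generator seeds of planted ρ_s = ±0.6 at n = 30; concordance recovery
uses 40 paired-panel seeds with ρ_s = −0.8 in 7 of 8 lineages at
n = 40 per lineage — effect sizes at which detection is near-certain,
so the checks isolate sign and counting logic rather than statistical
power.

## Known limitations

* IC50/EC50 values are consumed as given; no dose-response refitting,
  censoring handling, or quality filtering of curves.
* Cell-line matching is purely name-based; lines renamed between
  releases (or misidentified lines) will silently fail to join.
* Lineage labels are taken verbatim; no ontology mapping, so
  "NSCLC" and "lung_NSCLC" are different strata unless a rename map is
  supplied.
* The exact permutation test is conservative at very small n because
  of discreteness; at n = 5 only p ∈ {2/120, …} below 0.05 is
  achievable.
* Expression platform is not modeled; the matrix is treated as generic
  continuous values, valid for anything rank-preserving.
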