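# Methods

## The inference problem

Two bulk transcriptome cohorts are observed for the same disease contrast
(healthy control vs osteoarthritis) in two tissues: blood (PBMC) and
synovium (synovial fibroblasts). The question is which secreted signals
could carry disease-associated communication within and between the two
compartments. The procedure is deliberately simple and fully deterministic
given its inputs: differential expression defines per-tissue gene sets, a
curated ligand–receptor database supplies the admissible signal/sensor
pairs, and the communication map is the exact relational join of the two —
presence/absence on DEG status, with up/down directions carried as
annotations but never used as filters, and no expression-level weighting.
A gene curated in both roles participates in both. Within-tissue pairs
(BL→BL, SY→SY) are first-class outputs alongside the between-tissue classes.

## Normalisation stand-in

Array preprocessing (RMA) operates on raw probe data that this package does
not ingest; its visible effect — log2-scale intensities with per-sample
distributions aligned — is reproduced by `log2_transform` (optional, for
linear-scale input) followed by classic quantile normalisation: each
sample's ranked values are replaced by the across-sample mean of each rank.
Ties within a sample receive the mean of the reference values they span, so
tied inputs stay tied. Consequences used as test oracles: after
normalisation every sample shares the same sorted value multiset (hence
identical five-number box summaries), and the transform is idempotent. Exact
idempotence holds for tie-free columns; with within-sample ties the
tie-averaging perturbs the pooled reference at order (tie span)/(number of
samples), which is why the idempotence checks use continuous data.
Probe-to-gene collapsing is the plain arithmetic mean of a gene's probe
rows; unmapped probes are dropped and counted, never imputed. PCA treats
samples as observations and genes as centred (optionally unit-scaled)
features, via SVD, with the sign fixed so each loading column's
largest-magnitude entry is positive.

## Differential screening

The default test is Welch's unequal-variance two-sided *t* per gene,
t = (m_OA − m_HC)/√(s²_HC/n_HC + s²_OA/n_OA) with Welch–Satterthwaite
degrees of freedom; log2 fold change is defined OA − HC so "up" always means
higher in disease. The screening threshold is a strict *p* < α with α = 0.05
by default; the stricter BH-adjusted variant (`use_adjusted`) is exposed
because at these sample sizes it prunes the candidate sets drastically (in
the worked example, 196 → 119 blood DEGs). Genes with zero variance in both
groups and equal means are reported with t = 0, p = 1 rather than dropped,
keeping the gene universe stable for enrichment backgrounds.

The moderated option shrinks pooled per-gene variances toward a scaled
inverse-chi-square prior fitted by method of moments on log variances:
with z = log s² and e = z − ψ(df/2) + log(df/2), the excess of Var(e) over
the sampling floor ψ′(df/2) identifies the prior df d0 through the trigamma
inverse (Newton iteration), and the prior scale follows from the mean of e.
The posterior variance (d0·s0² + df·s²)/(d0 + df) enters a pooled-variance
*t* with df + d0 degrees of freedom; d0 → 0 recovers the pooled *t* and
d0 = ∞ gives every gene the common variance s0². Degenerate rule: when the
log variances have literally zero spread the fit returns (∞, the common
variance) directly — the point-mass case where the general moment mapping
would mis-scale s0². The fit requires ≥ 10 positive variances.

## Multiplicity and enrichment

Benjamini–Hochberg step-up is used everywhere an adjusted p is reported
(q_(i) = min_{j≥i} p_(j)·m/j, capped at 1). Over-representation uses the
one-sided hypergeometric tail P(X ≥ k), accumulated in log space; the
background is the measured gene universe of the tissue's matrix (not the
genome), term member sets are intersected with the background before
counting, and terms with zero query hits are excluded from testing and from
m — this changes adjusted values and is therefore stated. BH is applied
within each GO category (BP/MF/CC) by default, matching how category-grouped
dot plots are read; a flag switches to global adjustment. Only enrichment is
tested, not depletion.

## Synthetic study generator

The generator emulates the study design so that recovery can be scored
against ground truth. Per tissue, gene g in sample s is

x_gs = baseline_g + effect·d_g·1[s ∈ OA] + ε,  ε ~ N(0, σ²) i.i.d.

with d_g ∈ {+1, −1} for planted genes, baselines uniform on
`baseline_range` per tissue, and plantings drawn independently per tissue
from the ligand, receptor and background strata. Defaults and why:

| parameter | default | rationale |
|---|---|---|
| blood HC/OA | 33 / 108 | the blood cohort's design |
| synovium HC/OA | 11 / 11 | the synovium cohort's design |
| n_genes | 2,000 | preserves multiple-testing structure at test-friendly size (real platforms: ~20–25k) |
| n_ligands / n_receptors / n_pairs | 120 / 120 / 250 | Ramilowski-like density (~2.4k pairs over ~20k genes) scaled to the 2,000-gene universe |
| frac_de_* | 0.10 ligands/receptors, 0.05 background | typical bulk case/control DE fractions |
| effect_log2 | 1.0 | a twofold shift, a conventional moderate effect |
| sigma | 0.5 | log2-scale residual SD typical of array data |
| baseline_range | (4, 12) | the usual RMA log2 intensity range |

Noise is i.i.d. Gaussian on the log2 scale; ligand and receptor symbol
universes are disjoint by construction so truth-table recovery is
unambiguous (real databases overlap; dual-role handling is exercised by
hand-built fixtures in the map tests). The generator does **not** emulate
probe-level structure, batch effects, correlated gene modules,
heteroscedastic or heavy-tailed noise, or mean–variance coupling — so
passing recovery tests demonstrate the pipeline's correctness under its own
model, not robustness to real-array artefacts. With `effect_log2 = 0` the
truth table is empty regardless of the planting fractions, since nothing is
actually differential. Each operation draws from its own seeded generator
(child streams spawned from the study seed); identical configs give
byte-identical outputs.

## Numerical and formatting choices

- Strict `<` at every significance threshold.
- Quartiles by linear interpolation (type-7), for cross-implementation
  agreement.
- Volcano labels: top-n/2 up and top-n/2 down by p, ties by |log2fc|
  descending then symbol ascending; sides short of n/2 are clamped.
- Gene symbols uppercased and stripped at every ingestion point; edge/node
  sort key (direction_class, ligand, receptor); chord segments ordered by
  tissue, then ligand-before-receptor, then symbol — all serialisations are
  byte-deterministic and UTF-8/LF/tab.
- Readers reject malformed input with coordinates (duplicate ids,
  non-numeric cells, short GMT lines) instead of coercing.
- Hypergeometric tails: at most 5-point support sums in log space via
  logsumexp; validated exhaustively against exact rational enumeration for
  small populations.

## Problem sizes used in validation

Test and acceptance runs use the 2,000-gene universe at the real sample
sizes; replicate sets use 20 independently seeded studies; map-construction
checks run against a brute-force triple loop on random instances up to 10⁴
database pairs and 10³ DEGs per tissue; null enrichment calibration uses 500
simulated random queries. These sizes were chosen as the smallest at which
the multiplicity structure and stochastic margins of the full-scale design
are preserved.

## Known limitations

- The presence/absence join inherits all limitations of curated pair lists:
  edges are hypotheses about possible signalling, not evidence of flux.
- Bulk cohorts cannot attribute ligands or receptors to cell types; a
  between-tissue edge may in reality be mediated by a cell type absent from
  either compartment's profile.
- The two cohorts are independent case/control studies on different
  platforms; no cross-cohort normalisation is attempted (none is needed, as
  no statistic crosses tissues before the set-level join).
- With p < 0.05 unadjusted, roughly 5% of the database's ligands and
  receptors enter each tissue's sets by chance; the map therefore contains a
  predictable false-edge background, quantified by the null-study tests.
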