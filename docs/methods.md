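# Methods

## Co-occurrence model

Diagnoses are binary per patient: a patient either carries a 3-digit ICD9
code at least once or does not. All statistics are computed from the
co-occurrence summary (`N`, `I_i`, `C_ij`) by distinct-patient counting, so
repeat diagnoses never inflate counts. Relative risk
`RR_ij = C_ij/(I_i I_j/N)` and the phi coefficient
`Phi_ij = (N C_ij − I_i I_j)/sqrt(I_i I_j (N−I_i)(N−I_j))` both flag
independence (`RR = 1` iff `Phi = 0` for non-degenerate margins) but have
complementary biases: `Phi` is compressed when the two prevalences are very
different, `RR` is unstable for rare codes. Degenerate margins (incidence 0
or `N`) make `Phi` undefined; such pairs are carried with a missing value
and an explicit flag, never coerced to 0, so they cannot silently enter a
ranking.

When a patient appears with several ages (claims span years) the maximum
recorded age is used. Codes are stored as zero-padded 3-character strings
so leading zeros survive text round trips. Readers log dropped rows and a
run fails when more than 10 % of rows are malformed — an arbitrary but
explicit guardrail.

## Index-disease selection and disease groups

Codes with `RR > index-selection threshold` (default 1.2, strict
inequality) form the working set. Closely defined ICD9 codes co-occur
strongly among themselves, so codes are aggregated into clinically curated
disease groups (DGs). The package deliberately does **not** cut the
dendrogram automatically: hierarchical clustering of the inverse-RR
distance (`d = 1/RR`; complete linkage by default, configurable to average
or single — the clustering routine the approach was built around defaults
to complete) produces a leaf ordering that a domain expert uses to draw
group boundaries; the ICD9→DG assignment is then a validated input file.
Pairs never co-diagnosed have `RR = 0`; their distance is capped at 10× the
largest finite distance (and flagged) to keep the matrix clusterable. Tied
merges are resolved deterministically: at every merge the subtree
containing the lexicographically smallest code goes left, so the leaf order
is invariant to input permutation.

A patient carries a DG iff they carry at least one member code. Codes
outside every DG are kept under their own code during aggregation by
default — dropping them would shrink the population denominator `N` and
bias every DG-level `RR`.

## Age and sex stratification

Prevalence of a code set is compared between index-disease patients and
their complement over closed 5-year age windows (center 75 covers ages
73–77, both included; centers 65…95 by default). Confidence intervals use
the percentile bootstrap with patient-level resampling, B = 1000 by
default; empty windows yield missing values, not zeros. Sex-stratified
profiles recompute `N`, `I` and `C` within each stratum independently and
report Male − Female differences plus their ratio to the male value; a
stratum without index-disease patients is skipped with a warning.

## Gene maps

`mapping1` is the non-redundant union of heterogeneous gene–disease sources
translated to ICD9 through flat (term, vocabulary) → ICD9 crosswalk tables;
fan-out (one term, several codes) is allowed, unmapped terms are skipped
with logged counts and provenance labels are merged per association.
`mapping1_DG` associates a gene with a DG iff it is associated with any
member code. `mapping2`/`mapping2_DG` add, per disease, the first network
neighbors of its associated genes — one hop only, neighbors-of-neighbors
are not added — labelled `ppi-extension` in provenance; the extension is
monotone (never removes an association) and always contains its parent map.

## Over-representation analysis

Gene sets with at least 20 and fewer than 200 genes are retained (raw set
size, before universe intersection — the filter excludes too-specific and
too-generic terms, and applying it before intersection keeps it a property
of the collection alone). For each disease and collection, the one-sided
hypergeometric tail probability P(X ≥ overlap) is computed against the
universe of all genes in the disease map plus the collection under test
(configurable override), and Benjamini–Hochberg adjustment is applied
within one (disease, collection) family. Two cutoffs are kept distinct by
design: adjusted p < 0.01 builds the binary disease×gene-set feature map,
while 0.1 is the default for standalone over-representation reporting.

## Mechanistic distances and rank fusion

Similarity between the index disease's and a DG's feature sets (genes, or
enriched gene sets) uses three measures: shared count `T`, Jaccard ratio
`JC`, and `phi` — the same binary-correlation formula as patient-level
`Phi`, applied to membership indicators over the feature universe. `T` and
`JC` depend only on the two sets; `phi` also depends on the universe size.
Every measure column becomes a tie-shared (average) ranking with the
convention *larger rank = closer to the index disease*; a DG with no
mapped genes ranks lowest rather than being dropped, keeping columns
commensurate.

The summarized gene-based distance combines the `JC` and `phi` gene
columns; the summarized pathway-based distance combines the `JC`/`phi`
columns of the gene-set collections, excluding collections configured as
outliers (Biocarta-style labels by default). A diagnostic reports pairwise
Spearman correlations between rank columns, flags measures whose mean
correlation with the others falls below a threshold (default 0.2,
configurable; constant columns are flagged automatically) and prints
principal-component loadings of the rank matrix — an explicit, configurable
stand-in for iterative measure selection, since which measures are
redundant or outlying is dataset-dependent.

Rank combination sums the per-item ranks of the chosen columns and re-ranks
the sums; tied sums share the mean of the occupied combined positions, so
combined ranks always total n(n+1)/2. The final DG ranking combines exactly
four columns: `RR`, `Phi`, the gene summary and the pathway summary.

## Biomarker relevance and FWER

`relevance(g) = Σ_DG mapping1_DG[g,DG] · w_DG`, with `w` the DG-level `Phi`
(and separately `RR`) against the index disease; the score is linear in the
weights. Genes are ranked by each score and the final ranking averages the
two. Significance uses the max-statistic permutation null: each permutation
sums two independent uniform random rankings of the same genes and records
the maximum (`maxperm`); `fwer(g) = P(maxperm ≥ rank-sum(g))` over 10 000
permutations by default. The upper-tail direction is the standard
max-statistic convention and the one consistent with selecting genes at
FWER < 0.05; the observed statistic entering the comparison is the rank-sum
(not the raw relevance), matching the null's construction as a sum of two
rankings. The estimator is monotone nonincreasing in the observed score,
and for 3 genes it matches the exactly enumerable 36-outcome null.

## Synthetic data

The generator emulates an elderly claims population: ages uniform on
[65, 95], 58.3 % female — matching the demographic profile of the U.S.
Medicare extracts this kind of analysis is run on — with the index disease
at prevalence 0.1 and each other disease governed by
`P(d|index) = r·p_d` and `P(d|no index) = p_d(1 − r·p_c)/(1 − p_c)`, which
fixes the marginal prevalence at exactly `p_d` and the population relative
risk at exactly `r`. Validity requires `r·p_d ≤ 1` and `r·p_c ≤ 1`, checked
per disease. Diseases are conditionally independent given index status —
the minimal model that pins down every index-vs-disease `RR` without
committing to disease–disease dependence, which the analysis never uses.
Optional hooks plant sex-specific or age-window-specific relative risks.
Every simulated patient carries a routine-exam filler code (`V70`) so the
population denominator is recoverable from the claims file alone; without
it, disease-free patients would vanish from a claims-style table and every
`RR` would be biased.

The standard scenario plants three DGs ordered consistently in both
channels — relative risks 3.0 > 2.0 > 1.2 and shared-gene counts
20 > 10 > 2 versus the index disease — plus 3 and 2 planted one-hop
network neighbors for the first two DGs at zero background edge density
(so mapping growth is exact), and one gene set heavily overlapping DG1's
genes among eight random sets. Planted neighbor genes are drawn outside
every disease's gene set so each disease's one-hop growth equals its
planted count exactly.

What the generator does **not** emulate: ICD9 coding noise and billing
dynamics, longitudinal visit structure, disease–disease dependence beyond
the index, and the literature biases of real gene–disease databases.
Passing recovery tests therefore demonstrates correctness of the
estimators and of the fusion machinery on data satisfying the model
assumptions — not robustness to real-world coding artifacts.

## Problem sizes and numerical choices

Recovery tests use 20 000-patient populations (estimator checks use
200 000, where planted `RR` is recovered well within 5 % relative error and
`|Phi|` at independence stays below 0.01); FWER calibration uses 500 genes,
2 000 permutations and 100 replicates, chosen so the Monte-Carlo error on
the nominal 0.05 level is a few hundredths. All randomness flows through
`numpy.random.default_rng` seeds; regenerating with the same seed is
bit-identical. Ranking ties use average ranks everywhere
(`pandas.rank(method="average")`); hierarchical clustering, hypergeometric
tails, BH adjustment and Spearman correlations are delegated to
scipy/statsmodels.

## Pipeline configuration

`comorbnet run --config config.yaml` reads a flat YAML mapping with keys:
`diagnoses`, `gene_sources` (list), `crosswalk`, `genesets` (list of GMT
paths), `network`, `dg_map`, `outdir`, `seed` (required), and optional
`index_code` (496), `rr_select` (1.2), `alpha_map` (0.01), `alpha_report`
(0.1), `min_set_size`/`max_set_size` (20/200), `fwer_threshold` (0.05),
`n_perm` (10000), `bootstrap_reps` (1000), `linkage` (complete),
`outlier_threshold` (0.2), `summary_pathway_exclude` (["BIOCARTA"]). Every
stage's outputs are hashed into `manifest.json`; a resumed run recomputes
deterministically but refuses to overwrite intermediates whose hashes no
longer match.

## Known limitations

- Expert disease grouping is an input; the package only supplies the
  clustering-derived ordering that supports it.
- No regression adjustment for confounders: age and sex are handled by raw
  stratification only.
- The Fisher universe definition (map ∪ collection) is a convention;
  enrichment p-values shift under other universes, which is why it is
  configurable.
- Crosswalks are flat files; no ontology reasoning or ICD10 support.
- Unstratified statistics keep patients regardless of missing covariates;
  only the stratified views partition on age/sex.
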