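# Methods

## The procedure and its assumptions

`coreome` operates downstream of peptide identification and run-level
normalization: its input is a long-format table of normalized peptide
abundances per LC-MS/MS run, with explicit "nd" (not detected) entries. The
package assumes

- between-run normalization has already been applied by the upstream
  quantification software (no further normalization is performed);
- technical replicates within an experiment are exchangeable, and
  experiments are independent biological preparations from the same kind of
  starting material;
- a peptide's ionisation response is sample-invariant, which underlies both
  the use of summed peptide intensities for between-sample comparison and
  the TOP3 estimator for within-sample comparison.

Two abundance estimators coexist deliberately. Between-sample comparison
(enrichment ratios) uses the **sum of all unique peptides**, which is the
most precise per-protein signal when a protein is compared with itself
across samples. Within-sample comparison (mass contributions) uses **TOP3**,
because the summed intensity of a protein's three strongest peptides is
approximately proportional to molar amount across different proteins.
TOP3 is computed over unique peptides only: shared peptides would count the
same signal toward several groups and break the 100 % normalization of mass
contributions. Groups quantified by only two peptides keep their two-peptide
sum (flagged `topN<3`) rather than becoming nd, because two unique peptides
are the quantifiability floor of the pipeline and discarding such groups
would silently drop reportable proteins.

## Missing values

"nd" is a left-censored measurement, not a zero. It is carried as NaN,
excluded from every mean (a mean over all-nd values is itself nd), and never
imputed. Consequences used by the filter:

- an experiment where a group is nd in the target fraction counts as a
  *failed* experiment toward the k-of-n rule (not as missing), but a group
  detected in only two of three experiments can still reach k = 2;
- a group measured in the target but nd (or zero) in a reference fraction
  receives an infinite ratio marker that passes any threshold — absence from
  a reference is maximal enrichment evidence;
- a missing contaminant ratio never excludes a group, since the contaminant
  fraction exists in one experiment only and many genuine residents are
  simply not measured there.

## Filter conventions

The total-extract threshold is strict (ratio must exceed 6); the
soluble/membrane/contaminant thresholds keep values exactly at the threshold
(only strictly smaller ratios are discarded). These conventions follow the
filter's published wording, and the reference dataset contains a core member
with a soluble ratio of exactly 1.5 that must survive.

Status precedence follows the order in which the criteria are applied:
`fail_experiments` (k-of-n not met) before `excluded_contaminant` (every
available contaminant ratio below the cutoff) before `excluded_prior`
(annotation list); `core` requires passing all three.

Threshold calibration derives the contaminant cutoff from known
contaminant-organelle proteins: the maximum finite reference ratio, rounded
at 0.01 granularity, pushed to the **next** integer step (3.99 → 4.0;
0.0 → 1.0). The strictly-greater step guarantees every reference contaminant
is excluded by the calibrated cutoff, including references with ratio 0.

## Order of averaging

Replicate averaging happens before ratio formation (`average_then_ratio`):
per-experiment ratios are quotients of replicate-averaged relative
abundances. The alternative — per-replicate ratios averaged afterwards — is
exposed as `method="ratio_then_average"` in `enrichment_ratios`; the two
agree at zero noise and differ slightly under noise (the ratio of means is
less sensitive to small denominators). The default is the documented
convention throughout.

Mass-contribution percentages default to *percent of experiment-averaged
TOP3 values*. The per-replicate alternative (*average of per-sample
percentages*) is available via `convention="average_of_percentages"`.
Neither convention exactly reproduces the published percentage column of
the shipped reference dataset (which sums to 102.35 and is not recomputable
from the published averages — e.g. the top protein recomputes to ≈ 46 %
versus the printed 50.18 %), so the package reports its own arithmetic and
treats the published percentages as data. Similarly, one reference row
(FCLY) prints an average (2.05E+05) inconsistent with the nd-aware mean of
its printed per-experiment values (2.73E+05); the package reproduces the
printed averages only where they follow the stated rule.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies on:
five fractions, three experiments × three replicates, the contaminant (PG)
fraction present in one experiment only, per-class protein abundance
profiles, 2–12 peptides per protein, peptide-specific log-normal response
factors (σ = 0.5) reused across samples, multiplicative log-normal
measurement noise (default σ = 0.2, a typical replicate CV for label-free
intensities), left-censoring below a detection limit (default 100 on the
arbitrary intensity scale, ≈ 3 orders of magnitude below the strongest
simulated signals), and one protein pair sharing an identical peptide set.
It does **not** simulate raw spectra, retention-time drift, chromatographic
alignment artefacts, identification error, or intensity-dependent missing
patterns beyond simple left-censoring — so passing recovery tests show the
*procedure* is correct under its stated assumptions, not that it is robust
to every pathology of real data.

The default scenario holds 25 proteins in five classes: LD residents
(≥ 50-fold enriched over every reference in realized relative abundances),
PG contaminants (LD/PG ≈ 0.07, far below the cutoff, while still passing the
generic enrichment criteria — exercising the contaminant branch), soluble
and membrane backgrounds (dominating the reference fractions the way
abundant cytosolic/membrane proteins dominate a leaf extract), and
plastid-annotated proteins that pass every ratio but carry a prior
localization (exercising the annotation branch). Class means were chosen so
per-fraction totals are of comparable magnitude; because relative abundances
share a per-sample denominator, realized enrichment ratios equal the
designed means ratios only when those totals match — a single-protein
dataset, for instance, has relative abundance 1.0 everywhere and all ratios
collapse to 1. Test scenarios that assert exact ratios therefore use
balanced two-class designs with equal per-fraction totals.

Randomness flows from a single integer seed through per-protein
`numpy` sub-streams (`default_rng([seed, protein_index])`), so a dataset is
reproducible even under partial regeneration.

## Numerical and reporting choices

- Ratios: `inf` marker on absent references, NaN for nd; comparisons with
  NaN are false, so nd fails thresholds without special-casing.
- Reports: abundances in scientific notation with three significant digits,
  ratios with one decimal, percentages with two; missing values printed as
  `nd`. Reports carry no timestamp, making reruns byte-identical; the run
  summary embeds the package version and a hash of the analysis-relevant
  configuration.
- Table validation names offending row numbers, since small tables are
  hand-edited fixtures in practice.

## Problem sizes used in the test suite

Test and acceptance runs use the default 25-protein design (≈ 6 000–7 500
table rows), 20 simulated datasets for recovery statistics and 100 for the
fraction-mean calibration check; the published reference dataset has 28
groups. The full suite completes in a few seconds on one CPU.

## Known limitations

- Grouping merges only *identical* peptide sets; no parsimony or
  razor-peptide assignment. Subset relationships leave the subset protein
  without unique evidence, hence non-quantifiable — reported, not resolved.
- No statistical test accompanies the thresholds (the filter is purely
  rule-based, as published); no FDR is attached to the core call.
- Whether the minimum-2-peptide rule should count unique or all peptides is
  not decidable from the published description; this implementation counts
  unique peptides, consistent with uniqueness-based quantification, and the
  group report exposes both counts.
- Whether the contaminant criterion should be evaluated only in the
  experiment with a contaminant-fraction sample is assumed (the reference
  dataset provides that ratio for a single experiment).
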