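# Methods

## Data model

A `PanelDataset` is a metabolite × subject matrix of non-negative
abundances with an explicit boolean missingness mask — missing is a
state, never 0 or NaN-as-data, because the imputation step must still
distinguish "compound absent" from "below the limit of detection".
Each row carries a `MetaboliteAnnotation` (super-pathway, sub-pathway,
optional HMDB accession, source panel) and an imputation class derived
from the sub-pathway: any sub-pathway whose name contains `"Drug"`,
plus `"Tobacco Metabolites"`, is *structural-zero*; everything else is
*biological-minimum*. The marker set is an argument everywhere it is
used, since annotation vocabularies differ between vendors.

Panels are read and written as delimiter-separated text (TSV default,
CSV accepted) with a fixed five-column annotation header followed by
subject ids; an empty cell is the missing state. Plain text keeps
round-trips lossless and diffable; vendor spreadsheet parsing is out of
scope.

## Imputation

Structural-zero metabolites: missing → 0. Biological-minimum
metabolites: missing → the metabolite's minimum *observed* value over
all subjects, both cohorts pooled. Pooling is deliberate: the minimum
is a property of the assay's detection floor for that compound, not of
a cohort, and per-cohort minima would manufacture group differences at
exactly the metabolites where the data are weakest. A metabolite with
no observed value at all has no defensible fill and is a hard error.

The report stratifies biological-minimum metabolites into complete /
missing in ≤20% of subjects / more than 20%. The boundary is closed on
the low side (exactly 20% counts as low); with 52 subjects the boundary
(10.4 subjects) is unattainable, so the choice is documented but inert
at study scale.

Imputation precedes all statistics. `test_all(..., allow_missing=True)`
instead drops masked cells per metabolite — the robustness check that
ignores missing data rather than imputing it.

## Per-metabolite statistics

*Rank-sum test.* Two-sided Wilcoxon rank-sum. The `exact` method
enumerates the permutation null — via the exact Mann–Whitney
distribution for tie-free samples, or direct enumeration of label
assignments with midranks when ties are present (guarded to pooled
n ≤ 24); the two-sided p is 2·min(P(W ≤ w), P(W ≥ w)) capped at 1.
The `normal_approx` method uses midranks, tie-corrected variance and a
0.5 continuity correction. `auto` selects exact for pooled n ≤ 20
without ties. Two conventions: identical constant samples give p = 1
(no evidence), and samples are never transformed first — rank tests are
invariant under monotone transforms, and fold changes are reported on
the natural scale.

*FDR.* Benjamini–Hochberg step-up, either over the whole panel or
independently within each super-pathway ("dichotomized"). The
dichotomized variant trades panel-wide FDR control for power when a
small cohort is tested against a large panel; results are re-assembled
in input order and tagged with their scope.

*Fold changes.* FC = center(controls)/center(patients), center ∈
{mean, median}. A zero patient center with a positive control center is
*undefined-divergent* (`None`), not clamped to a number; both centers
zero is FC = 1. Direction (increased/decreased in patients) follows the
mean-based fold change; a divergent FC counts as decreased in patients.

*Volcano selection.* Keep metabolites with FC ≥ fc_min or
FC ≤ 1/fc_min (defaults fc_min = 2; a divergent FC counts as exceeding
any threshold) and raw p < p_max (default 0.1). Strict inequalities on
p throughout the package.

*Preprocessing transforms.* `normalize_matrix` (log, then
per-metabolite centering/scaling to sd 1) and `filter_features`
(drop the lowest fraction by IQR, RSD = sd/mean, or MAD/median) exist
for the projection-analysis path only; the rank-based pipeline does not
use them. Zeros under a log are replaced by half the smallest positive
value in the matrix — a conventional pseudo-floor, configurable in
principle by policy argument. Zero-variance rows autoscale to all zeros
with a warning rather than NaN.

## Set enrichment

Clusters are the sub-pathway partition (or an external two-column map);
clusters with fewer than 3 members are dropped, since a distributional
test on one or two p-values is uninformative. Each cluster is scored by
a one-sided KS test of its members' raw p-values against Uniform(0,1)
with alternative "stochastically smaller" (D⁺ statistic) — the
ChemRICH-style set statistic; the implementation is isolated behind
`ks_uniform_pvalue` so an alternative set statistic can be swapped in.
Cluster q-values are BH over retained clusters. Altered members are
those with raw p < 0.05, split by mean-fold-change direction
(patients vs controls); the key compound is the member with the
smallest p, ties broken lexicographically by metabolite id.

Drug clusters are scored like any other but flagged `is_drug`: their
zero-inflated, heavily tied data produce discrete p-value distributions
that the uniform null does not describe well, so reports conventionally
filter them.

Combined-panel enrichment simply concatenates the global and lipid
results: the statistic consumes only p-values and directions, which are
scale-free, so relative intensities and concentrations mix safely.

## Sub-pathway median-ratio summary

Per metabolite: ratio of cohort medians, controls/patients (medians,
because panel abundances span wide ranges and means are dominated by a
few subjects). Per sub-pathway: the arithmetic mean of its members'
defined ratios. Arithmetic averaging of ratios is asymmetric under
cohort swap — the swapped summary is recomputed from reciprocals, not
reciprocated — and a geometric alternative is available behind the
`average` flag; the arithmetic form is the default because it is the
plain "average of the ratios" a reader expects of this statistic.
Undefined ratios (patient median 0, control median positive — typical
for zero-imputed drugs) are excluded from the average and counted.
For display the 8 drug sub-pathways and tobacco metabolites are
conventionally excluded (94 → 85 sub-pathways on the default global
template); the computation itself excludes nothing.

## Synthetic cohort generator

The generator defines the conditions every calibration and recovery
test runs under. Per metabolite m and subject j:

log x_mj = μ + b_m + s_j + ε_mj (natural log), with

| parameter | default | meaning |
|---|---|---|
| μ (`baseline_log_mean`) | 11.5 | panel-wide log baseline (~10⁵ intensity units) |
| sd(b_m) (`metabolite_log_sd`) | 1.5 | between-metabolite spread — abundances span orders of magnitude |
| sd(s_j) (`subject_scale_sd`) | 0.05 | residual per-subject scale; panels arrive vendor-normalized, so most sample-level scale is already removed |
| sd(ε) (`baseline_log_sd`) | 0.3 | per-metabolite noise, ~30% CV, typical of normalized plasma panels |
| `lod_quantile` | 0.08 | left-censoring level for biological metabolites |
| `xenobiotic_usage_prob` | 0.14 | presence probability per drug/tobacco subject-compound pair |
| `n_controls` / `n_patients` | 26 / 26 | study-scale cohort |

Planted effects are multiplicative on the natural scale: patient values
are divided by the multiplier, so the multiplier is the expected
controls/patients ratio. Unaffected metabolites have multiplier exactly
1 — the generator plants no nuisance effect-size distribution, a
modeling choice that makes null calibration unambiguous.

Censoring uses a per-metabolite pooled quantile rather than a global
absolute threshold: with abundances spanning orders of magnitude, an
absolute cutoff would delete whole metabolites instead of trimming each
metabolite's low tail. This makes the missingness MNAR by construction
(censored latent values are strictly below the observed ones) but also
*homogeneous*: every biological metabolite loses about the same
fraction of cells, so real panels' long right tail of badly missing
metabolites (and hence a populated high-missingness stratum) is not
reproduced. The default censoring and usage levels together give ~16%
missing cells on the global template with roughly half of the missing
cells in the structural-zero classes, the regime the imputation
bookkeeping is designed for.

The per-subject scale deserves a note: it is what makes median-based
statistics non-trivially robust, but it also correlates all metabolites
measured on the same subjects. At large values this correlation
inflates the false-positive rate of *set-level* statistics (every
cluster inherits the same cohort-level imbalance) — exactly as it would
in real data without sample normalization. The default 0.05 models the
residual scale *after* vendor normalization; users simulating
unnormalized data should raise it and expect cluster-level type-I
inflation, which is a property of set statistics on correlated data,
not a bug in the KS test.

What passing tests on these cohorts does **not** show: robustness to
batch effects, instrument drift, compound misidentification, covariate
confounding (age/BMI), or heterogeneous per-metabolite missingness —
none of which the generator emulates.

## Numerical and design choices

- Percentages in summaries round half-up to one decimal
  (`round_half_up`), matching how such reports are conventionally
  printed; all internal computation is full precision.
- Exact-enumeration rank-sum is limited to pooled n ≤ 24
  (C(24,12) ≈ 2.7M label splits); beyond that the tie-corrected normal
  approximation is accurate to well under 0.02 in p.
- `test_all` uses a vectorized asymptotic path when the matrix is
  complete; all-constant rows get p = 1 by convention.
- Determinism: every stochastic component is driven by one
  `numpy.random.Generator` seeded from the config; identical configs
  produce byte-identical written panels and report bundles.
- Problem sizes in the test and acceptance runs (e.g. 1,000 null
  metabolites × 10 seeds for calibration, 10 seeds for recovery) were
  chosen to estimate a 5% rate to about ±1 percentage point, which the
  ±2-point assertion bands comfortably cover.

## Known limitations

- The KS set statistic assumes independent member p-values; with
  correlated metabolites (shared subjects, co-regulated compounds) its
  p-values are optimistic. The BH-over-clusters step does not repair
  this.
- Rank-sum p-values at n = 26 + 26 with heavy ties (zero-imputed drug
  compounds) are coarse and discrete; drug clusters should be read via
  the `is_drug` flag, not their enrichment p.
- Minimum-value imputation compresses group differences at
  high-missingness metabolites; the `allow_missing` testing path is the
  built-in sensitivity check.
- The arithmetic mean of ratios is biased upward relative to the
  geometric mean (Jensen); comparisons between sub-pathways with very
  different member variances should prefer the geometric flag.
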