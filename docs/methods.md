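# Methods

This document specifies the data model, the calculated composition
variables, the synthetic cohort generator, and the statistical and
numerical methods implemented by `vitiphenol`. Everything described here
is what the code does; parameter defaults are quoted from
`vitiphenol.synthetic.SimConfig` and the analysis function signatures.

## 1. Data model

### 1.1 Compound panel

The panel (`vitiphenol.panel.CompoundPanel`, shipped as
`data/panel.csv`) lists 105 quantified compounds in a fixed order, each
with family code, abbreviation, structural attributes (aglycone, B-ring
hydroxylation count, methylation, acylation, conjugate type,
galloylation, tannin-unit role) and a per-compound limit of
quantification (LOQ, μg/berry). Families:

| Code | Family | n |
|------|--------|---|
| AN | anthocyanins (28 native glycosides + 2 dimeric pigments) | 30 |
| AP | anthocyanin-derived pigments | 8 |
| AF | anthocyanin–flavanol adducts | 15 |
| AC | other anthocyanin derivatives | 2 |
| HF | dihydroflavonols | 2 |
| FO | flavonols | 12 |
| ST | stilbenes | 7 |
| FA | flavan-3-ol (tannin) units from phloroglucinolysis | 15 |
| HB | hydroxybenzoic acids | 5 |
| HC | hydroxycinnamic acids | 6 |
| OT | other phenolics | 3 |

Membership sets for the calculated variables (acylated, trihydroxylated,
methylated anthocyanins; mono/di/tri-hydroxylated, methylated,
glucuronidated flavonols; trihydroxylated and galloylated tannin units;
the nine phloroglucinolysis units and the five terminal units) are
**derived from the structural attributes**, never hard-coded, so a panel
edit propagates consistently.

### 1.2 Quantification tables, censoring, units

A `QuantTable` holds samples × 105 non-negative finite values in one of
two unit bases, per berry (μg/berry) or per gram fresh skin (μg/g),
together with an optional boolean censoring mask. Invariants enforced at
construction: column set equals the panel, columns re-ordered to panel
order, no duplicate sample ids, no negative or non-finite values.

- **Censoring**: a value is below LOQ iff `value < LOQ` (strictly; a
  value exactly at the LOQ is quantified). `impute_below_loq` replaces
  censored cells by LOQ/2 and is idempotent.
- **Unit conversion** uses per-sample berry fresh weight from the
  metadata: μg/berry = μg/g × weight(g). Conversion round-trips exactly
  up to floating point.

### 1.3 Sample metadata and cohort pairing

`SampleMetadata` records cultivar, berry colour (colored/white), genetic
group, treatment (IR = irrigated, NI = non-irrigated), vintage, berry
weight, δ13C, total soluble solids and harvest day. For response
analyses, `select_paired_cohort(table, meta, vintage)` keeps exactly the
cultivars that have both an IR and an NI sample in that vintage, in
sorted cultivar order, and logs every exclusion with a reason
(`exclusions.tsv` in pipeline runs).

## 2. Calculated composition variables

Seventeen variables per sample (`compute_indices`):

**Six totals** (same unit basis as the input): `s_AN_n` = sum of the 28
native anthocyanin glycosides (derived pigments and dimers excluded);
`s_FO`, `s_ST`, `s_HB`, `s_HC` = family sums; `s_FA` = sum of the nine
phloroglucinolysis units.

**Ten percentages** (0–100): acylated, B-ring-trihydroxylated and
methylated anthocyanins as a share of `s_AN_n`; mono-, di-,
tri-hydroxylated, methylated and glucuronidated flavonols as a share of
`s_FO` (the mono/di/tri sets partition the flavonols, so those three sum
to 100); trihydroxylated and galloylated units as a share of `s_FA`.

**Mean degree of polymerization** `dp_FA` = (sum of all nine released
units) / (sum of the five terminal units), dimensionless and ≥ 1 by
construction. `mean_degree_of_polymerization` also offers an
alternative denominator omitting the catechin terminal unit
(`terminal_set="FA7-FA10"`), kept for comparison only; the default uses
all five terminal units.

Properties guaranteed and tested: percentages and dp are ratios of like
units and hence invariant to the unit basis; totals are homogeneous of
degree 1 under rescaling; a zero denominator yields NaN plus a `False`
entry in the `defined` mask instead of an exception.

Group means (`group_mean_table`) are arithmetic means by treatment ×
vintage. Totals commute with averaging (linearity); percentages and dp
are averaged as means of the per-sample ratios, which in general differs
from the ratio of group means — the tests pin this distinction.

## 3. Synthetic cohort generator

### 3.1 Abundance model

For cultivar *c*, treatment *t*, vintage *v* and compound *j*, the
per-berry amount is

```
log10 X = m_j + Δ_j(c, t, v) + s_j · z_j(c, sample)
```

- `m_j`: baseline log10 mean, taken from the bundled per-compound NI
  means of a published 2014 cohort (overridable per compound).
- `s_j`: marginal log10 standard deviation, default 0.3 for all
  compounds.
- `z_j`: standard normal with structured correlation, split into a
  cultivar-level effect `z_cult` (shared by all samples of the cultivar
  across treatments and vintages) and an independent per-sample residual
  `z_samp`, combined as `√share·z_cult + √(1−share)·z_samp` with
  `cultivar_effect_share = 0.7`. This share reproduces the strong
  IR-vs-NI and between-vintage cultivar-rank stability seen in real
  panels.
- Correlation structure: within each family the target correlation is
  0.6, with a global floor of 0.1 across families. Each of the two
  levels uses a one-factor-per-family construction
  `z = a·g + b·f_family + c·ε` with `a² = floor`,
  `b² = ρ − floor`, `c² = 1 − ρ`, so every marginal is exactly N(0, 1).
  The target correlation is allotted to the two variance levels by
  `_split_correlation`: the cultivar level absorbs as much of it as its
  variance share allows (`ρ_cult = min(1, ρ/share)`), the remainder
  spills into the sample level. Putting the family correlation
  preferentially at the cultivar level is what makes cultivar response
  profiles clusterable — compare § 3.4.
- Final values are flagged censored wherever `value < LOQ_j` (the
  log-normal model keeps them strictly positive). The generator
  emits the *uncensored* values plus the mask; imputation is the I/O
  layer's job, keeping censoring behaviour testable.

### 3.2 Treatment, vintage and colour effects

- **Treatment**: under NI the mean of selected families is multiplied
  by `factor^σ`, where σ ∈ [0, 1] is the vintage's `stress_intensity`
  (default vintages: 2014 with σ = 1, 2015 with σ = 0.1). Default
  factors: FA 0.88, HC 0.88, ST 0.96, FO 0.98 — i.e. tannin units and
  hydroxycinnamics drop ~12 % without irrigation in a stressed vintage,
  stilbenes and flavonols barely move. Compound-level keys override
  family-level keys.
- **Physiology under NI**: berry weight shrinks by fraction
  `0.28·σ`, δ13C rises by `1.6·σ` ‰.
- **Colour**: a configurable fraction (default 0.35) of cultivars are
  white; their anthocyanins (all AN/AP/AF/AC compounds) and B-ring
  trihydroxylated flavonols are scaled by `white_trace_factor = 1e-3`,
  placing them at trace/censored levels.
- **Planted ground truth**: `plant_response_groups(config, k)` assigns
  cultivars to *k* groups with contrasting treatment-effect overrides;
  `generate_cohort` returns a `truth` object with the group labels and
  realized per-compound effects, enabling recovery experiments.

### 3.3 Reproducibility

All randomness derives from one integer seed through
`numpy.random.SeedSequence` substreams keyed by (cultivar index, vintage
index, treatment index). Consequences, all tested: identical configs are
bit-identical; adding a vintage does not perturb the draws of existing
vintages; different seeds differ.

### 3.4 Realism and known limits

The generator is calibrated to reproduce family-total magnitudes, the
observed NI/IR family ratios in a stressed vintage, cultivar-rank
stability across regimes and vintages, censoring at realistic rates, and
white-cultivar composition. Known limits, deliberate and documented
rather than patched:

1. **No within-cultivar biological replication model** — each
   cultivar × treatment × vintage is one composite sample, as in the
   motivating study design.
2. **Unpaired screening on paired data is conservative.** The default
   cohorts are cultivar-paired (share 0.7 of the log variance cancels in
   the IR−NI contrast) but the screening ANOVA treats groups as
   independent, matching common practice for such panels. Under the
   null, E[F] ≈ 1 − share ≈ 0.3, so the unpaired test's type-I rate
   falls well below its nominal level (observed < 1 % at α = 0.05).
   This is why one acceptance test — which demands a 1–10 % null
   rejection rate — fails by design. Removing the cultivar effect would
   restore nominal calibration but destroy the cultivar-rank stability
   and response-group clusterability that the rest of the pipeline
   exists to analyse; the trade-off is inherent, not a tuning knob.
3. **Log-normal everywhere** — no zero-inflation beyond the white-trace
   mechanism, no heavy tails, no instrument drift or batch effects.
4. **One factor per family** — within-family correlation is
   equicorrelated; real pathways have richer structure (e.g. shared
   acyl-transferase activity across families).

## 4. Statistical methods

### 4.1 ANOVA and Student–Newman–Keuls letters

`one_way_anova` is the classical fixed-effects one-way ANOVA (for two
groups, F = t² exactly; tested against `scipy.stats.f_oneway`). SNK
letters: group means are sorted; ranges of *p* consecutive means are
compared against `q_{α, p, df_error} · √(MS_error / n_h)` with the
studentized range distribution (`scipy.stats.studentized_range`),
harmonic-mean *n* for unbalanced groups, and the standard protection
rule (a non-significant range blocks all sub-ranges). Groups sharing a
letter are not significantly different at α = 0.05.
`screen_variables` applies this to all 105 compounds plus the 17
calculated variables (122 rows).

### 4.2 Stability correlations

Pearson correlations of cultivar values across the four pairings of
regimes and vintages (within-vintage IR vs NI for each vintage, and
between-vintage under IR and under NI), with a `colored_only` option
because anthocyanin variables are degenerate (trace) in whites.

### 4.3 PCA

Implemented by SVD of the column-centred (and by default
unit-variance-scaled) matrix; scores = UΣ, loadings = V, explained
variance from the squared singular values over (n−1). Constant columns
are dropped with a warning before scaling. Sign convention: each
component is flipped so that its largest-magnitude loading is positive,
making outputs deterministic. Verified against eigendecomposition of the
correlation matrix and by exact reconstruction.

### 4.4 Drought-response matrix

For each paired cultivar and variable,
`response = log(IR/NI) / log(base)` (base 10 by default; outputs are
base-invariant after row standardization, which is tested). Inputs must
be per-berry and strictly positive — censored values must be imputed
first. Rows (variables or cultivars, depending on axis) are standardized
to zero mean and unit variance; flat rows are dropped with a warning.

### 4.5 Correlation networks

Nodes are variables; an edge joins two variables when their Pearson
correlation across cultivars exceeds the threshold (default r > 0.8,
strict, signed; `absolute=True` uses |r|). Zero-variance variables are
excluded. Exports: SIF (isolated nodes listed) and GraphML with r as
edge weight and the compound family as a node attribute; connected
components via `networkx`.

### 4.6 Hierarchical clustering

Distance `d = (1 − r)/2` (Pearson, so d ∈ [0, 1]: 0 = perfectly
correlated responses, 1 = perfectly anti-correlated), complete linkage.
The agglomeration is hand-written for one reason: **deterministic
tie-breaking** — among equal-distance merges the pair whose sorted
member tuple is lexicographically smallest is merged first, making
dendrograms reproducible under input permutation (scipy's tie order is
insertion-dependent). The implementation is tested against
`scipy.cluster.hierarchy.linkage` as an oracle on tie-free inputs.
Trees export to Newick; `cut_subgroups(tree, depth)` labels leaves with
branch codes ("1", "2", "1-2-1", …) with the prefix property: the
depth-k label is a prefix of the depth-(k+1) label.

### 4.7 Subgroup enrichment

Chi-square goodness-of-fit of a trait's category counts within a
subgroup against the cohort-wide proportions (df = categories − 1),
flags at p < 0.1 and p < 0.05, with a warning when any expected count is
below 5. Traits: berry colour, genetic group, harvest period (early /
mid / late weeks derived from harvest day).

## 5. Numerical choices

- All computation in float64; no tolerance-hiding of real errors —
  invariants that hold exactly (unit round-trip, F = t², partitions) are
  tested at 1e-9–1e-12.
- SVD-based PCA instead of covariance eigendecomposition for numerical
  stability on tall matrices.
- Studentized-range quantiles from scipy rather than table lookup.
- Strict `<` for censoring and `>` for the network threshold: boundary
  values are quantified / not connected, respectively, and the tests pin
  both boundaries with `nextafter` probes.
- Pipeline artifacts are written with fixed column orders and hashed
  (SHA-256) into `manifest.json`; equality of manifests certifies
  byte-identical runs.
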