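# Methods

## Marker-selection cascade

The cascade operates on β-values (per-probe methylated fraction, in [0, 1])
and applies five filters in order; every comparison is strict, matching the
"over" / "more than" semantics of the thresholds.

| parameter | default | meaning |
|---|---|---|
| `fold_change_min` | 1.15 | tumor/normal ratio of per-probe mean β |
| `beta_methylated` | 0.2 | β above which a probe/gene/sample counts as methylated |
| `beta_blood_max` | 0.1 | normal-blood summary β above which a probe is excluded |
| `pan_cancer_mean_beta` | 0.2 | per-type mean β defining "methylated in that type" |
| `pan_cancer_max_types` | 4 | maximum number of methylated types tolerated |
| `gene_min_frequency` | 10 % | tumor methylation frequency a stable gene must exceed |

Aggregation choices that the thresholds alone do not fix:

* **Fold change** is the ratio of group means of β. A geometric-mean variant
  was rejected: β is bounded and frequently near zero, where log-ratios are
  unstable. A probe whose normal mean is exactly zero passes when its tumor
  mean is positive (unbounded fold change); these are counted in the log.
* **Blood exclusion** summarizes blood samples by their mean β;
  `blood_aggregate="max"` switches to the per-sample maximum for a stricter
  screen.
* **Gene stability** ("more than 10 % methylated") is read as the fraction
  of tumor *samples* whose gene-level β (maximum over the gene's surviving
  probes) exceeds 0.2 — consistent with how methylation frequency per gene
  is defined. A literal per-probe reading exists but would make the
  frequency definition circular; the sample reading is the default and the
  only one exposed.
* **Specificity classes** reuse the probe-level rule at gene level: a gene
  is methylated in a cancer type iff the mean over that type's samples of
  gene-level β exceeds 0.2. Class 3 = pancreas only, class 2 = 2–3 types,
  class 1 = 4 types; genes methylated in more than 4 types, or not in
  pancreas, fall outside the classes and are dropped with a log message.
  Within-class ranking: tumor methylation frequency, then mean pancreatic
  gene-level β (both descending), ties by gene symbol.
* Missing β-values are excluded from means; a probe with all values missing
  in a required group is dropped with a logged warning.

## ddPCR quantification and calibration

Copies per well follow the standard partition-occupancy inversion
λ = −ln(1 − positives/total), copies = λ · total. Saturated wells (every
droplet positive) are rejected rather than truncated. Replicate wells of
one (sample, assay) are merged by summing droplet counts before inversion.
The droplet volume (default 0.85 nL, the QX200 convention) only enters the
copies-per-µL conversion; all calls operate on per-well copies.

Calibration is unweighted OLS of observed methylated copies on input %
methylation over a mixture series with at least three distinct ratios; the
reported R² is the ordinary coefficient of determination. Inversion clips
the estimate to [0, 100] and logs clipped values; a non-positive slope
raises (non-identifiable calibration). The shipped reference coefficients
describe the response at a 1,000-copy total input; for other totals the
simulator scales the expected response by `total_copies / 1000`, an
assumption made explicit because the normalization used for patient samples
at other totals is not derivable from the assay description.

A methylation-positive call requires **both** estimated copies strictly
above the 100-copy detection floor and estimated percent strictly above the
marker's cutoff; the two limits are stated independently in the assay
characterization and combining them conjunctively is the conservative
reading. The *KRAS* mutant-allele-frequency limit (0.2 %) is inclusive
because it is a limit the assay is *set at*, and additionally requires at
least one mutant copy.

## ROC and cutoffs

AUC is the trapezoid-rule area over thresholds at all distinct score values
(equal to the normalized Mann–Whitney U; verified against brute-force pair
counting in the tests). The operating cutoff maximizes Youden's
J = sensitivity + specificity − 1 under the strict `measurement > cutoff`
rule, evaluated at midpoints between consecutive distinct scores so the
cutoff sits inside a separating gap; ties break toward higher specificity,
then the lower cutoff. The criterion is a package choice (the alternative,
closest-to-(0, 1), is exposed via `criterion="closest_topleft"`). The
shipped panel cutoffs (ADAMTS2 0.90, PCDH10 0.70, SEMA5A 0.24, SPSB4 0.20
qMSP; HOXA1 17.64 pyrosequencing %) derive from a private 22-sample tissue
set and ship as defaults, not as quantities this package can re-derive.

## Diagnostic rule and performance arithmetic

`combined` calls a sample positive when at least one marker is
methylation-positive or *KRAS* is mutant; `methylation_only` and
`kras_only` are the components. Unknown *KRAS* status counts as negative by
default (with a logged count), matching how known-status subsets are
tallied; `strict_kras=True` excludes such samples instead. Percentages are
rounded half-up to integer percent — the rounding that reproduces every
published count in the worked examples (23/47 → 49, 19/29 → 66, 43/46 → 93,
132/137 → 96, 12/14 → 86, 32/47 → 68). Wilson 95 % intervals are computed
as supplementary information only. When a cohort lacks one truth class the
undefined metric is reported as absent, never as zero.

## Concordance

Intervals are 0-based half-open (BED convention) throughout. A peak is
shared when it intersects ≥ `min_overlap_bp` (default 1) bases of any peak
of the other set; percentages are per set, so the report is symmetric under
swapping arguments. Signal correlation sums value × covered-bases into
fixed 1-kb bins (bin size is a package default; no external-tool setting is
reproduced) and computes Pearson r over bins with nonzero signal in at
least one sample — including jointly-empty genome would inflate r. Jointly
constant binned signal raises rather than returning an undefined r.

## Synthetic data: what it emulates, what it does not

The cohort generator plants a known marker architecture: pancreas-specific
genes (the recoverable truth), decoys shared with 1–3 other cancer types
(survive the cascade into classes 1–2), pan-cancer decoys (methylated in
> 4 types, removed by filter 3), and blood-methylated decoys (removed by
filter 4); a fraction of background probes carries SNP/problematic/sex-
chromosome flags (removed by filter 1). β noise is a normal truncated to
[0, 1] around the group mean (default sd 0.05; a beta-distribution noise
model is selectable); group means default to 0.6 (methylated) and 0.05
(background), values typical of hypermethylated CpG-island promoters vs
unmethylated background on 450K arrays. Default group sizes mirror the
study design (37 tumors, 3 normal pancreata, 95 blood samples, nine other
cancer types); the default 2,000 probes keep the drivers fast while leaving
every filter a non-trivial amount of work. The generator reproduces the
*decision logic*, not the variance structure, probe density, or
inter-probe correlation of real arrays — so passing tests demonstrate the
pipeline's correctness, not expected performance on real cohorts, and the
published absolute stage counts (5,575 / 1,933 / 1,271 / 604 / 420 probes)
are not reproducible at this scale.

The mixture-series simulator draws observed copies as Poisson around the
calibration line at the design ratios (0, 0.1, 0.5, 1, 2.5, 5, 10, 25, 50,
100 %); droplet wells are Binomial(N, 1 − e^(−copies/N)). The cfDNA cohort
generator either sheds markers stochastically (per-marker shed probability
in cancers, a small false-positive rate in controls) or, in deterministic
mode, encodes an explicit call matrix into wells that the quantification
pipeline decodes back exactly (positives at 2,000 copies, negatives at 10,
i.e. below the 100-copy floor). The paired-peak generator places peaks on a
disjoint slot grid and reuses a `shared_fraction` of slots, so the realized
overlap equals the requested fraction up to rounding.

The worked-example call tables in `mbdpanel.fixtures` are synthetic
reconstructions: per-sample marker assignments are arbitrary, only the
aggregate margins (cohort sizes, positives per rule, *KRAS* status counts,
marker-count distribution) are meaningful.

## Numerical choices and degenerate inputs

Seeding: each generator takes one integer seed; sub-streams derive from a
single `numpy` Generator so outputs are bit-reproducible per seed.
Degenerate inputs are handled explicitly: empty cohorts, all-flagged probe
sets (empty result plus warning), constant calibration response (slope 0,
R² 0), constant ROC scores (J = 0 at that value, warning), negative
expected mixture copies (clamped to 0, warning), saturated wells
(rejected).

## Known limitations

* Probe QC from raw intensities, IDAT parsing, read alignment and peak
  calling are out of scope; peaks and β-matrices are consumed as files.
* The calibration total-copies scaling is an assumption (see above).
* Reported R² of real mixture series, per-gene ROC cutoffs, and the
  sequencing-based overlap/correlation figures depend on non-public data
  and are represented here only by construction checks on synthetic inputs.
* Tissue/cfDNA concordance is summarized marginally (overlap fractions,
  binned r); no model of tumor heterogeneity is included.
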