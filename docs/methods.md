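# Methods

## Densitometry model

Voxel attenuation is mapped to tissue fraction with the standard linear
two-compartment (air/tissue) model, `f = (HU + 1000)/1000` clipped to
[0, 1]. No HU calibration beyond the nominal air/water anchors is modelled.
Segment tissue and air volumes are voxel-volume-weighted sums of `f` and
`1 − f`; TAR is volume-based (`100·T/A`, percent), so the thresholds used
throughout — the 11% lower-lobe floor, the 2-point equal-disease tolerance
and the 0.30-point combined-TAR tolerance — are absolute percentage points
on that scale. Mass-based TAR was considered and rejected: volumes are what
the planner's fraction windows are defined over, and the two differ only by
a density constant that cancels in every ratio we take.

The phantom generator inverts the TAR definition per segment
(`f = TAR/(100 + TAR)`, mean HU `= −1000(1 − f)`) and adds zero-mean
Gaussian HU noise (default SD 30 HU). Because the mapping is linear and the
noise sits well inside the clip window for the TAR ranges we generate
(5–25%), the recovered TAR is unbiased; the round-trip tolerance of 0.5
percentage points over 100 random specs is limited only by voxel-count
discretization and noise. Segments are laid out as slabs in a padded
rectangular grid — geometry carries no information here, only the label
map does. Phantoms serialize as a float32 HU NIfTI, an int16 label NIfTI
and a JSON label table.

## Heterogeneity index and combined TAR

Both quantities are ratios of raw volumes, not averages of ratios:

- `HI = lower-lobe TAR / segment TAR`. This orientation makes HI exceed 1
  exactly when the upper segment is less dense than its lower lobe, which
  is what "upper-lobe predominance" means, and is consistent with the
  ≥ 1.2 treatment floor.
- combined TAR `= 100·ΣT/ΣA` over an option's treated segments, i.e. the
  air-volume-weighted mean of segmental TARs. An unweighted mean would let
  a tiny segment's ratio dominate; since TAR is itself a volume ratio, the
  aggregated form is the one that equals the TAR of the union of the
  treated tissue. Both conventions are kept configurable in code but the
  aggregated form is the default and the tested one.

## Planner

The option matrix is exhaustive and canonical: session 1 is one treatable
segment of the primary lobe (left adds the merged LB1+2), session 2 is a
single or unordered pair from the contralateral lobe. The pair {LB1, LB2}
is the same tissue as the merged LB1+2 single and is deduplicated to it,
and LB1+2 never co-occurs with LB1 or LB2. This yields 24 options with a
left primary lobe, 21 with a right one, 45 enumerating both. The primary
side is not fixed by the design, so the default enumerates both and lets
the selection rules decide; a CLI flag pins it.

Fraction denominators: by default the left upper lobe's denominator is the
sum of its treatable segments, excluding the lingula. With the lingula
included (roughly a third of the lobe), the 60% ± 20% session-2 window can
become unattainable with only three treatable segments, which would make
the algorithm structurally infeasible on ordinary anatomy; the
whole-anatomical-lobe denominator remains available via
`--denominator anatomical`.

Selection order: constraint filtering (all comparisons inclusive) →
least-diseased protection → minimum combined TAR → 0.30-point near-tie
group broken by `|combined fraction − 110|` → lexicographic key as the
final deterministic tie-break. The protection step runs per lobe in a
fixed left-then-right order and each removal is guarded: if removing every
option that treats a lobe's unique least-diseased segment would empty the
set, nothing is removed for that lobe. A lobe has a unique least-diseased
segment only when its largest segmental TAR exceeds every other by more
than the 2-point tolerance; an option "treats" that segment if the
segment's tissue is anywhere in the plan, including inside the merged
LB1+2. Infeasibility ("no feasible plan") is a reported outcome with a
complete per-option audit, not an exception.

## Eligibility screen

Numeric criteria use the printed comparison directions with inclusive
boundaries (FEV1 = 20 %pred passes the 20–45% window, DLCO = 20 passes,
BMI = 32 passes, lower-lobe TAR = 11% passes). History and imaging items
that no number can decide are boolean attestations. Two genuinely open
points are surfaced rather than hidden: the dyspnea threshold is
implemented as mMRC ≥ 2 by default with a `gt2` switch (the design's two
statements of this criterion disagree), and the decision metadata records
which rule ran; right-heart-catheter pressures take precedence over
echocardiographic ones whenever both are present, via separate fields. The
hospitalization exclusion is an integer count with threshold > 3.

## Trial statistics

Sample size uses the exact noncentral-*t* power of the pooled two-sample
t-test (df `= n_t + n_c − 2`, noncentrality `δ/(σ√(1/n_t + 1/n_c))`), with
the treatment arm held to exactly `ratio × n_control`, so returned totals
are multiples of ratio + 1. Under this convention the quality-of-life
endpoint assumptions (11, 14) give 20/40 = 60 and the lung-function
assumptions (12, 15) also give 60 — a design total of 59 can only arise by
relaxing the exact ratio (19.67/39.33 rounded), a software-specific
rounding we deliberately do not reproduce; the exact-ratio answer lands
within 3 of it. Dropout inflation is `ceil(n·(1+rate))` with a small
rounding guard against float noise.

"Worst prior" imputation after a serious adverse event is direction-aware
(lowest prior FEV1/6MWT, highest prior SGRQ) — left undefined in the
design prose, but any other reading would let an SAE improve a subject's
analysed outcome. The FEV1 responder threshold "≥ 12% difference" is
implemented as relative change of %predicted (the convention used in the
predecessor vapour-ablation study for the same endpoint), with an
absolute-points switch.

Randomization is permuted-block, stratified by site, each site's block
stream seeded independently from the scheme seed; block size defaults to 3
(2 treatment, 1 control) and must be a multiple of ratio + 1, so marginal
imbalance is bounded by one incomplete block per site.

## Synthetic cohorts and power

Outcomes are normal with a common per-arm SD and the specified mean
improvement (applied downward for SGRQ), the t-test's own design
assumption. Baselines are drawn inside the screening windows (FEV1
N(32, 5) %pred, SGRQ N(60, 10), 6MWT N(320, 70) m) — realism choices that
affect nothing the tests assert, since all analyses are change-based.
Missingness is Bernoulli per subject (15% missing the 12-month visit, 40%
of those attributed to an SAE, 3% with no follow-up at all) so every
branch of the imputation ladder is exercised; no dropout–outcome
correlation is modelled by default. The Monte-Carlo power engine draws
whole trials in vectorized batches and reports the rejection fraction of
`scipy.stats.ttest_ind` with its binomial standard error; at the 40/20
design it reproduces the analytic noncentral-*t* power of ≈ 0.805.

What the generators do *not* emulate: real HRCT texture, fissure anatomy
or segmentation error in the phantoms; non-normal or correlated outcomes,
informative dropout, or site effects in the cohorts. Green tests therefore
establish the algorithms' correctness against their stated rules, not
performance on clinical data.

## Problem sizes

The default suite runs the planner-vs-oracle comparison on 500 random
lungs in the acceptance tests (plus smaller sweeps in unit tests), 100
phantom round-trips, and 10,000-replicate power simulations (100,000 in
the acceptance script); these sizes put Monte-Carlo error well below every
margin asserted while keeping the whole suite under a minute.

## Known limitations

- Vapour dose/energy per segment is not computed (no formula is defined
  for it); the planner stops at the segment set and volumes.
- Real DICOM/HRCT ingestion and automatic lobe/segment segmentation are
  out of scope; the phantom pathway is a stand-in fixture format.
- The two rendered equations of the source design (HI and combined TAR)
  are published only as images; their direction and aggregation are
  inferred from the surrounding prose as described above.
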