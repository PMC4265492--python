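# segplan

Quantitative-CT segmental treatment planning for bronchoscopic lung volume
reduction (LVR) in upper-lobe-predominant emphysema, together with the
statistics of the two-arm trial design built around that planner: sample
size, co-primary multiplicity rule, responder definitions, missing-data
imputation, and site-stratified blocked randomization.

It is written for clinical-trial statisticians and interventional-pulmonology
researchers who want the segment-selection algorithm and the design
machinery as inspectable, testable code, exercisable end to end on synthetic
lungs and cohorts (no patient data is required or shipped).

## The model

**Densitometry.** CT attenuation maps linearly to tissue fraction
(air = −1000 HU → 0, water-density tissue = 0 HU → 1, clipped). For each
bronchopulmonary segment *s* with tissue volume *T_s* and air volume *A_s*
(ml), the tissue-to-air ratio is

    TAR_s = 100 · T_s / A_s   [%]

Lower TAR = less dense = more emphysematous. The treatable upper-lobe
segments are LB1, LB2, LB3 on the left (LB1 and LB2 may merge into the
single apicoposterior segment LB1+2; the lingula LB4/LB5 is never treated)
and RB1, RB2, RB3 on the right.

**Heterogeneity index.** Per segment, relative to the ipsilateral lower lobe:

    HI_s = TAR_lower_lobe / TAR_s

so HI > 1 means the upper segment is more diseased than the lower lobe; a
segment qualifies for treatment when HI ≥ 1.2.

**Planning.** Every candidate plan treats one segment of a primary upper
lobe in session 1 and one or two segments of the contralateral lobe in
session 2. A candidate survives iff

- session-1 volume is 50% ± 20% of its lobe, session-2 volume 60% ± 20% of
  its lobe, and the combination 110% +20/−15 of the two lobes (each lobe
  counts as 100%, so the combined scale runs to 200%);
- neither session exceeds 1700 ml;
- every treated segment has HI ≥ 1.2.

Options treating a lobe's *unique* least-diseased segment (largest TAR by
more than 2 TAR points) are then removed — unless none would remain. Among
the rest, the lowest combined TAR (`100·ΣT/ΣA` over treated segments) wins;
options within 0.30 TAR points of the minimum are near-ties, broken by
closeness of the combined fraction to the 110% target, then
lexicographically for determinism. Every enumerated option carries a full
constraint audit in the output.

**Trial statistics.** Sample size is the smallest exact-2:1 design whose
two-sided noncentral-*t* power reaches the target; the two-endpoint
Hochberg rule declares the trial positive iff both co-primary p-values are
≤ 0.05 or either is ≤ 0.025; the 12-month analysis value falls through
observed → worst-prior (after a serious adverse event; direction-aware) →
last-observation-carried-forward → baseline intent-to-treat.

## Worked example

Sample size for the quality-of-life endpoint (mean difference 11 points,
SD 14, 80% power, two-sided α = 0.05, 2:1 allocation, 15% dropout):

```bash
$ segplan samplesize --delta 11 --sd 14 --ratio 2 --dropout 0.15
{ "n_control": 20, "n_treatment": 40, "n_total": 60,
  "achieved_power": 0.8054519348471201, "n_total_inflated": 69 }
```

20 controls and 40 treated subjects are the smallest exact-2:1 design with
noncentral-*t* power ≥ 0.80 (achieved 0.805); inflating 60 by 15%
anticipated loss gives 69 to enrol.

Planning on the shipped synthetic lung `tests/data/segments_f1.csv`:

```bash
$ segplan plan --segments tests/data/segments_f1.csv
{ "feasible": true,
  "chosen": { "key": "right:RB1|LB1+2",
    "metrics": { "session1_fraction": 32.45, "session2_fraction": 65.09,
                 "combined_fraction": 97.53, "combined_tar": 6.91,
                 "segment_hi": { "RB1": 2.06, "LB1+2": 2.15 } } },
  "notes": ["removed options treating least-diseased LB3 (left)"] }
```

Of 45 enumerated options the planner treats RB1 (32.4% of the right lobe,
session 1) and the merged LB1+2 (65.1% of the left lobe, session 2):
combined fraction 97.5% sits inside the 95–130% window, both segments clear
HI ≥ 1.2 comfortably, and the plan carries the lowest combined TAR (6.91%,
i.e. the most disease) after LB3 — the left lobe's clearly least-diseased
segment — was protected. Exit code 3 signals "no feasible plan".

Other subcommands: `screen` (eligibility criteria on a patient JSON),
`randomize` (site-stratified permuted blocks), `simulate` (Monte-Carlo
power), `fixture-lung` (synthetic segment tables), `phantom` (NIfTI voxel
phantom from a segment table).

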