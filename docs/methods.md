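# Methods

## Period assignment and averaging

The day is partitioned into three half-open windows: morning [04:00, 11:00),
midday [11:00, 16:00), evening [16:00, 28:00), where 24:00–28:00 denotes
00:00–04:00 of the next calendar day and is attributed to the *previous*
logical day's evening. The protocol literature writes these windows with
touching endpoints without stating inclusion; half-open intervals are the
only convention that yields an exact partition, so a reading at 11:00
belongs to midday and one at 04:00 to morning.

Within each (logical day, period) cell only the first reading counts.
"First" is resolved by timestamp; ties on identical timestamps keep the
earlier input row and log a warning (device extracts are minute-resolved,
so ties can occur). Deduplication is idempotent and caps each period's
contribution at one reading per day. Averages are plain arithmetic means of
the retained readings; a period without readings reports `n_used = 0` and
absent means — there is no imputation, matching a protocol that averages
whatever was measured. Readings outside a participant's configured 14-day
window are dropped with a warning; the protocol does not define a behavior
for late readings and silently averaging them would change the estimand.

## Triage

Grade bands use inclusive comparisons (systolic **or** diastolic at or above
the bound): Grade I 140/90, Grade II 160/100, Grade III 180/110 mmHg.
Source texts mix "≥ 160/100" and "> 160/100"; guideline-style grade bands
are conventionally closed on the left, and the thresholds are configurable
for sensitivity analyses.

A period average based on two or fewer retained measurements never triggers
a notification, regardless of its value (`min_measurements = 3`). The two
operating policies are explicit parameters rather than calendar logic;
`policy_for_date` provides the historical mapping (Grade II+ before
2014-07-01, Grade III-only from then on) for timeline simulations. When
periods qualify at different grades the reported grade is the maximum over
eligible periods — the natural choice for a severity statement, though not
uniquely dictated by the source material. The physician review meeting that
preceded real letters is outside algorithmic scope; the `reasons` audit
trail stands in for the discussion record.

Letters are rendered deterministically from the triage result, the category
flags, and the period averages, so letter output can be diffed across runs.

## Laboratory flagging

Reference intervals are inclusive on both ends (clinical reference intervals
conventionally are); a value exactly at a bound is normal. The morphology
rule is abnormal on blast cells, multiple atypical cells, or **more than**
30 erythroblasts per 200 nucleated cells (strict inequality at 30). Missing
analytes are reported as explicitly missing — never silently normal — and
contribute no abnormality to categories, with a log note.

The roll-up from analytes to the five categories is configuration, because
no authoritative mapping is published: renal = creatinine/BUN; liver =
AST/ALT; hematological = hemoglobin/platelets/leukocytes plus the
morphology rule; blood sugar = glucose alone. Uric acid, sodium and CRP are
flagged but map to no category by default. No lipid thresholds exist in the
reference table, so lipid abnormality is accepted as a precomputed boolean
column; the synthetic generator emits it directly. Samples are nonfasting;
that caveat is documentation only and no adjustment is made.

## Association tests

`chisq_yates` implements the continuity-corrected chi-squared statistic with
the correction clamped at zero (so perfectly balanced tables score exactly
0), with the p-value from the χ²₁ upper tail. `fisher_exact` conditions on
both margins and sums hypergeometric point probabilities ≤ the observed
one, with a 1e-7 relative tie tolerance so equal-probability tables are
counted despite floating point; this is the common software convention for
a two-sided Fisher p, and it reproduces the published small-cell p-values
(0.5889 for counts 3/39/25/187), which rules out mid-p variants.

The selection rule — Fisher iff the smallest observed cell is ≤ 5 —
is reverse-engineered from which published pairs carry the Fisher marker
(minimum cells 5 and 3) versus the chi-squared marker (minimum cells ≥ 10);
callers can force either method. The continuity correction is likewise kept
on because it is the only variant consistent with the published chi-squared
p-values (0.3576 for counts 51/67/50/86; uncorrected gives ≈ 0.29). Both
choices are package defaults, not claims about uniqueness.

Accuracy caveat: the corrected χ² p approximates the exact conditional
(fixed-margins) p well in the tails but can deviate by several percent —
and near p ≈ 1 by up to ~0.1 — because a continuous tail is matched to a
discrete distribution. Where exactness matters, force Fisher.

A category with zero variation among notified participants makes its pairs
untestable; those results carry p = 1 with a degenerate-table note rather
than an error, so a report is always produced.

## Behavior change

Percentages are computed over respondents only (no-answer tracked
separately) and rounded half-up to one decimal — the rounding that
reproduces every published percentage (Python's banker's rounding does
not). McNemar's statistic uses the standard continuity correction
(|b−c|−1)²/(b+c); when b + c < 25 an exact binomial p accompanies it. The
correction overshoots when b = c (exact p = 1, corrected p ≈ 0.92 for any
discordance size); the exact companion is the better report in that corner.
The dichotomy is "under regular treatment" vs the other four behaviors, and
is configurable.

The published paired analysis reports P = 0.08 for the 68 → 107 increase in
regular treatment among 151 paired respondents. No discordant split
consistent with those marginals yields 0.08 under the standard test (the
minimum discordance c − b = 39 with b ≤ 44 forces p < 0.01), so that value
is treated as unreconstructable; the package implements the standard test
and the test suite pins the bound rather than guessing the original
computation.

## Synthetic cohort

The generator's defaults describe a plausible cohort of the kind the
pipeline targets; they are configuration, not estimates.

- **Demographics.** Sex ~ Bernoulli(female_fraction = 2/3). Age is a
  two-component normal mixture, means 35 and 65 years (SDs 7 and 8, weights
  0.45/0.55), clipped to [20, 95] — bimodal with peaks in the 30s and 60s
  and ≈ 40% over 60. The mixture parameters are qualitative: the emulated
  studies publish the shape, not the numbers.
- **Blood pressure.** A latent grade per participant (default prevalences
  0.70/0.20/0.07/0.03 for none/I/II/III) places a true BP uniformly within
  the grade's band, kept 1–2 mmHg inside the cut-offs. Readings add
  N(0, 8²) mmHg noise, are rounded to integers, and are constrained to
  systolic > diastolic. Presence of a reading per (day, period) follows
  adherence probabilities (morning 0.90, midday 0.25, evening 0.85);
  same-period repeats are 1 + Poisson(0.08) readings, an assumption — the
  real repeat distribution is not described.
- **Category flags.** The five binary categories follow a pairwise
  log-linear model P(x) ∝ exp(h·x + Σ_{i<j} J_ij x_i x_j). With only five
  binary variables the 32-state distribution is enumerated exactly and
  sampled directly — no Markov chain, no burn-in, fully deterministic given
  the seed. The field terms h are solved by Newton iteration so the model's
  marginals equal the configured base rates even under nonzero couplings;
  exp(J_ij) is the conditional odds ratio of pair (i, j), and equals the
  marginal odds ratio when no other couplings involve i or j.
- **Lab values.** Each abnormal category places its carrier analyte
  (glucose, creatinine, hemoglobin, AST) 5–40% of the range width outside
  the bound (below, for hemoglobin); everything else sits mid-range, so the
  flagging stage recovers the intended flags exactly. Lipid is emitted as
  its boolean column.
- **Behavior.** A pre answer is drawn from a configurable distribution
  (default close to the published pre-survey mix). The post answer keeps
  regular treatment with probability 0.95, and otherwise switches to
  regular treatment with probability 0.50 if triage (run on the generated
  readings with the configured policy) notified the participant, 0.10 if
  not. Response rates default to 0.90 (pre) and 0.64 (post).

All randomness flows through one `numpy.random.Generator` seeded from the
config, so identical configurations give byte-identical CSVs.

What the generator does **not** emulate: real within-person BP dynamics
(diurnal cycles, trends, white-coat effects), measurement-device error
structure, informative missingness (adherence independent of BP), any
dependence of lab values on BP or age, or the real cohort's absolute counts
(participants measured, letters sent). Passing tests therefore demonstrate
that the pipeline's logic and inference behave correctly under the stated
statistical structure, not that the generator resembles any particular
population.

`recover_parameters` closes the loop: triage sensitivity/specificity
against the latent grade (Wilson 95% intervals), pairwise odds ratios of the
generated flags (Woolf intervals, Haldane 0.5 correction on zero cells)
against exp(J), and the care-transition probabilities against their
configured values.

## Pipeline

Stages persist every intermediate as CSV so later stages can be re-run from
disk with identical results (tested). Validation distinguishes blocking
errors (missing columns, unparseable timestamps, non-physical pressures)
from warnings (a lab row whose participant has no measurements is retained).
The manifest records the package version, a configuration hash, and row
counts per stage.

## Problem sizes and tolerances

The test suite and acceptance script use simulation sizes chosen to make the
statistical checks informative at interactive runtimes: 1,000 participants
for the triage property sweep; 5,000 for demographic calibration (binomial
4-SE bands); 2,000 participants × 100 replicates for odds-ratio coverage
(expect ≥ 90% coverage of a configured OR of 8) and × 1,000 replicates for
the null false-significance rate (exact binomial consistency with
α = 0.005); exhaustive Fisher-oracle verification over all 2×2 tables with
n ≤ 30 in exact rational arithmetic. Fisher ties use a 1e-7 relative
tolerance; field-term calibration solves marginals to 1e-8.
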