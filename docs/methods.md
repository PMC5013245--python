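# Methods

## The referral model

The Module Referral Advice (MRA) is a deterministic rule table mapping
scored screening instruments to one of three colors per topic. All
comparisons are boundary-inclusive, exactly as the deployed cut-offs state
them ("27–35" includes both endpoints, "≥150 min" includes 150):

| topic | green | orange | red |
|---|---|---|---|
| fatigue (CIS subjective fatigue, 8 items 1–7) | < 27 | 27–35 | > 35 |
| return to work (4 CaSUN work-needs items, total 0–20) | no needs | 3–12 | ≥ 13 |
| mood (HADS-A, HADS-D 0–21; MAC negative adjustment 16–64) | A < 8 and D < 8 and MAC ≤ 36 | (A ≥ 8 or D ≥ 8 or MAC > 36) and both ≤ 15 | A > 15 or D > 15 |
| relationships (SSL-D 6–24; CaSUN sexuality/fertility needs) | SSL-D ≤ 7, or no needs | SSL-D 8–9 and needs | SSL-D ≥ 10 and needs |
| physical activity (≥150 min/wk MVPA; ≥30 min moderate on ≥5 d/wk) | both conditions | one condition | neither |
| diet (5 food-group recommendations) | ≥ 4 met | 2–3 met | ≤ 1 met |
| smoking | never / quit before diagnosis | quit after diagnosis | current |

Two cells the published rule table leaves open were decided here and are
design choices of this package, not recovered facts:

* **work-needs totals 1–2** (between "no needs" and the 3–12 orange band)
  are green — green explicitly covers "no or minor complaints", and this
  keeps the rule total;
* **SSL-D ≥ 8 without CaSUN relationship needs** is green — both the orange
  and red rows require the needs flag, so absent needs cannot trigger them.

The mood red column is read as the union of its two clauses (either HADS
subscale above 15), which is the only reading under which the three columns
partition the input space; this is verified exhaustively against an
independent straight-line re-implementation over the full
22 × 22 × 49 (HADS-A × HADS-D × MAC) grid, and all scalar rules are swept
over their entire ranges in the test suite.

All thresholds live in a single `MRACutoffs` dataclass, overridable from a
JSON file (`knwtriage classify --cutoffs`). Instrument scoring is plain
summation; the CIS classifier accepts scores 1–56 although item-level
scoring yields 8–56, so externally supplied scores quoted on the
conventional 1–56 range are not rejected. Raw SQUASH activity-diary scoring
(per-activity MET assignment) is out of scope; the pipeline ingests the two
derived physical-activity quantities.

## Adherence statistics

Module use is dichotomised from logging data: a module is used when pages
1, 2 **and** 3 all appear in its page-visit events ("any three pages" does
not qualify). For a topic and a pair of colors, the 2×2 table of
used/not-used by color is tested with the **uncorrected** Pearson
chi-square, computed in closed form as n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
with the p-value from the upper tail of χ²(1); the Yates correction is
deliberately absent, as only the uncorrected statistic reproduces the
published values. Effect size is the cross-product odds ratio with a Woolf
log-normal CI, exp(log OR ± z·√(1/a+1/b+1/c+1/d)). A zero cell yields an
infinite/zero OR with a flag rather than an exception; a zero margin makes
the chi-square undefined and raises a named error. The published CI method
is unknown (the printed intervals are slightly wider than Woolf, possibly
Cornfield-type), so printed CIs are displayed for reference but never used
as a pass/fail comparison.

**Aggregate reconstruction.** With N = 231 and the published percentages
(share of each color; share of users within a color), cell counts are
rebuilt as `n_color = round(N·pct/100)`, `n_used = round(n_color·pct/100)`
with nearest-integer rounding, half away from zero (no half cases occur
with the published values). This reproduces 20 of the 21 published
chi-square/OR entries within 0.01 — most to the printed precision — and
exposes one internal inconsistency in the published table: the
physical-activity red/orange odds ratio is printed as .186, yet the
reconstructed table (3, 9, 31, 52) reproduces the printed chi-square 0.696
exactly and gives OR 0.559. The report flags this entry.

P-values are displayed to three decimals with values below .0005 shown as
"<.001".

## The synthetic cohort generator

No individual-level data are available, so the generator emulates the study
conditions from published aggregates; its defaults are those conditions.

* **Colors.** Per-topic colors are drawn independently across topics and
  participants from the published marginals (triples that print as 100.1%
  are normalised to sum to 1). A Gaussian-copula hook for cross-topic
  correlation exists but is off by default: no correlations are published
  to calibrate it.
* **Scores.** Generation is score-first: given target colors, instrument
  scores are drawn uniformly from the preimage of each color under the rule
  table (rejection sampling for the two-dimensional mood region), so
  classification of a generated profile reproduces the target colors by
  construction — the round-trip identity is tested over all 3⁷ color
  vectors.
* **Module use.** Bernoulli per module conditional on the drawn color, with
  the published conditional-use probabilities; the residual-symptoms module
  uses its published marginal rate (0.204). Indicators are iid given the
  color — no variance-reducing balancing — so chi-square tests computed on
  synthetic cohorts retain their nominal null distributions.
* **Page logs.** A used module gets pages 1..K (K uniform on 3..10) at its
  use week; an unused module gets, with probability 0.3, a partial glance at
  pages 1–2 (these choices are unpublished plumbing; only "at least the
  first three pages" is load-bearing).
* **Engagement timing.** A participant's last-activity week L follows a
  geometric distribution calibrated so P(L ≤ 16) = 0.80, matching the
  published participant-level statement that ~80% of users were active only
  within the first 16 weeks; per-module weeks are uniform on 0..L with one
  used module pinned at L. Weeks count from first access (week 0).
* **Appreciation.** Ratings are truncated normal on the scale bounds
  (1–10 overall and per module, 1–5 content subquestions), rounded to
  integers. The parent (μ, σ) are moment-matched so that the *discretised*
  truncated distribution has exactly the published mean and SD — the
  published statistics are sample moments of integer ratings, and matching
  the continuous parent instead would bias the simulated overall mean by
  about −0.06. Non-response is Bernoulli at the published responder rate
  182/231 ≈ 0.788; non-responders have all ratings missing, responders rate
  only the modules they used.
* **Demographics** are drawn from the published baseline marginals
  (categorical frequencies; normal draws for age, BMI and weeks since
  treatment, clipped to plausible ranges). They are descriptive furniture:
  no downstream statistic in this package conditions on them.

Identical config + seed gives byte-identical output files (single
sequential PCG64 stream, deterministic writers, floats serialised with
`repr`).

### What the generator does not emulate

Topic independence is a simplification with visible consequences: the
published cohort has more all-or-nothing participants (14.3% used no
module; SD of modules used 1.6) than an independent-topics cohort can
produce (≈8%; SD ≈1.2), because real complaints cluster. Individual-level
summaries that depend on the joint distribution — the mean 2.9 referred
modules, the usage-count SD, the "at least one red MRA" share — are
therefore **not** recovery targets, and passing tests say nothing about
cross-topic structure in real data. Marginal and per-topic conditional
quantities, which are what the adherence statistics consume, are recovered
and are the tested surface.

## Numerical and testing choices

* Sample SD (n−1) everywhere; a single observation reports SD 0 by
  convention. Missing appreciation answers are excluded pairwise, never
  imputed.
* The published module-count distribution has an open "six or more" bin;
  comparisons value it at 6, which reproduces the published mean 2.1 and
  makes the recomputed SD a lower bound (1.5 vs the published 1.6, which
  depends on the unpublished split).
* The chi-square implementation is cross-checked in tests against
  `scipy.stats.chi2_contingency(correction=False)` and, exhaustively for
  all tables with total ≤ 40, against the expected-count definition in
  exact rational arithmetic; the OR and Woolf CI against statsmodels'
  `Table2x2`.
* Calibration-recovery checks simulate cohorts of 50,000 participants; the
  rarest color cell (mood red, 1.7% marginal) holds only ~850 participants
  per cohort, so recovery estimates pool a few replicate cohorts to keep
  Monte Carlo error small relative to the comparison bands. Appreciation
  recovery uses 231-participant replicates so responder counts vary
  realistically around 182.
* Moment matching solves a 2-parameter root-finding problem
  (`scipy.optimize.fsolve` on mean/SD of the discretised truncated normal,
  parameterised by μ and log σ); solutions are cached per scale. If the
  solver failed to converge the generator would fall back to the published
  values as parent parameters; this does not occur for any published scale.

## Known limitations

* The deployed system's handling of the two open rule cells is unknown;
  the defaults above are explicit, conservative choices.
* Reconstructed counts inherit the rounding of the published percentages;
  entries are reproducible only because no rounding half-cases occur.
* The generator's within-participant page/week plumbing is invented beyond
  the published facts it is calibrated to (first-three-pages rule, 16-week
  engagement share) and should not be used to study browsing behaviour.
* Regression analyses of module-count, appreciation and relevance
  predictors on individual-level covariates are out of scope.
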