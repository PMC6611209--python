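# Methods

## Scope and model

The package implements the Basic Priority Rating (BPR) family for
health-program priority-setting: the original Hanlon equation, the
Vilnius–Dandoy revision, the Neiger revision, and the PAHO-adapted
equation, together with the workflow that surrounds them in practice —
multi-rater aggregation, ranking, tier stratification, sensitivity
analysis, synthetic panels, and scoring-template I/O. The equations are
pure arithmetic on bounded ratings; everything scientific in this package
is therefore about (a) faithful component definitions and ranges, (b) how
a panel of raters is reduced to one score per program, and (c) how
sensitive the resulting ranking is to the modelling choices.

Component ranges follow the modern convention: the four seriousness
factors are 0–5 each so that B = B1+B2+B3+B4 cannot exceed 20. The
1984 formulation allowed 0–10 per factor, which can push B past its
nominal range; that historical scale is deliberately not implemented.

## The F multiplier and its reciprocal bounds

Institutional positioning F is a multiplier with neutral value 1.00, so
its bounds must be reciprocal: maximum 1.50, minimum 1/1.5 = 2/3. Scoring
sheets conventionally print the minimum as the two-decimal 0.67, which is
slightly below the exact bound, so validation accepts F down to
2/3 − 0.005 while documentation and the sensitivity tooling treat 2/3 as
the exact lower bound. The earlier trial range 0.50–2.00 (a halving to a
doubling effect) is available to the `f_range_experiment` only, which
remaps each program's F piecewise-linearly onto trial bounds with F = 1
as a fixed point ([2/3, 1] → [f_min, 1], [1, 1.5] → [1, f_max]), so the
neutral meaning of 1.00 is preserved. Trial scores are computed as
(BPR at F=1) × remapped F rather than by constructing component objects,
because trial bounds wider than the canonical range would (by design)
fail validation. The experiment applies to the PAHO equation, the only
one that uses F.

## Benefit–cost in the Vilnius–Dandoy equation

The benefit–cost term carries its own 0–10 point range, which a literal
quotient B/C cannot guarantee (B/C is unbounded as C → 0). It is
therefore treated as an independently rated component; a convenience
constructor `benefit_cost_from_quotient` computes min(B/C, 10) for users
who want the quotient reading, and refuses C = 0.

## Panel aggregation

The canonical pipeline averages components first and computes a single
BPR from the mean components, matching how pilot-test results present
mean components alongside one BPR per program. Because the equations are
nonlinear (products of sums), averaging per-rater BPRs instead gives a
different number; that variant is available behind
`score_panel(..., aggregate_scores=True)` and documented as
non-canonical. The aggregation statistic is the arithmetic mean;
`statistic="median"` is offered for robustness but is never the default.

Numerical detail: means use `math.fsum` (a correctly rounded sum), so
shuffling rater order, program order, or iterating the score matrix
"horizontally" (program-major) versus "vertically" (component-major)
yields bit-identical results; a unanimous panel averages to exactly the
common value. Seriousness is averaged factor-wise when every contributing
rater supplied the four factors, otherwise on the 0–20 total;
effectiveness is averaged on its 0–10 value (the scale on which panel
means are reported). PEARL flags aggregate by per-flag unanimity — a flag
passes only if every contributing rater passed it — a conservative choice
consistent with PEARL's veto semantics; the mean of binary flags would
not be a flag.

Missing data are an error by default (strict policy, naming rater,
program and component); `missing="skip"` drops a rater from the cells
they left blank and logs contributing counts. Panels below six raters are
scored but trigger a warning, reflecting the recommended minimum panel of
six national experts.

## Ranking and tiers

Programs are ordered by descending BPR with competition ranking for ties
(tied programs share the minimum rank, the next rank is skipped) and
program id as a deterministic secondary key. Tier stratification defaults
to rank tertiles — earlier ranks fill the high tier first, and when n is
not divisible by 3 the remainder enlarges high, then medium — because no
published tier cutoffs exist; explicit (high_min, medium_min) BPR
thresholds are accepted and must be strictly decreasing.

## Sensitivity analysis

Rank concordance between two scenarios (two methods, a trial F range
versus F ≡ 1, or a perturbed panel versus the original) is reported as
Spearman's ρ and Kendall's τ-b on the rank vectors, with per-program
ΔBPR and Δrank and the maximum rank shift. τ-b is used so that ties are
handled; a ranking compared with itself is defined as concordance 1
exactly (scipy returns NaN on constant vectors). Methods that differ by
a positive monotone rescaling (e.g. Neiger versus PAHO when E ≡ 0 and
F ≡ 1) always reach τ = 1. One-at-a-time perturbation adds a delta to a
named component on every targeted sheet, clamps to the legal range, and
counts clamped cells in the report.

## Synthetic panels

The generator emulates the structure of a pilot panel: each rater's score
for each rated quantity is the scenario's true (consensus) value plus
independent Gaussian noise, truncated at the range bounds — the simplest
defensible model of rater disagreement on bounded ordinal scales.
Truncation biases means near the bounds; this is measured by the recovery
experiments, not corrected. `noise_sd` is expressed in rating points and
defaults to 1.0, a stated assumption (no rater-level dispersion data are
published): one point on a 0–10 scale is a plausible expert spread.
Percent-scaled quantities (efficacy C1, reach C2) use 10 × noise_sd; F
receives noise on the log scale with sd = 0.05 × noise_sd, so its
reciprocal bounds are treated symmetrically, then is clamped to
[2/3, 1.5] and rounded to two decimals. With `integer_ratings` the point
scores round to whole points, emulating hand-filled sheets. Panels are
reproducible bit-for-bit under a seed (fixed draw order: raters outer,
programs in catalog order, components in a fixed sequence).

What passing synthetic tests does not show: real raters are not unbiased
Gaussian perturbations of a shared consensus — country panels can hold
systematically different views, ratings correlate across components, and
strategic rating is possible. The generator validates the pipeline's
arithmetic, invariances and convergence behaviour, not the behaviour of
real panels.

The ranking-recovery experiment draws replicate panels under child seeds,
scores each, and reports the fraction of programs recovering their exact
true rank plus the probability of recovering the high-priority tertile
set exactly. It requires a strict true ranking (tied true BPRs are
rejected with advice to perturb the scenario). With the pilot consensus
as truth and unit noise, full-ranking recovery rises with panel size but
stays well below 1 even at 48 raters, because the top two programs sit
only 0.7 BPR points apart — a useful reminder that adjacent ranks in
published tables are not strongly determined.

## Template I/O

The canonical exchange format is UTF-8 comma-separated text with `#`
metadata lines, a header row, and one row per rater × program; a `rater`
column distinguishes sheets, and the PEARL columns are prefixed
(`pearl_p` … `pearl_l`) to avoid clashing with component E. Decimal
separator is the dot. Cells are written with Python's shortest-repr
float formatting, so read(write(x)) round-trips at full precision.
Results files carry Group, Program, the mean components, BPR displayed
at one decimal, a full-precision `BPR_full` column, Ranking, and Tier,
ordered by rank. The exact column set of any official spreadsheet
template is not published; this layout is inferred from the published
results table and documented as such. Native `.xlsx` is intentionally
not the canonical format (text diffs and exact round-trips matter more);
spreadsheet users can export CSV.

## Problem sizes used in validation

The test suite enumerates the full integer component grid per method
(about 10⁵ combinations in total) for range and monotonicity checks;
order-invariance runs over 100 random synthetic panels; component-RMSE
convergence uses panel sizes {3, 6, 12, 48} averaged over 100 seeds; and
ranking recovery uses 400 replicates at panel sizes {3, 12, 48}. These
sizes give stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

- Ratings are treated as interval-scaled numbers, as the method itself
  does; no ordinal-scale modelling.
- No rater-reliability weighting, bias correction, or inter-country
  correlation modelling.
- BC is a rating, never estimated from economic data.
- Tier cutoffs beyond tertiles/thresholds (e.g. clustering) are out of
  scope.
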