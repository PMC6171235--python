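# Methods

## The rules as implemented

All rules are retrospective whole-series tests: a rule "signals" if its
pattern occurs anywhere in the series, and a rule combination signals if any
member rule does. This is the event the likelihood-ratio framework
classifies; sequential stopping-time behaviour is covered only by the
closed-form average run lengths for the single-point rule (see below).

**Useful data points.** Observations exactly equal to the centre line
neither break nor contribute to a run and are ignored when counting
crossings. The *n* entering both runs-analysis limit formulas is the count
of off-centre points. This convention is applied uniformly — including to
Western Electric rule 4 — so the engine has a single definition of a run.

**Runs rules.** With n useful points, the longest-run limit is
round(log₂(n) + 3). Rounding is half-away-from-zero; exact .5 ties cannot
occur for integer n (log₂(n) + 3 = k.5 would require n = 2^(k−2.5)), so the
tie rule is documented for completeness only. The crossings limit is the
smallest integer k with binomial(n − 1, ½) CDF ≥ 0.05 (`scipy.stats.binom.ppf`),
i.e. a standard lower 5% binomial quantile; the test requires n ≥ 2 and is
skipped, with an explicit flag in the report, below that. Signals use strict
inequalities: longest run **>** limit, crossings **<** limit. For n = 24
this yields limits of 8 and 8, so a run of more than 8 or fewer than 8
crossings signals. Brute-force enumeration of all 2^m side sequences
(m ≤ 12, in the test suite) confirms that the crossing count follows
binomial(m − 1, ½) exactly and that the crossings test's false-positive
probability is the largest achievable value not exceeding 5% given an
integer cut-off.

**Zone rules.** "Beyond" a sigma limit is strict — a value exactly on a
limit does not trigger. Ties have probability zero for continuous data, and
strictness makes boundary behaviour deterministic. Rules 2 and 3 require
the qualifying points (2 of 3 beyond 2σ, 4 of 5 beyond 1σ) to lie on the
*same side* of the centre line, per the Western Electric handbook; windows
are contiguous and full-length, so series shorter than the window cannot
trigger. The rule statements alone leave the side condition implicit, and a
side-agnostic reading would slightly inflate the false-positive rate of the
combined rule sets; the handbook convention was chosen as the authoritative
one.

## Diagnostic measures

For a rule set evaluated on series with known ground truth, sensitivity and
specificity are the proportions signalling among shift-present and not
signalling among shift-absent series; LR+ = sensitivity/(1 − specificity),
LR− = (1 − sensitivity)/specificity. A zero denominator proportion reports
the ratio as infinity with an explicit flag rather than a silent NaN; an
optional Jeffreys-style correction (add 0.5 to each confusion cell) is
available for small replicate counts but is off by default so that raw
Monte-Carlo estimates are reported unadjusted.

Closed forms are provided for the single-point k-sigma rule under a normal
process: per-point tail α = 2(1 − Φ(k)) (0.0027 at k = 3), ARL₀ = 1/α
(≈ 370), detection probability p(δ) = (1 − Φ(k − δ)) + Φ(−k − δ), and
ARL₁ = 1/p (2.0 at δ = 3). For a whole series of n independent points,
specificity = (1 − α)ⁿ and sensitivity = 1 − (1 − p(δ))ⁿ. This closed form
is the independent oracle against which the stochastic pipeline is checked;
at n = 10, δ = 2 it gives LR+ = 30.8 and LR− = 0.183. ARLs for composite
rule sets have no closed form here and are not simulated: the runs rules
adapt their limits to the growing series, which makes simulated stopping
times ill-behaved, so ARLs are deliberately confined to the single-point
rule.

## The simulation study

The generator emulates the phase-2 monitoring scenario: process centre and
SD are known in advance, limits are fixed at 0 ± 1, 2, 3, and a sustained
shift displaces the data, not the limits. Each simulated series is `length`
iid draws from N(shift, 1). The default design is the full factorial of
lengths {10, 20, 40} × arms {shift 0, shift 2 SD} × 10,000 replicates —
60,000 series in total — scored by the four standard rule combinations
(`we1`, `we1-4`, `anhoej`, `anhoej+we1`). The defaults are the study
conditions; they are what the acceptance checks and the shipped tables
refer to.

The whole-series shift (rather than a mid-series changepoint) is the
scenario under which the closed-form oracle for the single-point rule
matches the simulated benchmark values; a `changepoint_fraction` option
places the shift mid-series for exploration but is off by default.

**Randomness.** Every replicate draws from its own `numpy` substream seeded
deterministically by (root seed, length, arm, replicate), where arm is 0
for shift-absent and 1 for shift-present. Consequences: adding rule sets,
reordering cells, or changing the shift size never changes the noise;
identical configs give bit-identical tables; and comparisons across shift
sizes use common random numbers, so power curves across shifts are exactly,
not just statistically, ordered in expectation. Evaluation is *paired*: the
same series are scored by every rule set, sharpening between-rule-set
comparisons. Cross-language or cross-numpy-version bit-exactness is not
promised; statistical agreement is.

**What the generator does not emulate.** Real improvement data are often
autocorrelated, non-normal, seasonal, or drift gradually rather than
jumping; phase-1 practice recomputes limits as data accrue. None of this is
simulated. Passing tests therefore demonstrate correct operating
characteristics under the stated normal, independent, fixed-limit, sustained
shift conditions — not performance guarantees for arbitrary real data.

## Problem sizes and tolerances

The test suite uses 10,000 replicates per arm where a benchmark value is
asserted (matching the design above) and 300–5,000 replicates for
structural checks where only reproducibility or ordering is at stake.
Stochastic assertions are gated at four binomial standard errors of the
relevant closed-form value (delta-method propagation for ratios), i.e. a
per-assertion false-alarm probability well below 10⁻⁴. The exact
enumeration of side sequences stops at m = 12 (8,190 sequences), enough to
cover every distinct crossings-limit value reachable at small n.

## Interface design choices

* **Run-chart mode is the default** (`analyze`): centre at the sample
  median, Anhøj rules only — the recommended first filter for improvement
  data. Control-chart mode uses the sample mean (or a fixed centre) and
  adds the 3-sigma rule.
* **No SD estimation.** Control-chart mode requires an explicit process SD.
  Estimating sigma from the plotted data (e.g. via moving ranges) is a
  phase-1 task whose interaction with the rules is not evaluated here;
  shipping an unevaluated estimator would misrepresent the validated
  surface.
* **Fail-fast I/O.** Non-numeric or missing cells abort with the offending
  row number; no silent imputation. Verdicts go to stdout, logs to stderr,
  and errors carry a machine-parseable category with a distinct exit code.
* **Extensibility.** Rule sets are disjunctions over rule ids resolved at
  the boundary (`resolve_ruleset`), so additional published rules (Nelson,
  Westgard, …) can be added without touching the evaluation machinery; none
  are shipped, as none were evaluated.

## Known limitations

* Likelihood-ratio estimates at 10,000 replicates carry Monte-Carlo error
  of roughly ±6% (LR+) and ±2% (LR−) at the benchmark cell; single-run
  values should be read with that in mind.
* The crossings test is undefined below two useful points and the runs
  limits are approximations validated for the chart lengths studied
  (10–40 points); both limits are non-decreasing in n, so behaviour
  degrades gracefully, but very short charts have little power.
* Only normal, independent series are simulated (see above); p/u/c-type
  attribute charts and non-normal count data are out of scope.
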