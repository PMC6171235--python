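"""Run-chart and control-chart rules for detecting non-random variation.

This module implements two families of retrospective tests applied to an
ordered sequence of observations plotted against a centre line:

* the **Anhøj rules** — a runs analysis that signals when the longest run of
  points on one side of the centre line is unusually long
  (> round(log2(n) + 3)) or the number of centre-line crossings is unusually
  small (< the lower 5% quantile of binomial(n − 1, 0.5)), where *n* counts
  only *useful* points, i.e. observations not falling exactly on the centre
  line;

* the **Western Electric zone rules 1–4** — one or more points beyond a
  3-sigma limit; two of three successive points beyond a 2-sigma limit on the
  same side; four of five successive points beyond a 1-sigma limit on the
  same side; eight or more successive points on one side of the centre line.

All rules are pure functions of the data and a :class:`ChartSpec`; they hold
the centre and sigma limits fixed (a phase-2 reading of the chart, where the
process parameters are known in advance).

Conventions adopted here and applied uniformly:

* "Beyond" a sigma limit is strict: a value exactly on a limit does not
  trigger.  Ties have probability zero for continuous data, and strictness
  makes boundary behaviour deterministic.
* Points exactly on the centre line neither break nor contribute to a run,
  for the Western Electric rule 4 as well as for the Anhøj runs rule.
* Zone rules 2 and 3 require the qualifying points to fall on the *same*
  side of the centre line, following the Western Electric handbook.
* Windows for rules 2 and 3 are contiguous and full-length (3 and 5 points);
  there are no partial windows at the series edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import binom

from .errors import ConfigurationError, InvalidSeriesError

__all__ = [
    "ChartSpec",
    "RuleResult",
    "RuleReport",
    "RULESETS",
    "RULE_IDS",
    "as_series",
    "useful_count",
    "longest_run",
    "count_crossings",
    "run_limit",
    "crossings_limit",
    "we_rule1",
    "we_rule2",
    "we_rule3",
    "we_rule4",
    "anhoej_signal",
    "apply_ruleset",
    "rule_signals",
    "resolve_ruleset",
]

RULE_IDS = ("we1", "we2", "we3", "we4", "anhoej_runs", "anhoej_crossings")

#: Named rule combinations evaluated throughout the package.  ``anhoej`` is
#: the pair of runs tests usable on a plain run chart; the others add the
#: sigma-limit zone rules of a control chart.
RULESETS: Mapping[str, frozenset[str]] = {
    "we1": frozenset({"we1"}),
    "we1-4": frozenset({"we1", "we2", "we3", "we4"}),
    "anhoej": frozenset({"anhoej_runs", "anhoej_crossings"}),
    "anhoej+we1": frozenset({"anhoej_runs", "anhoej_crossings", "we1"}),
}


@dataclass(frozen=True)
class ChartSpec:
    """Centre line and process standard deviation of a control chart.

    Parameters
    ----------
    centre:
        Process centre (mean or median) in the units of the measurements.
    sd:
        Process standard deviation; must be strictly positive.

    The six sigma limits centre ± 1·sd, ± 2·sd, ± 3·sd are derived, never
    stored, so they can never fall out of order.
    """

    centre: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.centre) and math.isfinite(self.sd)):
            raise ConfigurationError("chart centre and sd must be finite")
        if self.sd <= 0:
            raise ConfigurationError(f"chart sd must be > 0, got {self.sd}")

    def limit(self, k: float) -> float:
        """Value of the ``k``-sigma limit (``k`` may be negative)."""
        return self.centre + k * self.sd

    @property
    def limits(self) -> tuple[float, ...]:
        """The six sigma limits in increasing order (−3, −2, −1, +1, +2, +3)."""
        return tuple(self.limit(k) for k in (-3, -2, -1, 1, 2, 3))


@dataclass(frozen=True)
class RuleResult:
    """Outcome of one rule on one series: the boolean signal plus evidence
    (observed statistic, its critical value, triggering indices)."""

    rule: str
    signal: bool
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RuleReport:
    """Per-rule results for one series together with the overall verdict.

    ``signal`` is the disjunction of the member rule signals: the chart shows
    non-random variation if any requested rule fires anywhere in the series.
    """

    results: dict[str, RuleResult]
    n_useful: int
    signal: bool

    @property
    def triggered(self) -> list[str]:
        """Rule ids that signalled, in canonical order."""
        return [r for r in RULE_IDS if r in self.results and self.results[r].signal]


def as_series(values: Iterable[float]) -> np.ndarray:
    """Validate and convert an observation sequence to a 1-D float array.

    Raises :class:`InvalidSeriesError` if the sequence is empty, not
    one-dimensional, or contains non-finite values (NaN/inf).  Missing-value
    handling is an I/O concern; the rule engine refuses them outright.
    """
    try:
        x = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise InvalidSeriesError(f"series is not numeric: {exc}") from exc
    if x.ndim != 1:
        raise InvalidSeriesError(f"series must be one-dimensional, got shape {x.shape}")
    if x.size == 0:
        raise InvalidSeriesError("series is empty")
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise InvalidSeriesError(f"series contains a non-finite value at position {bad}")
    return x


def _useful_sides(x: np.ndarray, centre: float) -> tuple[np.ndarray, np.ndarray]:
    """Original indices and signs (±1) of the points off the centre line."""
    idx = np.flatnonzero(x != centre)
    return idx, np.sign(x[idx] - centre)


def _runs(sides: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets (within the useful subsequence) and lengths of maximal
    same-side runs."""
    if sides.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    change = np.flatnonzero(sides[1:] != sides[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [sides.size]))
    return starts, ends - starts


def useful_count(values: Iterable[float], centre: float) -> int:
    """Number of *useful* data points: observations strictly different from
    the centre.  On-centre points neither break nor contribute to runs, so
    they are excluded from the n entering the runs-analysis limit formulas.
    """
    x = as_series(values)
    return int(np.count_nonzero(x != centre))


def longest_run(values: Iterable[float], centre: float) -> int:
    """Length of the longest run of successive points on one side of the
    centre line, after dropping on-centre points.  Returns 0 if every point
    sits on the centre line."""
    x = as_series(values)
    _, sides = _useful_sides(x, centre)
    _, lengths = _runs(sides)
    return int(lengths.max()) if lengths.size else 0


def count_crossings(values: Iterable[float], centre: float) -> int:
    """Number of centre-line crossings: adjacent pairs of useful points on
    opposite sides, with on-centre points ignored.  Equals (number of runs
    − 1) whenever at least one useful point exists."""
    x = as_series(values)
    _, sides = _useful_sides(x, centre)
    if sides.size == 0:
        return 0
    return int(np.count_nonzero(sides[1:] != sides[:-1]))


def run_limit(n_useful: int) -> int:
    """Upper 95% prediction limit for the longest run in a random process
    with ``n_useful`` useful points: round(log2(n) + 3), rounded to the
    nearest integer.  A run *strictly longer* than this signals a shift.

    Half-way ties cannot occur for integer n (log2(n) + 3 = k.5 would need
    n = 2**(k − 2.5)), so the round-half-away-from-zero choice is moot.
    """
    if n_useful < 1:
        raise InvalidSeriesError(f"run_limit needs n_useful >= 1, got {n_useful}")
    return int(math.floor(math.log2(n_useful) + 3 + 0.5))


@lru_cache(maxsize=None)
def crossings_limit(n_useful: int) -> int:
    """Lower 5% prediction bound for the number of crossings.

    In a random process the crossing count follows binomial(n − 1, 0.5); the
    bound is the smallest integer k whose CDF is at least 0.05.  An observed
    count *strictly below* this value signals a shift.
    """
    if n_useful < 2:
        raise InvalidSeriesError(f"crossings_limit needs n_useful >= 2, got {n_useful}")
    return int(binom.ppf(0.05, n_useful - 1, 0.5))


def we_rule1(values: Iterable[float], spec: ChartSpec) -> RuleResult:
    """One or more points beyond a 3-sigma limit (strictly outside)."""
    x = as_series(values)
    d = x - spec.centre
    idx = np.flatnonzero(np.abs(d) > 3 * spec.sd)
    return RuleResult("we1", bool(idx.size), {"indices": idx.tolist()})


def _zone_rule(
    rule: str, x: np.ndarray, spec: ChartSpec, k_sigma: float, need: int, window: int
) -> RuleResult:
    """Shared k-of-m zone test: ``need`` of ``window`` successive points
    strictly beyond the ``k_sigma`` limit on the same side of the centre."""
    d = x - spec.centre
    for side_mask in (d > k_sigma * spec.sd, d < -k_sigma * spec.sd):
        if x.size < window:
            break
        counts = np.convolve(side_mask.astype(np.intp), np.ones(window, dtype=np.intp), "valid")
        hits = np.flatnonzero(counts >= need)
        if hits.size:
            start = int(hits[0])
            in_window = np.flatnonzero(side_mask[start : start + window]) + start
            return RuleResult(
                rule,
                True,
                {"window_start": start, "indices": in_window.tolist()},
            )
    return RuleResult(rule, False, {"window_start": None, "indices": []})


def we_rule2(values: Iterable[float], spec: ChartSpec) -> RuleResult:
    """Two of three successive points beyond a 2-sigma limit, same side."""
    return _zone_rule("we2", as_series(values), spec, 2.0, 2, 3)


def we_rule3(values: Iterable[float], spec: ChartSpec) -> RuleResult:
    """Four of five successive points beyond a 1-sigma limit, same side."""
    return _zone_rule("we3", as_series(values), spec, 1.0, 4, 5)


def we_rule4(values: Iterable[float], spec: ChartSpec) -> RuleResult:
    """Eight or more successive points on one side of the centre line.

    Uses the same on-centre convention as the runs analysis: points exactly
    on the centre line neither break nor contribute to the run.
    """
    x = as_series(values)
    idx, sides = _useful_sides(x, spec.centre)
    starts, lengths = _runs(sides)
    longest = int(lengths.max()) if lengths.size else 0
    evidence: dict = {"longest_run": longest, "limit": 8, "indices": []}
    if longest >= 8:
        j = int(np.argmax(lengths))
        evidence["indices"] = idx[starts[j] : starts[j] + lengths[j]].tolist()
    return RuleResult("we4", longest >= 8, evidence)


def anhoej_signal(values: Iterable[float], centre: float) -> tuple[bool, dict[str, RuleResult]]:
    """Apply the two Anhøj runs-analysis tests against a centre line.

    Returns the combined verdict (either test signalling is diagnostic of
    non-random variation) and the per-test results.  The crossings test is
    skipped, with an explicit flag, when fewer than two useful points exist;
    the runs test is skipped when no useful point exists.
    """
    x = as_series(values)
    _, sides = _useful_sides(x, centre)
    n = int(sides.size)
    _, lengths = _runs(sides)
    lr = int(lengths.max()) if lengths.size else 0

    if n >= 1:
        rl = run_limit(n)
        runs_res = RuleResult(
            "anhoej_runs",
            lr > rl,
            {"longest_run": lr, "limit": rl, "n_useful": n, "skipped": False},
        )
    else:
        runs_res = RuleResult(
            "anhoej_runs",
            False,
            {"longest_run": 0, "limit": None, "n_useful": 0, "skipped": True},
        )

    if n >= 2:
        nc = int(np.count_nonzero(sides[1:] != sides[:-1]))
        cl = crossings_limit(n)
        cross_res = RuleResult(
            "anhoej_crossings",
            nc < cl,
            {"crossings": nc, "limit": cl, "n_useful": n, "skipped": False},
        )
    else:
        cross_res = RuleResult(
            "anhoej_crossings",
            False,
            {"crossings": 0, "limit": None, "n_useful": n, "skipped": True},
        )

    results = {"anhoej_runs": runs_res, "anhoej_crossings": cross_res}
    return runs_res.signal or cross_res.signal, results


def resolve_ruleset(ruleset: str | Iterable[str]) -> frozenset[str]:
    """Resolve a named rule set or an iterable of rule ids to a frozenset,
    validating every id."""
    if isinstance(ruleset, str):
        key = ruleset.lower()
        if key in RULESETS:
            return RULESETS[key]
        if key in RULE_IDS:
            return frozenset({key})
        raise ConfigurationError(
            f"unknown rule set {ruleset!r}; known sets: {', '.join(RULESETS)}"
        )
    rules = frozenset(str(r).lower() for r in ruleset)
    if not rules:
        raise ConfigurationError("rule set is empty")
    unknown = rules - set(RULE_IDS)
    if unknown:
        raise ConfigurationError(f"unknown rule ids: {', '.join(sorted(unknown))}")
    return rules


_WE_RULES = {"we1": we_rule1, "we2": we_rule2, "we3": we_rule3, "we4": we_rule4}


def apply_ruleset(
    values: Iterable[float],
    spec: ChartSpec,
    ruleset: str | Iterable[str] = "anhoej",
) -> RuleReport:
    """Evaluate a rule combination on a series against a chart specification.

    The verdict is retrospective: a rule "fires" if its pattern occurs
    anywhere in the series, and the combined signal is the disjunction over
    the member rules.  The full per-rule report is returned regardless of
    the verdict so that the evidence (runs, crossings, triggering indices)
    can be inspected or printed.
    """
    rules = resolve_ruleset(ruleset)
    x = as_series(values)
    results: dict[str, RuleResult] = {}
    if rules & {"anhoej_runs", "anhoej_crossings"}:
        _, anhoej = anhoej_signal(x, spec.centre)
        for rid in ("anhoej_runs", "anhoej_crossings"):
            if rid in rules:
                results[rid] = anhoej[rid]
    for rid, fn in _WE_RULES.items():
        if rid in rules:
            results[rid] = fn(x, spec)
    return RuleReport(
        results=results,
        n_useful=useful_count(x, spec.centre),
        signal=any(r.signal for r in results.values()),
    )


def rule_signals(values: np.ndarray, spec: ChartSpec) -> dict[str, bool]:
    """Fast path: boolean signals of all six rules in one pass.

    Used by the simulation study, which evaluates every rule once per series
    and combines them into rule-set verdicts afterwards; agrees with the
    evidence-carrying functions above on every input.
    """
    x = np.asarray(values, dtype=float)
    d = x - spec.centre
    sides = np.sign(d)
    sides = sides[sides != 0]
    n = sides.size
    if n:
        n_cross = int(np.count_nonzero(sides[1:] != sides[:-1]))
        change = np.flatnonzero(sides[1:] != sides[:-1])
        bounds = np.concatenate(([0], change + 1, [n]))
        lr = int(np.diff(bounds).max())
    else:
        n_cross, lr = 0, 0

    sd = spec.sd
    out: dict[str, bool] = {}
    out["we1"] = bool(np.any(np.abs(d) > 3 * sd))
    out["we2"] = _k_of_m(d > 2 * sd, 2, 3) or _k_of_m(d < -2 * sd, 2, 3)
    out["we3"] = _k_of_m(d > sd, 4, 5) or _k_of_m(d < -sd, 4, 5)
    out["we4"] = lr >= 8
    out["anhoej_runs"] = n >= 1 and lr > run_limit(n)
    out["anhoej_crossings"] = n >= 2 and n_cross < crossings_limit(n)
    return out


def _k_of_m(mask: np.ndarray, k: int, m: int) -> bool:
    if mask.size < m:
        return False
    cs = np.cumsum(mask, dtype=np.intp)
    window = cs[m - 1 :].copy()
    window[1:] -= cs[:-m]
    return bool(window.max() >= k)
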