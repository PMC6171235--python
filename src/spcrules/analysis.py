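"""Chart analysis of user data and regeneration of the simulation-study
likelihood-ratio table.

Two analysis modes mirror recommended practice for improvement data:

* **run-chart mode** (default): centre line at the sample median, Anhøj
  runs rules only.  This is "filter no. 1" — it needs no sigma limits and
  no distributional assumptions.
* **control-chart mode**: centre line at the sample mean (or a fixed value)
  with user-supplied process SD; applies the Anhøj rules plus the 3-sigma
  rule.  The SD must be supplied explicitly: estimating it from the data at
  hand is a phase-1 problem this tool deliberately does not solve, since
  the rule evaluation framework assumes known process parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import ConfusionCounts, likelihood_ratios
from .errors import ConfigurationError
from .io import SeriesFile
from .rules import ChartSpec, RuleReport, apply_ruleset
from .simulate import StudyConfig, run_study

__all__ = ["AnalysisReport", "analyze", "summarize_study", "reproduce_figure2"]

RULE_DESCRIPTIONS = {
    "we1": "point(s) beyond the 3-sigma limits",
    "we2": "2 of 3 successive points beyond a 2-sigma limit",
    "we3": "4 of 5 successive points beyond a 1-sigma limit",
    "we4": "8 or more successive points on one side of the centre line",
    "anhoej_runs": "unusually long run",
    "anhoej_crossings": "unusually few crossings",
}


@dataclass(frozen=True)
class AnalysisReport:
    """Result of reading one chart: the parameters used, the per-rule
    report, and a human-readable verdict."""

    mode: str
    centre_source: str
    centre: float
    sd: float | None
    ruleset: str | tuple[str, ...]
    report: RuleReport

    @property
    def verdict(self) -> str:
        return "non-random variation" if self.report.signal else "random variation"

    def describe(self) -> str:
        """Multi-line plain-text summary suitable for printing."""
        lines = [
            f"mode: {self.mode} chart",
            f"centre: {self.centre:g} ({self.centre_source})",
        ]
        if self.sd is not None:
            lines.append(f"sd: {self.sd:g}")
        lines.append(f"useful data points: {self.report.n_useful}")
        for rid, res in self.report.results.items():
            mark = "SIGNAL" if res.signal else "ok"
            detail = ""
            if rid == "anhoej_runs" and not res.evidence.get("skipped"):
                detail = (
                    f" (longest run {res.evidence['longest_run']},"
                    f" limit {res.evidence['limit']})"
                )
            elif rid == "anhoej_crossings" and not res.evidence.get("skipped"):
                detail = (
                    f" (crossings {res.evidence['crossings']},"
                    f" limit {res.evidence['limit']})"
                )
            elif res.evidence.get("skipped"):
                detail = " (skipped: too few useful points)"
            elif res.signal and res.evidence.get("indices"):
                detail = f" (points {res.evidence['indices']})"
            lines.append(f"  {rid}: {mark}{detail}")
        if self.report.signal:
            reasons = "; ".join(
                RULE_DESCRIPTIONS[r] for r in self.report.triggered
            )
            lines.append(f"verdict: non-random variation ({reasons})")
        else:
            lines.append("verdict: random variation")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "centre": self.centre,
            "centre_source": self.centre_source,
            "sd": self.sd,
            "n_useful": self.report.n_useful,
            "verdict": self.verdict,
            "triggered": self.report.triggered,
            "rules": {
                rid: {"signal": res.signal, **res.evidence}
                for rid, res in self.report.results.items()
            },
        }


def analyze(
    data: SeriesFile | np.ndarray,
    mode: str = "run",
    centre: float | str | None = None,
    sd: float | None = None,
    ruleset: str | tuple[str, ...] | None = None,
) -> AnalysisReport:
    """Analyse a series for non-random variation.

    Parameters
    ----------
    data:
        A parsed :class:`~spcrules.io.SeriesFile` or a plain array.
    mode:
        ``"run"`` (median centre, Anhøj rules) or ``"control"`` (mean
        centre, Anhøj rules + 3-sigma rule; requires ``sd``).
    centre:
        Override the centre: a number, ``"median"`` or ``"mean"``.
    sd:
        Process standard deviation; required whenever the rule set includes
        a sigma-limit rule.
    ruleset:
        Override the mode's default rule combination.
    """
    values = data.values if isinstance(data, SeriesFile) else np.asarray(data, float)
    if mode not in ("run", "control"):
        raise ConfigurationError(f"mode must be 'run' or 'control', got {mode!r}")

    if centre is None:
        centre = "median" if mode == "run" else "mean"
    if isinstance(centre, str):
        source = centre
        if centre == "median":
            centre_value = float(np.median(values))
        elif centre == "mean":
            centre_value = float(np.mean(values))
        else:
            raise ConfigurationError(
                f"centre must be a number, 'median' or 'mean', got {centre!r}"
            )
    else:
        source, centre_value = "fixed", float(centre)

    if ruleset is None:
        ruleset = "anhoej" if mode == "run" else "anhoej+we1"

    from .rules import resolve_ruleset

    members = resolve_ruleset(ruleset)
    needs_sd = bool(members & {"we1", "we2", "we3"})
    if needs_sd and sd is None:
        raise ConfigurationError(
            "sigma-limit rules need a process SD: pass sd explicitly "
            "(SD estimation from the plotted data is out of scope)"
        )
    spec = ChartSpec(centre_value, sd if sd is not None else 1.0)
    report = apply_ruleset(values, spec, ruleset)
    return AnalysisReport(
        mode=mode,
        centre_source=source,
        centre=centre_value,
        sd=sd,
        ruleset=ruleset,
        report=report,
    )


def summarize_study(table: pd.DataFrame, correction: float = 0.0) -> pd.DataFrame:
    """Append diagnostic-summary columns (sensitivity, specificity, LR+,
    LR−, infinity flags) to a tidy confusion table from
    :func:`~spcrules.simulate.run_study`."""
    out = table.copy()
    summaries = []
    for _, row in table.iterrows():
        c = ConfusionCounts.from_proportions(
            tp=row["tp"], fp=row["fp"], n_pos=int(row["n_reps"]), n_neg=int(row["n_reps"])
        )
        summaries.append(likelihood_ratios(c, correction=correction))
    out["sensitivity"] = [s.sensitivity for s in summaries]
    out["specificity"] = [s.specificity for s in summaries]
    out["lr_pos"] = [s.lr_pos for s in summaries]
    out["lr_neg"] = [s.lr_neg for s in summaries]
    out["lr_pos_infinite"] = [s.lr_pos_infinite for s in summaries]
    out["lr_neg_infinite"] = [s.lr_neg_infinite for s in summaries]
    return out


def reproduce_figure2(config: StudyConfig | None = None) -> pd.DataFrame:
    """Regenerate the likelihood-ratio table of the simulation study.

    With the default configuration this simulates 10,000 series per arm for
    lengths 10, 20 and 40 with a 2 SD shift, scores each series with the
    four standard rule combinations, and returns one row per (ruleset,
    length) with LR+ and LR− alongside the confusion proportions.
    """
    if config is None:
        config = StudyConfig()
    return summarize_study(run_study(config))
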