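"""Diagnostic value of chart rules: sensitivity, specificity, likelihood
ratios and average run lengths.

A chart rule is a diagnostic test for non-random variation.  Writing α for
the false-positive probability (signal given a random process) and β for the
false-negative probability (no signal given a real shift):

* sensitivity = 1 − β, specificity = 1 − α;
* LR+ = sensitivity / (1 − specificity): how many times more likely a
  positive result is when a shift is present than when it is not (> 10 is
  strong evidence *for* a shift);
* LR− = (1 − sensitivity) / specificity (< 0.1 is strong evidence against);
* ARL0 = 1/α, the average number of points between false alarms in control;
  ARL1 = 1/(1 − β), the average number of points to detection out of
  control.

Unlike predictive values, likelihood ratios do not depend on the prevalence
of non-random variation, which is what makes them usable for comparing rule
combinations across simulated conditions.

Closed forms are provided for the single-point 3-sigma rule (any observation
strictly outside centre ± k·SD), whose per-point signal probability under a
normal process is elementary; these serve as independent oracles for the
Monte-Carlo study in :mod:`spcrules.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import ConfigurationError

__all__ = [
    "ConfusionCounts",
    "DiagnosticSummary",
    "likelihood_ratios",
    "alpha_point",
    "arl0",
    "arl1_point",
    "we1_series_oracle",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts from classifying series with known ground truth.

    ``tp``/``fn`` partition the ``n_pos`` shift-present series, ``fp``/``tn``
    the ``n_neg`` shift-absent series.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigurationError("n_pos and n_neg must be >= 1")
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")
        if not math.isclose(self.tp + self.fn, self.n_pos, rel_tol=1e-9):
            raise ConfigurationError("tp + fn must equal n_pos")
        if not math.isclose(self.fp + self.tn, self.n_neg, rel_tol=1e-9):
            raise ConfigurationError("fp + tn must equal n_neg")

    @classmethod
    def from_proportions(
        cls, tp: float, fp: float, n_pos: int, n_neg: int
    ) -> "ConfusionCounts":
        """Build counts from the true- and false-positive *proportions*."""
        return cls(
            tp=tp * n_pos,
            fp=fp * n_neg,
            tn=(1.0 - fp) * n_neg,
            fn=(1.0 - tp) * n_pos,
            n_pos=n_pos,
            n_neg=n_neg,
        )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Derived diagnostic measures for one rule set under one condition.

    ``lr_pos_infinite`` / ``lr_neg_infinite`` flag likelihood ratios whose
    denominator proportion was exactly zero; the ratio is then reported as
    ``math.inf`` rather than a silent NaN.
    """

    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    lr_pos_infinite: bool = False
    lr_neg_infinite: bool = False

    @property
    def alpha(self) -> float:
        return 1.0 - self.specificity

    @property
    def beta(self) -> float:
        return 1.0 - self.sensitivity


def likelihood_ratios(c: ConfusionCounts, correction: float = 0.0) -> DiagnosticSummary:
    """Convert confusion counts to sensitivity, specificity, LR+ and LR−.

    LR+ = TP/FP = sensitivity/(1 − specificity) and
    LR− = FN/TN = (1 − sensitivity)/specificity, where TP, FP, FN, TN are
    the proportions positive/negative within each arm.

    A zero false-positive proportion makes LR+ infinite and a zero
    true-negative proportion makes LR− infinite; both are reported as
    ``inf`` with an explicit flag.  ``correction`` optionally adds a
    constant (e.g. 0.5, Jeffreys-style) to every cell before forming
    proportions — useful for small replicate counts, off by default so that
    raw Monte-Carlo estimates are reported unadjusted.
    """
    if correction < 0:
        raise ConfigurationError("correction must be >= 0")
    tp = c.tp + correction
    fp = c.fp + correction
    tn = c.tn + correction
    fn = c.fn + correction
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)

    if fp > 0:
        lr_pos, pos_inf = (tp / (tp + fn)) / (fp / (fp + tn)), False
    else:
        lr_pos, pos_inf = math.inf, True
    if tn > 0:
        lr_neg, neg_inf = (fn / (tp + fn)) / (tn / (fp + tn)), False
    else:
        lr_neg, neg_inf = math.inf, True

    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        lr_pos_infinite=pos_inf,
        lr_neg_infinite=neg_inf,
    )


def alpha_point(k_sigma: float = 3.0) -> float:
    """Probability that a single in-control normal observation falls
    strictly outside centre ± k·SD: the two-sided tail 2·(1 − Φ(k)).

    For the conventional 3-sigma limits this is 0.0027.
    """
    if k_sigma < 0:
        raise ConfigurationError("k_sigma must be >= 0")
    return float(2.0 * norm.sf(k_sigma))


def arl0(k_sigma: float = 3.0) -> float:
    """In-control average run length 1/α for the single-point k-sigma rule:
    the expected number of points between false alarms (≈ 370 at 3 sigma)."""
    a = alpha_point(k_sigma)
    if a == 0:
        return math.inf
    return 1.0 / a


def detection_probability(shift: float, k_sigma: float = 3.0) -> float:
    """P(single point strictly outside ± k·SD | mean shifted by ``shift`` SD):
    (1 − Φ(k − shift)) + Φ(−k − shift)."""
    return float(norm.sf(k_sigma - shift) + norm.cdf(-k_sigma - shift))


def arl1_point(shift: float, k_sigma: float = 3.0) -> float:
    """Out-of-control average run length 1/(1 − β) of the single-point
    k-sigma rule under a sustained mean shift of ``shift`` SD units.

    Reduces to :func:`arl0` at shift 0 and approaches 1 for large shifts
    (e.g. 2.0 at a 3 SD shift with 3-sigma limits).
    """
    p = detection_probability(shift, k_sigma)
    if p == 0:
        return math.inf
    return 1.0 / p


def we1_series_oracle(
    n: int, shift: float, k_sigma: float = 3.0
) -> DiagnosticSummary:
    """Closed-form operating characteristics of the any-point-outside-±k rule
    for a series of ``n`` independent normal points.

    With independent points, specificity = (1 − α)ⁿ and
    sensitivity = 1 − (Φ(k − δ) − Φ(−k − δ))ⁿ for a whole-series shift δ.
    This is the analytic benchmark against which the Monte-Carlo study's
    single-point-rule cells are checked.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    specificity = (1.0 - alpha_point(k_sigma)) ** n
    sensitivity = 1.0 - (1.0 - detection_probability(shift, k_sigma)) ** n

    if specificity < 1.0:
        lr_pos, pos_inf = sensitivity / (1.0 - specificity), False
    else:
        lr_pos, pos_inf = math.inf, True
    if specificity > 0.0:
        lr_neg, neg_inf = (1.0 - sensitivity) / specificity, False
    else:
        lr_neg, neg_inf = math.inf, True
    return DiagnosticSummary(
        sensitivity=sensitivity,
        specificity=specificity,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        lr_pos_infinite=pos_inf,
        lr_neg_infinite=neg_inf,
    )
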