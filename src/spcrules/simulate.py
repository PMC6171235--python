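"""Seeded Monte-Carlo study of chart-rule operating characteristics.

The study design is a full factorial over series length and shift size.
For every length, two arms of ``n_reps`` series each are simulated:

* a shift-absent arm — iid draws from N(centre, sd);
* a shift-present arm — iid draws from N(centre + shift·sd, sd).

The chart specification stays fixed (the shift displaces the data, not the
limits): this is the phase-2 scenario of monitoring against known process
parameters after a sustained change.  Every simulated series is classified
by every requested rule combination — a *paired* evaluation that reuses the
same series across rule sets and sharpens between-rule-set comparisons —
and the resulting confusion proportions per (ruleset, length) cell feed the
likelihood-ratio summaries in :mod:`spcrules.diagnostics`.

Randomness is reproducible: each replicate gets its own substream derived
deterministically from (root seed, length, arm, replicate), so adding rule
sets, reordering cells, or changing the shift size never changes the noise.
Keying the substream by arm rather than by shift value also gives common
random numbers across shift sizes, which makes power comparisons across
shifts exact rather than merely statistical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .rules import RULE_IDS, RULESETS, ChartSpec, resolve_ruleset, rule_signals

__all__ = ["StudyConfig", "simulate_series", "run_study"]

DEFAULT_RULESETS = ("we1", "we1-4", "anhoej", "anhoej+we1")


@dataclass(frozen=True)
class StudyConfig:
    """Full-factorial simulation design.

    Defaults reproduce the reference study: 10,000 replicates per arm for
    series lengths 10, 20 and 40, a sustained shift of 2 SD, and a fixed
    chart at centre 0 with sigma limits at ±1, ±2, ±3.

    ``changepoint_fraction`` optionally places the shift mid-series (the
    shift starts at ``round(fraction · length)``); by default the whole
    series is displaced.
    """

    lengths: tuple[int, ...] = (10, 20, 40)
    shift: float = 2.0
    n_reps: int = 10_000
    seed: int = 1
    rulesets: tuple[str, ...] = DEFAULT_RULESETS
    centre: float = 0.0
    sd: float = 1.0
    changepoint_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if not self.lengths or any(n < 2 for n in self.lengths):
            raise ConfigurationError("lengths must be a non-empty list of integers >= 2")
        if self.shift < 0:
            raise ConfigurationError("shift must be >= 0 (in SD units)")
        if self.changepoint_fraction is not None and not (
            0.0 < self.changepoint_fraction < 1.0
        ):
            raise ConfigurationError("changepoint_fraction must be in (0, 1)")
        for rs in self.rulesets:
            resolve_ruleset(rs)
        object.__setattr__(self, "lengths", tuple(int(n) for n in self.lengths))
        object.__setattr__(self, "rulesets", tuple(self.rulesets))

    @property
    def spec(self) -> ChartSpec:
        return ChartSpec(self.centre, self.sd)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        d = dict(d)
        for key in ("lengths", "rulesets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Load a config from JSON or YAML depending on the file suffix."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def simulate_series(
    length: int,
    shift: float,
    rng: np.random.Generator,
    centre: float = 0.0,
    sd: float = 1.0,
    changepoint: int | None = None,
) -> np.ndarray:
    """Draw one series of iid normal observations with a known shift.

    ``shift`` is in SD units and displaces the mean of the whole series, or
    only of the points from ``changepoint`` onwards when a changepoint index
    is given.
    """
    if length < 1:
        raise ConfigurationError("length must be >= 1")
    x = rng.normal(loc=centre, scale=sd, size=length)
    if changepoint is None:
        x += shift * sd
    else:
        if not 0 <= changepoint <= length:
            raise ConfigurationError("changepoint must lie within the series")
        x[changepoint:] += shift * sd
    return x


def _replicate_rng(seed: int, length: int, arm: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate substream; arm 0 = shift absent, 1 = present."""
    return np.random.default_rng(np.random.SeedSequence([seed, length, arm, replicate]))


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the full factorial study and return tidy confusion proportions.

    One row per (ruleset, length) cell with columns ``ruleset, length,
    shift, tp, fp, tn, fn, n_reps, seed``; ``tp``/``fn`` are the proportions
    of shift-present series that did / did not signal, ``fp``/``tn`` the
    same for shift-absent series.  Deterministic given the config seed.
    """
    spec = config.spec
    rule_members = {rs: resolve_ruleset(rs) for rs in config.rulesets}
    rows = []
    for length in config.lengths:
        changepoint = (
            None
            if config.changepoint_fraction is None
            else int(round(config.changepoint_fraction * length))
        )
        # signal counts per (ruleset, arm)
        counts = {rs: [0, 0] for rs in config.rulesets}
        for arm, shift in ((0, 0.0), (1, config.shift)):
            for rep in range(config.n_reps):
                rng = _replicate_rng(config.seed, length, arm, rep)
                x = simulate_series(
                    length, shift, rng, config.centre, config.sd, changepoint
                )
                fired = rule_signals(x, spec)
                for rs, members in rule_members.items():
                    if any(fired[r] for r in members):
                        counts[rs][arm] += 1
        for rs in config.rulesets:
            fp = counts[rs][0] / config.n_reps
            tp = counts[rs][1] / config.n_reps
            rows.append(
                {
                    "ruleset": rs,
                    "length": length,
                    "shift": config.shift,
                    "tp": tp,
                    "fp": fp,
                    "tn": 1.0 - fp,
                    "fn": 1.0 - tp,
                    "n_reps": config.n_reps,
                    "seed": config.seed,
                }
            )
    return pd.DataFrame(rows)
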