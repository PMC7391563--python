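"""Scoring of sand-sifting behaviour trials.

A trial confines one fish (or a group of three females) with a tray holding a
thin beige sand layer over black sand; sifting brings black sand to the
surface.  The turned-over area is measured by brightness-thresholding the
before/after photographs (dark pixels = turned sand), the before-trial area is
subtracted, the result is corrected for incidental scraping, and efficiency is
the corrected area percentage divided by the number of strikes (+0.001 so that
zero areas survive log10 transformation).

Scrape correction reads the ordinal scrape-effect factor e as the fraction of
blackened area attributable to scraping, so the strike-attributable area is
the remainder: area * (1 - e).  Latency and scraping counts are carried in the
data model but drive no statistic; they are summarised descriptively only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SCRAPE_EFFECTS",
    "TrialRecord",
    "EfficiencyScore",
    "quantify_sand_area",
    "net_turned_area",
    "efficiency",
    "trial_efficiency",
    "exclude_trials",
    "aggregate_individual",
    "group_efficiency",
]

SCRAPE_EFFECTS = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9)
EFFICIENCY_OFFSET = 0.001
DEFAULT_THRESHOLD = 80.0


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial of one individual (or one female group member)."""

    individual: str
    cls: str                        # CAL / TAE / F2 / SANDSIFTER
    sex: str
    trial: int                      # 1-3
    strikes: int
    latency_min: float | None = None
    scraping: int = 0
    scrape_effect: float = 0.0
    hiding: int = 1
    interaction: int = 1
    area_before_pct: float = 0.0
    area_after_pct: float = 0.0
    sl_mm: float | None = None
    group: str | None = None

    def __post_init__(self):
        if self.strikes < 0 or self.scraping < 0:
            raise ValueError(f"{self.individual} trial {self.trial}: negative count")
        if not (1 <= self.hiding <= 5 and 1 <= self.interaction <= 5):
            raise ValueError(f"{self.individual} trial {self.trial}: "
                             "ordinal scores must lie in 1..5")
        if not any(math.isclose(self.scrape_effect, e) for e in SCRAPE_EFFECTS):
            raise ValueError(f"{self.individual} trial {self.trial}: scrape effect "
                             f"{self.scrape_effect} not in {SCRAPE_EFFECTS}")
        for pct in (self.area_before_pct, self.area_after_pct):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{self.individual} trial {self.trial}: "
                                 "area percentage outside [0, 100]")


@dataclass(frozen=True)
class EfficiencyScore:
    """Sand-sifting efficiency: area %/strike plus the log-transform offset."""

    raw: float                      # area/strikes + 0.001
    log10: float
    size_corrected: float | None = None

    def __post_init__(self):
        if self.raw < EFFICIENCY_OFFSET:
            raise ValueError("raw efficiency below the log offset floor")


def quantify_sand_area(image: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Percentage of pixels at or below ``threshold`` brightness (0-255 scale).

    Dark pixels are turned-over (black-layer) sand, so the measured area is
    monotone nondecreasing in the threshold; the default cut of 80 separates
    the beige and black grain brightness distributions.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    return float(100.0 * np.mean(img <= threshold))


def net_turned_area(
    before_pct: float,
    after_pct: float,
    scrape_effect: float = 0.0,
    mode: str = "complement",
) -> float:
    """Turned-over area attributable to strikes, as a percentage.

    The before-trial percentage is subtracted from the after-trial one,
    floored at zero (a warning is emitted when after < before), then
    multiplied by (1 - e) where e is the fraction of blackened area due to
    scraping.  ``mode='off'`` skips the scrape correction.
    """
    for pct in (before_pct, after_pct):
        if not 0.0 <= pct <= 100.0:
            raise ValueError("area percentages must lie in [0, 100]")
    if mode not in {"complement", "off"}:
        raise ValueError("mode must be 'complement' or 'off'")
    diff = after_pct - before_pct
    if diff < 0:
        warnings.warn("after-trial area below before-trial area; flooring at 0",
                      stacklevel=2)
        diff = 0.0
    if mode == "complement":
        diff *= (1.0 - scrape_effect)
    return diff


def efficiency(area_pct: float, strikes: int) -> EfficiencyScore | None:
    """Efficiency score, or None when no strike occurred (not computable)."""
    if strikes < 0:
        raise ValueError("strike count must be nonnegative")
    if strikes == 0:
        return None
    raw = area_pct / strikes + EFFICIENCY_OFFSET
    return EfficiencyScore(raw=raw, log10=math.log10(raw))


def trial_efficiency(trial: TrialRecord, mode: str = "complement") -> EfficiencyScore | None:
    """Efficiency of one trial from its stored area percentages."""
    area = net_turned_area(trial.area_before_pct, trial.area_after_pct,
                           trial.scrape_effect, mode=mode)
    return efficiency(area, trial.strikes)


def exclude_trials(trials: list[TrialRecord]) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Drop trials where the fish never struck and hid or displayed throughout.

    Exclusion rule: strikes == 0 and (hiding == 5 or interaction == 5); such
    trials are uninformative about sifting propensity.
    """
    valid, excluded = [], []
    for t in trials:
        if t.strikes == 0 and (t.hiding == 5 or t.interaction == 5):
            excluded.append(t)
        else:
            valid.append(t)
    return valid, excluded


def aggregate_individual(
    trials: list[TrialRecord],
    statistic: str = "max",
    mode: str = "complement",
) -> pd.DataFrame:
    """Per-individual summary of strikes and efficiency over valid trials.

    ``statistic`` is ``max`` or ``mean`` (per the analysis of repeated male
    trials) or ``per_trial`` which returns the long table unchanged.
    Efficiency aggregates only over trials where it is computable (>= 1
    strike); individuals with no computable trial get NaN efficiency.
    """
    rows = []
    for t in trials:
        eff = trial_efficiency(t, mode=mode)
        rows.append({"individual": t.individual, "cls": t.cls, "sex": t.sex,
                     "trial": t.trial, "strikes": t.strikes,
                     "efficiency": eff.raw if eff else np.nan,
                     "log10_efficiency": eff.log10 if eff else np.nan,
                     "sl_mm": t.sl_mm})
    long = pd.DataFrame(rows)
    if statistic == "per_trial":
        return long
    if statistic not in {"max", "mean"}:
        raise ValueError("statistic must be 'max', 'mean' or 'per_trial'")
    agg = long.groupby("individual").agg(
        cls=("cls", "first"),
        sex=("sex", "first"),
        strikes=("strikes", statistic),
        efficiency=("efficiency", statistic),
        n_trials=("trial", "count"),
        sl_mm=("sl_mm", "mean"),
    )
    agg["log10_efficiency"] = np.log10(agg["efficiency"])
    return agg


def group_efficiency(
    strike_counts: list[int],
    area_pct: float,
    sl_mm: list[float] | None = None,
) -> tuple[EfficiencyScore | None, float | None]:
    """Efficiency of a female group: shared turned area over summed strikes.

    Returns (score, mean SL); the score is None when no fish in the group
    struck (as for the one all-zero group in the study design).
    """
    total = int(sum(strike_counts))
    if total < 0:
        raise ValueError("strike counts must be nonnegative")
    score = efficiency(area_pct, total)
    mean_sl = float(np.mean(sl_mm)) if sl_mm else None
    return score, mean_sl
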