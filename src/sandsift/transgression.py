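"""Transgression thresholds, permutation tests and allometric size correction.

Transgressive segregation is scored two ways: the classical criterion (an F2
value outside the pooled parental range) and the conservative thresholds of
Parnell-style mean +/- 2 SD bounds — the upper threshold is the higher
parental mean plus twice *that* parent's sample SD, the lower threshold the
lower parental mean minus twice its own SD.  Small parental samples therefore
widen the thresholds, which is the intended conservatism.  Values exactly on
a threshold are not transgressive (strict inequality).

Class-mean comparisons use a two-sided permutation test on the difference in
means, with full enumeration of relabelings when feasible and an add-one
Monte-Carlo estimate otherwise.  Size correction regresses log10 trait on
log10 standard length, pooled across classes when a class-by-slope
interaction F-test (Benjamini-Hochberg adjusted across traits) is
nonsignificant, falling back to per-class regressions otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "TransgressionThresholds",
    "thresholds",
    "classify",
    "perm_test",
    "size_correct",
]

EXACT_LIMIT = 1_000_000


@dataclass(frozen=True)
class TransgressionThresholds:
    upper: float                   # max parental mean + 2 SD of that parent
    lower: float                   # min parental mean - 2 SD of that parent
    classical_min: float           # pooled parental range
    classical_max: float

    def __post_init__(self):
        for v in (self.upper, self.lower, self.classical_min, self.classical_max):
            if not math.isfinite(v):
                raise ValueError("thresholds must be finite")


def thresholds(parent_a, parent_b) -> TransgressionThresholds:
    """Transgression thresholds from the two parental samples.

    The SD attached to each threshold is the sample SD (n-1 denominator) of
    the parent contributing the extreme mean.  Each parent needs at least two
    values for its SD to exist.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each parental sample needs at least two values")
    mean_a, mean_b = a.mean(), b.mean()
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    hi_sd = sd_a if mean_a >= mean_b else sd_b
    lo_sd = sd_a if mean_a < mean_b else sd_b
    pooled = np.concatenate([a, b])
    return TransgressionThresholds(
        upper=float(max(mean_a, mean_b) + 2.0 * hi_sd),
        lower=float(min(mean_a, mean_b) - 2.0 * lo_sd),
        classical_min=float(pooled.min()),
        classical_max=float(pooled.max()),
    )


def classify(values, thr: TransgressionThresholds,
             ids=None) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag transgressive values against a set of thresholds.

    Returns a per-value table with ``above_upper``, ``below_lower`` and
    ``outside_classical_range`` flags (strict inequalities throughout) plus
    direction counts.
    """
    vals = np.asarray(values, dtype=float)
    ids = list(ids) if ids is not None else list(range(len(vals)))
    table = pd.DataFrame({
        "value": vals,
        "above_upper": vals > thr.upper,
        "below_lower": vals < thr.lower,
        "outside_classical_range": (vals > thr.classical_max) | (vals < thr.classical_min),
    }, index=pd.Index(ids, name="individual"))
    table["direction"] = np.select(
        [table["above_upper"], table["below_lower"]], ["up", "down"], default="none")
    counts = {
        "above_upper": int(table["above_upper"].sum()),
        "below_lower": int(table["below_lower"].sum()),
        "outside_classical_range": int(table["outside_classical_range"].sum()),
    }
    return table, counts


def perm_test(
    x,
    y,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "auto",
) -> float:
    """Two-sided permutation p-value for the difference in sample means.

    ``mode='exact_enumeration'`` enumerates all C(n1+n2, n1) relabelings and
    returns the exact tail proportion; ``'monte_carlo'`` samples ``n_perm``
    relabelings and returns the add-one estimate (1 + hits) / (B + 1), which
    never reaches zero; ``'auto'`` enumerates when the count is at most 10^6.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    n1, n = x.size, pooled.size
    observed = abs(x.mean() - y.mean())
    total_sum = pooled.sum()
    n2 = n - n1
    eps = 1e-12 * max(1.0, observed)

    def stat_from_sum(s1: float) -> float:
        return abs(s1 / n1 - (total_sum - s1) / n2)

    n_comb = math.comb(n, n1)
    if mode == "auto":
        mode = "exact_enumeration" if n_comb <= EXACT_LIMIT else "monte_carlo"
    if mode == "exact_enumeration":
        if n_comb > EXACT_LIMIT:
            raise ValueError(f"{n_comb} relabelings exceed the enumeration limit")
        hits = sum(
            stat_from_sum(pooled[list(idx)].sum()) >= observed - eps
            for idx in combinations(range(n), n1)
        )
        return hits / n_comb
    if mode != "monte_carlo":
        raise ValueError("mode must be 'auto', 'exact_enumeration' or 'monte_carlo'")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat_from_sum(pooled[perm[:n1]].sum()) >= observed - eps:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def size_correct(
    traits,
    sl,
    classes,
    pool: str = "auto",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allometric size correction of positive traits against standard length.

    ``traits`` is a Series or DataFrame of positive trait values, ``sl`` the
    standard lengths, ``classes`` the class labels.  Each trait is log10
    transformed and regressed on log10 SL; the residuals are the
    size-corrected values.  ``pool='auto'`` fits a single pooled regression
    for traits whose class-by-slope interaction F-test is nonsignificant
    after Benjamini-Hochberg adjustment across traits, and per-class
    regressions otherwise; ``'all'`` and ``'per_class'`` force either mode.

    Returns (residuals, report) where the report carries per-trait F, p,
    FDR-adjusted p and the mode used.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    frame = traits.to_frame() if isinstance(traits, pd.Series) else pd.DataFrame(traits)
    sl = np.asarray(sl, dtype=float)
    cls = np.asarray(classes)
    if np.any(sl <= 0) or (frame.to_numpy() <= 0).any():
        raise ValueError("traits and SL must be positive for log transformation")
    if pool not in {"auto", "all", "per_class"}:
        raise ValueError("pool must be 'auto', 'all' or 'per_class'")
    log_sl = np.log10(sl)
    labels = pd.unique(cls)
    dummies = pd.get_dummies(pd.Categorical(cls, categories=labels),
                             drop_first=True).to_numpy(dtype=float)

    stats_rows = []
    for name in frame.columns:
        log_y = np.log10(frame[name].to_numpy(dtype=float))
        base = np.column_stack([np.ones_like(log_sl), log_sl, dummies])
        inter = np.column_stack([base, dummies * log_sl[:, None]])
        fit0 = sm.OLS(log_y, base).fit()
        fit1 = sm.OLS(log_y, inter).fit()
        df_num = fit1.df_model - fit0.df_model
        if df_num <= 0 or fit1.df_resid <= 0:
            f_stat, p = np.nan, 1.0
        else:
            f_stat = ((fit0.ssr - fit1.ssr) / df_num) / (fit1.ssr / fit1.df_resid)
            from scipy import stats as sps
            p = float(sps.f.sf(f_stat, df_num, fit1.df_resid))
        stats_rows.append({"trait": name, "F": f_stat, "p": p})
    report = pd.DataFrame(stats_rows).set_index("trait")
    report["p_fdr"] = multipletests(report["p"].to_numpy(), method="fdr_bh")[1]

    residuals = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    modes = []
    for name in frame.columns:
        log_y = np.log10(frame[name].to_numpy(dtype=float))
        if pool == "all":
            use_pooled = True
        elif pool == "per_class":
            use_pooled = False
        else:
            use_pooled = report.loc[name, "p_fdr"] >= alpha
        if use_pooled:
            x = np.column_stack([np.ones_like(log_sl), log_sl])
            beta, *_ = np.linalg.lstsq(x, log_y, rcond=None)
            residuals[name] = log_y - x @ beta
        else:
            res = np.empty_like(log_y)
            for lab in labels:
                sel = cls == lab
                x = np.column_stack([np.ones(sel.sum()), log_sl[sel]])
                beta, *_ = np.linalg.lstsq(x, log_y[sel], rcond=None)
                res[sel] = log_y[sel] - x @ beta
            residuals[name] = res
        modes.append("pooled" if use_pooled else "per_class")
    report["mode"] = modes
    return residuals, report
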