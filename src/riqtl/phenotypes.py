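"""Strain-level trait derivation from per-animal records.

Per-animal tables are long-format pandas DataFrames:

* survival:  one row per animal with ``strain, animal_id, survival_day,
  censored`` (censored animals survived the 10-day observation window);
* body weight: one row per animal per day with ``strain, animal_id, day,
  body_weight`` (baseline at day -1);
* echo: one row per animal per session with ``strain, animal_id, day``
  plus one column per echo trait (EF %, FS %, LV mass, volumes, ...).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CENSOR_DAY",
    "km_survival_curve",
    "median_survival",
    "survival_rate",
    "bw_loss",
    "normalize_2z8",
    "echo_delta",
    "EchoDelta",
    "strain_trait_table",
]

CENSOR_DAY = 10


def _strain_rows(records: pd.DataFrame, strain: str) -> pd.DataFrame:
    rows = records[records["strain"] == strain]
    if rows.empty:
        raise ValueError(f"no animals recorded for strain {strain!r}")
    return rows


def km_survival_curve(
    durations: np.ndarray, events: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate at each distinct event time.

    Returns (event_times, survival_probability_just_after_each_time).
    """
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    times = np.unique(durations[events])
    surv = np.empty(len(times))
    s = 1.0
    for i, t in enumerate(times):
        at_risk = np.sum(durations >= t)
        deaths = np.sum((durations == t) & events)
        s *= 1.0 - deaths / at_risk
        surv[i] = s
    return times, surv


def median_survival(records: pd.DataFrame, strain: str) -> float:
    """Kaplan-Meier median survival day, censoring at day 10.

    Returns ``math.inf`` when the survival curve never drops to 0.5 within
    the observation window (report as ">=10").
    """
    rows = _strain_rows(records, strain)
    durations = rows["survival_day"].to_numpy(float)
    events = ~rows["censored"].to_numpy(bool)
    if not events.any():
        return math.inf
    times, surv = km_survival_curve(durations, events)
    crossing = times[surv <= 0.5]
    return float(crossing[0]) if crossing.size else math.inf


def format_median_survival(value: float, censor_day: int = CENSOR_DAY) -> str:
    return f">={censor_day}" if math.isinf(value) else f"{value:g}"


def survival_rate(records: pd.DataFrame, strain: str, day: int) -> float:
    """Fraction of the strain's animals still alive strictly after ``day``."""
    rows = _strain_rows(records, strain)
    alive = rows["censored"].to_numpy(bool) | (rows["survival_day"].to_numpy(float) > day)
    return float(alive.mean())


def bw_loss(
    weights: pd.DataFrame,
    strain: str,
    day: int,
    baseline_day: int = -1,
) -> tuple[float, float]:
    """Strain-mean body-weight loss at ``day`` relative to baseline.

    Returns ``(grams, percent)`` as positive loss magnitudes (weight gain
    comes out negative). Only animals measured on both days contribute;
    animals missing a baseline are skipped with a warning. Percent is
    computed per animal against its own baseline, so it is unit-invariant.
    """
    rows = _strain_rows(weights, strain)
    base = rows[rows["day"] == baseline_day].set_index("animal_id")["body_weight"]
    current = rows[rows["day"] == day].set_index("animal_id")["body_weight"]
    missing_base = current.index.difference(base.index)
    if len(missing_base):
        warnings.warn(
            f"{strain}: {len(missing_base)} animal(s) lack a baseline weight; skipped",
            stacklevel=2,
        )
    shared = current.index.intersection(base.index)
    if shared.empty:
        raise ValueError(f"{strain}: no animal has both baseline and day-{day} weights")
    loss = base.loc[shared] - current.loc[shared]
    percent = 100.0 * loss / base.loc[shared]
    return float(loss.mean()), float(percent.mean())


def normalize_2z8(values: np.ndarray | pd.Series) -> np.ndarray:
    """Affine-standardize to mean 8 and sample SD 2 (2Z + 8)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector (zero SD)")
    z = (x - x.mean()) / sd
    # refinement pass: kills cancellation error when |mean| >> sd
    z = z - z.mean()
    z = z / z.std(ddof=1)
    return 2.0 * z + 8.0


@dataclass(frozen=True)
class EchoDelta:
    """Paired baseline/post comparison of one echo trait within a strain."""

    strain: str
    trait: str
    baseline_mean: float
    post_mean: float
    n_pairs: int
    p_value: float | None
    zero_variance: bool = False

    @property
    def delta(self) -> float:
        return self.post_mean - self.baseline_mean


def echo_delta(
    records: pd.DataFrame,
    strain: str,
    trait: str,
    baseline_day: int = -1,
    post_day: int = 5,
) -> EchoDelta:
    """Strain means at baseline and post days plus a paired two-sided t test.

    With fewer than two complete pairs the means are returned and the
    p-value is absent. A constant nonzero paired difference has zero
    variance: the t statistic is undefined, so the result is flagged
    (``zero_variance``) with no p-value; an identically-zero difference
    yields p = 1.
    """
    rows = _strain_rows(records, strain)
    base = rows[rows["day"] == baseline_day].set_index("animal_id")[trait].dropna()
    post = rows[rows["day"] == post_day].set_index("animal_id")[trait].dropna()
    shared = base.index.intersection(post.index)
    b, p = base.loc[shared].to_numpy(float), post.loc[shared].to_numpy(float)
    n = len(shared)
    if n < 2:
        return EchoDelta(strain, trait, float(b.mean()) if n else math.nan,
                         float(p.mean()) if n else math.nan, n, None)
    diff = p - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return EchoDelta(strain, trait, float(b.mean()), float(p.mean()), n, 1.0)
        return EchoDelta(strain, trait, float(b.mean()), float(p.mean()), n, None,
                         zero_variance=True)
    t = stats.ttest_rel(p, b)
    return EchoDelta(strain, trait, float(b.mean()), float(p.mean()), n, float(t.pvalue))


def strain_trait_table(
    survival: pd.DataFrame | None = None,
    weights: pd.DataFrame | None = None,
    echo: pd.DataFrame | None = None,
    *,
    survival_days: tuple[int, ...] = (6, 7, 8, 9, 10),
    bw_days: tuple[int, ...] = (10,),
    echo_traits: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Assemble the strain x trait table used for mapping.

    One row per (strain, trait) with columns ``strain, trait, value, n``.
    Sexes are pooled (unweighted mean over animals).
    """
    out: list[dict] = []
    if survival is not None:
        for strain, grp in survival.groupby("strain"):
            med = median_survival(survival, strain)
            out.append({"strain": strain, "trait": "median_survival",
                        "value": med if math.isfinite(med) else float(CENSOR_DAY),
                        "n": len(grp)})
            for day in survival_days:
                out.append({"strain": strain, "trait": f"survival_rate_day{day}",
                            "value": survival_rate(survival, strain, day), "n": len(grp)})
    if weights is not None:
        for strain in weights["strain"].unique():
            for day in bw_days:
                try:
                    grams, percent = bw_loss(weights, strain, day)
                except ValueError:
                    continue
                n = weights[(weights["strain"] == strain) & (weights["day"] == day)].shape[0]
                out.append({"strain": strain, "trait": f"bw_loss_g_day{day}",
                            "value": grams, "n": n})
                out.append({"strain": strain, "trait": f"bw_loss_pct_day{day}",
                            "value": percent, "n": n})
    if echo is not None:
        for strain in echo["strain"].unique():
            for trait in echo_traits:
                d = echo_delta(echo, strain, trait)
                out.append({"strain": strain, "trait": f"{trait}_day5",
                            "value": d.post_mean, "n": d.n_pairs})
    return pd.DataFrame(out, columns=["strain", "trait", "value", "n"])


def trait_series(table: pd.DataFrame, trait: str) -> pd.Series:
    """Extract one trait as a strain-indexed series from the long table."""
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not present in table")
    return sub.set_index("strain")["value"]
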