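"""Hypothesis tests for the compiled metric tables.

Three comparison designs are used on the vessel-function tables:

* ``vessel_paired`` — dominant vs. non-dominant within a session: paired,
  two-tail t with Bonferroni correction across the metric·segment family.
* ``group_unpaired`` — treatment group vs. healthy/control: unpaired
  two-tail t (Welch by default) with Bonferroni across the family.
* ``timecourse_one_tail`` — follow-up week vs. week-0 baseline: paired,
  one-tail t at α = 0.05 with the direction of functional loss (transport
  time increases; packet frequency and velocity decrease), uncorrected.

Raw and adjusted p values are always both reported, since the appropriate
family size is a design choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "DegenerateTestError", "t_test", "bonferroni",
           "compare_design", "DESIGNS"]

DESIGNS = ("vessel_paired", "group_unpaired", "timecourse_one_tail")


class DegenerateTestError(ValueError):
    """Zero variance with zero effect: the t statistic is 0/0-undefined."""


@dataclass
class TestResult:
    comparison: str
    n: int
    t_statistic: float
    degrees_of_freedom: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    alpha: float
    significant: bool
    n_dropped: int = 0
    degenerate: bool = False

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p value: ``min(1, m * p_raw)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def _drop_missing(x: np.ndarray, y: np.ndarray, paired: bool,
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    if paired:
        keep = ~(np.isnan(x) | np.isnan(y))
        return x[keep], y[keep], int((~keep).sum())
    kx, ky = ~np.isnan(x), ~np.isnan(y)
    return x[kx], y[ky], int((~kx).sum() + (~ky).sum())


def t_test(x, y, paired: bool, tails: int = 2, direction: str | None = None,
           equal_var: bool = False, alpha: float = 0.05,
           comparison: str = "") -> TestResult:
    """Classical t test with explicit missing-value and degeneracy handling.

    Parameters
    ----------
    paired
        Paired (equal lengths, pairwise missing-value dropping) vs.
        independent samples (Welch degrees of freedom unless
        ``equal_var=True``).
    tails, direction
        ``tails=2`` for two-sided; ``tails=1`` needs ``direction`` —
        ``"greater"``/``"less"`` states the alternative for
        ``mean(x) - mean(y)``.

    Zero variance with a nonzero effect yields ``p = 0`` flagged degenerate;
    zero variance with zero effect raises :class:`DegenerateTestError`
    rather than fabricating ``p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if tails == 1 and direction not in ("greater", "less"):
        raise ValueError("one-tail tests need direction 'greater' or 'less'")
    if paired and x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    x, y, n_dropped = _drop_missing(x, y, paired)
    if paired and x.size < 2:
        raise ValueError("need >= 2 usable pairs")
    if not paired and (x.size < 2 or y.size < 2):
        raise ValueError("need >= 2 usable observations per group")

    alternative = "two-sided" if tails == 2 else direction
    if paired:
        diffs = x - y
        if float(np.std(diffs, ddof=1)) == 0.0:
            return _degenerate(float(diffs.mean()), x.size, x.size - 1,
                               tails, direction, alpha, comparison, n_dropped)
        res = sps.ttest_rel(x, y, alternative=alternative)
        n = int(x.size)
    else:
        if float(np.std(x, ddof=1)) == 0.0 and float(np.std(y, ddof=1)) == 0.0:
            dfree = x.size + y.size - 2
            return _degenerate(float(x.mean() - y.mean()), int(min(x.size, y.size)),
                               dfree, tails, direction, alpha, comparison, n_dropped)
        res = sps.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
        n = int(min(x.size, y.size))

    p = float(res.pvalue)
    return TestResult(
        comparison=comparison, n=n,
        t_statistic=float(res.statistic), degrees_of_freedom=float(res.df),
        p_raw=p, p_adjusted=p, m_comparisons=1, alpha=alpha,
        significant=p < alpha, n_dropped=n_dropped,
    )


def _degenerate(effect: float, n: int, dfree: float, tails: int,
                direction: str | None, alpha: float, comparison: str,
                n_dropped: int) -> TestResult:
    if effect == 0.0:
        raise DegenerateTestError(
            f"{comparison or 'test'}: zero variance with zero effect (0/0)")
    t_stat = math.copysign(math.inf, effect)
    aligned = (tails == 2
               or (direction == "greater" and effect > 0)
               or (direction == "less" and effect < 0))
    p = 0.0 if aligned else 1.0
    return TestResult(comparison=comparison, n=n, t_statistic=t_stat,
                      degrees_of_freedom=float(dfree), p_raw=p, p_adjusted=p,
                      m_comparisons=1, alpha=alpha, significant=p < alpha,
                      n_dropped=n_dropped, degenerate=True)


def _adjust(results: list[TestResult], m: int | None = None) -> list[TestResult]:
    m_eff = m if m is not None else max(1, len(results))
    out = []
    for r in results:
        p_adj = bonferroni(r.p_raw, m_eff)
        out.append(replace(r, p_adjusted=p_adj, m_comparisons=m_eff,
                           significant=p_adj < r.alpha))
    return out


# ---------------------------------------------------------------------------
# design runner

_LOSS_DIRECTION = {  # alternative for (followup - baseline) under functional loss
    "transport_time": "greater",
    "packet_frequency": "less",
    "packet_velocity": "less",
    "node_area": "greater",
}


def compare_design(table: pd.DataFrame, design: str, alpha: float = 0.05,
                   m: int | None = None, equal_var: bool = False,
                   ) -> list[TestResult]:
    """Run the matching test per metric·segment family on a tidy table.

    ``table`` is the :func:`lymphnir.longitudinal.compile_timecourse` schema
    (columns animal_id, week, group, vessel, metric, segment, value,
    baseline_value).  ``m`` overrides the Bonferroni family size (default:
    the number of comparisons actually run; the one-tail timecourse design
    is uncorrected).  Comparisons with fewer than two usable pairs are
    skipped; if none are usable the call fails.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    results: list[TestResult] = []

    if design == "vessel_paired":
        sub = table[table["vessel"].isin(["dominant", "nondominant"])]
        for (metric, segment), grp in sub.groupby(["metric", "segment"], sort=True):
            wide = grp.pivot_table(index=["animal_id", "week"], columns="vessel",
                                   values="value", aggfunc="first", dropna=False)
            if not {"dominant", "nondominant"} <= set(wide.columns):
                continue
            res = _try_test(wide["dominant"].to_numpy(), wide["nondominant"].to_numpy(),
                            paired=True, tails=2, alpha=alpha,
                            comparison=f"{metric}/{segment}: dominant vs nondominant")
            if res:
                results.append(res)
        results = _adjust(results, m)

    elif design == "group_unpaired":
        groups = sorted(table["group"].unique())
        if len(groups) != 2:
            raise ValueError(f"group_unpaired needs exactly 2 groups, got {groups}")
        g0, g1 = groups
        keys = ["vessel", "metric", "segment", "week"]
        for key, grp in table.groupby(keys, sort=True):
            x = grp.loc[grp["group"] == g0, "value"].to_numpy()
            y = grp.loc[grp["group"] == g1, "value"].to_numpy()
            label = "/".join(str(k) for k in key) + f": {g0} vs {g1}"
            res = _try_test(x, y, paired=False, tails=2, alpha=alpha,
                            equal_var=equal_var, comparison=label)
            if res:
                results.append(res)
        results = _adjust(results, m)

    else:  # timecourse_one_tail
        sub = table[table["week"] > 0]
        for (vessel, metric, segment, week), grp in sub.groupby(
                ["vessel", "metric", "segment", "week"], sort=True):
            direction = _LOSS_DIRECTION.get(metric, "less")
            res = _try_test(grp["value"].to_numpy(), grp["baseline_value"].to_numpy(),
                            paired=True, tails=1, direction=direction, alpha=alpha,
                            comparison=f"{vessel}/{metric}/{segment}: week {week} vs week 0")
            if res:
                results.append(res)
        results = _adjust(results, m if m is not None else 1)

    if not results:
        raise ValueError(f"design {design!r}: no comparison had >= 2 usable pairs")
    return results


def _try_test(x, y, **kwargs) -> TestResult | None:
    try:
        return t_test(x, y, **kwargs)
    except DegenerateTestError:
        raise
    except ValueError:
        return None
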