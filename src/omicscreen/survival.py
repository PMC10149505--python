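"""Survival comparisons (log-rank) and small clinical utilities.

The log-rank test is implemented directly so that the per-group
observed/expected event table is available alongside the statistic: at
each distinct event time the observed events per group are compared with
their hypergeometric expectation given the groups at risk, and the
quadratic form of the summed differences against the summed covariance
yields a chi-square with (groups - 1) degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SurvivalRecord


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float, pd.DataFrame]:
    """Multi-group log-rank test.

    Returns ``(chi_square, p, table)`` where ``table`` lists per group the
    subject count, observed events and expected events.  Raises with a
    single group; returns ``(nan, nan, table)`` when there are no events.
    """
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    g_index = {g: i for i, g in enumerate(groups)}
    k = len(groups)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    membership = np.array([g_index[r.group] for r in records])

    table = pd.DataFrame(
        {
            "n": [int(np.sum(membership == i)) for i in range(k)],
            "observed": [int(np.sum(events & (membership == i))) for i in range(k)],
        },
        index=groups,
    )
    if events.sum() == 0:
        table["expected"] = np.nan
        return np.nan, np.nan, table

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = at_risk.sum()
        d_t = int(np.sum(events & (times == t)))
        n_g = np.array([np.sum(at_risk & (membership == i)) for i in range(k)])
        d_g = np.array([np.sum(events & (times == t) & (membership == i)) for i in range(k)])
        e_g = d_t * n_g / n_t
        observed += d_g
        expected += e_g
        if n_t > 1:
            factor = d_t * (n_t - d_t) / (n_t - 1)
            for i in range(k):
                for j in range(k):
                    delta = 1.0 if i == j else 0.0
                    cov[i, j] += factor * (n_g[i] / n_t) * (delta - n_g[j] / n_t)

    diff = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    table["expected"] = expected
    return chi2, p, table


def median_split_groups(
    expression: dict[str, float], survival: list[SurvivalRecord]
) -> list[SurvivalRecord]:
    """Relabel survival records into "high" / "low" by the median of an
    expression value; ties at the median go to "low"."""
    missing = [r.subject_id for r in survival if r.subject_id not in expression]
    if missing:
        raise ValueError(f"expression undefined for subjects: {missing}")
    values = np.array([expression[r.subject_id] for r in survival])
    if np.all(values == values[0]):
        raise ValueError("constant expression: degenerate median split")
    median = float(np.median(values))
    return [
        SurvivalRecord(
            r.subject_id,
            r.time,
            r.event,
            "high" if expression[r.subject_id] > median else "low",
        )
        for r in survival
    ]


def tumor_volume(a: float, b: float) -> float:
    """Xenograft volume from caliper diameters: v = 0.5 * a * b^2 (mm^3),
    with a the major and b the minor diameter."""
    if a < 0 or b < 0:
        raise ValueError("diameters must be >= 0")
    if b > a:
        raise ValueError("minor diameter b cannot exceed major diameter a")
    return 0.5 * a * b**2
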