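"""Loewe-additivity combination index for drug pairs.

For a combination (d_A, d_B) producing observed effect E (fraction
inhibited, i.e. 1 - viability), the combination index is

    CI = d_A / D_A(E) + d_B / D_B(E)

where D_X(E) is the dose at which drug X alone reaches effect E under its
fitted log-logistic curve.  CI < 1 indicates synergy, CI = 1 additivity
(exactly 1 for a sham "drug with itself" combination), CI > 1 antagonism.
The inversion is closed-form for the [0,1]-bounded three-parameter model:

    D(E) = e * ((1 - c) / (1 - E - c) - 1)^(1/b)

and is undefined once E reaches a single agent's maximal effect 1 - c.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DoseResponseFit, SynergyResult

_EDGE = 1e-12


def invert_effect(fit: DoseResponseFit, effect: float) -> float:
    """Dose at which the fitted curve alone reaches ``effect``; NaN when the
    effect exceeds the curve's maximal achievable effect ``1 - c``."""
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")
    if fit.b <= 0:
        raise ValueError("non-invertible fit: slope b must be > 0")
    if not (0.0 < effect < 1.0):
        raise ValueError("effect must be in (0, 1)")
    max_effect = 1.0 - fit.c
    if effect >= max_effect - _EDGE:
        return np.nan
    ratio = (1.0 - fit.c) / (1.0 - effect - fit.c) - 1.0
    if ratio <= 0:
        return np.nan
    return float(fit.e * ratio ** (1.0 / fit.b))


def loewe_ci(
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
    dose_a: float,
    dose_b: float,
    observed_effect: float,
) -> SynergyResult:
    """Combination index of one dose pair at the observed combined effect."""
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be >= 0")
    if not (0.0 < observed_effect < 1.0):
        raise ValueError("observed_effect must be in (0, 1)")
    da = invert_effect(fit_a, observed_effect)
    db = invert_effect(fit_b, observed_effect)
    if np.isnan(da) or np.isnan(db):
        which = fit_a.drug if np.isnan(da) else fit_b.drug
        return SynergyResult(
            dose_a, dose_b, observed_effect, np.nan, np.nan, defined=False,
            reason=f"effect exceeds maximal single-agent effect of {which or 'a drug'}",
        )
    ci = dose_a / da + dose_b / db
    if ci <= 0:
        return SynergyResult(
            dose_a, dose_b, observed_effect, np.nan, np.nan, defined=False,
            reason="zero total dose",
        )
    return SynergyResult(dose_a, dose_b, observed_effect, float(ci), float(np.log10(ci)), True)


def ci_grid(
    fit_a: DoseResponseFit,
    fit_b: DoseResponseFit,
    combo: pd.DataFrame,
    synergy_threshold: float = 0.9,
    antagonism_threshold: float = 1.1,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Elementwise Loewe CI over a dose grid of observed viabilities.

    ``combo`` has drug-A doses as index, drug-B doses as columns and
    observed viabilities as values.  Per-cell failures (effect out of the
    invertible range) are recorded as NaN without aborting the grid.
    Returns ``(ci matrix, log10 ci matrix, qualitative counts)``.
    """
    doses_a = [float(d) for d in combo.index]
    doses_b = [float(d) for d in combo.columns]
    if min(doses_a) <= 0 or min(doses_b) <= 0:
        raise ValueError("grid doses must be positive")
    ci = pd.DataFrame(np.nan, index=combo.index, columns=combo.columns, dtype=float)
    log_ci = ci.copy()
    counts = {"synergistic": 0, "additive": 0, "antagonistic": 0, "undefined": 0}
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            viability = float(combo.iloc[i, j])
            if not np.isfinite(viability):
                raise ValueError("grid viabilities must be finite")
            effect = 1.0 - viability
            if not (0.0 < effect < 1.0):
                counts["undefined"] += 1
                continue
            res = loewe_ci(fit_a, fit_b, da, db, effect)
            if not res.defined:
                counts["undefined"] += 1
                continue
            ci.iloc[i, j] = res.ci
            log_ci.iloc[i, j] = res.log10_ci
            if res.ci < synergy_threshold:
                counts["synergistic"] += 1
            elif res.ci > antagonism_threshold:
                counts["antagonistic"] += 1
            else:
                counts["additive"] += 1
    return ci, log_ci, counts
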