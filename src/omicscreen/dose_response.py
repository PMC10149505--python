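"""Plate normalization, log-logistic fitting, IC50 / activity area, and
BPH-vs-tumor drug selectivity.

The response model is the three-parameter log-logistic with the upper
asymptote fixed at 1 (viability of untreated cells):

    f(d) = c + (1 - c) / (1 + (d / e)^b)

with slope ``b > 0``, lower asymptote ``c`` in [0, 1] and inflection dose
``e`` (µM).  IC50 is the absolute dose at which fitted viability crosses
0.5, censored at "> max dose" when the curve never reaches it.  The
activity area AA is the discrete sum over tested doses of (1 - viability)
clipped to [0, 1]; the 7-dose companion score 7-AA is ``n_doses - AA``, a
resistance-oriented value (larger = less sensitive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import DoseResponseFit, PlateRecord, SampleAnnotation


def loglogistic3(dose, b: float, c: float, e: float):
    """Viability at ``dose`` µM for parameters (b, c, e); f(0) = 1."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        out = c + (1.0 - c) / (1.0 + (dose / e) ** b)
    return out if out.ndim else float(out)


def normalize_viability(records: list[PlateRecord]) -> pd.DataFrame:
    """Normalize treatment signals to each cell line's mean DMSO signal.

    Returns a table with one row per (cell, drug, dose): replicate-level
    viabilities, their mean, and the number of replicates.  Positive
    (total-kill) controls are excluded from normalization but are
    summarized per cell as a Z'-like separation statistic when present.
    """
    cells = sorted({r.cell_id for r in records})
    dmso: dict[str, list[float]] = {c: [] for c in cells}
    pos: dict[str, list[float]] = {c: [] for c in cells}
    for r in records:
        if r.well_type == "dmso_control":
            dmso[r.cell_id].append(r.signal)
        elif r.well_type == "positive_control":
            pos[r.cell_id].append(r.signal)
    missing = [c for c in cells if not dmso[c]]
    if missing:
        raise ValueError(f"no DMSO control wells for cell line(s): {missing}")
    dmso_mean = {c: float(np.mean(v)) for c, v in dmso.items()}

    zprime: dict[str, float] = {}
    for c in cells:
        if len(pos[c]) >= 2 and len(dmso[c]) >= 2:
            sd_n, sd_p = np.std(dmso[c], ddof=1), np.std(pos[c], ddof=1)
            sep = abs(dmso_mean[c] - np.mean(pos[c]))
            zprime[c] = float(1.0 - 3.0 * (sd_n + sd_p) / sep) if sep > 0 else np.nan
        else:
            zprime[c] = np.nan

    grouped: dict[tuple[str, str, float], list[float]] = {}
    for r in records:
        if r.well_type != "treatment":
            continue
        key = (r.cell_id, r.drug, r.dose)
        grouped.setdefault(key, []).append(r.signal / dmso_mean[r.cell_id])
    rows = []
    for (cell, drug, dose), vias in sorted(grouped.items()):
        rows.append(
            {
                "cell_id": cell,
                "drug": drug,
                "dose_uM": dose,
                "viability": float(np.mean(vias)),
                "replicate_viabilities": tuple(vias),
                "n_replicates": len(vias),
                "zprime": zprime[cell],
            }
        )
    return pd.DataFrame(rows)


def fit_loglogistic3(
    doses: np.ndarray,
    viabilities: np.ndarray,
    cell_id: str = "",
    drug: str = "",
) -> DoseResponseFit:
    """Bounded least-squares fit of the 3-parameter log-logistic curve.

    Multi-start over a grid of inflection doses spanning the tested range;
    bounds b in [0.05, 20], c in [0, 1], e in [min dose / 100, max dose x 100].
    """
    doses = np.asarray(doses, dtype=float)
    viabilities = np.asarray(viabilities, dtype=float)
    if doses.shape != viabilities.shape:
        raise ValueError("doses and viabilities must have equal length")
    ok = np.isfinite(doses) & np.isfinite(viabilities) & (doses > 0)
    doses, viabilities = doses[ok], viabilities[ok]
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct positive doses to fit")
    order = np.argsort(doses)
    doses, viabilities = doses[order], viabilities[order]
    n_doses = np.unique(doses).size

    lo = np.array([0.05, 0.0, doses.min() / 100.0])
    hi = np.array([20.0, 1.0, doses.max() * 100.0])

    def residuals(theta):
        b, c, e = theta
        return loglogistic3(doses, b, c, e) - viabilities

    best = None
    e_grid = np.geomspace(doses.min() / 3.0, doses.max() * 3.0, 5)
    c0 = float(np.clip(viabilities.min(), 0.0, 0.99))
    for e0 in e_grid:
        for b0 in (1.0, 2.5):
            x0 = np.clip(np.array([b0, c0, e0]), lo, hi)
            try:
                sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return DoseResponseFit(
            cell_id, drug, np.nan, np.nan, np.nan, np.nan, True, np.nan, np.nan,
            np.nan, int(doses.size), converged=False, message="no start converged",
        )

    b, c, e = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)

    # absolute IC50: f(d) = 0.5  =>  d = e * ((1-c)/(0.5-c) - 1)^(1/b)
    max_dose = float(doses.max())
    if c >= 0.5 or loglogistic3(max_dose, b, c, e) > 0.5:
        ic50, censored = np.nan, True
    else:
        ic50 = float(e * ((1.0 - c) / (0.5 - c) - 1.0) ** (1.0 / b))
        censored = ic50 > max_dose
        if censored:
            ic50 = np.nan

    unique_doses = np.unique(doses)
    mean_v = np.array([viabilities[doses == d].mean() for d in unique_doses])
    aa, seven = activity_area(mean_v, n_doses=len(unique_doses))
    return DoseResponseFit(
        cell_id, drug, b, c, e, ic50, censored, aa, seven, rss, int(doses.size)
    )


def activity_area(
    viabilities_at_doses: np.ndarray, n_doses: int = 7
) -> tuple[float, float]:
    """AA = sum over doses of (1 - viability) clipped to [0, 1]; the
    companion score is ``n_doses - AA``.  Their sum is exact."""
    v = np.asarray(viabilities_at_doses, dtype=float)
    if v.size != n_doses:
        raise ValueError(f"expected {n_doses} per-dose viabilities, got {v.size}")
    aa = float(np.sum(1.0 - np.clip(v, 0.0, 1.0)))
    return aa, float(n_doses) - aa


def screen_pipeline(
    records: list[PlateRecord], n_doses: int = 7, aa_orientation: str = "resistance"
) -> tuple[list[DoseResponseFit], pd.DataFrame, pd.DataFrame]:
    """Fit every cell x drug pair and assemble the screen matrices.

    Returns ``(fits, seven_aa, log10_ic50)`` where the two DataFrames are
    cell x drug.  With ``aa_orientation="resistance"`` the score matrix is
    n_doses - AA; with ``"activity"`` it is AA itself.
    """
    if aa_orientation not in ("resistance", "activity"):
        raise ValueError("aa_orientation must be 'resistance' or 'activity'")
    table = normalize_viability(records)
    fits = []
    for (cell, drug), sub in table.groupby(["cell_id", "drug"], sort=True):
        sub = sub.sort_values("dose_uM")
        if sub.shape[0] < 4:
            continue
        fit = fit_loglogistic3(
            sub["dose_uM"].to_numpy(), sub["viability"].to_numpy(), cell, drug
        )
        fits.append(fit)
    cells = sorted({f.cell_id for f in fits})
    drugs = sorted({f.drug for f in fits})
    seven = pd.DataFrame(np.nan, index=cells, columns=drugs)
    lic50 = pd.DataFrame(np.nan, index=cells, columns=drugs)
    for f in fits:
        score = f.seven_aa if aa_orientation == "resistance" else f.aa
        seven.loc[f.cell_id, f.drug] = score
        if not f.ic50_censored:
            lic50.loc[f.cell_id, f.drug] = np.log10(f.ic50)
    return fits, seven, lic50


def drug_selectivity(
    seven_aa: pd.DataFrame,
    annotations: list[SampleAnnotation],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Unpaired two-sided Student's t-test (pooled variance) per drug on the
    7-AA scores of BPH vs tumor cells."""
    group_of = {a.sample_id: a.group for a in annotations if not a.reference_flag}
    unknown = [c for c in seven_aa.index if c not in group_of]
    if unknown:
        raise ValueError(f"cells absent from annotation: {unknown}")
    rows = []
    for drug in seven_aa.columns:
        col = seven_aa[drug].dropna()
        bph = col[[group_of[c] == "BPH" for c in col.index]].to_numpy()
        tum = col[[group_of[c] == "tumor" for c in col.index]].to_numpy()
        if len(bph) < 2 or len(tum) < 2:
            rows.append(
                {"drug": drug, "t": np.nan, "p": np.nan, "selective": False,
                 "reason": "fewer than 2 cells in a group"}
            )
            continue
        if np.std(bph) == 0 and np.std(tum) == 0 and bph.mean() == tum.mean():
            rows.append({"drug": drug, "t": 0.0, "p": 1.0, "selective": False, "reason": None})
            continue
        t, p = stats.ttest_ind(tum, bph, equal_var=True)
        rows.append(
            {"drug": drug, "t": float(t), "p": float(p),
             "selective": bool(p < alpha), "reason": None}
        )
    return pd.DataFrame(rows).set_index("drug")
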