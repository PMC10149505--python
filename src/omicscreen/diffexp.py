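"""Per-layer differential expression and cross-layer integration.

Tumor-vs-BPH differences are tested feature-wise with the two-sided
Wilcoxon rank-sum test; a feature is called up-regulated when p < alpha
and its tumor/BPH fold change exceeds the layer's upper gate, down when
the fold change falls below the lower gate.  Fold changes on log2-ratio
layers (proteome, surfaceome) are ratios of geometric means; on TPM they
are ratios of arithmetic means.  The layers are then intersected into the
cancer-related gene (CRG) set together with the top mutated genes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CRGSet, DifferentialResult, OmicsMatrix, SampleAnnotation

EXACT_MAX_N = 20  # combined sample size up to which the rank-sum test is exact


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str | None]:
    """Spearman rho with a two-sided p-value.

    rho is the Pearson correlation of average ranks.  For n <= 9 the
    p-value is exact by enumerating all rank permutations; for larger n it
    uses the t approximation with n - 2 degrees of freedom.  Constant input
    yields ``(nan, nan, "constant input")``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan, "constant input"
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # exact permutation null of the rank correlation
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
        null = (pc @ rxc) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p, None


def _ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum: exact enumeration when the combined sample is
    small and tie-free, otherwise the tie-corrected normal approximation.
    No continuity correction: at panel-scale group sizes it makes the test
    conservative enough to break p-value calibration.  Returns (W, p)."""
    n = x.size + y.size
    ties = np.unique(np.concatenate([x, y])).size < n
    method = "exact" if (n <= EXACT_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    # W = rank sum of x = U_x + n_x (n_x + 1) / 2
    w = float(res.statistic + x.size * (x.size + 1) / 2.0)
    return w, float(res.pvalue)


def _fold_change(tumor: np.ndarray, bph: np.ndarray, log_scale: bool) -> float:
    if log_scale:
        return float(2.0 ** (tumor.mean() - bph.mean()))
    denom = bph.mean()
    if denom <= 0:
        return np.nan
    return float(tumor.mean() / denom)


def wilcoxon_de(
    matrix: OmicsMatrix,
    annotations: list[SampleAnnotation],
    fc_up: float = 1.2,
    fc_down: float = 1 / 1.2,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> list[DifferentialResult]:
    """Feature-wise tumor-vs-BPH differential test.

    Features with fewer than 2 non-missing values in either group are
    reported with NA p-value rather than dropped.  ``test`` may be
    ``"wilcoxon"`` (default) or ``"ttest"`` (pooled-variance Student's t).
    """
    group_of = {a.sample_id: a.group for a in annotations if not a.reference_flag}
    for s in matrix.sample_ids:
        if s not in group_of:
            raise ValueError(f"sample {s!r} has no group annotation")
    if test not in ("wilcoxon", "ttest"):
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    cols = np.array([group_of[s] for s in matrix.sample_ids])
    tumor_cols = cols == "tumor"
    bph_cols = cols == "BPH"
    values = matrix.values
    log_scale = matrix.log_scale

    results: list[DifferentialResult] = []
    for i, feature in enumerate(matrix.feature_ids):
        row = values[i]
        t_vals = row[tumor_cols]
        b_vals = row[bph_cols]
        t_vals = t_vals[~np.isnan(t_vals)]
        b_vals = b_vals[~np.isnan(b_vals)]
        if t_vals.size < 2 or b_vals.size < 2:
            results.append(
                DifferentialResult(feature, matrix.layer, np.nan, np.nan, np.nan, "ns",
                                   reason="fewer than 2 samples per group")
            )
            continue
        fc = _fold_change(t_vals, b_vals, log_scale)
        if np.array_equal(np.sort(t_vals), np.sort(b_vals)):
            stat, p = (0.0, 1.0) if test == "ttest" else _ranksum(t_vals, b_vals)
            results.append(DifferentialResult(feature, matrix.layer, fc, stat, p, "ns"))
            continue
        if test == "wilcoxon":
            stat, p = _ranksum(t_vals, b_vals)
        else:
            tt = stats.ttest_ind(t_vals, b_vals, equal_var=True)
            stat, p = float(tt.statistic), float(tt.pvalue)
        if p < alpha and fc > fc_up:
            direction = "up"
        elif p < alpha and fc < fc_down:
            direction = "down"
        else:
            direction = "ns"
        results.append(DifferentialResult(feature, matrix.layer, fc, stat, p, direction))
    return results


def de_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "layer": [r.layer for r in results],
            "fold_change": [r.fold_change for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("feature")


def overlap_sets(
    results_by_layer: dict[str, list[DifferentialResult]],
) -> tuple[pd.DataFrame, dict[frozenset[str], int]]:
    """Per-gene significance membership per layer and every region count.

    A gene is a member of a layer when its direction there is "up" or
    "down" (i.e. it passed that layer's p and fold-change gates).  Region
    counts are keyed by the exact set of layers a gene is significant in,
    so each gene contributes to exactly one region.
    """
    layers = sorted(results_by_layer)
    members: dict[str, set[str]] = {
        layer: {r.feature for r in results if r.direction != "ns"}
        for layer, results in results_by_layer.items()
    }
    genes = sorted(set().union(*members.values())) if members else []
    table = pd.DataFrame(
        {layer: [g in members[layer] for g in genes] for layer in layers}, index=genes
    )
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(layers) + 1):
        for combo in itertools.combinations(layers, r):
            counts[frozenset(combo)] = 0
    for g in genes:
        region = frozenset(layer for layer in layers if g in members[layer])
        counts[region] += 1
    return table, counts


def fc_concordance(
    proteome_de: list[DifferentialResult],
    surfaceome_de: list[DifferentialResult],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, float, str | None]:
    """Pearson correlation of log2 fold changes between matched proteins.

    Features whose proteome p-value is >= alpha (or NA) are excluded
    before the correlation.  Returns ``(pair table, rho, p, reason)``.
    """
    prot = {r.feature: r for r in proteome_de}
    surf = {r.feature: r for r in surfaceome_de}
    shared = [f for f in prot if f in surf]
    rows = []
    for f in shared:
        rp = prot[f]
        rs = surf[f]
        if not np.isfinite(rp.p_value) or rp.p_value >= alpha:
            continue
        if not (np.isfinite(rp.fold_change) and np.isfinite(rs.fold_change)):
            continue
        if rp.fold_change <= 0 or rs.fold_change <= 0:
            continue
        rows.append(
            {"feature": f,
             "log2fc_proteome": np.log2(rp.fold_change),
             "log2fc_surfaceome": np.log2(rs.fold_change)}
        )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        return table, np.nan, np.nan, "fewer than 3 surviving pairs"
    rho, p = stats.pearsonr(table["log2fc_proteome"], table["log2fc_surfaceome"])
    return table, float(rho), float(p), None


def assemble_crgs(overlap_genes: set[str], top_mutated: set[str]) -> CRGSet:
    """Union of multi-omics overlap genes and top mutated genes; a gene in
    both records provenance ``multiomics_overlap``."""
    provenance = {g: "top_mutation" for g in top_mutated}
    provenance.update({g: "multiomics_overlap" for g in overlap_genes})
    genes = frozenset(provenance)
    return CRGSet(genes=genes, provenance=provenance)


def mrna_protein_correlation(
    rna: OmicsMatrix,
    protein: OmicsMatrix,
    sd_quantile: float = 0.1,
) -> tuple[pd.DataFrame, float, str | None]:
    """Per-gene Spearman correlation of mRNA vs protein across samples.

    Genes must be complete (no missing values) in both layers and sit in
    the top ``sd_quantile`` fraction by standard deviation in both layers.
    Returns ``(per-gene table, median rho, reason)``.
    """
    if not (0 < sd_quantile <= 1):
        raise ValueError("sd_quantile must be in (0, 1]")
    shared_samples = [s for s in rna.sample_ids if s in set(protein.sample_ids)]
    if len(shared_samples) < 3:
        raise ValueError("need >= 3 shared samples")
    shared_genes = [g for g in rna.feature_ids if g in set(protein.feature_ids)]
    r = rna.data.loc[shared_genes, shared_samples]
    p = protein.data.loc[shared_genes, shared_samples]
    complete = ~(r.isna().any(axis=1) | p.isna().any(axis=1))
    r, p = r.loc[complete], p.loc[complete]
    if r.empty:
        return pd.DataFrame(), np.nan, "no complete genes"
    r_sd = r.std(axis=1)
    p_sd = p.std(axis=1)
    r_cut = r_sd.quantile(1.0 - sd_quantile)
    p_cut = p_sd.quantile(1.0 - sd_quantile)
    keep = r.index[(r_sd >= r_cut) & (p_sd >= p_cut)]
    if len(keep) == 0:
        return pd.DataFrame(), np.nan, "no genes pass the SD filter"
    rows = []
    for g in keep:
        rho, pv, reason = spearman(r.loc[g].to_numpy(), p.loc[g].to_numpy())
        rows.append({"gene": g, "rho": rho, "p": pv, "reason": reason})
    table = pd.DataFrame(rows).set_index("gene")
    median_rho = float(table["rho"].median(skipna=True))
    return table, median_rho, None
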