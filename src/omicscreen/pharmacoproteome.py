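"""Protein x drug association matrix and CRG-drug summaries.

Each protein's normalized abundance across the screened cells is rank-
correlated (Spearman) with each drug's 7-AA score.  Proteins missing in
half or more of the cells are dropped up front; each remaining pair is
correlated over its pairwise-complete cells (minimum 5).  Following the
masking rule, coefficients whose p-value is not below alpha are reset to
missing, so the delivered rho matrix shows significant associations only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AssociationMatrix, CRGSet, OmicsMatrix
from .diffexp import spearman


def _fast_spearman(values: np.ndarray, aa: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman for complete data: proteins x cells vs cells x drugs."""
    n = values.shape[1]
    rp = np.apply_along_axis(stats.rankdata, 1, values)
    ra = np.apply_along_axis(stats.rankdata, 0, aa)
    rp = rp - rp.mean(axis=1, keepdims=True)
    ra = ra - ra.mean(axis=0, keepdims=True)
    denom = np.sqrt((rp**2).sum(axis=1))[:, None] * np.sqrt((ra**2).sum(axis=0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rp @ ra) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return rho, p


def associate_proteins_drugs(
    protein: OmicsMatrix,
    seven_aa: pd.DataFrame,
    max_missing_frac: float = 0.5,
    alpha: float = 0.05,
    min_pairs: int = 5,
) -> AssociationMatrix:
    """Spearman association of every protein with every drug's 7-AA.

    ``protein`` is features x cells; ``seven_aa`` is cells x drugs.  Cells
    are matched by id.  Proteins with a missing fraction >= ``max_missing_frac``
    across the shared cells are excluded before any correlation.
    """
    shared = [c for c in seven_aa.index if c in set(protein.sample_ids)]
    if not shared:
        raise ValueError("no shared cells between protein matrix and screen table")
    pdata = protein.data[shared]
    aa = seven_aa.loc[shared]

    frac_missing = pdata.isna().mean(axis=1)
    kept = pdata.loc[frac_missing < max_missing_frac]
    proteins = list(kept.index)
    drugs = list(aa.columns)

    rho = np.full((len(proteins), len(drugs)), np.nan)
    pmat = np.full((len(proteins), len(drugs)), np.nan)

    if not kept.isna().to_numpy().any() and not aa.isna().to_numpy().any() and len(shared) >= min_pairs:
        rho, pmat = _fast_spearman(kept.to_numpy(), aa.to_numpy())
    else:
        pv = kept.to_numpy()
        av = aa.to_numpy()
        for i in range(len(proteins)):
            for j in range(len(drugs)):
                ok = ~(np.isnan(pv[i]) | np.isnan(av[:, j]))
                if ok.sum() < min_pairs:
                    continue
                r, p, reason = spearman(pv[i, ok], av[ok, j])
                if reason is None:
                    rho[i, j], pmat[i, j] = r, p

    rho_df = pd.DataFrame(rho, index=proteins, columns=drugs)
    p_df = pd.DataFrame(pmat, index=proteins, columns=drugs)
    significant = (p_df < alpha) & rho_df.notna()
    masked = rho_df.where(significant)
    return AssociationMatrix(
        rho=masked,
        p=p_df,
        significant_mask=significant,
        rho_unmasked=rho_df,
        alpha=alpha,
        n_significant=int(significant.to_numpy().sum()),
    )


def crg_drug_summary(
    assoc: AssociationMatrix, crgs: CRGSet
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-drug counts of CRGs with significant positive / negative rho.

    Returns ``(per-drug counts, flattened CRG-drug pair list, unmapped genes)``.
    CRG genes without a row in the association matrix are reported as
    unmapped, not errors.
    """
    if not crgs.genes:
        raise ValueError("empty CRG set")
    mapped = [g for g in sorted(crgs.genes) if g in set(assoc.proteins)]
    unmapped = [g for g in sorted(crgs.genes) if g not in set(assoc.proteins)]
    counts = []
    pairs = []
    for drug in assoc.drugs:
        n_pos = n_neg = 0
        for gene in mapped:
            r = assoc.rho.loc[gene, drug]
            if pd.isna(r):
                continue
            pairs.append(
                {"gene": gene, "drug": drug, "rho": float(r),
                 "p": float(assoc.p.loc[gene, drug])}
            )
            if r > 0:
                n_pos += 1
            elif r < 0:
                n_neg += 1
        counts.append({"drug": drug, "n_positive": n_pos, "n_negative": n_neg})
    counts_df = pd.DataFrame(counts).set_index("drug")
    pairs_df = pd.DataFrame(pairs, columns=["gene", "drug", "rho", "p"])
    return counts_df, pairs_df, unmapped
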