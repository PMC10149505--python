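"""Normalization, QC and imputation of abundance matrices.

The TMT proteome workflow is: median normalization of reporter intensities
(sample-loading calibration), ratio to the in-batch internal reference
channel followed by log2, then QC on the per-sample distributions (dip
test for unimodality, Pearson agreement of the reference channels across
batches).  The label-free surfaceome workflow merges the two LC-MS/MS runs
per sample cellwise and filters to surface-annotated proteins before the
same differential analysis is applied downstream.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .datatypes import OmicsMatrix, QCReport, SampleAnnotation
from .dip import dip_test

logger = logging.getLogger("omicscreen")


def median_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Rescale each sample so its median equals the grand median.

    The target is the median of the original per-sample medians, which
    keeps the output on the original intensity scale.  The missing mask is
    unchanged.  Idempotent: a second application is a no-op.
    """
    data = matrix.data
    medians = data.median(axis=0, skipna=True)
    dead = medians.index[medians.isna()].tolist()
    if dead:
        raise ValueError(f"all-missing sample(s): {dead}")
    if (medians <= 0).any():
        bad = medians.index[medians <= 0].tolist()
        raise ValueError(f"non-positive sample median(s), cannot rescale: {bad}")
    target = float(np.median(medians.to_numpy()))
    scaled = data * (target / medians)
    return OmicsMatrix(scaled, matrix.layer)


def _reference_by_batch(annotations: list[SampleAnnotation]) -> dict[str, str]:
    refs: dict[str, list[str]] = {}
    for a in annotations:
        if a.reference_flag:
            refs.setdefault(a.batch, []).append(a.sample_id)
    batches = {a.batch for a in annotations}
    out = {}
    for batch in sorted(batches):
        found = refs.get(batch, [])
        if len(found) != 1:
            raise ValueError(
                f"batch {batch!r} must have exactly one reference channel, found {len(found)}"
            )
        out[batch] = found[0]
    return out


def reference_ratio_log2(
    matrix: OmicsMatrix, annotations: list[SampleAnnotation]
) -> OmicsMatrix:
    """log2(sample / in-batch internal reference); reference columns dropped.

    A feature whose reference value is missing (or non-positive) in a batch
    comes out missing for every sample of that batch.
    """
    ann = {a.sample_id: a for a in annotations}
    unknown = [s for s in matrix.sample_ids if s not in ann]
    if unknown:
        raise ValueError(f"samples absent from annotation: {unknown}")
    present = [a for a in annotations if a.sample_id in set(matrix.sample_ids)]
    ref_of_batch = _reference_by_batch(present)

    data = matrix.data
    out = {}
    for sample in matrix.sample_ids:
        a = ann[sample]
        if a.reference_flag:
            continue
        ref_col = data[ref_of_batch[a.batch]]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(data[sample] / ref_col)
        ratio[~np.isfinite(ratio)] = np.nan
        out[sample] = ratio
    return OmicsMatrix(pd.DataFrame(out, index=matrix.feature_ids), matrix.layer)


def qc_report(
    matrix: OmicsMatrix,
    annotations: list[SampleAnnotation],
    n_boot: int = 1000,
    seed: int = 0,
    dip_alpha: float = 0.05,
    reference_corr_threshold: float = 0.97,
) -> QCReport:
    """Per-sample dip test plus pairwise reference-channel correlations.

    Every sample needs >= 20 non-missing values for the dip test.  The QC
    passes when every dip p-value exceeds ``dip_alpha`` (no evidence
    against unimodality) and every reference-pair Pearson r reaches
    ``reference_corr_threshold``.
    """
    warnings_list: list[str] = []
    dip_stats: dict[str, float] = {}
    dip_ps: dict[str, float] = {}
    for sample in matrix.sample_ids:
        values = matrix.data[sample].dropna().to_numpy()
        if values.size < 20:
            raise ValueError(
                f"sample {sample!r} has only {values.size} non-missing values; dip test needs >= 20"
            )
        d, p = dip_test(values, n_boot=n_boot, seed=seed)
        dip_stats[sample] = d
        dip_ps[sample] = p

    ref_ids = [
        a.sample_id
        for a in annotations
        if a.reference_flag and a.sample_id in set(matrix.sample_ids)
    ]
    correlations: list[tuple[str, str, float]] = []
    if len(ref_ids) < 2:
        warnings_list.append("fewer than two reference samples; reference QC skipped")
        reference_pass = True
    else:
        for s1, s2 in itertools.combinations(ref_ids, 2):
            pair = matrix.data[[s1, s2]].dropna()
            r = float(pair[s1].corr(pair[s2], method="pearson"))
            correlations.append((s1, s2, r))
        reference_pass = all(r >= reference_corr_threshold for _, _, r in correlations)

    dip_pass = all(p > dip_alpha for p in dip_ps.values())
    return QCReport(
        dip_statistics=dip_stats,
        dip_p_values=dip_ps,
        reference_correlations=correlations,
        dip_pass=dip_pass,
        reference_pass=reference_pass,
        warnings=warnings_list,
    )


def combine_surface_runs(run1: OmicsMatrix, run2: OmicsMatrix) -> OmicsMatrix:
    """Merge two LFQ runs cellwise: mean when both observed, the unique
    value when one is missing, missing when both are."""
    if run1.feature_ids != run2.feature_ids or run1.sample_ids != run2.sample_ids:
        raise ValueError("runs must share identical feature and sample spaces")
    if run1.layer != run2.layer:
        raise ValueError("runs must carry the same layer tag")
    a, b = run1.values, run2.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        merged = np.nanmean(np.stack([a, b]), axis=0)
    return OmicsMatrix(
        pd.DataFrame(merged, index=run1.feature_ids, columns=run1.sample_ids),
        run1.layer,
    )


def filter_surface_annotated(
    matrix: OmicsMatrix, surface_flags: dict[str, bool]
) -> OmicsMatrix:
    """Keep only features flagged as cell-surface; unflagged features are
    treated as not surface-annotated.  Row order is preserved."""
    keep = [f for f in matrix.feature_ids if surface_flags.get(f, False)]
    if not keep:
        logger.warning("surface-annotation filter removed every feature")
        warnings.warn("surface-annotation filter removed every feature", stacklevel=2)
    return OmicsMatrix(matrix.data.loc[keep], matrix.layer)


def knn_impute(
    matrix: OmicsMatrix, k: int = 10, max_missing_frac: float = 0.2
) -> OmicsMatrix:
    """Drop high-missingness features, then impute the rest by feature-KNN.

    Features with a missing fraction >= ``max_missing_frac`` are removed.
    Each remaining missing cell is replaced by the unweighted mean of the
    ``k`` nearest features, with Euclidean distance computed over the
    co-observed samples and rescaled by the number of shared samples
    (nan-Euclidean).  Observed values are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 < max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in (0, 1]")
    frac = matrix.data.isna().mean(axis=1)
    kept = matrix.data.loc[frac < max_missing_frac]
    if kept.empty:
        raise ValueError("no features survive the missingness filter")
    if not kept.isna().to_numpy().any():
        return OmicsMatrix(kept, matrix.layer)
    n_complete = int((~kept.isna().any(axis=1)).sum())
    if k > max(n_complete, 1):
        warnings.warn(
            f"k={k} exceeds the {n_complete} complete features; using all available neighbors",
            stacklevel=2,
        )
        k = max(n_complete, 1)
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    # rows = features so that neighbors are features and distances run
    # across samples
    imputed = imputer.fit_transform(kept.to_numpy())
    observed = ~kept.isna().to_numpy()
    filled = kept.to_numpy().copy()
    filled[~observed] = imputed[~observed]
    return OmicsMatrix(
        pd.DataFrame(filled, index=kept.index, columns=kept.columns), matrix.layer
    )
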