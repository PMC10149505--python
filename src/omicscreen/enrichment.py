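"""Preranked gene-set enrichment with gene-set permutation.

The enrichment score is the classic weighted Kolmogorov-Smirnov walk: a
running sum over the ranked list that rises by |score|^weight (normalized
over in-set genes) at each set member and falls by 1/(N - |S|) at each
miss; ES is the signed extremum.  Significance comes from a per-set null
of random same-size gene sets drawn from the ranked list ("gene-set"
permutation); NES divides ES by the mean |null ES| of matching sign, the
p-value is the doubled matching-sign tail, and FDR is Benjamini-Hochberg
across sets.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import EnrichmentResult, GeneSet


def enrichment_score(
    ranked: list[tuple[str, float]],
    gene_set: GeneSet,
    weight: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """ES and running sum of the KS walk for one gene set.

    ``ranked`` must be unique genes sorted by decreasing score.  Returns
    ``(es, running_sum, leading_edge)``; raises if the set covers the whole
    list, returns ``(nan, zeros, [])`` if the intersection is empty.
    """
    genes = [g for g, _ in ranked]
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    scores = np.array([s for _, s in ranked], dtype=float)
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranked list must be sorted by decreasing score")
    hit = np.array([g in gene_set.members for g in genes])
    n = len(genes)
    n_hit = int(hit.sum())
    if n_hit == 0:
        return np.nan, np.zeros(n), []
    if n_hit == n:
        raise ValueError(f"gene set {gene_set.name!r} covers the entire ranked list")

    inc = np.zeros(n)
    if weight == 0:
        inc[hit] = 1.0 / n_hit
    else:
        w = np.abs(scores[hit]) ** weight
        total = w.sum()
        if total == 0:
            inc[hit] = 1.0 / n_hit
        else:
            inc[hit] = w / total
    inc[~hit] = -1.0 / (n - n_hit)
    running = np.cumsum(inc)
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_max:], hit[i_max:]) if h]
    return es, running, leading


def preranked_gsea(
    ranked: list[tuple[str, float]],
    sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Gene-set-permutation GSEA over a collection of sets.

    For each observed set, ``n_perm`` random gene sets of the same size are
    drawn from the ranked list to form the null ES distribution.  Seeded
    and reproducible.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = [g for g, _ in ranked]
    n = len(genes)
    observed = []
    for gs in sets:
        size = len(gs.members & set(genes))
        if size == 0:
            observed.append((gs.name, np.nan, 0, []))
            continue
        if size > n // 2:
            import warnings

            warnings.warn(
                f"gene set {gs.name!r} covers more than half the ranked list", stacklevel=2
            )
        es, _, leading = enrichment_score(ranked, gs, weight=weight)
        observed.append((gs.name, es, size, leading))

    # share null distributions across sets of equal effective size
    sizes = sorted({size for _, _, size, _ in observed if size > 0})
    nulls: dict[int, np.ndarray] = {}
    idx = np.arange(n)
    for size in sizes:
        null = np.empty(n_perm)
        for b in range(n_perm):
            members = frozenset(genes[i] for i in rng.choice(idx, size=size, replace=False))
            gs = GeneSet(name=f"_null_{size}_{b}", members=members)
            null[b], _, _ = enrichment_score(ranked, gs, weight=weight)
        nulls[size] = null

    results = []
    p_values = []
    for name, es, size, leading in observed:
        if size == 0 or not np.isfinite(es):
            results.append([name, np.nan, np.nan, np.nan, np.nan, ()])
            p_values.append(np.nan)
            continue
        null = nulls[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1.0)
        else:
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else np.nan
            tail = np.sum(np.abs(same_sign) >= abs(es))
            p = min(1.0, 2.0 * (1.0 + tail) / (1.0 + same_sign.size))
        results.append([name, float(es), float(nes), float(p), np.nan, tuple(leading)])
        p_values.append(p)

    finite = np.array([np.isfinite(p) for p in p_values])
    fdr = np.full(len(p_values), np.nan)
    if finite.any():
        _, q, _, _ = multipletests(np.array(p_values)[finite], method="fdr_bh")
        fdr[finite] = q
    out = []
    for row, q in zip(results, fdr):
        name, es, nes, p, _, leading = row
        out.append(EnrichmentResult(name, es, nes, p, float(q), leading))
    return out


def rank_from_de(de_frame, metric: str = "signed_logp") -> list[tuple[str, float]]:
    """Build a ranked (gene, score) list from a differential table.

    ``signed_logp``: sign(log2FC) * -log10(p); ``log2fc``: the log2 fold
    change itself.  NA rows are dropped; ties are broken by gene id for
    determinism.
    """
    import pandas as pd

    df = de_frame.dropna(subset=["p_value", "fold_change"])
    df = df[df["fold_change"] > 0]
    if metric == "signed_logp":
        p = df["p_value"].clip(lower=1e-300)
        score = np.sign(np.log2(df["fold_change"])) * (-np.log10(p))
    elif metric == "log2fc":
        score = np.log2(df["fold_change"])
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    ranked = pd.DataFrame({"score": score}, index=df.index)
    ranked = ranked.sort_values(["score"], ascending=False, kind="mergesort")
    ranked = ranked.loc[sorted(ranked.index)].sort_values("score", ascending=False, kind="mergesort")
    return list(zip(ranked.index, ranked["score"].astype(float)))
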