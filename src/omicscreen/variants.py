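"""Descriptive summaries of MAF-like variant tables.

Counts by classification, type and sample; ranking of the most recurrently
mutated genes (by number of mutated patients, ties broken by total
mutation count then gene symbol); and the tumor/benign mutated-gene
overlap partition.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import VariantRecord, VariantSummary


def _to_frame(records: list[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "gene": [r.gene for r in records],
            "classification": [r.variant_classification for r in records],
            "type": [r.variant_type for r in records],
        }
    )


def variant_summary(records: list[VariantRecord], top_n: int = 10) -> VariantSummary:
    """Exact tallies by classification, type and sample, plus top genes."""
    if not records:
        return VariantSummary({}, {}, {}, pd.DataFrame(), 0)
    df = _to_frame(records)
    classification_counts = df["classification"].value_counts().to_dict()
    type_counts = df["type"].value_counts().to_dict()
    per_sample = df["sample_id"].value_counts().to_dict()
    n_patients = df["sample_id"].nunique()
    top = top_mutated_genes(records, n=top_n, total_patients=n_patients)
    return VariantSummary(
        classification_counts={k: int(v) for k, v in classification_counts.items()},
        type_counts={k: int(v) for k, v in type_counts.items()},
        per_sample_counts={k: int(v) for k, v in per_sample.items()},
        top_genes=top,
        total_records=len(records),
    )


def top_mutated_genes(
    records: list[VariantRecord], n: int = 10, total_patients: int | None = None
) -> pd.DataFrame:
    """Rank genes by number of mutated patients.

    Ties are broken by total mutation count, then lexicographically.
    ``patient_fraction`` = mutated patients / ``total_patients`` (defaults
    to the number of distinct samples in ``records``).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    df = _to_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["gene", "n_mutations", "n_patients", "patient_fraction"]
        ).set_index("gene")
    n_seen = df["sample_id"].nunique()
    if total_patients is None:
        total_patients = n_seen
    if total_patients < n_seen:
        raise ValueError("total_patients below the number of distinct samples")
    per_gene = df.groupby("gene").agg(
        n_mutations=("sample_id", "size"), n_patients=("sample_id", "nunique")
    )
    per_gene["patient_fraction"] = per_gene["n_patients"] / total_patients
    breakdown = df.groupby(["gene", "classification"]).size().unstack(fill_value=0)
    per_gene = per_gene.join(breakdown)
    per_gene = per_gene.reset_index()
    per_gene = per_gene.sort_values(
        by=["n_patients", "n_mutations", "gene"], ascending=[False, False, True]
    ).set_index("gene")
    return per_gene.head(n)


def group_gene_overlap(
    tumor_records: list[VariantRecord], bph_records: list[VariantRecord]
) -> dict[str, object]:
    """Three-way partition of mutated gene symbols between the two groups."""
    tumor_genes = {r.gene for r in tumor_records}
    bph_genes = {r.gene for r in bph_records}
    shared = tumor_genes & bph_genes
    return {
        "tumor_only": sorted(tumor_genes - bph_genes),
        "shared": sorted(shared),
        "bph_only": sorted(bph_genes - tumor_genes),
        "n_tumor_only": len(tumor_genes - bph_genes),
        "n_shared": len(shared),
        "n_bph_only": len(bph_genes - tumor_genes),
    }


def carrier_flags(records: list[VariantRecord], genes: set[str]) -> dict[str, bool]:
    """Per-sample flag: altered if any of ``genes`` is mutated in the sample."""
    altered = {r.sample_id for r in records if r.gene in genes}
    samples = {r.sample_id for r in records}
    return {s: s in altered for s in sorted(samples)}
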