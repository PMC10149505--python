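"""Shared domain types for the multi-omics / drug-screen pipeline.

The central container is :class:`OmicsMatrix`, a thin validated wrapper
around a feature x sample :class:`pandas.DataFrame` in which ``NaN``
encodes a missing measurement.  Record-like inputs (plate wells, variants,
survival subjects) are plain dataclasses so that readers can validate each
row against its invariants as it is parsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

Layer = Literal["proteome", "surfaceome", "transcriptome"]
VALID_LAYERS = ("proteome", "surfaceome", "transcriptome")

#: layers whose values live on a log2 scale after preprocessing
LOG_SCALE_LAYERS = ("proteome", "surfaceome")

WellType = Literal["treatment", "dmso_control", "positive_control"]
VALID_WELL_TYPES = ("treatment", "dmso_control", "positive_control")


@dataclass(frozen=True)
class SampleAnnotation:
    """One cohort sample: disease group, TMT batch and reference role."""

    sample_id: str
    group: str  # "BPH" | "tumor"; ignored for reference channels
    batch: str
    gleason: int | None = None
    reference_flag: bool = False

    def __post_init__(self) -> None:
        if not self.reference_flag and self.group not in ("BPH", "tumor"):
            raise ValueError(
                f"sample {self.sample_id!r}: group must be 'BPH' or 'tumor', got {self.group!r}"
            )
        if self.gleason is not None and not (6 <= self.gleason <= 10):
            raise ValueError(f"sample {self.sample_id!r}: Gleason score must be in 6..10")


def check_unique_annotations(annotations: list[SampleAnnotation]) -> None:
    ids = [a.sample_id for a in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids in annotation: {dupes}")


class OmicsMatrix:
    """Feature x sample abundance matrix with an explicit missing mask.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
        ``NaN`` marks missing cells; every non-missing value must be finite.
    layer
        One of ``proteome`` (TMT reporter / log2 ratios), ``surfaceome``
        (LFQ intensities) or ``transcriptome`` (TPM or counts).
    """

    def __init__(self, data: pd.DataFrame, layer: Layer) -> None:
        if layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {layer!r}; expected one of {VALID_LAYERS}")
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique().tolist())
            raise ValueError(f"duplicate feature ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = sorted(data.columns[data.columns.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = data.to_numpy(dtype=float)
        observed = ~np.isnan(values)
        if not np.isfinite(values[observed]).all():
            raise ValueError("non-missing values must be finite")
        self._data = data.astype(float)
        self.layer: Layer = layer

    # -- accessors -------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def feature_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def log_scale(self) -> bool:
        return self.layer in LOG_SCALE_LAYERS

    def subset_features(self, features: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(self._data.loc[features], self.layer)

    def subset_samples(self, samples: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(self._data[samples], self.layer)

    def equals(self, other: "OmicsMatrix") -> bool:
        return self.layer == other.layer and self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover
        n_missing = int(self.missing_mask.sum())
        return (
            f"OmicsMatrix(layer={self.layer!r}, features={self.shape[0]}, "
            f"samples={self.shape[1]}, missing={n_missing})"
        )


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant call (MAF-like row)."""

    sample_id: str
    gene: str
    variant_classification: str
    variant_type: str

    def __post_init__(self) -> None:
        if not self.variant_classification:
            raise ValueError("variant_classification must be nonempty")


@dataclass(frozen=True)
class PlateRecord:
    """One well of a viability screen plate."""

    cell_id: str
    drug: str
    dose: float  # µM; 0 for control wells
    replicate: int
    signal: float  # raw luminescence
    well_type: str

    def __post_init__(self) -> None:
        if self.well_type not in VALID_WELL_TYPES:
            raise ValueError(f"unknown well_type {self.well_type!r}")
        if self.well_type == "treatment" and not self.dose > 0:
            raise ValueError(
                f"treatment well ({self.cell_id}, {self.drug}) must have dose > 0"
            )
        if self.well_type != "treatment" and self.dose != 0:
            raise ValueError("control wells must have dose = 0")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"subject {self.subject_id!r}: time must be finite and >= 0")


@dataclass
class QCReport:
    """Per-sample unimodality diagnostics and reference-channel agreement."""

    dip_statistics: dict[str, float]
    dip_p_values: dict[str, float]
    reference_correlations: list[tuple[str, str, float]]
    dip_pass: bool
    reference_pass: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.dip_pass and self.reference_pass


@dataclass(frozen=True)
class DifferentialResult:
    feature: str
    layer: str
    fold_change: float  # linear scale, tumor / BPH
    statistic: float
    p_value: float
    direction: str  # up | down | ns
    reason: str | None = None  # set when the test could not be run


@dataclass
class CRGSet:
    """Cancer-related genes: multi-omics overlap plus top mutated genes."""

    genes: frozenset[str]
    provenance: dict[str, str]  # gene -> multiomics_overlap | top_mutation

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.genes):
            raise ValueError("provenance must cover exactly the CRG genes")
        if not self.genes:
            raise ValueError("CRG set is empty")


@dataclass
class DoseResponseFit:
    """A fitted three-parameter log-logistic dose-response curve.

    Viability model ``f(d) = c + (1 - c) / (1 + (d / e)**b)`` with the
    upper asymptote fixed at 1.  ``aa`` is the activity area (sum over the
    tested doses of 1 - viability) and ``seven_aa`` its resistance-oriented
    complement ``n_doses - aa``.
    """

    cell_id: str
    drug: str
    b: float
    c: float
    e: float
    ic50: float  # µM; NaN when censored
    ic50_censored: bool
    aa: float
    seven_aa: float
    rss: float
    n_points: int
    converged: bool = True
    message: str = ""

    def viability(self, dose: float | np.ndarray) -> float | np.ndarray:
        from .dose_response import loglogistic3

        return loglogistic3(dose, self.b, self.c, self.e)


@dataclass
class AssociationMatrix:
    """Protein x drug Spearman associations with the significance mask.

    ``rho`` holds NaN wherever the pair is not significant at ``alpha`` (or
    could not be computed); ``rho_unmasked`` retains every computed
    coefficient for diagnostics.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    significant_mask: pd.DataFrame
    rho_unmasked: pd.DataFrame
    alpha: float
    n_significant: int

    @property
    def proteins(self) -> list[str]:
        return list(self.rho.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.rho.columns)


@dataclass(frozen=True)
class SynergyResult:
    dose_a: float
    dose_b: float
    observed_effect: float
    ci: float  # NaN when undefined
    log10_ci: float
    defined: bool
    reason: str | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: tuple[str, ...]


@dataclass
class VariantSummary:
    classification_counts: dict[str, int]
    type_counts: dict[str, int]
    per_sample_counts: dict[str, int]
    top_genes: pd.DataFrame  # gene, n_mutations, n_patients, patient_fraction, per-class breakdown
    total_records: int
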