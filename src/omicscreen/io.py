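"""Readers and writers for the plain-text formats the pipeline consumes.

Matrices are TSV with feature ids in the first column and sample ids in the
header; an empty cell, ``NA`` or ``NaN`` (case-insensitive) denotes a
missing value and missing values are always written back as ``NA``.
Parsing is locale-independent: only the decimal point is accepted.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GeneSet,
    Layer,
    OmicsMatrix,
    PlateRecord,
    SampleAnnotation,
    SurvivalRecord,
    VariantRecord,
)

MISSING_TOKENS = {"", "na", "nan"}


def _parse_cell(token: str, row: str, column: str) -> float:
    token = token.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"non-numeric value {token!r} at feature {row!r}, sample {column!r}"
        ) from None


def read_omics_matrix(path: str | Path, layer: Layer) -> OmicsMatrix:
    """Read a feature x sample TSV into an :class:`OmicsMatrix`.

    Row and column order are preserved from the file.  Duplicate feature
    ids and non-numeric non-missing cells are hard errors.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and not (len(r) == 1 and r[0].startswith("#"))]
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    header = [c.strip() for c in rows[0][1:]]
    feature_ids: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(rows) - 1, len(header)), dtype=float)
    for i, row in enumerate(rows[1:]):
        fid = row[0].strip()
        if fid in seen:
            raise ValueError(f"{path}: duplicate feature id {fid!r}")
        seen.add(fid)
        feature_ids.append(fid)
        if len(row) - 1 != len(header):
            raise ValueError(f"{path}: row {fid!r} has {len(row) - 1} cells, expected {len(header)}")
        for j, token in enumerate(row[1:]):
            values[i, j] = _parse_cell(token, fid, header[j])
    data = pd.DataFrame(values, index=feature_ids, columns=header)
    return OmicsMatrix(data, layer)


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("feature\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def _sniff_delimiter(path: Path) -> str:
    with path.open() as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_plate_table(path: str | Path) -> list[PlateRecord]:
    """Read a long-format plate table (CSV or TSV) into validated records."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ["cell_id", "drug", "dose_uM", "replicate", "signal", "well_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plate-table columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PlateRecord(
                cell_id=str(row.cell_id),
                drug=str(row.drug),
                dose=float(row.dose_uM),
                replicate=int(row.replicate),
                signal=float(row.signal),
                well_type=str(row.well_type),
            )
        )
    return records


def write_plate_table(records: list[PlateRecord], path: str | Path, comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("cell_id\tdrug\tdose_uM\treplicate\tsignal\twell_type\n")
        for r in records:
            fh.write(
                f"{r.cell_id}\t{r.drug}\t{r.dose!r}\t{r.replicate}\t{r.signal!r}\t{r.well_type}\n"
            )


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a MAF-like TSV; extra columns beyond the required four are ignored."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    colmap = {
        "sample_id": ["sample_id", "sample", "tumor_sample_barcode"],
        "gene": ["gene", "hugo_symbol"],
        "variant_classification": ["variant_classification", "classification"],
        "variant_type": ["variant_type", "type"],
    }
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for key, aliases in colmap.items():
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
        else:
            raise ValueError(f"{path}: missing required column {key!r}")
    return [
        VariantRecord(
            sample_id=str(row[resolved["sample_id"]]),
            gene=str(row[resolved["gene"]]),
            variant_classification=str(row[resolved["variant_classification"]]),
            variant_type=str(row[resolved["variant_type"]]),
        )
        for _, row in df.iterrows()
    ]


def write_variant_table(records: list[VariantRecord], path: str | Path, comment: str | None = None) -> None:
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("sample_id\tgene\tvariant_classification\tvariant_type\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.gene}\t{r.variant_classification}\t{r.variant_type}\n")


def read_gene_sets_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description (discarded), tab-separated members."""
    sets = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            members = frozenset(f.strip() for f in fields[2:] if f.strip())
            sets.append(GeneSet(name=fields[0], members=members))
    return sets


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    """Sample sheet TSV: sample_id, group, batch, optional gleason, reference_flag."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "group", "batch"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing sample-sheet column {col!r}")
    annotations = []
    for _, row in df.iterrows():
        gleason = None
        if "gleason" in df.columns and pd.notna(row["gleason"]):
            gleason = int(row["gleason"])
        ref = bool(row["reference_flag"]) if "reference_flag" in df.columns else False
        annotations.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                batch=str(row["batch"]),
                gleason=gleason,
                reference_flag=ref,
            )
        )
    ids = [a.sample_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return annotations


def write_sample_sheet(annotations: list[SampleAnnotation], path: str | Path, comment: str | None = None) -> None:
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("sample_id\tgroup\tbatch\tgleason\treference_flag\n")
        for a in annotations:
            gl = "NA" if a.gleason is None else str(a.gleason)
            fh.write(f"{a.sample_id}\t{a.group}\t{a.batch}\t{gl}\t{a.reference_flag}\n")


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Survival TSV with columns subject_id, time, event, group."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("subject_id", "time", "event", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing survival column {col!r}")
    return [
        SurvivalRecord(
            subject_id=str(r["subject_id"]),
            time=float(r["time"]),
            event=bool(r["event"]),
            group=str(r["group"]),
        )
        for _, r in df.iterrows()
    ]


def write_survival_table(records: list[SurvivalRecord], path: str | Path, comment: str | None = None) -> None:
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("subject_id\ttime\tevent\tgroup\n")
        for r in records:
            fh.write(f"{r.subject_id}\t{r.time!r}\t{int(r.event)}\t{r.group}\n")
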