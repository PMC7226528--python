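"""Data model, readers/writers and pairing validation.

All tabular inputs are delimited text (tab by default, comma accepted).
Genomic coordinates are normalized to a 0-based half-open convention at the
reader boundary; BED is taken as 0-based half-open, GFF3 as 1-based closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("tumor", "normal")
HPV_STATUSES = ("positive", "negative", "unknown")

#: disease-free survival statuses counted as events
DFS_EVENT_STATUSES = frozenset({"recidive", "exitus_disease"})
DFS_STATUSES = frozenset(
    {"disease_free", "exitus_other", "recidive", "exitus_disease"}
)


class CohortError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV (or CSV) with a header row; decimal point is locale-fixed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


@dataclass
class ExpressionMatrix:
    """Feature × sample expression table.

    ``values`` holds log2 intensities (``scale="log2"``) or raw non-negative
    integer counts (``scale="count"``); rows are probes or genes depending on
    ``level``.
    """

    values: pd.DataFrame
    level: str = "gene"
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise CohortError(f"unknown feature level {self.level!r}")
        if self.scale not in ("log2", "count"):
            raise CohortError(f"unknown scale {self.scale!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise CohortError(f"duplicate sample ids: {dupes}")
        if self.level == "gene" and self.values.index.duplicated().any():
            dupes = sorted(
                self.values.index[self.values.index.duplicated()].unique()
            )
            raise CohortError(f"duplicate gene ids in gene-level matrix: {dupes}")
        if self.values.isna().any().any():
            raise CohortError("missing expression values are not permitted")
        if self.scale == "count":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise CohortError("count matrix contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise CohortError("count matrix contains non-integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ProbeAnnotation:
    """probe_id → gene_symbol map with optional technical-replicate groups.

    ``replicate_group`` keys probes that are technical replicates of one
    another; probes without a group are treated as singletons.
    """

    table: pd.DataFrame  # columns: probe_id, gene_symbol, replicate_group

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol"}
        if not required.issubset(self.table.columns):
            raise CohortError(f"probe annotation needs columns {sorted(required)}")
        if "replicate_group" not in self.table.columns:
            self.table = self.table.assign(replicate_group=self.table["probe_id"])
        # a physical probe maps to at most one gene symbol
        per_probe = self.table.groupby("replicate_group")["gene_symbol"].nunique()
        if (per_probe > 1).any():
            bad = per_probe[per_probe > 1].index.tolist()
            raise CohortError(f"probe groups map to multiple genes: {bad}")


@dataclass
class GeneAnnotation:
    """Gene coordinates, 0-based half-open."""

    table: pd.DataFrame  # columns: gene_symbol, chromosome, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene_symbol", "chromosome", "start", "end"}
        if not required.issubset(self.table.columns):
            raise CohortError(f"gene annotation needs columns {sorted(required)}")
        if "strand" not in self.table.columns:
            self.table = self.table.assign(strand="unknown")
        t = self.table
        if (t["start"].astype(np.int64) < 0).any():
            raise CohortError("negative start coordinate")
        bad = t[t["start"].astype(np.int64) >= t["end"].astype(np.int64)]
        if len(bad):
            raise CohortError(
                f"start >= end after normalization for: {bad['gene_symbol'].tolist()}"
            )

    def get(self, gene: str) -> pd.Series:
        hit = self.table[self.table["gene_symbol"] == gene]
        if hit.empty:
            raise KeyError(f"gene {gene!r} not in annotation")
        return hit.iloc[0]


@dataclass
class SampleTable:
    """Sample → patient/tissue/HPV/batch metadata."""

    table: pd.DataFrame  # columns: sample_id, patient_id, tissue, hpv_status[, batch]

    def __post_init__(self) -> None:
        required = {"sample_id", "patient_id", "tissue", "hpv_status"}
        if not required.issubset(self.table.columns):
            raise CohortError(f"sample table needs columns {sorted(required)}")
        t = self.table
        if t["sample_id"].duplicated().any():
            raise CohortError("duplicate sample_id in sample table")
        bad_tissue = set(t["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise CohortError(f"unknown tissue values: {sorted(bad_tissue)}")
        bad_hpv = set(t["hpv_status"]) - set(HPV_STATUSES)
        if bad_hpv:
            raise CohortError(f"unknown hpv_status values: {sorted(bad_hpv)}")

    def hpv_of_patients(self) -> pd.Series:
        """patient_id → hpv_status (consistent across a patient's samples)."""
        per = self.table.groupby("patient_id")["hpv_status"].agg(set)
        conflict = per[per.map(len) > 1]
        if len(conflict):
            raise CohortError(
                f"conflicting HPV status within patients: {conflict.index.tolist()}"
            )
        return per.map(lambda s: next(iter(s)))


@dataclass
class ClinicalTable:
    """Per-patient follow-up: overall and (optionally) disease-free survival.

    A textual ``dfs_status`` column is collapsed to the binary ``dfs_event``:
    recurrence and disease-specific death count as events.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient_id", "os_months", "os_event"}
        if not required.issubset(self.table.columns):
            raise CohortError(f"clinical table needs columns {sorted(required)}")
        t = self.table.copy()
        t["os_months"] = pd.to_numeric(t["os_months"])
        t["os_event"] = pd.to_numeric(t["os_event"]).astype(int)
        if (t["os_months"] < 0).any():
            raise CohortError("negative os_months")
        if not set(t["os_event"]).issubset({0, 1}):
            raise CohortError("os_event must be 0/1")
        if "dfs_status" in t.columns and "dfs_event" not in t.columns:
            bad = set(t["dfs_status"]) - DFS_STATUSES - {""}
            if bad:
                raise CohortError(f"unknown dfs_status values: {sorted(bad)}")
            t["dfs_event"] = (
                t["dfs_status"].isin(DFS_EVENT_STATUSES).astype(int)
            )
        if "dfs_months" in t.columns:
            t["dfs_months"] = pd.to_numeric(t["dfs_months"])
            if (t["dfs_months"].dropna() < 0).any():
                raise CohortError("negative dfs_months")
        if "dfs_event" in t.columns:
            t["dfs_event"] = pd.to_numeric(t["dfs_event"]).astype(int)
        self.table = t

    @property
    def has_dfs(self) -> bool:
        return {"dfs_months", "dfs_event"}.issubset(self.table.columns)


@dataclass
class PairingResult:
    """Outcome of tumor/normal pairing validation."""

    paired_patients: list[str]
    n_tumor_only: int
    n_normal_only: int


@dataclass
class CohortDataset:
    """Bundle of all inputs for one cohort (plus simulation truth if any)."""

    expression: ExpressionMatrix
    samples: SampleTable
    probes: Optional[ProbeAnnotation] = None
    clinical: Optional[ClinicalTable] = None
    annotation: Optional[GeneAnnotation] = None
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        known = set(self.expression.sample_ids)
        missing = set(self.samples.table["sample_id"]) - known
        if missing:
            raise CohortError(
                f"sample table refers to samples absent from expression: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path, scale: str = "log2", level: str = "probe"
) -> ExpressionMatrix:
    """Read a feature × sample matrix; first column = feature ids, header = samples."""
    path = Path(path)
    if path.exists():
        # pandas mangles duplicate headers; check the raw header line
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        body = header[1:]
        if len(set(body)) != len(body):
            dupes = sorted({s for s in body if body.count(s) > 1})
            raise CohortError(f"duplicate sample ids: {dupes}")
    raw = _read_table(path)
    feat_col = raw.columns[0]
    frame = raw.set_index(feat_col)
    try:
        numeric = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        for col in frame.columns:  # locate the offending cell for the message
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame[col][coerced.isna() & (frame[col] != "")]
            empty = frame[col][frame[col] == ""]
            if len(bad) or len(empty):
                row = (list(bad.index) + list(empty.index))[0]
                raise CohortError(
                    f"non-numeric value in column {col!r}, row {row!r}"
                ) from exc
        raise CohortError(f"non-numeric values in {path}") from exc
    numeric.index.name = feat_col
    return ExpressionMatrix(numeric, level=level, scale=scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    return SampleTable(_read_table(path))


def read_clinical_table(path: str | Path) -> ClinicalTable:
    return ClinicalTable(_read_table(path))


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    return ProbeAnnotation(_read_table(path))


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise CohortError(f"BED line needs >=4 fields: {line!r}")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 else "unknown"
            rows.append(
                {
                    "gene_symbol": name,
                    "chromosome": chrom,
                    "start": int(start),
                    "end": int(end),
                    "strand": strand if strand in "+-" else "unknown",
                }
            )
    return pd.DataFrame(rows)


def _read_gff3(path: Path, symbol_attribute: str = "Name") -> pd.DataFrame:
    from gffutils.iterators import DataIterator

    rows = []
    for feature in DataIterator(str(path)):
        if feature.featuretype != "gene":
            continue
        attrs = feature.attributes
        symbol = (attrs[symbol_attribute] or [feature.id])[0] if (
            symbol_attribute in attrs
        ) else feature.id
        rows.append(
            {
                "gene_symbol": symbol,
                "chromosome": feature.seqid,
                # GFF3 is 1-based closed; shift start to 0-based half-open
                "start": int(feature.start) - 1,
                "end": int(feature.end),
                "strand": feature.strand if feature.strand in "+-" else "unknown",
            }
        )
    return pd.DataFrame(rows)


def read_gene_annotation(
    path: str | Path, symbol_attribute: str = "Name"
) -> GeneAnnotation:
    """Read gene coordinates from BED or GFF3, normalizing to 0-based half-open.

    Parameters
    ----------
    symbol_attribute:
        GFF3 attribute key to use as the gene symbol (``Name`` by default).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        table = _read_bed(path)
    elif suffix in (".gff", ".gff3"):
        table = _read_gff3(path, symbol_attribute=symbol_attribute)
    else:
        raise CohortError(f"unknown annotation format {suffix!r} (want .bed/.gff3)")
    if table.empty:
        raise CohortError(f"no gene records found in {path}")
    return GeneAnnotation(table)


def validate_pairing(samples: SampleTable) -> PairingResult:
    """Return patients with exactly one tumor and one normal sample.

    Patients with only one tissue are counted and excluded; two samples of
    the same tissue for one patient make the pairing ambiguous and raise.
    """
    t = samples.table
    counts = t.pivot_table(
        index="patient_id", columns="tissue", values="sample_id", aggfunc="count"
    ).reindex(columns=list(TISSUES)).fillna(0).astype(int)
    multi = counts[(counts["tumor"] > 1) | (counts["normal"] > 1)]
    if len(multi):
        raise CohortError(
            f"ambiguous pairing, >1 sample of one tissue for: {multi.index.tolist()}"
        )
    paired = counts[(counts["tumor"] == 1) & (counts["normal"] == 1)]
    tumor_only = int(((counts["tumor"] == 1) & (counts["normal"] == 0)).sum())
    normal_only = int(((counts["tumor"] == 0) & (counts["normal"] == 1)).sum())
    if tumor_only or normal_only:
        logger.info(
            "pairing: %d paired patients, %d tumor-only, %d normal-only excluded",
            len(paired), tumor_only, normal_only,
        )
    return PairingResult(sorted(paired.index), tumor_only, normal_only)


def paired_sample_map(samples: SampleTable) -> pd.DataFrame:
    """patient_id → (tumor sample_id, normal sample_id) for paired patients."""
    pairing = validate_pairing(samples)
    t = samples.table
    wide = t[t["patient_id"].isin(pairing.paired_patients)].pivot(
        index="patient_id", columns="tissue", values="sample_id"
    )
    return wide[["tumor", "normal"]]
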