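"""Expression surrogate for genomic co-amplification around an anchor gene.

Amplification of a chromosomal segment (e.g. 11q13 around CCND1) raises the
expression of every gene it covers, so coordinated tumor/normal fold-change
increases across an anchor gene's neighbours serve as a surrogate marker
when DNA copy-number data is unavailable. The window is a fixed flank
(default 1 Mb) on both sides of the anchor; membership is by interval
overlap, so genes straddling the window edge count.

Coordinates are the internal 0-based half-open convention. "Downstream"
means increasing chromosomal coordinate relative to the anchor's end,
independent of strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CohortError,
    ExpressionMatrix,
    GeneAnnotation,
    SampleTable,
    paired_sample_map,
)
from .deregulation import _lfc_for_gene
from .preprocess import filter_low_expression


@dataclass(frozen=True)
class WindowSpec:
    """Anchor gene plus symmetric flank (base pairs) defining the window."""

    anchor: str
    flank: int = 1_000_000

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise CohortError("flank must be positive")


@dataclass
class WindowProfile:
    """Coordinate-ordered window genes with per-patient log2 fold changes.

    ``genes`` columns: gene_symbol, start, end, side (upstream/anchor/
    downstream), expressed. ``lfc`` rows cover expressed genes only
    (genes × paired patients); unexpressed genes stay listed but masked.
    """

    spec: WindowSpec
    genes: pd.DataFrame
    lfc: pd.DataFrame

    @property
    def expressed_genes(self) -> list[str]:
        return self.genes.loc[self.genes["expressed"], "gene_symbol"].tolist()


def select_window_genes(annotation: GeneAnnotation, spec: WindowSpec) -> pd.DataFrame:
    """Genes overlapping [anchor.start − flank, anchor.end + flank), sorted by start.

    Side labels: ``upstream`` if the gene ends at or before the anchor start,
    ``downstream`` if it starts at or after the anchor end, ``anchor``
    otherwise (the anchor itself and any gene overlapping it).
    """
    anchor = annotation.get(spec.anchor)
    lo = int(anchor["start"]) - spec.flank
    hi = int(anchor["end"]) + spec.flank
    t = annotation.table
    on_chrom = t[t["chromosome"] == anchor["chromosome"]].copy()
    starts = on_chrom["start"].astype(np.int64)
    ends = on_chrom["end"].astype(np.int64)
    hit = on_chrom[(starts < hi) & (ends > lo)].copy()
    hit["start"] = hit["start"].astype(np.int64)
    hit["end"] = hit["end"].astype(np.int64)
    side = np.where(
        hit["end"] <= int(anchor["start"]),
        "upstream",
        np.where(hit["start"] >= int(anchor["end"]), "downstream", "anchor"),
    )
    hit["side"] = side
    hit = hit.sort_values(["start", "gene_symbol"]).reset_index(drop=True)
    return hit[["gene_symbol", "chromosome", "start", "end", "strand", "side"]]


def window_lfc_matrix(
    m: ExpressionMatrix,
    samples: SampleTable,
    annotation: GeneAnnotation,
    spec: WindowSpec,
    intensity_threshold: float = 5.0,
) -> WindowProfile:
    """Per-patient log2 fold changes for expressed genes in the anchor window.

    The low-intensity filter (mean log2 intensity below ``intensity_threshold``
    over all samples) defines the expressed-gene mask; unexpressed genes are
    retained in the gene list but excluded from the fold-change matrix.
    """
    if m.level != "gene":
        raise CohortError("window profile expects a gene-level matrix")
    genes = select_window_genes(annotation, spec)
    present = genes[genes["gene_symbol"].isin(m.values.index)]
    if present.empty:
        raise CohortError("no window gene present in the expression matrix")
    sub = ExpressionMatrix(
        m.values.loc[present["gene_symbol"]], level="gene", scale="log2"
    )
    try:
        expressed_m, _removed = filter_low_expression(sub, intensity_threshold)
        expressed = set(expressed_m.values.index)
    except CohortError:
        expressed = set()
    genes = genes.assign(
        expressed=genes["gene_symbol"].isin(expressed)
    )
    if not genes["expressed"].any():
        raise CohortError("no expressed gene in the window")
    pairs = paired_sample_map(samples)
    rows = {}
    for gene in genes.loc[genes["expressed"], "gene_symbol"]:
        fct = _lfc_for_gene(m, pairs, gene)
        rows[gene] = fct.set_index("patient_id")["lfc"]
    lfc = pd.DataFrame(rows).T
    lfc.index.name = "gene_symbol"
    return WindowProfile(spec=spec, genes=genes, lfc=lfc)


def coamplification_call(
    profile: WindowProfile,
    patients: Optional[Sequence[str]] = None,
    min_genes: int = 2,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Per-patient co-amplification surrogate call from downstream genes.

    Score: number (and fraction) of expressed downstream window genes with
    lfc >= ``lfc_cut``; the flag is true when the count reaches
    ``min_genes``. With no expressed downstream gene the flag is undefined
    (NA). ``patients`` restricts the patient set (typically the
    anchor-upregulated group).
    """
    downstream = profile.genes[
        (profile.genes["side"] == "downstream") & profile.genes["expressed"]
    ]["gene_symbol"].tolist()
    cols = list(profile.lfc.columns) if patients is None else [
        p for p in patients if p in profile.lfc.columns
    ]
    if patients is not None and len(cols) < len(patients):
        missing = sorted(set(patients) - set(cols))
        raise CohortError(f"patients absent from window profile: {missing}")
    out = pd.DataFrame({"patient_id": cols}).set_index("patient_id")
    out["n_downstream_expressed"] = len(downstream)
    if not downstream:
        out["n_up"] = np.nan
        out["frac_up"] = np.nan
        out["coamplified"] = pd.array([pd.NA] * len(cols), dtype="boolean")
        return out.reset_index()
    block = profile.lfc.loc[downstream, cols]
    n_up = (block >= lfc_cut).sum(axis=0)
    out["n_up"] = n_up.astype(int)
    out["frac_up"] = n_up / len(downstream)
    out["coamplified"] = pd.array((n_up >= min_genes).to_numpy(), dtype="boolean")
    return out.reset_index()
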