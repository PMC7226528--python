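"""Per-patient paired fold-change computation and three-way classification.

The central statistic: for every paired patient, the log2 fold change of a
gene between the tumor and the matched normal sample, classified as
upregulated (FC > 2), not deregulated (0.5 < FC < 2) or downregulated
(FC < 0.5). Boundary fold changes (exactly 2 or 0.5) fall in the middle
class: both defining inequalities are strict, so the open up/down sets
exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CohortError, ExpressionMatrix, SampleTable, paired_sample_map

#: default linear fold-change thresholds (upper, lower)
DEFAULT_UPPER = 2.0
DEFAULT_LOWER = 0.5

CALLS = ("up", "not", "down")


@dataclass(frozen=True)
class Thresholds:
    upper: float = DEFAULT_UPPER
    lower: float = DEFAULT_LOWER

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise CohortError(
                f"need 0 < lower < upper, got ({self.lower}, {self.upper})"
            )


def _lfc_for_gene(
    m: ExpressionMatrix, pairs: pd.DataFrame, gene: str
) -> pd.DataFrame:
    if m.scale != "log2":
        raise CohortError("paired fold changes require log2-scale data")
    if gene not in m.values.index:
        raise CohortError(f"gene {gene!r} absent from expression matrix")
    if pairs.empty:
        raise CohortError("no paired patients")
    row = m.values.loc[gene]
    lfc = row[pairs["tumor"]].to_numpy() - row[pairs["normal"]].to_numpy()
    return pd.DataFrame(
        {
            "patient_id": pairs.index,
            "lfc": lfc,
            "fc": np.exp2(lfc),
        }
    ).reset_index(drop=True)


def paired_lfc(
    m: ExpressionMatrix, samples: SampleTable, gene: str
) -> pd.DataFrame:
    """Tumor-minus-normal log2 fold change per paired patient for one gene.

    Returns a frame with columns ``patient_id``, ``lfc``, ``fc`` (= 2**lfc).
    Unpaired patients are excluded; a missing gene is an error.
    """
    return _lfc_for_gene(m, paired_sample_map(samples), gene)


def classify(fc: float, upper: float = DEFAULT_UPPER, lower: float = DEFAULT_LOWER) -> str:
    """Three-way call for a linear fold change; boundaries map to ``not``."""
    if fc <= 0 or not np.isfinite(fc):
        raise CohortError(f"fold change must be positive and finite, got {fc}")
    if fc > upper:
        return "up"
    if fc < lower:
        return "down"
    return "not"


def classify_series(
    fc: pd.Series, upper: float = DEFAULT_UPPER, lower: float = DEFAULT_LOWER
) -> pd.Series:
    """Vectorized :func:`classify`."""
    arr = fc.to_numpy(dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise CohortError("fold changes must be positive and finite")
    out = np.where(arr > upper, "up", np.where(arr < lower, "down", "not"))
    return pd.Series(pd.Categorical(out, categories=list(CALLS)), index=fc.index)


def deregulation_calls(
    m: ExpressionMatrix,
    samples: SampleTable,
    genes: list[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Fold changes and calls for several genes over all paired patients.

    Columns: patient_id, gene_symbol, lfc, fc, call, upper, lower. The
    threshold columns echo the thresholds used so written tables are
    self-describing.
    """
    pairs = paired_sample_map(samples)
    frames = []
    for gene in genes:
        fct = _lfc_for_gene(m, pairs, gene)
        fct["gene_symbol"] = gene
        fct["call"] = classify_series(fct["fc"], thresholds.upper, thresholds.lower)
        frames.append(fct)
    out = pd.concat(frames, ignore_index=True)
    out["upper"] = thresholds.upper
    out["lower"] = thresholds.lower
    return out[["patient_id", "gene_symbol", "lfc", "fc", "call", "upper", "lower"]]


def summarize(calls: pd.DataFrame, samples: SampleTable) -> pd.DataFrame:
    """Call counts and fractions per gene, overall and per HPV stratum.

    Patients with unknown HPV status stay in the whole-cohort stratum
    (``all``) but are excluded from ``hpv_pos`` / ``hpv_neg``.
    """
    hpv = samples.hpv_of_patients()
    merged = calls.merge(
        hpv.rename("hpv_status"), left_on="patient_id", right_index=True, how="left"
    )
    strata = {
        "all": merged,
        "hpv_pos": merged[merged["hpv_status"] == "positive"],
        "hpv_neg": merged[merged["hpv_status"] == "negative"],
    }
    rows = []
    for stratum, sub in strata.items():
        for gene, g in sub.groupby("gene_symbol", observed=True):
            counts = g["call"].value_counts()
            n = int(len(g))
            row = {"gene_symbol": gene, "stratum": stratum, "n": n}
            for call in CALLS:
                c = int(counts.get(call, 0))
                row[f"n_{call}"] = c
                row[f"frac_{call}"] = c / n if n else float("nan")
            rows.append(row)
    out = pd.DataFrame(rows).sort_values(["gene_symbol", "stratum"])
    return out.reset_index(drop=True)
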