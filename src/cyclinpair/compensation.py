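"""Cross-gene deregulation coupling: cross-tabulation and a permutation test.

"Compensation" is the reciprocal pattern where one gene's downregulation is
accompanied by the other's upregulation (and vice versa). The module
cross-tabulates two genes' three-way calls over the shared paired patients,
reports the two directional fractions, and offers a permutation test whose
statistic counts opposite-direction patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import CohortError
from .deregulation import CALLS


@dataclass
class CrossTab:
    """3×3 call contingency table for a gene pair (rows = gene A)."""

    gene_a: str
    gene_b: str
    counts: pd.DataFrame  # index/columns = up, not, down
    n: int

    def __post_init__(self) -> None:
        if int(self.counts.to_numpy().sum()) != self.n:
            raise CohortError("crosstab cells do not sum to n")

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["total"] = out.sum(axis=1)
        out.loc["total"] = out.sum(axis=0)
        return out


@dataclass
class CompensationResult:
    """Directional compensation fractions (and optional permutation test)."""

    gene_a: str
    gene_b: str
    n_down_a: int
    n_down_a_up_b: int
    n_up_a: int
    n_up_a_down_b: int
    frac_down_a_up_b: Optional[float]
    frac_up_a_down_b: Optional[float]
    p_value: Optional[float] = None
    observed_statistic: Optional[int] = None
    null_mean: Optional[float] = None
    null_sd: Optional[float] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _align_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    a = calls_a.set_index("patient_id")["call"]
    b = calls_b.set_index("patient_id")["call"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise CohortError("no shared patients between the two call sets")
    if len(shared) < max(len(a), len(b)):
        warnings.warn(
            f"patient sets differ; intersecting to {len(shared)} patients"
        )
    return pd.DataFrame({"a": a.loc[shared], "b": b.loc[shared]})


def cross_tabulate(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> CrossTab:
    """3×3 contingency table of gene A calls (rows) vs gene B calls (columns)."""
    both = _align_calls(calls_a, calls_b)
    counts = (
        pd.crosstab(both["a"], both["b"])
        .reindex(index=list(CALLS), columns=list(CALLS), fill_value=0)
        .astype(int)
    )
    counts.index.name = "gene_a_call"
    counts.columns.name = "gene_b_call"
    gene_a = str(calls_a["gene_symbol"].iloc[0]) if "gene_symbol" in calls_a else "A"
    gene_b = str(calls_b["gene_symbol"].iloc[0]) if "gene_symbol" in calls_b else "B"
    return CrossTab(gene_a, gene_b, counts, int(len(both)))


def compensation_fractions(ct: CrossTab) -> CompensationResult:
    """Fractions of A-down patients with B up, and A-up patients with B down.

    An empty denominator yields ``None`` (undefined), never 0.
    """
    n_down_a = int(ct.counts.loc["down"].sum())
    n_down_a_up_b = int(ct.counts.loc["down", "up"])
    n_up_a = int(ct.counts.loc["up"].sum())
    n_up_a_down_b = int(ct.counts.loc["up", "down"])
    return CompensationResult(
        gene_a=ct.gene_a,
        gene_b=ct.gene_b,
        n_down_a=n_down_a,
        n_down_a_up_b=n_down_a_up_b,
        n_up_a=n_up_a,
        n_up_a_down_b=n_up_a_down_b,
        frac_down_a_up_b=(n_down_a_up_b / n_down_a) if n_down_a else None,
        frac_up_a_down_b=(n_up_a_down_b / n_up_a) if n_up_a else None,
    )


def _opposite_count(a: np.ndarray, b: np.ndarray) -> int:
    return int(((a == "up") & (b == "down")).sum() + ((a == "down") & (b == "up")).sum())


def coupling_permutation_test(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> CompensationResult:
    """One-sided permutation test for opposite-direction coupling.

    Statistic: number of patients with (A up, B down) or (A down, B up).
    The null permutes gene B's calls across patients; the add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` avoids p = 0. Directional
    ("compensation" predicts an excess of opposite-direction pairs), hence
    one-sided.
    """
    if n_perm < 100:
        raise CohortError("n_perm must be >= 100")
    both = _align_calls(calls_a, calls_b)
    # order-invariant: permutation stream applied to a canonical patient order
    both = both.sort_index()
    a = np.asarray(both["a"], dtype=object)
    b = np.asarray(both["b"], dtype=object)
    ct = cross_tabulate(calls_a, calls_b)
    result = compensation_fractions(ct)
    if len(set(a)) < 2 or len(set(b)) < 2:
        warnings.warn("fewer than 2 distinct calls in a gene: p undefined")
        return result
    observed = _opposite_count(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null[i] = _opposite_count(a, rng.permutation(b))
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    result.p_value = float(p)
    result.observed_statistic = observed
    result.null_mean = float(null.mean())
    result.null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    result.n_perm = n_perm
    result.seed = seed
    return result
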