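"""Normalization and feature-collapsing stages.

Microarray path: quantile normalization → technical-replicate averaging →
probe-to-gene collapse → low-intensity filter. Count path: median-of-ratios
size factors followed by a log2(x+1) transform. All averaging happens on the
log2 scale (i.e. geometric means of intensities).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core_io import CohortError, ExpressionMatrix, ProbeAnnotation

logger = logging.getLogger(__name__)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    After the transform each sample's sorted value vector equals the
    across-sample mean of sorted vectors, and within-sample ranks are
    preserved. Tied values receive the mean of the target quantiles they
    span (the classic limma/preprocessCore ``ties = average`` behaviour),
    which makes the operation idempotent.
    """
    if m.scale != "log2":
        raise CohortError("quantile normalization expects log2-scale data")
    if m.n_features == 1:
        warnings.warn("single-feature matrix: quantile normalization is a no-op")
        return ExpressionMatrix(m.values.copy(), level=m.level, scale=m.scale)
    values = m.values.to_numpy(dtype=float)
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(target)
        ranked[order] = target
        # average target quantiles over ties (rare in float data: fast path)
        sorted_col = col[order]
        if (sorted_col[1:] != sorted_col[:-1]).all():
            out[:, j] = ranked
        else:
            s = pd.Series(ranked).groupby(col, sort=False).transform("mean")
            out[:, j] = s.to_numpy()
    frame = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(frame, level=m.level, scale=m.scale)


def average_technical_replicates(
    m: ExpressionMatrix, probes: ProbeAnnotation
) -> tuple[ExpressionMatrix, ProbeAnnotation]:
    """Average technical-replicate probe rows (log2 scale), one row per group.

    Returns the collapsed matrix plus a probe annotation keyed by the
    replicate-group id so downstream gene collapse stays consistent.
    """
    ann = probes.table.set_index("probe_id")
    missing = [f for f in m.feature_ids if f not in ann.index]
    if missing:
        raise CohortError(f"probes missing from annotation: {missing[:5]}...")
    groups = ann.loc[m.feature_ids, "replicate_group"]
    collapsed = m.values.groupby(groups.to_numpy()).mean()
    collapsed.index.name = "probe_id"
    gene_map = (
        probes.table.groupby("replicate_group")["gene_symbol"].first().reindex(
            collapsed.index
        )
    )
    new_ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": collapsed.index,
                "gene_symbol": gene_map.to_numpy(),
                "replicate_group": collapsed.index,
            }
        ).reset_index(drop=True)
    )
    out = ExpressionMatrix(collapsed, level="probe", scale=m.scale)
    return out, new_ann


def collapse_probes_to_genes(
    m: ExpressionMatrix, probes: ProbeAnnotation
) -> ExpressionMatrix:
    """Average the probes targeting each gene into one gene row (log2 scale).

    Probes without a gene symbol are dropped (and counted in the log).
    """
    if m.level != "probe":
        raise CohortError("collapse expects a probe-level matrix")
    ann = probes.table.set_index("probe_id")["gene_symbol"]
    mapped = ann.reindex(m.feature_ids)
    unmapped = mapped.isna() | (mapped == "")
    if unmapped.all():
        raise CohortError("no probe maps to a gene symbol")
    if unmapped.any():
        logger.info("dropping %d unmapped probes", int(unmapped.sum()))
    kept = m.values.loc[~unmapped.to_numpy()]
    genes = mapped[~unmapped]
    collapsed = kept.groupby(genes.to_numpy()).mean()
    collapsed.index.name = "gene_symbol"
    return ExpressionMatrix(collapsed, level="gene", scale=m.scale)


def filter_low_expression(
    m: ExpressionMatrix, threshold: float = 5.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose mean log2 intensity over all samples is below ``threshold``.

    The boundary is kept: a gene with mean exactly equal to the threshold is
    retained (strictly-lower genes are removed). Returns the filtered matrix
    and the list of removed genes.
    """
    if m.scale != "log2":
        raise CohortError("intensity filter expects log2-scale data")
    means = m.values.mean(axis=1)
    keep = means >= threshold
    removed = sorted(m.values.index[~keep])
    if not keep.any():
        raise CohortError("intensity filter removed every gene")
    if removed:
        logger.info("intensity filter removed %d genes", len(removed))
    return (
        ExpressionMatrix(m.values.loc[keep], level=m.level, scale=m.scale),
        removed,
    )


def size_factor_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios depth normalization for counts, then log2(x+1).

    Size factors are the per-sample median ratio to the per-gene geometric
    mean, computed over genes with all-nonzero counts; output values are
    ``log2(count / size_factor + 1)``.
    """
    if m.scale != "count":
        raise CohortError("size-factor normalization expects count data")
    if m.n_samples < 2:
        raise CohortError("need >=2 samples for size-factor normalization")
    counts = m.values.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise CohortError("no gene with nonzero counts in every sample")
    ref = counts[nonzero]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    normalized = np.log2(counts / size_factors[None, :] + 1.0)
    frame = pd.DataFrame(normalized, index=m.values.index, columns=m.values.columns)
    out = ExpressionMatrix(frame, level=m.level, scale="log2")
    out.size_factors_ = pd.Series(size_factors, index=m.values.columns)
    return out


def center_batches(m: ExpressionMatrix, batches: pd.Series) -> ExpressionMatrix:
    """Optional per-batch, per-gene mean centering (off by default in the pipeline).

    Each gene is shifted within every batch so batch means agree with the
    gene's overall mean. A lightweight alternative to empirical-Bayes batch
    correction for data that is otherwise already processed.
    """
    batches = batches.reindex(m.values.columns)
    if batches.isna().any():
        raise CohortError("every sample needs a batch label for centering")
    overall = m.values.mean(axis=1)
    out = m.values.copy()
    for batch, cols in m.values.columns.to_series().groupby(batches):
        shift = m.values[cols].mean(axis=1) - overall
        out[cols] = m.values[cols].sub(shift, axis=0)
    return ExpressionMatrix(out, level=m.level, scale=m.scale)
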