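"""End-to-end pipeline: config in, report directory out.

Stages: load (or simulate) a cohort → preprocess to a gene-level log2
matrix → per-patient deregulation calls and summaries → cross-gene
compensation tables → anchor-window co-amplification profile → survival
tables → run manifest. Every output table echoes the thresholds and strata
that produced it, and the manifest (config, seed, versions, checksums)
fully determines the report: identical manifests mean identical outputs.

Raw p-values are reported throughout without multiple-testing correction;
the report header flags this.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import gammaln

from . import __version__
from .compensation import compensation_fractions, coupling_permutation_test, cross_tabulate
from .core_io import (
    ClinicalTable,
    CohortDataset,
    CohortError,
    SampleTable,
    read_clinical_table,
    read_expression,
    read_gene_annotation,
    read_probe_annotation,
    read_sample_table,
)
from .deregulation import Thresholds, deregulation_calls, summarize
from .locus_window import WindowSpec, coamplification_call, window_lfc_matrix
from .preprocess import (
    average_technical_replicates,
    center_batches,
    collapse_probes_to_genes,
    quantile_normalize,
    size_factor_normalize,
)
from .simulate import SimulationConfig, simulate_cohort
from .survival import survival_by_deregulation

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "genes": ["CCND1", "CCND2", "CCND3"],
    "anchor": "CCND1",
    "thresholds": {"upper": 2.0, "lower": 0.5},
    # None = auto: on for file inputs, off for simulated cohorts (the
    # generator emits already-normalized intensities)
    "quantile_normalize": None,
    "batch_center": False,
    "filter_threshold": 5.0,
    "window": {"flank": 1_000_000, "min_genes": 2, "lfc_cut": 1.0},
    "endpoints": ["os"],
    "survival": {"min_group_size": 3, "reference": "not"},
    "permutation": {"n_perm": 999, "seed": 0},
    "genome_build": "unspecified",
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge_defaults(user: dict) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key] = {**config[key], **value}
        else:
            config[key] = value
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_defaults(user)


def _load_dataset(config: dict) -> CohortDataset:
    if "simulate" in config:
        sim = SimulationConfig(**config["simulate"])
        return simulate_cohort(sim)
    inputs = config.get("inputs")
    if not inputs:
        raise CohortError("config needs either a 'simulate' or an 'inputs' block")
    expression = read_expression(
        inputs["expression"],
        scale=inputs.get("scale", "log2"),
        level=inputs.get("level", "probe"),
    )
    samples = read_sample_table(inputs["samples"])
    clinical = (
        read_clinical_table(inputs["clinical"]) if inputs.get("clinical") else None
    )
    probes = (
        read_probe_annotation(inputs["probes"]) if inputs.get("probes") else None
    )
    annotation = (
        read_gene_annotation(inputs["annotation"])
        if inputs.get("annotation")
        else None
    )
    return CohortDataset(
        expression=expression,
        samples=samples,
        probes=probes,
        clinical=clinical,
        annotation=annotation,
    )


def _preprocess(dataset: CohortDataset, config: dict):
    m = dataset.expression
    if m.scale == "count":
        return size_factor_normalize(m)
    qn = config.get("quantile_normalize")
    if qn is None:
        qn = "simulate" not in config
    if qn:
        m = quantile_normalize(m)
    if config.get("batch_center", False):
        batches = dataset.samples.table.set_index("sample_id")["batch"]
        m = center_batches(m, batches)
    if m.level == "probe":
        if dataset.probes is None:
            raise CohortError("probe-level matrix requires probe annotation")
        m, probes = average_technical_replicates(m, dataset.probes)
        m = collapse_probes_to_genes(m, probes)
    return m


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: Optional[int] = None,
    skip_survival: bool = False,
    plots: bool = False,
) -> Path:
    """Run every stage and write the report; returns the report directory.

    ``seed`` (if given) overrides both the simulation seed and the
    permutation-test seed, so one integer pins all randomness.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge_defaults(config)
    if seed is not None:
        if "simulate" in config:
            config["simulate"]["seed"] = int(seed)
        config["permutation"]["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "load"
        dataset = _load_dataset(config)

        stage = "preprocess"
        gene_matrix = _preprocess(dataset, config)

        stage = "deregulation"
        thresholds = Thresholds(**config["thresholds"])
        genes = [g for g in config["genes"] if g in gene_matrix.values.index]
        missing = sorted(set(config["genes"]) - set(genes))
        if missing:
            logger.warning("target genes absent from matrix: %s", missing)
        if not genes:
            raise CohortError("no target gene present in the expression matrix")
        calls = deregulation_calls(gene_matrix, dataset.samples, genes, thresholds)
        calls.to_csv(outdir / "deregulation_calls.tsv", sep="\t", index=False)
        summary = summarize(calls, dataset.samples)
        summary["upper"] = thresholds.upper
        summary["lower"] = thresholds.lower
        summary.to_csv(outdir / "deregulation_summary.tsv", sep="\t", index=False)

        stage = "compensation"
        comp_results = {}
        anchor_gene = genes[0]
        for other in genes[1:]:
            ct = cross_tabulate(
                calls[calls["gene_symbol"] == anchor_gene],
                calls[calls["gene_symbol"] == other],
            )
            ct.with_margins().to_csv(
                outdir / f"crosstab_{anchor_gene}_{other}.tsv", sep="\t"
            )
            res = coupling_permutation_test(
                calls[calls["gene_symbol"] == anchor_gene],
                calls[calls["gene_symbol"] == other],
                n_perm=int(config["permutation"]["n_perm"]),
                seed=int(config["permutation"].get("seed", 0)),
            )
            comp_results[f"{anchor_gene}_{other}"] = res.to_dict()
        with open(outdir / "compensation.json", "w") as fh:
            json.dump(comp_results, fh, indent=2, sort_keys=True)

        stage = "locus_window"
        if dataset.annotation is not None and config.get("anchor"):
            anchor = config["anchor"]
            if anchor in dataset.annotation.table["gene_symbol"].to_numpy():
                spec = WindowSpec(anchor=anchor, flank=int(config["window"]["flank"]))
                profile = window_lfc_matrix(
                    gene_matrix, dataset.samples, dataset.annotation, spec,
                    intensity_threshold=float(config["filter_threshold"]),
                )
                wg = profile.genes.copy()
                wg["genome_build"] = config.get("genome_build", "unspecified")
                wg.to_csv(outdir / "window_genes.tsv", sep="\t", index=False)
                profile.lfc.to_csv(outdir / "window_lfc.tsv", sep="\t")
                anchor_up = calls[
                    (calls["gene_symbol"] == anchor) & (calls["call"] == "up")
                ]["patient_id"].tolist()
                coamp = coamplification_call(
                    profile,
                    patients=anchor_up or None,
                    min_genes=int(config["window"]["min_genes"]),
                    lfc_cut=float(config["window"]["lfc_cut"]),
                )
                coamp["min_genes"] = config["window"]["min_genes"]
                coamp["lfc_cut"] = config["window"]["lfc_cut"]
                coamp.to_csv(outdir / "coamplification_calls.tsv", sep="\t", index=False)
            else:
                logger.warning("anchor %s missing from annotation; window skipped",
                               anchor)

        stage = "survival"
        if dataset.clinical is not None and not skip_survival:
            surv_rows, logrank_rows = [], []
            for endpoint in config["endpoints"]:
                for gene in genes:
                    for stratum in ("all", "hpv_neg", "hpv_pos"):
                        try:
                            report = survival_by_deregulation(
                                calls, dataset.clinical, dataset.samples,
                                gene=gene, stratum=stratum, endpoint=endpoint,
                                reference=config["survival"]["reference"],
                                min_group_size=int(
                                    config["survival"]["min_group_size"]
                                ),
                            )
                        except CohortError as exc:
                            logger.warning(
                                "survival skipped for %s/%s/%s: %s",
                                gene, stratum, endpoint, exc,
                            )
                            continue
                        for group, row in report.group_table.iterrows():
                            out = {
                                "endpoint": report.endpoint,
                                "gene_symbol": gene,
                                "stratum": stratum,
                                "group": group,
                                **row.to_dict(),
                                "hr": np.nan, "hr_ci_lower": np.nan,
                                "hr_ci_upper": np.nan, "hr_p": np.nan,
                                "small_group": group in report.small_groups,
                            }
                            if report.cox is not None and group == report.cox.reference:
                                out["hr"] = 1.0
                            if (
                                report.cox is not None
                                and group in report.cox.table.index
                            ):
                                c = report.cox.table.loc[group]
                                out.update(
                                    hr=c["hr"], hr_ci_lower=c["ci_lower"],
                                    hr_ci_upper=c["ci_upper"], hr_p=c["p"],
                                )
                            surv_rows.append(out)
                        if report.logrank is not None:
                            logrank_rows.append(
                                {
                                    "endpoint": report.endpoint,
                                    "gene_symbol": gene,
                                    "stratum": stratum,
                                    "statistic": report.logrank.statistic,
                                    "df": report.logrank.df,
                                    "p": report.logrank.p_value,
                                }
                            )
                        if plots:
                            _plot_km(report, outdir)
            if surv_rows:
                pd.DataFrame(surv_rows).to_csv(
                    outdir / "survival_groups.tsv", sep="\t", index=False
                )
            if logrank_rows:
                pd.DataFrame(logrank_rows).to_csv(
                    outdir / "logrank.tsv", sep="\t", index=False
                )
        elif dataset.clinical is None:
            logger.warning("no clinical table: survival stage skipped")

        stage = "associations"
        variables = config.get("clinical_variables")
        if variables and dataset.clinical is not None:
            assoc = clinical_association_tests(
                dataset.samples, dataset.clinical, variables,
                seed=int(config["permutation"].get("seed", 0)),
            )
            assoc.to_csv(outdir / "clinical_associations.tsv", sep="\t", index=False)

        stage = "manifest"
        _write_manifest(outdir, config, seed)
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        (outdir / "INCOMPLETE.txt").write_text(
            f"pipeline failed at stage {stage!r}: {exc}\n"
        )
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return outdir


def _plot_km(report, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in sorted(report.curves.items()):
        ax.step(
            np.r_[0, curve.timeline], np.r_[1.0, curve.survival.to_numpy()],
            where="post", label=f"{group} (n={curve.n})",
        )
    ax.set_xlabel("months")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{report.gene} {report.stratum} {report.endpoint}")
    ax.legend()
    fig.savefig(
        outdir / f"km_{report.gene}_{report.stratum}_{report.endpoint}.png",
        dpi=120,
    )
    plt.close(fig)


def _write_manifest(outdir: Path, config: dict, seed: Optional[int]) -> None:
    import lifelines
    import scipy

    files = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "note": "raw p-values; no multiple-testing correction applied",
        "config": config,
        "seed": seed,
        "versions": {
            "cyclinpair": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "lifelines": lifelines.__version__,
        },
        "outputs_sha256": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# clinical association tests


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an r×c table under the fixed-margins hypergeometric."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _fisher_exact_mc(
    table: np.ndarray, n_mc: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo Fisher exact p for r×c tables (probability criterion)."""
    rng = np.random.default_rng(seed)
    obs = _log_table_prob(table)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0).astype(int))
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm), 1)
        if _log_table_prob(t) <= obs + 1e-9:
            hits += 1
    return (1 + hits) / (1 + n_mc)


def clinical_association_tests(
    samples: SampleTable,
    clinical: ClinicalTable,
    variables: dict[str, str],
    seed: int = 0,
) -> pd.DataFrame:
    """Association of clinical variables with the HPV(+)/HPV(−) split.

    ``variables`` maps column names in the clinical table to ``continuous``
    (Kruskal–Wallis across HPV groups) or ``categorical`` (Fisher's exact
    test; Monte-Carlo estimate for tables larger than 2×2). Patients with
    unknown HPV status are excluded; single-level variables are skipped.
    Stars: ``***`` p < 0.001, ``*`` p < 0.05, else ``n.s.``.
    """
    hpv = samples.hpv_of_patients()
    merged = clinical.table.merge(
        hpv.rename("hpv_status"), left_on="patient_id", right_index=True
    )
    merged = merged[merged["hpv_status"].isin(["positive", "negative"])]
    rows = []
    for var, kind in variables.items():
        if var not in merged.columns:
            rows.append({"variable": var, "test": "none", "statistic": np.nan,
                         "p": np.nan, "note": "column missing"})
            continue
        sub = merged.dropna(subset=[var])
        if sub[var].nunique() < 2:
            rows.append({"variable": var, "test": "none", "statistic": np.nan,
                         "p": np.nan, "note": "single level; skipped"})
            continue
        if kind == "continuous":
            groups = [
                pd.to_numeric(g[var]).to_numpy()
                for _, g in sub.groupby("hpv_status")
            ]
            stat, p = stats.kruskal(*groups)
            test = "kruskal-wallis"
        elif kind == "categorical":
            table = pd.crosstab(sub[var], sub["hpv_status"]).to_numpy()
            if table.shape == (2, 2):
                stat, p = stats.fisher_exact(table)
                test = "fisher-exact"
            else:
                stat, p = np.nan, _fisher_exact_mc(table, seed=seed)
                test = "fisher-exact-mc"
        else:
            raise CohortError(f"unknown variable kind {kind!r} for {var!r}")
        stars = "***" if p < 0.001 else ("*" if p < 0.05 else "n.s.")
        rows.append({"variable": var, "test": test, "statistic": stat,
                     "p": p, "note": stars})
    return pd.DataFrame(rows)
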