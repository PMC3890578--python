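"""End-to-end orchestration of the QC workflow.

Order of stages: normalize -> global PCA outlier removal -> identity /
contamination checks (drop swapped or contaminated samples) -> renormalize
on the retained samples -> per-gene outlier masking -> gene filters ->
surrogate covariates -> catalog replication per covariate condition ->
condition comparison. Every sample dropped is accounted for in the run
manifest with a reason, and the whole run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import concord, exprqc
from . import eqtl as eqtl_mod
from .datatypes import CovariateSet, EqtlCatalog, ExpressionMatrix, GenotypeMatrix, RnaCallSet
from .io import FLOAT_FMT, read_catalog_tsv, read_expression_tsv, read_genotype_tsv, read_genotype_vcf, read_rna_vcf

DEFAULT_CONDITIONS = ("none", "known", "known+surrogates")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; YAML-loadable, CLI-overridable."""

    # inputs (unused when an in-memory bundle is supplied)
    genotypes_path: str | None = None
    rna_calls_path: str | None = None
    counts_path: str | None = None
    annotation_path: str | None = None
    catalog_path: str | None = None
    covariates_path: str | None = None
    # stage toggles
    pca_outliers: bool = True
    contamination_check: bool = True
    per_gene_outliers: bool = True
    # methods and thresholds
    normalization: str = "log2_depth"
    covariate_conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    sd_threshold: float = exprqc.DEFAULT_SD_THRESHOLD
    n_pcs: int = exprqc.DEFAULT_N_PCS
    n_surrogates: int = exprqc.DEFAULT_N_PCS
    dr_clean: float = concord.DR_CLEAN
    dr_highconf: float = concord.DR_HIGHCONF
    borderline_dst: float = concord.BORDERLINE_DST
    cis_window: int = eqtl_mod.DEFAULT_CIS_WINDOW
    lambda0: float = eqtl_mod.DEFAULT_LAMBDA0
    log2_sum_min: float = exprqc.DEFAULT_LOG2_SUM_MIN
    count_sum_min: float = exprqc.DEFAULT_COUNT_SUM_MIN
    n_gw_pairs: int = 5000
    seed: int = 0
    outdir: str | None = None
    record_timing: bool = True

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "covariate_conditions" in data:
            data["covariate_conditions"] = tuple(data["covariate_conditions"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_conditions"] = list(self.covariate_conditions)
        # where the outputs land is not part of what was computed; keeping
        # it out makes the manifest byte-reproducible across run locations
        d.pop("outdir")
        d.pop("record_timing")
        return d


@dataclass
class PipelineResult:
    manifest: dict
    reports: list
    comparison: pd.DataFrame | None
    concordance: concord.ConcordanceReport | None
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix
    covariates: CovariateSet
    analysis_genes: np.ndarray
    timings: dict[str, float] = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    required = {
        "genotypes_path": config.genotypes_path,
        "counts_path": config.counts_path,
        "annotation_path": config.annotation_path,
        "catalog_path": config.catalog_path,
    }
    if config.contamination_check:
        required["rna_calls_path"] = config.rna_calls_path
    missing = {k: v for k, v in required.items() if v is None or not os.path.exists(v)}
    if missing:
        raise FileNotFoundError(
            "missing pipeline inputs: " + json.dumps(sorted(missing), default=str)
        )
    gp = config.genotypes_path
    genotypes = (
        read_genotype_vcf(gp) if str(gp).endswith(".vcf") else read_genotype_tsv(gp)
    )
    expression = read_expression_tsv(config.counts_path, config.annotation_path)
    catalog = read_catalog_tsv(config.catalog_path)
    rna = read_rna_vcf(config.rna_calls_path) if config.rna_calls_path else None
    covariates = (
        pd.read_csv(config.covariates_path, sep="\t", index_col=0)
        if config.covariates_path
        else pd.DataFrame(index=pd.Index(expression.samples, name="sample"))
    )
    return genotypes, rna, expression, catalog, covariates


def known_design(covariates: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Numeric design for the known covariates (age, sex, site/cohort).

    Multi-level site/cohort columns are one-hot encoded dropping the first
    level. Case status is deliberately excluded from eQTL covariates.
    """
    cov = covariates.loc[samples]
    blocks = []
    for col in ("age", "sex"):
        if col in cov:
            blocks.append(cov[[col]].astype(float))
    for col in ("site", "cohort"):
        if col in cov:
            dummies = pd.get_dummies(cov[col], prefix=col, drop_first=True)
            if not dummies.empty:
                blocks.append(dummies.astype(float))
    if not blocks:
        return pd.DataFrame(index=cov.index)
    return pd.concat(blocks, axis=1)


def run(config: PipelineConfig, bundle=None) -> PipelineResult:
    """Execute the full QC workflow; see module docstring for stage order."""
    timings: dict[str, float] = {}

    def timed(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *a):
                timings[name] = time.perf_counter() - self_.t0

        return _T()

    if bundle is not None:
        genotypes = bundle.genotypes
        rna = bundle.rna_calls
        expression = bundle.expression
        catalog = bundle.catalog
        covariates_df = bundle.covariates
    else:
        genotypes, rna, expression, catalog, covariates_df = _load_inputs(config)

    initial_samples = list(expression.samples)
    dropped: list[dict] = []
    stages: list[dict] = []
    concordance = None

    with timed("normalize"):
        log2 = exprqc.normalize(
            expression.counts, expression.genes, config.normalization
        )
    stages.append({"name": "normalize", "method": config.normalization})

    retained = list(expression.samples)
    if config.pca_outliers:
        with timed("pca_outliers"):
            flags, var_exp, _ = exprqc.pca_sample_outliers(
                log2, config.n_pcs, config.sd_threshold
            )
        out = [s for s, f in zip(retained, flags) if f]
        for s in out:
            dropped.append({"sample": s, "reason": "pca_outlier"})
        retained = [s for s in retained if s not in set(out)]
        stages.append(
            {
                "name": "pca_outliers",
                "n_pcs": config.n_pcs,
                "sd_threshold": config.sd_threshold,
                "variance_explained": round(float(var_exp.sum()), 6),
                "dropped": sorted(out),
            }
        )

    if config.contamination_check:
        if rna is None:
            raise ValueError("contamination check enabled but no RNA calls")
        with timed("concordance"):
            # RNA samples retained so far, matched against ALL DNA samples
            # so a swap with a dropped donor is still detectable
            concordance = concord.concordance_report(
                genotypes,
                rna.subset_samples(retained),
                dr_clean=config.dr_clean,
                borderline_dst=config.borderline_dst,
            )
        swapped = [
            s for s in retained if not concordance.identity_ok.get(s, True)
        ]
        contaminated = [
            s
            for s in retained
            if s not in set(swapped)
            and concordance.flags.get(s, "clean") == "contaminated"
        ]
        for s in swapped:
            dropped.append({"sample": s, "reason": "identity_mismatch"})
        for s in contaminated:
            dropped.append({"sample": s, "reason": "contaminated"})
        retained = [s for s in retained if s not in set(swapped) | set(contaminated)]
        stages.append(
            {
                "name": "concordance",
                "dr_clean": config.dr_clean,
                "borderline_dst": config.borderline_dst,
                "dropped": sorted(swapped + contaminated),
            }
        )

    expression = expression.subset_samples(retained)
    genotypes_r = genotypes.subset_samples(retained)
    with timed("renormalize"):
        log2 = exprqc.normalize(
            expression.counts, expression.genes, config.normalization
        )
    expression.log2values = log2

    frac_genes_masked = 0.0
    if config.per_gene_outliers:
        with timed("per_gene_outliers"):
            mask, frac_genes_masked = exprqc.per_gene_outliers(
                log2, config.sd_threshold
            )
        expression.outlier_mask = mask
        stages.append(
            {
                "name": "per_gene_outliers",
                "sd_threshold": config.sd_threshold,
                "n_masked_entries": int(mask.sum()),
                "frac_genes_with_outlier": round(frac_genes_masked, 6),
            }
        )

    with timed("filter_genes"):
        analysis_genes, decomposition_genes = exprqc.filter_genes(
            log2, expression.counts, config.log2_sum_min, config.count_sum_min
        )
    stages.append(
        {
            "name": "filter_genes",
            "log2_sum_min": config.log2_sum_min,
            "count_sum_min": config.count_sum_min,
            "n_analysis_genes": int(analysis_genes.sum()),
            "n_decomposition_genes": int(decomposition_genes.sum()),
        }
    )

    with timed("surrogates"):
        surrogates = exprqc.compute_surrogates(
            log2,
            decomposition_genes,
            n_components=min(
                config.n_surrogates, len(retained) - 1, int(decomposition_genes.sum())
            ),
            mask=expression.outlier_mask,
        )
    known = known_design(covariates_df, retained)
    covset = CovariateSet(
        known=known,
        surrogates=surrogates,
        labels=list(known.columns)
        + [f"PC{i + 1}" for i in range(surrogates.shape[1])],
    )
    stages.append({"name": "surrogates", "n_components": surrogates.shape[1]})

    # restrict the analysis to filtered genes
    expr_analysis = ExpressionMatrix(
        genes=expression.genes.loc[analysis_genes].reset_index(drop=True),
        samples=expression.samples,
        counts=expression.counts[analysis_genes],
        log2values=log2[analysis_genes],
        outlier_mask=expression.outlier_mask[analysis_genes],
    )

    with timed("cis_pairs"):
        gw_pairs = eqtl_mod.cis_pairs(
            genotypes_r.snps, expr_analysis.genes, config.cis_window
        )
        if len(gw_pairs) > config.n_gw_pairs:
            rng = np.random.default_rng(config.seed)
            gw_pairs = gw_pairs.iloc[
                np.sort(rng.choice(len(gw_pairs), config.n_gw_pairs, replace=False))
            ].reset_index(drop=True)

    reports = []
    for condition in config.covariate_conditions:
        with timed(f"replication[{condition}]"):
            design = covset.design(condition)
            reports.append(
                eqtl_mod.replication_report(
                    catalog,
                    genotypes_r,
                    expr_analysis,
                    design if design.shape[1] else None,
                    gw_pairs,
                    condition_label=condition,
                    lambda0=config.lambda0,
                )
            )
    comparison = (
        eqtl_mod.compare_conditions(reports) if len(reports) >= 2 else None
    )
    stages.append(
        {
            "name": "replication",
            "cis_window": config.cis_window,
            "lambda0": config.lambda0,
            "n_genome_wide_pairs": int(len(gw_pairs)),
            "conditions": [r.summary() for r in reports],
        }
    )

    manifest = {
        "config": config.to_dict(),
        "samples": {
            "initial": len(initial_samples),
            "retained": len(retained),
            "dropped": sorted(dropped, key=lambda d: d["sample"]),
        },
        "stages": stages,
    }
    assert manifest["samples"]["initial"] == manifest["samples"]["retained"] + len(
        manifest["samples"]["dropped"]
    )

    result = PipelineResult(
        manifest=manifest,
        reports=reports,
        comparison=comparison,
        concordance=concordance,
        expression=expr_analysis,
        genotypes=genotypes_r,
        covariates=covset,
        analysis_genes=analysis_genes,
        timings=timings,
    )
    if config.outdir:
        write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    """Write manifest, per-condition reports and the comparison table.

    The manifest JSON is byte-deterministic; wall-clock timings go to a
    separate sidecar so reruns reproduce the manifest exactly.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if config.record_timing:
        with open(os.path.join(outdir, "timings.json"), "w") as fh:
            json.dump(
                {k: round(v, 4) for k, v in result.timings.items()}, fh, indent=2
            )
            fh.write("\n")
    for rep in result.reports:
        rep.per_pair.to_csv(
            os.path.join(outdir, f"replication_{rep.condition_label}.tsv"),
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
    if result.comparison is not None:
        result.comparison.to_csv(
            os.path.join(outdir, "comparison.tsv"),
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
    if result.concordance is not None:
        result.concordance.to_frame().to_csv(
            os.path.join(outdir, "concordance.tsv"),
            sep="\t",
            float_format=FLOAT_FMT,
        )


def run_sweep(
    base: PipelineConfig, conditions: pd.DataFrame, bundle=None
) -> tuple[pd.DataFrame, list[PipelineResult]]:
    """Run the pipeline once per condition row and tabulate the metrics.

    ``conditions`` has a ``condition`` label column plus any PipelineConfig
    field to override (e.g. normalization, pca_outliers, per_gene_outliers,
    covariate_conditions).
    """
    if conditions["condition"].duplicated().any():
        raise ValueError("duplicate condition labels in sweep")
    rows = []
    results = []
    for _, row in conditions.iterrows():
        overrides = {
            k: v for k, v in row.items() if k != "condition" and pd.notna(v)
        }
        if "covariate_conditions" in overrides and isinstance(
            overrides["covariate_conditions"], str
        ):
            overrides["covariate_conditions"] = tuple(
                overrides["covariate_conditions"].split(",")
            )
        cfg = dataclasses.replace(base, outdir=None, **overrides)
        res = run(cfg, bundle=bundle)
        results.append(res)
        for rep in res.reports:
            s = rep.summary()
            s["condition"] = f"{row['condition']}/{rep.condition_label}"
            rows.append(s)
    return pd.DataFrame(rows), results


def differential_expression(
    log2values: np.ndarray,
    mask: np.ndarray | None,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene OLS of expression on case status plus covariates.

    Masked entries are excluded per gene. Returns beta/se/t/p per gene;
    zero-variance or undersized genes are reported untested. Status exactly
    confounded with a covariate raises :class:`eqtl.CollinearityError`
    naming the column.
    """
    status = np.asarray(status, dtype=float)
    if len(np.unique(status)) < 2:
        raise ValueError("need at least two status groups")
    if covariates is not None and covariates.shape[1]:
        base = np.column_stack([np.ones(status.size), covariates])
        full = np.column_stack([base, status])
        if np.linalg.matrix_rank(full) <= np.linalg.matrix_rank(base):
            # find the offending covariate column
            for j in range(covariates.shape[1]):
                sub = np.column_stack(
                    [np.ones(status.size), covariates[:, j], status]
                )
                if np.linalg.matrix_rank(sub) < 3:
                    raise eqtl_mod.CollinearityError(
                        f"status confounded with covariate column {j}"
                    )
            raise eqtl_mod.CollinearityError(
                "status confounded with the covariate set"
            )
    X = np.asarray(log2values, dtype=float)
    rows = []
    for gi in range(X.shape[0]):
        res = eqtl_mod.eqtl_regression(
            X[gi],
            status.astype(int),
            covariates,
            None if mask is None else mask[gi],
        )
        rows.append(
            (gi, res.n, res.beta, res.se, res.t, res.p_raw, res.tested, res.reason)
        )
    return pd.DataFrame(
        rows, columns=["gene", "n", "beta", "se", "t", "p", "tested", "reason"]
    )


def stability_check(
    de_before: pd.DataFrame, de_after: pd.DataFrame, k: int
) -> float:
    """Overlap fraction of the top-k differentially expressed genes.

    Genes are ranked by p among those tested in both runs; returns
    |top-k(before) ∩ top-k(after)| / k.
    """
    both = set(de_before.loc[de_before["tested"], "gene"]) & set(
        de_after.loc[de_after["tested"], "gene"]
    )
    b = de_before[de_before["gene"].isin(both)].nsmallest(k, "p")
    a = de_after[de_after["gene"].isin(both)].nsmallest(k, "p")
    if len(b) < k or len(a) < k:
        raise ValueError("k exceeds the genes tested in both runs")
    return len(set(b["gene"]) & set(a["gene"])) / k
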