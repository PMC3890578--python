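"""cis-eQTL testing and replication scoring.

The replication machinery is the scoring loop of the whole QC framework:
a catalog of known SNP:gene pairs is re-tested in the data at hand, the
resulting p-values are adjusted for genome-wide inflation (genomic control),
and three summary metrics — the fraction replicating at adjusted p < 0.05,
the fraction at Storey q < 0.05, and pi1 = 1 - pi0 — profile how well a
given data-handling choice preserves known biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MISSING,
    EqtlCatalog,
    ExpressionMatrix,
    GenotypeMatrix,
    ReplicationReport,
)

#: cis window: a SNP within this many bp of either gene end (or inside the
#: gene body) is tested against that gene. Boundary inclusive.
DEFAULT_CIS_WINDOW = 1_000_000

#: median of the 1-df chi-square distribution, the null reference for the
#: genomic inflation factor.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

DEFAULT_LAMBDA0 = 0.50


class CollinearityError(ValueError):
    """Covariate design is rank deficient."""


def cis_distance(pos: int, start: int, end: int) -> int:
    """Distance from a SNP to the nearer gene end; 0 inside the gene body."""
    if start <= pos <= end:
        return 0
    return min(abs(pos - start), abs(pos - end))


def cis_pairs(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> pd.DataFrame:
    """Enumerate SNP:gene pairs within the cis window.

    ``snps`` needs columns snp_id/chrom/pos; ``genes`` needs
    gene_id/chrom/start/end. Strand is ignored: both gene ends are used
    symmetrically. The window boundary is inclusive.

    Returns a DataFrame with snp_id, gene_id, distance.
    """
    out = []
    for chrom, gsub in genes.groupby("chrom", sort=True):
        ssub = snps.loc[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        pos = ssub["pos"].to_numpy()
        start = gsub["start"].to_numpy()[:, None]
        end = gsub["end"].to_numpy()[:, None]
        dist = np.maximum(
            np.maximum(start - pos[None, :], pos[None, :] - end), 0
        )
        gi, si = np.nonzero(dist <= window)
        out.append(
            pd.DataFrame(
                {
                    "snp_id": ssub["snp_id"].to_numpy()[si],
                    "gene_id": gsub["gene_id"].to_numpy()[gi],
                    "distance": dist[gi, si],
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["snp_id", "gene_id", "distance"])
    return pd.concat(out, ignore_index=True)


@dataclass
class EqtlResult:
    beta: float
    se: float
    t: float
    p_raw: float
    n: int
    tested: bool = True
    reason: str = ""

    @classmethod
    def untested(cls, reason: str, n: int = 0) -> "EqtlResult":
        return cls(np.nan, np.nan, np.nan, np.nan, n, tested=False, reason=reason)


def _check_covariate_rank(covariates: np.ndarray) -> None:
    X = np.column_stack([np.ones(covariates.shape[0]), covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(covariates.shape[1]):
            sub = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(j)
        raise CollinearityError(
            f"rank-deficient covariates; collinear columns: {collinear}"
        )


def eqtl_regression(
    expression: np.ndarray,
    genotype: np.ndarray,
    covariates: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> EqtlResult:
    """OLS of expression on minor-allele dosage plus covariates.

    Masked entries (``mask`` True) and missing genotypes are dropped
    pairwise. The genotype t statistic is referred to a t distribution with
    n - (#covariates) - 2 degrees of freedom (intercept + dosage term).

    A constant genotype after filtering yields an *untested* result, distinct
    from p = 1; rank-deficient covariates raise :class:`CollinearityError`.
    """
    y = np.asarray(expression, dtype=float)
    g = np.asarray(genotype, dtype=float)
    keep = ~np.isnan(y)
    keep &= np.asarray(genotype) != MISSING
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    ncov = 0 if covariates is None else covariates.shape[1]
    y, g = y[keep], g[keep]
    C = None if covariates is None else np.asarray(covariates, float)[keep]
    n = y.size
    if n < ncov + 3:
        return EqtlResult.untested("insufficient samples", n)
    if np.all(g == g[0]):
        return EqtlResult.untested("constant genotype", n)
    if np.all(y == y[0]):
        return EqtlResult.untested("zero-variance expression", n)
    if C is not None and ncov:
        _check_covariate_rank(C)
        X = np.column_stack([np.ones(n), g, C])
    else:
        X = np.column_stack([np.ones(n), g])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return EqtlResult.untested("rank-deficient design", n)
    resid = y - X @ beta
    df = n - ncov - 2
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    b = float(beta[1])
    if se == 0.0:
        if b == 0.0:
            # response constant given the design: nothing to test
            return EqtlResult.untested("zero-variance expression", n)
        # perfect fit: infinite t, p -> 0
        return EqtlResult(b, 0.0, np.inf, 0.0, n)
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return EqtlResult(b, se, t, p, n)


def scan_pairs(
    pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: np.ndarray | None = None,
    use_mask: bool = True,
) -> pd.DataFrame:
    """Run :func:`eqtl_regression` for each SNP:gene pair.

    ``expression.log2values`` must be populated (run normalization first).
    Returns per-pair beta/se/t/p_raw/n/tested.
    """
    if expression.log2values is None:
        raise ValueError("expression matrix has no normalized log2 values")
    snp_idx = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    gene_idx = {g: i for i, g in enumerate(expression.genes["gene_id"])}
    if genotypes.samples != expression.samples:
        raise ValueError("genotype and expression sample order differ")
    log2 = expression.log2values
    mask = expression.outlier_mask if use_mask else None
    rows = []
    for snp_id, gene_id in zip(pairs["snp_id"], pairs["gene_id"]):
        si = snp_idx.get(snp_id)
        gi = gene_idx.get(gene_id)
        if si is None or gi is None:
            raise KeyError(f"unresolvable pair ({snp_id}, {gene_id})")
        res = eqtl_regression(
            log2[gi],
            genotypes.calls[:, si],
            covariates,
            None if mask is None else mask[gi],
        )
        rows.append(
            (snp_id, gene_id, res.n, res.beta, res.se, res.t, res.p_raw,
             res.tested, res.reason)
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "gene_id", "n", "beta", "se", "t", "p_raw",
                 "tested", "reason"],
    )


def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor from a set of association p-values.

    Each p is mapped to its 1-df chi-square quantile; lambda is the median
    chi-square divided by the null median (~0.4549). Intended for the
    genome-wide cis scan, not the catalog.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.size < 100:
        warnings.warn(
            f"lambda estimated from only {p.size} p-values; unstable",
            stacklevel=2,
        )
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def gc_adjust(p_raw: np.ndarray, lambda_gw: float) -> np.ndarray:
    """Genomic-control adjustment of p-values.

    Chi-square quantiles are divided by max(lambda, 1) and mapped back
    through the 1-df survival function; lambda < 1 is never used to deflate.
    """
    if lambda_gw <= 0:
        raise ValueError("lambda must be positive")
    p = np.atleast_1d(np.asarray(p_raw, dtype=float))
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    lam = max(lambda_gw, 1.0)
    if lam == 1.0:
        return p.copy()
    chi = stats.chi2.isf(p, 1) / lam
    return stats.chi2.sf(chi, 1)


def storey_pi0(p_values: np.ndarray, lambda0: float = DEFAULT_LAMBDA0) -> float:
    """Storey's pi0 at a fixed tuning parameter lambda0."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("no p-values")
    pi0 = (p > lambda0).sum() / (m * (1.0 - lambda0))
    return float(min(max(pi0, 0.0), 1.0))


def storey_q(
    p_values: np.ndarray, lambda0: float = DEFAULT_LAMBDA0
) -> tuple[np.ndarray, float]:
    """Storey q-values with pi0 estimated at fixed lambda0.

    q for the largest p is pi0*p; descending through the order statistics,
    q_i = min(pi0 * p_i * m / i, q_{i+1}). Output is monotone in p and
    invariant to input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    pi0 = storey_pi0(p, lambda0)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = np.empty(m)
    prev = min(pi0 * ps[-1], 1.0)
    q_sorted[-1] = prev
    for i in range(m - 2, -1, -1):
        prev = min(pi0 * ps[i] * m / (i + 1), prev)
        q_sorted[i] = prev
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, pi0


def pi1(p_values: np.ndarray, lambda0: float = DEFAULT_LAMBDA0) -> float:
    """Estimated proportion of replicating tests, 1 - pi0."""
    return 1.0 - storey_pi0(p_values, lambda0)


def replication_report(
    catalog: EqtlCatalog,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: np.ndarray | None,
    genome_wide_pairs: pd.DataFrame,
    condition_label: str,
    lambda0: float = DEFAULT_LAMBDA0,
    use_mask: bool = True,
) -> ReplicationReport:
    """Score one data-handling condition by catalog replication.

    The genome-wide cis scan supplies the inflation factor; catalog p-values
    are genomic-control adjusted with it, then summarized as pct_p05,
    pct_q05 (Storey q at fixed lambda0) and pi1. Untested pairs (constant
    genotype, insufficient samples) are excluded from all three denominators
    and counted separately.
    """
    resolved = catalog.resolve(
        set(genotypes.snps["snp_id"]), set(expression.genes["gene_id"])
    )
    if len(resolved) == 0:
        raise ValueError("catalog empty after resolving against inputs")
    gw = scan_pairs(genome_wide_pairs, genotypes, expression, covariates,
                    use_mask=use_mask)
    gw_p = gw.loc[gw["tested"], "p_raw"].to_numpy()
    lam = genomic_lambda(gw_p)
    per_pair = scan_pairs(resolved.pairs, genotypes, expression, covariates,
                          use_mask=use_mask)
    tested = per_pair["tested"].to_numpy()
    p_adj = np.full(len(per_pair), np.nan)
    q = np.full(len(per_pair), np.nan)
    p_t = per_pair.loc[tested, "p_raw"].to_numpy()
    n_tested = int(tested.sum())
    if n_tested == 0:
        raise ValueError("no catalog pair could be tested")
    adj = gc_adjust(np.clip(p_t, np.finfo(float).tiny, 1.0), lam)
    q_t, pi0 = storey_q(adj, lambda0)
    p_adj[tested] = adj
    q[tested] = q_t
    per_pair = per_pair.assign(p_adjusted=p_adj, q=q)
    return ReplicationReport(
        condition_label=condition_label,
        per_pair=per_pair,
        lambda_gw=lam,
        pct_p05=float((adj < 0.05).mean()),
        pct_q05=float((q_t < 0.05).mean()),
        pi1=1.0 - pi0,
        n_tested=n_tested,
        n_untested=int((~tested).sum()) + resolved.n_dropped,
    )


def compare_conditions(
    reports: list[ReplicationReport],
    metrics: tuple[str, ...] = ("pct_p05", "pct_q05", "pi1"),
) -> pd.DataFrame:
    """Tabulate the replication metrics across conditions.

    One row per condition; a ``best_<metric>`` marker column flags the
    condition maximizing each requested metric. No between-condition test is
    performed — raw differences are the comparison.
    """
    if len(reports) < 2:
        raise ValueError("need at least two conditions to compare")
    labels = [r.condition_label for r in reports]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    rows = pd.DataFrame([r.summary() for r in reports])
    cols = ["condition", "lambda_gw"] + [m for m in metrics] + [
        "n_tested", "n_untested"
    ]
    rows = rows[[c for c in cols if c in rows.columns]]
    for m in metrics:
        best = rows[m].to_numpy().argmax()
        rows[f"best_{m}"] = [i == best for i in range(len(rows))]
    return rows
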