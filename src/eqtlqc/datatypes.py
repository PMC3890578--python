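"""Core in-memory containers shared across the QC pipeline.

Conventions
-----------
* Genotypes are coded as minor-allele dosage 0/1/2, with ``-1`` for missing.
* Genomic coordinates are 1-based inclusive.
* Matrices are dense numpy arrays; sample and feature identifiers live in
  plain lists / pandas objects alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: minimum read depth for an RNA genotype call to be retained; calls are kept
#: only when strictly more than this many reads cover the site.
DEPTH_MIN = 20

#: default heterozygote-calling rule parameters for RNA allele evidence
HET_MIN_READS = 2
HET_MIN_FRAC = 0.15


@dataclass
class GenotypeMatrix:
    """DNA genotype calls: the "truth" side of identity/contamination checks.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``calls``).
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``. Row order matches columns of ``calls``.
    calls : ndarray of int8, shape (n_samples, n_snps)
        Minor-allele dosage in {0, 1, 2}, or -1 for missing.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency over non-missing calls (folded)."""
        obs = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            f = np.where(
                obs.sum(axis=0) > 0,
                np.where(self.calls == MISSING, 0, self.calls).sum(axis=0)
                / (2.0 * np.maximum(obs.sum(axis=0), 1)),
                np.nan,
            )
        return np.minimum(f, 1.0 - f)

    @property
    def missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def filter_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
        )

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            samples=list(samples), snps=self.snps, calls=self.calls[idx]
        )


def call_from_allele_depths(
    ref_depth: np.ndarray,
    alt_depth: np.ndarray,
    min_depth: int = DEPTH_MIN,
    het_min_reads: int = HET_MIN_READS,
    het_min_frac: float = HET_MIN_FRAC,
) -> np.ndarray:
    """Genotype-call RNA allele evidence with a depth-aware het rule.

    A site is called heterozygous iff each allele has at least
    ``het_min_reads`` supporting reads *and* the minor allele carries at least
    ``het_min_frac`` of the reads; otherwise the majority allele's homozygote
    is called (ties go to the reference allele). Sites with total depth not
    exceeding ``min_depth`` are withheld (-1).
    """
    ref = np.asarray(ref_depth, dtype=np.int64)
    alt = np.asarray(alt_depth, dtype=np.int64)
    depth = ref + alt
    minor = np.minimum(ref, alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        minor_frac = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
    het = (minor >= het_min_reads) & (minor_frac >= het_min_frac)
    calls = np.where(het, 1, np.where(alt > ref, 2, 0)).astype(np.int8)
    calls[depth <= min_depth] = MISSING
    return calls


@dataclass
class RnaCallSet:
    """RNA-derived genotype evidence: allele depths plus derived calls.

    Calls are recomputed from allele depths on access, so operations that act
    on read evidence (e.g. in-silico mixing) automatically propagate to the
    called genotypes. Sites with depth <= ``min_depth`` reads are withheld.
    """

    samples: list[str]
    snp_ids: list[str]
    ref_depth: np.ndarray  # (n_samples, n_snps)
    alt_depth: np.ndarray
    min_depth: int = DEPTH_MIN
    het_min_reads: int = HET_MIN_READS
    het_min_frac: float = HET_MIN_FRAC

    def __post_init__(self) -> None:
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        shape = (len(self.samples), len(self.snp_ids))
        if self.ref_depth.shape != shape or self.alt_depth.shape != shape:
            raise ValueError("allele-depth matrices must be samples x snps")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("allele depths must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    @property
    def calls(self) -> np.ndarray:
        """Dosage calls (0/1/2, -1 withheld) under the het rule."""
        return call_from_allele_depths(
            self.ref_depth,
            self.alt_depth,
            self.min_depth,
            self.het_min_reads,
            self.het_min_frac,
        )

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    def subset_samples(self, samples: list[str]) -> "RnaCallSet":
        idx = [self.sample_index(s) for s in samples]
        return RnaCallSet(
            samples=list(samples),
            snp_ids=list(self.snp_ids),
            ref_depth=self.ref_depth[idx],
            alt_depth=self.alt_depth[idx],
            min_depth=self.min_depth,
            het_min_reads=self.het_min_reads,
            het_min_frac=self.het_min_frac,
        )


@dataclass
class ExpressionMatrix:
    """Gene expression counts plus normalized values and an outlier mask.

    ``genes`` carries the annotation needed downstream: chrom, start, end
    (1-based inclusive), strand, length, gc fraction. ``outlier_mask`` marks
    entries excluded from all downstream statistics (True = excluded).
    """

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, length, gc
    samples: list[str]
    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    log2values: np.ndarray | None = None
    outlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts must be genes x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.counts.shape, dtype=bool)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.outlier_mask.shape != self.counts.shape:
            raise ValueError("outlier_mask must match counts shape")
        if self.log2values is not None:
            self.log2values = np.asarray(self.log2values, dtype=float)
            if self.log2values.shape != self.counts.shape:
                raise ValueError("log2values must match counts shape")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def gene_index(self, gene_id: str) -> int:
        return int(self.genes.index[self.genes["gene_id"] == gene_id][0])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in samples]
        return ExpressionMatrix(
            genes=self.genes,
            samples=list(samples),
            counts=self.counts[:, idx],
            log2values=None
            if self.log2values is None
            else self.log2values[:, idx],
            outlier_mask=self.outlier_mask[:, idx],
        )


@dataclass
class CovariateSet:
    """Sample covariates: known (age, sex, site, status) plus surrogates.

    ``known`` rows follow the expression sample order; ``surrogates`` holds
    data-derived components (PC scores). ``labels`` records provenance per
    column of the assembled design.
    """

    known: pd.DataFrame
    surrogates: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def design(self, include: str = "known") -> np.ndarray:
        """Assemble a numeric covariate design matrix (no intercept).

        ``include`` is one of ``none``, ``known``, ``surrogates``,
        ``known+surrogates``.
        """
        n = len(self.known)
        blocks: list[np.ndarray] = []
        if include not in {"none", "known", "surrogates", "known+surrogates"}:
            raise ValueError(f"unknown covariate condition {include!r}")
        if "known" in include.split("+"):
            blocks.append(self.known.to_numpy(dtype=float))
        if "surrogates" in include.split("+"):
            if self.surrogates is None:
                raise ValueError("surrogates requested but none computed")
            if self.surrogates.size:
                blocks.append(np.asarray(self.surrogates, dtype=float))
        if not blocks:
            return np.empty((n, 0))
        out = np.column_stack(blocks)
        if np.isnan(out).any():
            raise ValueError("covariates contain missing values")
        return out


@dataclass
class EqtlCatalog:
    """Gold-standard SNP:gene pairs whose replication scores data handling."""

    pairs: pd.DataFrame  # snp_id, gene_id, optional source
    n_dropped: int = 0

    def __post_init__(self) -> None:
        dup = self.pairs.duplicated(subset=["snp_id", "gene_id"])
        if dup.any():
            self.pairs = self.pairs.loc[~dup].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def resolve(
        self, snp_ids: set[str], gene_ids: set[str]
    ) -> "EqtlCatalog":
        """Drop pairs whose SNP or gene is absent, recording the count."""
        ok = self.pairs["snp_id"].isin(snp_ids) & self.pairs["gene_id"].isin(
            gene_ids
        )
        return EqtlCatalog(
            pairs=self.pairs.loc[ok].reset_index(drop=True),
            n_dropped=int((~ok).sum()),
        )


@dataclass
class ReplicationReport:
    """Per-pair cis-eQTL statistics plus the three replication metrics.

    Summary metrics (fractions in [0,1]):

    * ``pct_p05`` — fraction of tested catalog pairs with inflation-adjusted
      p < 0.05;
    * ``pct_q05`` — fraction with Storey q < 0.05;
    * ``pi1``     — 1 - pi0, the estimated proportion of replicating pairs.

    ``lambda_gw`` is the genomic inflation factor estimated from the
    genome-wide cis scan (raw, unclamped).
    """

    condition_label: str
    per_pair: pd.DataFrame  # snp_id, gene_id, n, beta, se, t, p_raw, p_adjusted, q, tested
    lambda_gw: float
    pct_p05: float
    pct_q05: float
    pi1: float
    n_tested: int
    n_untested: int

    def summary(self) -> dict:
        return {
            "condition": self.condition_label,
            "lambda_gw": self.lambda_gw,
            "pct_p05": self.pct_p05,
            "pct_q05": self.pct_q05,
            "pi1": self.pi1,
            "n_tested": self.n_tested,
            "n_untested": self.n_untested,
        }
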