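"""Synthetic genotype + RNA-seq data with full truth records.

Every downstream stage (identity checks, contamination detection, outlier
rules, eQTL replication scoring) is exercised against data generated here,
so the generator plants the structures those stages are meant to find:

* Hardy-Weinberg genotypes on synthetic chromosomes, dense enough that cis
  windows around genes always contain SNPs;
* additive cis-eQTL effects on log2 expression for a configurable subset of
  catalog pairs (the rest of the catalog is null);
* batch ("site") effects, GC/length bias with per-sample slopes, library
  size variation, Poisson counting noise;
* cross-sample contamination (a fraction of a sample's RNA evidence and
  expression comes from a donor; fraction 1.0 expresses a sample swap);
* global expression-outlier samples and isolated per-gene outlier entries.

All draws are deterministic given the config seed. Each operation consumes
its own stream derived from (seed, operation-key), so outputs do not depend
on the order in which operations are invoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    EqtlCatalog,
    ExpressionMatrix,
    GenotypeMatrix,
    RnaCallSet,
)
from .eqtl import DEFAULT_CIS_WINDOW, cis_distance

_CHROMS = (("chr1", 40_000_000), ("chr2", 40_000_000))

# fixed sub-stream keys: (seed, key) seeds an independent Generator per op
_STREAM_GENOTYPES = 1
_STREAM_EXPRESSION = 2
_STREAM_RNA = 3
_STREAM_COVARIATES = 4
_STREAM_POWER = 5

# GC/length bias of the count model: mean and between-sample SD of the
# per-sample log2-per-unit-GC slope, and of the log2-per-log10(length) slope.
_GC_SLOPE_MEAN, _GC_SLOPE_SD = 2.0, 0.5
_LEN_SLOPE_MEAN, _LEN_SLOPE_SD = -0.5, 0.2
_BASELINE_MEAN, _BASELINE_SD = 7.0, 1.0

# planted catalog SNPs are kept inside this window so the default 1 Mb cis
# scan can always rediscover them (strictly inside the boundary)
_PLANT_WINDOW = 800_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate a desk-scale cohort: 60 samples, 3,000 array SNPs,
    1,500 genes, a 900-pair catalog of which 30% carry a real effect, two
    collection sites, and RNA genotyping depth ~50x.
    """

    n_samples: int = 60
    n_snps: int = 3000
    n_genes: int = 1500
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_true_eqtls: int = 270
    eqtl_effect_sd: float = 0.25  # log2 units per minor allele (fixed magnitude)
    n_null_catalog: int = 630
    batch_levels: int = 2
    batch_effect_sd: float = 0.3  # log2 units
    noise_sd: float = 0.25  # log2 units
    library_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    contaminated_samples: tuple[tuple[str, str, float], ...] = ()
    global_outlier_samples: tuple[tuple[str, float], ...] = ()
    per_gene_outlier_rate: float = 0.001
    per_gene_outlier_shift: float = 8.0  # in per-gene SD units
    rna_depth_mean: float = 50.0
    rna_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_snps", "n_genes", "batch_levels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_eqtls < 0 or self.n_null_catalog < 0:
            raise ValueError("catalog sizes must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.per_gene_outlier_rate <= 1):
            raise ValueError("per_gene_outlier_rate must be in [0,1]")
        if not (0 <= self.rna_error_rate <= 1):
            raise ValueError("rna_error_rate must be in [0,1]")
        if self.library_size_range[0] <= 0 or (
            self.library_size_range[0] > self.library_size_range[1]
        ):
            raise ValueError("library_size_range must be positive, ordered")
        for s, d, f in self.contaminated_samples:
            if s == d:
                raise ValueError(f"contamination donor equals recipient {s}")
            if not (0 <= f <= 1):
                raise ValueError("contamination fraction must be in [0,1]")
        if self.n_true_eqtls + self.n_null_catalog > self.n_genes:
            raise ValueError("catalog larger than the gene set")

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(key)))

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(1, self.n_samples + 1)]

    @property
    def contamination_map(self) -> dict[str, tuple[str, float]]:
        return {s: (d, f) for s, d, f in self.contaminated_samples}


@dataclass
class Truth:
    """Ground-truth record of everything the generator planted."""

    true_eqtls: list[tuple[str, str, float]]  # snp_id, gene_id, effect
    contaminated: dict[str, tuple[str, float]]
    global_outliers: set[str]
    per_gene_outliers: set[tuple[str, str]]  # gene_id, sample
    catalog: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SimBundle:
    """Everything one synthetic study comprises."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    truth: Truth
    catalog: EqtlCatalog
    covariates: pd.DataFrame
    rna_calls: RnaCallSet


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotypes at SNPs on synthetic chromosomes.

    Per SNP the minor-allele frequency is uniform on ``maf_range`` and calls
    are Binomial(2, maf). Positions are uniform over two 40 Mb chromosomes,
    dense enough that every gene has cis SNPs while plenty of SNPs fall
    beyond any given 1 Mb window.
    """
    rng = config.rng(_STREAM_GENOTYPES)
    total = sum(length for _, length in _CHROMS)
    raw = np.sort(rng.choice(total, size=config.n_snps, replace=False))
    chroms = np.empty(config.n_snps, dtype=object)
    pos = np.empty(config.n_snps, dtype=np.int64)
    offset = 0
    for name, length in _CHROMS:
        sel = (raw >= offset) & (raw < offset + length)
        chroms[sel] = name
        pos[sel] = raw[sel] - offset + 1  # 1-based
        offset += length
    maf = rng.uniform(*config.maf_range, size=config.n_snps)
    calls = rng.binomial(2, maf, size=(config.n_samples, config.n_snps))
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i:06d}" for i in range(1, config.n_snps + 1)],
            "chrom": chroms,
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        samples=config.sample_ids, snps=snps, calls=calls.astype(np.int8)
    )


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Sample covariate table: age, sex, site (= batch) and case status."""
    rng = config.rng(_STREAM_COVARIATES)
    n = config.n_samples
    return pd.DataFrame(
        {
            "age": np.round(np.clip(rng.normal(45, 15, n), 18, 90)),
            "sex": rng.integers(0, 2, n),
            "site": rng.integers(0, config.batch_levels, n),
            "status": (rng.random(n) < 0.4).astype(int),
        },
        index=pd.Index(config.sample_ids, name="sample"),
    )


def _simulate_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = np.round(10 ** rng.uniform(3, 5, config.n_genes)).astype(int)
    starts = np.empty(config.n_genes, dtype=np.int64)
    chroms = np.empty(config.n_genes, dtype=object)
    n_chrom = len(_CHROMS)
    assign = rng.integers(0, n_chrom, config.n_genes)
    for ci, (name, length) in enumerate(_CHROMS):
        sel = assign == ci
        starts[sel] = rng.integers(1, length - lengths[sel] - 1)
        chroms[sel] = name
    order = np.lexsort((starts, np.asarray([c for c in assign])))
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(1, config.n_genes + 1)],
            "chrom": chroms[order],
            "start": starts[order],
            "end": starts[order] + lengths[order] - 1,
            "strand": np.where(rng.random(config.n_genes) < 0.5, "+", "-"),
            "length": lengths[order],
            "gc": rng.uniform(0.30, 0.70, config.n_genes),
        }
    )
    return genes


def _plant_catalog(
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pick catalog SNP:gene pairs, all within the default cis window."""
    n_pairs = config.n_true_eqtls + config.n_null_catalog
    if n_pairs == 0:
        return pd.DataFrame(columns=["snp_id", "gene_id", "effect", "source"])
    gene_order = rng.permutation(len(genes))
    chosen: list[tuple[str, str]] = []
    snp_by_chrom = {
        c: sub.reset_index(drop=True) for c, sub in snps.groupby("chrom")
    }
    for gi in gene_order:
        if len(chosen) == n_pairs:
            break
        grow = genes.iloc[gi]
        sub = snp_by_chrom.get(grow["chrom"])
        if sub is None:
            continue
        d = np.maximum(
            np.maximum(grow["start"] - sub["pos"], sub["pos"] - grow["end"]), 0
        )
        cand = np.nonzero(d.to_numpy() <= _PLANT_WINDOW)[0]
        if cand.size == 0:
            continue
        pick = cand[rng.integers(0, cand.size)]
        chosen.append((sub["snp_id"].iloc[pick], grow["gene_id"]))
    if len(chosen) < n_pairs:
        raise ValueError(
            "could not place the requested catalog (too few cis SNPs)"
        )
    effects = np.zeros(n_pairs)
    signs = np.where(rng.random(config.n_true_eqtls) < 0.5, -1.0, 1.0)
    effects[: config.n_true_eqtls] = signs * config.eqtl_effect_sd
    cat = pd.DataFrame(
        {
            "snp_id": [c[0] for c in chosen],
            "gene_id": [c[1] for c in chosen],
            "effect": effects,
            "source": ["planted"] * config.n_true_eqtls
            + ["null"] * config.n_null_catalog,
        }
    )
    return cat


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, Truth]:
    """Generate counts with planted cis effects, bias, batch and outliers.

    Per gene the latent log2 expression is
    ``baseline + effect*dosage + batch + gc/length bias + N(0, noise_sd)``;
    counts are Poisson around library-size-scaled exponentiated latent
    values. Contaminated samples draw their counts from the mixture
    ``(1-f)*recipient + f*donor`` of expression profiles. Outlier shifts are
    expressed in units of the gene's cross-sample latent SD, recorded in the
    returned :class:`Truth`.
    """
    if genotypes.n_samples != config.n_samples:
        raise ValueError("genotype matrix does not match config sample count")
    rng = config.rng(_STREAM_EXPRESSION)
    genes = _simulate_genes(config, rng)
    catalog = _plant_catalog(genes, genotypes.snps, config, rng)
    covariates = simulate_covariates(config)
    n_g, n_s = config.n_genes, config.n_samples

    # verify planted pairs are discoverable by the default cis scan
    snp_pos = genotypes.snps.set_index("snp_id")[["chrom", "pos"]]
    gene_pos = genes.set_index("gene_id")[["chrom", "start", "end"]]
    for _, row in catalog.iterrows():
        if row["effect"] == 0.0:
            continue
        sp = snp_pos.loc[row["snp_id"]]
        gp = gene_pos.loc[row["gene_id"]]
        if sp["chrom"] != gp["chrom"] or cis_distance(
            int(sp["pos"]), int(gp["start"]), int(gp["end"])
        ) > DEFAULT_CIS_WINDOW:
            raise ValueError(
                f"planted effect {row['snp_id']}:{row['gene_id']} lies "
                "outside the cis window"
            )

    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, n_g)
    latent = np.tile(baseline[:, None], (1, n_s))

    batch = covariates["site"].to_numpy()
    batch_fx = rng.normal(0.0, config.batch_effect_sd, (n_g, config.batch_levels))
    latent += batch_fx[:, batch]

    gc_slope = rng.normal(_GC_SLOPE_MEAN, _GC_SLOPE_SD, n_s)
    len_slope = rng.normal(_LEN_SLOPE_MEAN, _LEN_SLOPE_SD, n_s)
    gc_dev = genes["gc"].to_numpy() - 0.5
    len_dev = np.log10(genes["length"].to_numpy()) - 4.0
    latent += gc_dev[:, None] * gc_slope[None, :]
    latent += len_dev[:, None] * len_slope[None, :]

    gene_row = {g: i for i, g in enumerate(genes["gene_id"])}
    snp_col = {s: i for i, s in enumerate(genotypes.snps["snp_id"])}
    true_eqtls = []
    for _, row in catalog.iterrows():
        if row["effect"] == 0.0:
            continue
        dos = genotypes.calls[:, snp_col[row["snp_id"]]].astype(float)
        dos[dos == MISSING] = np.nan
        dos = np.nan_to_num(dos, nan=np.nanmean(dos) if np.isfinite(np.nanmean(dos)) else 0.0)
        latent[gene_row[row["gene_id"]]] += row["effect"] * dos
        true_eqtls.append((row["snp_id"], row["gene_id"], float(row["effect"])))

    # contamination mixes the *biological* expression profiles; measurement
    # noise is drawn afterwards, once per measured library (a mixed library
    # is assayed once — it does not average two noise realizations)
    sample_idx = {s: i for i, s in enumerate(config.sample_ids)}
    contaminated = config.contamination_map
    mu_signal = np.exp2(latent)
    for sample, (donor, frac) in contaminated.items():
        si, di = sample_idx[sample], sample_idx[donor]
        mu_signal[:, si] = (1.0 - frac) * mu_signal[:, si] + frac * mu_signal[:, di]
    latent = np.log2(mu_signal)
    latent += rng.normal(0.0, config.noise_sd, (n_g, n_s))

    gene_sd = latent.std(axis=1)
    gene_sd[gene_sd == 0] = 1.0
    global_outliers: set[str] = set()
    for sample, shift in config.global_outlier_samples:
        si = sample_idx[sample]
        signs = np.where(rng.random(n_g) < 0.5, -1.0, 1.0)
        latent[:, si] += shift * gene_sd * signs
        global_outliers.add(sample)

    per_gene_outliers: set[tuple[str, str]] = set()
    if config.per_gene_outlier_rate > 0:
        hits = rng.random((n_g, n_s)) < config.per_gene_outlier_rate
        gi_idx, si_idx = np.nonzero(hits)
        signs = np.where(rng.random(gi_idx.size) < 0.5, -1.0, 1.0)
        latent[gi_idx, si_idx] += (
            config.per_gene_outlier_shift * gene_sd[gi_idx] * signs
        )
        for gi, si in zip(gi_idx, si_idx):
            per_gene_outliers.add(
                (genes["gene_id"].iloc[gi], config.sample_ids[si])
            )

    mu = np.exp2(latent)
    lib = rng.integers(
        config.library_size_range[0],
        config.library_size_range[1] + 1,
        size=n_s,
    )
    p = mu / mu.sum(axis=0, keepdims=True)
    counts = rng.poisson(lib[None, :] * p)

    expr = ExpressionMatrix(
        genes=genes, samples=config.sample_ids, counts=counts
    )
    truth = Truth(
        true_eqtls=true_eqtls,
        contaminated=dict(contaminated),
        global_outliers=global_outliers,
        per_gene_outliers=per_gene_outliers,
        catalog=catalog,
    )
    return expr, truth


def simulate_rna_calls(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> RnaCallSet:
    """RNA-level genotype evidence, optionally cross-contaminated.

    Depth per site is Poisson(rna_depth_mean). Each read's allele comes from
    the labeled sample's DNA genotype with probability ``1 - fraction`` and
    from the donor's otherwise, then flips with probability
    ``rna_error_rate``. Sites with depth <= 20 reads are withheld by the
    call rule downstream.
    """
    for sample, (donor, _) in config.contamination_map.items():
        if donor not in genotypes.samples:
            raise ValueError(f"contamination donor {donor} not genotyped")
        if sample not in genotypes.samples:
            raise ValueError(f"contaminated sample {sample} not genotyped")
    rng = config.rng(_STREAM_RNA)
    n_s, n_m = genotypes.n_samples, genotypes.n_snps
    ref_depth = np.zeros((n_s, n_m), dtype=np.int64)
    alt_depth = np.zeros((n_s, n_m), dtype=np.int64)
    contaminated = config.contamination_map
    e = config.rna_error_rate
    for si, sample in enumerate(genotypes.samples):
        depth = rng.poisson(config.rna_depth_mean, n_m)
        g_rec = genotypes.calls[si].astype(float)
        donor, frac = contaminated.get(sample, (None, 0.0))
        if donor is not None:
            g_don = genotypes.calls[genotypes.sample_index(donor)].astype(float)
        else:
            g_don = g_rec
        n_rec = rng.binomial(depth, 1.0 - frac)
        n_don = depth - n_rec
        # missing DNA genotypes contribute no evidence
        ok_rec = g_rec != MISSING
        ok_don = g_don != MISSING
        alt_rec = np.where(
            ok_rec, rng.binomial(n_rec, np.where(ok_rec, g_rec, 0) / 2.0), 0
        )
        alt_don = np.where(
            ok_don, rng.binomial(n_don, np.where(ok_don, g_don, 0) / 2.0), 0
        )
        n_tot = np.where(ok_rec, n_rec, 0) + np.where(ok_don, n_don, 0)
        alt = alt_rec + alt_don
        ref = n_tot - alt
        if e > 0:
            flips_to_ref = rng.binomial(alt, e)
            flips_to_alt = rng.binomial(ref, e)
            alt = alt - flips_to_ref + flips_to_alt
            ref = n_tot - alt
        ref_depth[si] = ref
        alt_depth[si] = alt
    return RnaCallSet(
        samples=list(genotypes.samples),
        snp_ids=list(genotypes.snps["snp_id"]),
        ref_depth=ref_depth,
        alt_depth=alt_depth,
    )


def simulate_all(config: SimulationConfig) -> SimBundle:
    """Run the full generator and collect every artifact in one bundle."""
    genotypes = simulate_genotypes(config)
    expression, truth = simulate_expression(genotypes, config)
    rna = simulate_rna_calls(genotypes, config)
    catalog = EqtlCatalog(
        pairs=truth.catalog[["snp_id", "gene_id", "source"]].copy()
    )
    covariates = simulate_covariates(config)
    return SimBundle(
        config=config,
        genotypes=genotypes,
        expression=expression,
        truth=truth,
        catalog=catalog,
        covariates=covariates,
        rna_calls=rna,
    )


def empirical_power(
    effect: float,
    maf: float,
    n: int,
    noise_sd: float,
    n_reps: int = 200,
    alpha: float = 0.05,
    mean_count: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Power of the per-pair dosage regression by direct simulation.

    Draws ``n_reps`` replicate cohorts at the given sample size, MAF and
    noise level, optionally passing the latent expression through the
    Poisson count layer at depth ``mean_count`` (so counting noise is part
    of the power calculation), and reports the fraction rejecting at
    ``alpha`` (two-sided).
    """
    from scipy import stats as _st

    if rng is None:
        rng = np.random.default_rng(0)
    g = rng.binomial(2, maf, size=(n_reps, n)).astype(float)
    y = effect * g + rng.normal(0.0, noise_sd, size=(n_reps, n))
    if mean_count is not None:
        mu = mean_count * np.exp2(y - y.mean(axis=1, keepdims=True))
        y = np.log2(rng.poisson(mu) + 0.5)
    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (gc**2).sum(axis=1)
    ok = sxx > 0
    sxy = (gc * yc).sum(axis=1)
    syy = (yc**2).sum(axis=1)
    beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
    rss = syy - np.where(ok, beta, 0.0) * sxy
    df = n - 2
    se = np.sqrt(np.maximum(rss, 0.0) / df / np.where(ok, sxx, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * _st.t.sf(np.abs(t), df)
    p = p[ok & np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no informative replicate (constant genotypes)")
    return float((p < alpha).mean())
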