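"""Expression-matrix quality control.

Normalization (depth-only or GC-aware quantile), the two gene filters
(summed log2 for analysis, summed counts for decomposition), global sample
outliers by the 6-PC / 3-SD rule, per-gene outlier masking by the per-gene
3-SD rule, and PCA surrogate covariates.

Conventions: PCA treats samples as observations and genes as variables,
centered but not scaled; outlier statistics use population SD (ddof=0) and
the SD rules are strict inequalities, so a point at exactly the threshold
is not flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA

DEFAULT_SD_THRESHOLD = 3.0
DEFAULT_N_PCS = 6
DEFAULT_LOG2_SUM_MIN = 100.0
DEFAULT_COUNT_SUM_MIN = 10
DEFAULT_GC_BINS = 10

NORMALIZATION_METHODS = ("log2_depth", "gc_quantile", "external")


def _quantile_normalize_between_samples(x: np.ndarray) -> np.ndarray:
    """Classic full-quantile normalization across columns (samples).

    Ties receive the average target value (average ranks), so the result is
    invariant to gene ordering.
    """
    n = x.shape[0]
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        r = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(r, np.arange(1, n + 1), target)
    return out


def _gc_quantile_within_sample(
    col: np.ndarray, bin_ids: np.ndarray, n_bins: int
) -> np.ndarray:
    """Full-quantile normalization across GC bins within one sample.

    Each bin's empirical distribution is mapped onto the mean quantile
    function across bins, so systematic GC-dependent shifts are removed
    while the overall distribution is preserved.
    """
    grid = (np.arange(100) + 0.5) / 100
    qfuns = np.empty((n_bins, grid.size))
    for b in range(n_bins):
        vals = col[bin_ids == b]
        qfuns[b] = np.quantile(vals, grid)
    target = qfuns.mean(axis=0)
    out = np.empty_like(col, dtype=float)
    for b in range(n_bins):
        idx = np.nonzero(bin_ids == b)[0]
        vals = col[idx]
        r = (rankdata(vals, method="average") - 0.5) / idx.size
        out[idx] = np.interp(r, grid, target)
    return out


def normalize(
    counts: np.ndarray,
    annotation: pd.DataFrame | None = None,
    method: str = "log2_depth",
    external: np.ndarray | None = None,
    n_gc_bins: int = DEFAULT_GC_BINS,
) -> np.ndarray:
    """Normalize a genes x samples count matrix to log2 values.

    * ``log2_depth`` — log2(count / library_size * 1e6 + 0.5) (depth only);
    * ``gc_quantile`` — within-sample full-quantile normalization across
      equal-frequency GC bins, then between-sample full-quantile
      normalization, then log2 with a 0.5 offset; requires ``annotation``
      with a ``gc`` column;
    * ``external`` — a precomputed log2 matrix (e.g. from a dedicated
      normalization package) ingested as-is after a shape check.
    """
    counts = np.asarray(counts, dtype=float)
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "external":
        if external is None:
            raise ValueError("external method requires a log2 matrix")
        external = np.asarray(external, dtype=float)
        if external.shape != counts.shape:
            raise ValueError(
                f"external matrix shape {external.shape} != {counts.shape}"
            )
        return external.copy()
    if method == "log2_depth":
        lib = counts.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with zero total counts")
        return np.log2(counts / lib * 1e6 + 0.5)
    # gc_quantile
    if annotation is None or "gc" not in annotation:
        raise ValueError("gc_quantile requires gene annotation with gc")
    gc = annotation["gc"].to_numpy(dtype=float)
    if gc.size != counts.shape[0]:
        raise ValueError("annotation rows must match count matrix genes")
    n_bins = min(n_gc_bins, counts.shape[0])
    # equal-frequency bins by GC rank; ties broken by input order
    order = np.argsort(gc, kind="stable")
    bin_ids = np.empty(gc.size, dtype=int)
    bin_ids[order] = np.minimum(
        (np.arange(gc.size) * n_bins) // gc.size, n_bins - 1
    )
    within = np.empty_like(counts)
    for j in range(counts.shape[1]):
        within[:, j] = _gc_quantile_within_sample(counts[:, j], bin_ids, n_bins)
    between = _quantile_normalize_between_samples(within)
    return np.log2(between + 0.5)


def filter_genes(
    log2values: np.ndarray,
    counts: np.ndarray,
    log2_sum_min: float = DEFAULT_LOG2_SUM_MIN,
    count_sum_min: float = DEFAULT_COUNT_SUM_MIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene filters for analysis and for data decomposition.

    Returns two boolean masks over genes: the *analysis* set (summed log2
    across samples >= ``log2_sum_min``) and the *decomposition* set (summed
    counts >= ``count_sum_min``). Both boundaries are inclusive.
    """
    analysis = np.asarray(log2values).sum(axis=1) >= log2_sum_min
    decomposition = np.asarray(counts).sum(axis=1) >= count_sum_min
    return analysis, decomposition


def pca_sample_outliers(
    log2values: np.ndarray,
    n_pcs: int = DEFAULT_N_PCS,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag global expression outliers in principal-component space.

    PCA is run on samples (observations) over genes (variables), centered
    and unscaled. A sample is an outlier iff its score on any of the first
    ``n_pcs`` components lies strictly more than ``sd_threshold`` population
    SDs from that component's mean score.

    Returns ``(flags, variance_explained, scores)``.
    """
    X = np.asarray(log2values, dtype=float).T  # samples x genes
    n, p = X.shape
    if n_pcs > min(n, p) - 1:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(samples, genes) - 1 = {min(n, p) - 1}"
        )
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0)  # ddof=0
    with np.errstate(invalid="ignore"):
        dev = np.abs(scores - mean)
    flagged = np.zeros(n, dtype=bool)
    for k in range(n_pcs):
        if sd[k] > 0 and np.isfinite(sd_threshold):
            flagged |= dev[:, k] > sd_threshold * sd[k]
    return flagged, pca.explained_variance_ratio_, scores


def per_gene_outliers(
    log2values: np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    prior_mask: np.ndarray | None = None,
    leave_one_out: bool = False,
    min_samples: int = 3,
) -> tuple[np.ndarray, float]:
    """Mask single expression values far from their gene's mean.

    Per gene, entries with ``|x - mean| > sd_threshold * sd`` are masked
    (strict inequality, population SD, single non-iterative pass including
    the candidate itself unless ``leave_one_out``). Entries already True in
    ``prior_mask`` are excluded from the statistics and carried over. Genes
    with zero variance or fewer than ``min_samples`` usable samples produce
    no flags.

    Returns the combined mask and the fraction of genes with at least one
    newly masked sample.
    """
    X = np.asarray(log2values, dtype=float)
    n_genes, n_samples = X.shape
    prior = (
        np.zeros_like(X, dtype=bool)
        if prior_mask is None
        else np.asarray(prior_mask, dtype=bool)
    )
    mask = prior.copy()
    newly = np.zeros(n_genes, dtype=bool)
    for gi in range(n_genes):
        use = ~prior[gi]
        if use.sum() < min_samples:
            continue
        vals = X[gi, use]
        if leave_one_out:
            idx = np.nonzero(use)[0]
            for j, col in enumerate(idx):
                rest = np.delete(vals, j)
                mu, sd = rest.mean(), rest.std()
                if sd > 0 and abs(vals[j] - mu) > sd_threshold * sd:
                    mask[gi, col] = True
                    newly[gi] = True
        else:
            mu, sd = vals.mean(), vals.std()
            if sd == 0:
                continue
            hit = np.abs(X[gi] - mu) > sd_threshold * sd
            hit &= use
            if hit.any():
                mask[gi] |= hit
                newly[gi] = True
    return mask, float(newly.mean())


def compute_surrogates(
    log2values: np.ndarray,
    decomposition_genes: np.ndarray | None = None,
    n_components: int = DEFAULT_N_PCS,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Principal-component surrogate covariates.

    PC scores per sample over the decomposition gene set (centered,
    unscaled). Masked entries are replaced by the gene's unmasked mean
    before decomposition. Returns a samples x n_components score matrix;
    ``n_components = 0`` yields an empty matrix.
    """
    X = np.asarray(log2values, dtype=float)
    if decomposition_genes is not None:
        sel = np.asarray(decomposition_genes, dtype=bool)
        if not sel.any():
            raise ValueError("decomposition gene set is empty")
        X = X[sel]
        mask = None if mask is None else np.asarray(mask, dtype=bool)[sel]
    n_genes, n_samples = X.shape
    if n_components == 0:
        return np.empty((n_samples, 0))
    if n_components > min(n_samples, n_genes):
        raise ValueError("n_components exceeds available rank")
    if mask is not None and mask.any():
        X = X.copy()
        for gi in np.nonzero(mask.any(axis=1))[0]:
            use = ~mask[gi]
            fill = X[gi, use].mean() if use.any() else 0.0
            X[gi, ~use] = fill
    if not (X - X.mean(axis=1, keepdims=True)).any():
        # identical samples: no variation to decompose
        return np.zeros((n_samples, n_components))
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(X.T)
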