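"""Sample identity and contamination checks from paired DNA/RNA genotypes.

Two complementary diagnostics:

* **IBS DST** — pairwise identity-by-state distance,
  ``(N_IBS2 + 0.5 * N_IBS1) / N`` over jointly non-missing SNPs. An RNA
  sample should best-match its labeled DNA sample with DST near 1.0; a
  best match elsewhere indicates a swap.
* **Discordance Ratio (DR)** — among RNA calls that are heterozygous, the
  fraction whose matched DNA genotype is homozygous. Clean libraries have
  DR near zero; reads from a second individual introduce spurious RNA
  heterozygotes at the recipient's homozygous sites, so DR rises with the
  contaminating fraction. A mixing experiment at controlled purity ratios
  turns the observed DR into a contamination estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, RnaCallSet

#: DR below which a library is treated as clean (sufficient quality)
DR_CLEAN = 0.2
#: DR below which a library qualifies as a high-confidence mixing input
DR_HIGHCONF = 0.1
#: best-match DST below this triggers a DR investigation
BORDERLINE_DST = 0.90


class IncomparableSamplesError(ValueError):
    """No jointly non-missing SNP between two genotype vectors."""


class DrUndefinedError(ValueError):
    """No heterozygous RNA call; the discordance ratio is undefined."""


def ibs_dst(a: np.ndarray, b: np.ndarray) -> float:
    """Pairwise IBS distance between two dosage vectors.

    Over SNPs non-missing in both: IBS2 = identical calls, IBS1 = calls
    sharing exactly one allele (|a-b| = 1), IBS0 = opposite homozygotes.
    DST = (N_IBS2 + 0.5*N_IBS1)/N, in [0, 1]. Missing calls are dropped
    pairwise.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must cover the same SNP list")
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise IncomparableSamplesError("no jointly non-missing SNPs")
    diff = np.abs(a[ok].astype(np.int64) - b[ok].astype(np.int64))
    n2 = int((diff == 0).sum())
    n1 = int((diff == 1).sum())
    return (n2 + 0.5 * n1) / n


def dst_matrix(dna: GenotypeMatrix, rna: RnaCallSet) -> pd.DataFrame:
    """All-vs-all DST between RNA samples (rows) and DNA samples (columns)."""
    shared = [s for s in rna.snp_ids if s in set(dna.snps["snp_id"])]
    if not shared:
        raise IncomparableSamplesError("no shared SNPs between DNA and RNA")
    dna_col = {s: i for i, s in enumerate(dna.snps["snp_id"])}
    rna_col = {s: i for i, s in enumerate(rna.snp_ids)}
    d_idx = [dna_col[s] for s in shared]
    r_idx = [rna_col[s] for s in shared]
    D = dna.calls[:, d_idx]
    R = rna.calls[:, r_idx]
    out = np.empty((len(rna.samples), len(dna.samples)))
    for i in range(R.shape[0]):
        for j in range(D.shape[0]):
            out[i, j] = ibs_dst(R[i], D[j])
    return pd.DataFrame(out, index=list(rna.samples), columns=list(dna.samples))


def discordance_ratio(dna_calls: np.ndarray, rna_calls: np.ndarray) -> float:
    """DR = #{DNA homozygous & RNA heterozygous} / #{RNA heterozygous}.

    Only sites with a retained RNA call and a non-missing DNA genotype
    enter. Raises :class:`DrUndefinedError` when there is no heterozygous
    RNA call — deliberately distinct from DR = 0.
    """
    dna = np.asarray(dna_calls)
    rna = np.asarray(rna_calls)
    if dna.shape != rna.shape:
        raise ValueError("call vectors must cover the same SNP list")
    ok = (dna != MISSING) & (rna != MISSING)
    het = ok & (rna == 1)
    n_het = int(het.sum())
    if n_het == 0:
        raise DrUndefinedError("no heterozygous RNA calls")
    discord = int((het & (dna != 1)).sum())
    return discord / n_het


@dataclass
class ConcordanceReport:
    """Identity and contamination status per RNA sample.

    ``dst`` is the RNA-by-DNA DST matrix; ``best_match`` the DNA sample
    maximizing DST per RNA sample; ``identity_ok`` whether that best match
    is the labeled pair; ``dr`` the per-sample discordance ratio against the
    labeled DNA (NaN when undefined); ``flags`` one of clean / borderline /
    contaminated.
    """

    dst: pd.DataFrame
    best_match: pd.Series
    identity_ok: pd.Series
    dr: pd.Series
    flags: pd.Series

    def to_frame(self) -> pd.DataFrame:
        best_dst = pd.Series(
            [self.dst.loc[s, self.best_match[s]] for s in self.dst.index],
            index=self.dst.index,
        )
        return pd.DataFrame(
            {
                "best_match": self.best_match,
                "dst": best_dst,
                "identity_ok": self.identity_ok,
                "dr": self.dr,
                "flag": self.flags,
            }
        ).rename_axis("sample")


def match_samples(
    dna: GenotypeMatrix,
    rna: RnaCallSet,
    borderline_dst: float = BORDERLINE_DST,
) -> ConcordanceReport:
    """Verify sample identity by all-vs-all DST.

    ``identity_ok`` is True iff the labeled DNA sample is the best match.
    Samples whose best-match DST falls below ``borderline_dst`` are flagged
    ``borderline`` for DR investigation; DR fields are filled by
    :func:`concordance_report`.
    """
    if dna.n_samples < 2:
        raise ValueError("need at least two DNA samples to match against")
    dst = dst_matrix(dna, rna)
    best = dst.idxmax(axis=1)
    identity_ok = pd.Series(
        [best[s] == s for s in dst.index], index=dst.index
    )
    flags = pd.Series(
        np.where(dst.max(axis=1) < borderline_dst, "borderline", "clean"),
        index=dst.index,
    )
    dr = pd.Series(np.nan, index=dst.index)
    return ConcordanceReport(dst, best, identity_ok, dr, flags)


def sample_dr(dna: GenotypeMatrix, rna: RnaCallSet) -> pd.Series:
    """Discordance ratio of each RNA sample against its labeled DNA."""
    shared = [s for s in rna.snp_ids if s in set(dna.snps["snp_id"])]
    dna_col = {s: i for i, s in enumerate(dna.snps["snp_id"])}
    rna_col = {s: i for i, s in enumerate(rna.snp_ids)}
    d_idx = [dna_col[s] for s in shared]
    r_idx = [rna_col[s] for s in shared]
    calls = rna.calls
    out = {}
    for sample in rna.samples:
        if sample not in dna.samples:
            out[sample] = np.nan
            continue
        try:
            out[sample] = discordance_ratio(
                dna.calls[dna.sample_index(sample), d_idx],
                calls[rna.sample_index(sample), r_idx],
            )
        except DrUndefinedError:
            out[sample] = np.nan
    return pd.Series(out, name="dr")


def concordance_report(
    dna: GenotypeMatrix,
    rna: RnaCallSet,
    dr_clean: float = DR_CLEAN,
    borderline_dst: float = BORDERLINE_DST,
) -> ConcordanceReport:
    """Full identity + contamination report.

    Flags: ``contaminated`` if DR >= ``dr_clean``; otherwise ``borderline``
    if the best-match DST falls below ``borderline_dst``; else ``clean``.
    """
    rep = match_samples(dna, rna, borderline_dst)
    rep.dr = sample_dr(dna, rna)
    contaminated = rep.dr >= dr_clean
    rep.flags = pd.Series(
        np.where(contaminated, "contaminated", rep.flags),
        index=rep.flags.index,
    )
    return rep


def mix_call_evidence(
    rna: RnaCallSet,
    recipient: str,
    donor: str,
    purity: float,
    rng: np.random.Generator | None = None,
) -> RnaCallSet:
    """In-silico read mixing of two RNA samples at a controlled purity.

    A purity of 10 means 10% of the reads in the mixed evidence come from
    the recipient and 90% from the donor. Per SNP, the target depth is the
    recipient's depth n; k ~ Binomial(n, purity/100) reads are drawn without
    replacement from the recipient's read pool and n-k from the donor's
    (with replacement if the donor pool is shallower). Returns a
    single-sample call set named after the recipient, re-called by the het
    rule and suitable for a DR against the recipient's DNA.

    purity = 100 and donor == recipient are exact no-ops (merging a
    library's reads with themselves changes nothing).
    """
    if not (0 < purity <= 100):
        raise ValueError("purity must lie in (0, 100]")
    ri = rna.sample_index(recipient)
    di = rna.sample_index(donor)
    if purity == 100 or ri == di:
        ref, alt = rna.ref_depth[ri].copy(), rna.alt_depth[ri].copy()
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        n = rna.ref_depth[ri] + rna.alt_depth[ri]
        alt_r = rna.alt_depth[ri]
        n_d = rna.ref_depth[di] + rna.alt_depth[di]
        alt_d = rna.alt_depth[di]
        k = rng.binomial(n, purity / 100.0)
        m = n - k
        safe_n = np.maximum(n, 1)
        alt_from_rec = rng.hypergeometric(alt_r, safe_n - alt_r, np.minimum(k, n))
        alt_from_rec = np.where(n > 0, alt_from_rec, 0)
        safe_nd = np.maximum(n_d, 1)
        hg = rng.hypergeometric(alt_d, safe_nd - alt_d, np.minimum(m, n_d))
        bn = rng.binomial(m, alt_d / safe_nd)
        alt_from_don = np.where(n_d >= m, hg, bn)
        # donor with no coverage contributes nothing; site depth shrinks
        m_eff = np.where(n_d > 0, m, 0)
        alt = alt_from_rec + np.where(n_d > 0, alt_from_don, 0)
        tot = k + m_eff
        ref = tot - alt
    return RnaCallSet(
        samples=[recipient],
        snp_ids=list(rna.snp_ids),
        ref_depth=ref[None, :],
        alt_depth=alt[None, :],
        min_depth=rna.min_depth,
        het_min_reads=rna.het_min_reads,
        het_min_frac=rna.het_min_frac,
    )


@dataclass
class ContaminationEstimate:
    """Inversion of the DR-vs-purity calibration curve.

    ``status`` is one of ``clean`` (observed DR at or below the unmixed
    baseline), ``estimated`` (bracketed by the curve) or ``above_range``
    (beyond the most-contaminated calibration point). Contamination bounds
    are percentages of reads from a foreign sample.
    """

    status: str
    contamination_low: float
    contamination_high: float
    point: float
    curve: pd.DataFrame


def calibration_curve(
    dna: GenotypeMatrix,
    rna: RnaCallSet,
    clean_pairs: list[tuple[str, str]],
    purities: list[float],
    rng: np.random.Generator | None = None,
    dr_highconf: float = DR_HIGHCONF,
) -> pd.DataFrame:
    """Mean/SD DR at each mixing purity across high-confidence clean pairs.

    Every recipient and donor must itself be clean (DR < ``dr_highconf``)
    so the curve reflects mixing alone.
    """
    if len(set(purities)) < 2:
        raise ValueError("need at least two calibration purities")
    if rng is None:
        rng = np.random.default_rng(0)
    drs = sample_dr(dna, rna)
    for rec, don in clean_pairs:
        for s in (rec, don):
            if not (drs[s] < dr_highconf):
                raise ValueError(
                    f"calibration sample {s} is not high-confidence "
                    f"(DR {drs[s]:.3f} >= {dr_highconf})"
                )
    rows = []
    for purity in sorted(set(purities)):
        vals = []
        for rec, don in clean_pairs:
            mixed = mix_call_evidence(rna, rec, don, purity, rng)
            vals.append(
                discordance_ratio(
                    dna.sample_calls(rec), mixed.calls[0]
                )
            )
        rows.append((purity, float(np.mean(vals)), float(np.std(vals))))
    return pd.DataFrame(rows, columns=["purity", "mean_dr", "sd_dr"])


def calibrate_and_estimate(
    observed_dr: float,
    dna: GenotypeMatrix,
    rna: RnaCallSet,
    clean_pairs: list[tuple[str, str]],
    purities: list[float] = (10, 20, 30, 40, 50, 100),
    rng: np.random.Generator | None = None,
    dr_highconf: float = DR_HIGHCONF,
) -> ContaminationEstimate:
    """Estimate a sample's contamination level from its observed DR.

    Builds the mean-DR-vs-purity calibration curve over clean-pair mixes and
    inverts it: the contamination interval is the purity bin whose DR range
    brackets ``observed_dr``, with a linear-interpolation point estimate
    inside the bracketing segment. Ties at a knot resolve toward the
    lower-contamination endpoint.
    """
    curve = calibration_curve(dna, rna, clean_pairs, purities, rng, dr_highconf)
    # sort by purity descending: DR ascends with contamination = 100 - purity
    c = curve.sort_values("purity", ascending=False).reset_index(drop=True)
    pur = c["purity"].to_numpy(dtype=float)
    # DR rises with contamination in expectation; enforce monotonicity so
    # sampling noise between adjacent purities cannot break the inversion
    dr = np.maximum.accumulate(c["mean_dr"].to_numpy())
    if observed_dr <= dr[0]:
        return ContaminationEstimate("clean", 0.0, 100.0 - pur[0], 0.0, curve)
    if observed_dr > dr[-1]:
        return ContaminationEstimate(
            "above_range", 100.0 - pur[-1], 100.0, 100.0 - pur[-1], curve
        )
    # first knot at or above the observed value (ties -> lower contamination)
    hi = int(np.searchsorted(dr, observed_dr, side="left"))
    lo = hi - 1
    if dr[hi] == observed_dr:
        point = 100.0 - pur[hi]
    else:
        frac = (observed_dr - dr[lo]) / (dr[hi] - dr[lo])
        point = (100.0 - pur[lo]) + frac * (pur[lo] - pur[hi])
    return ContaminationEstimate(
        "estimated", 100.0 - pur[lo], 100.0 - pur[hi], float(point), curve
    )
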