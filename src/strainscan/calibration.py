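"""Multiple-testing calibration, scan quality control and locus grouping.

Two significance thresholds are used side by side: a strict Bonferroni
cutoff over (number of SDPs) x (number of scans passing QC), and a milder
"suggestive" cutoff based on the effective number of independent tests —
the number of phenotype eigenvectors needed to explain a fixed fraction of
trait variance, times the effective number of independent genotype tests
inferred by inverting the median minimum p-value of permutation scans.

Scan QC automates the visual QQ-plot inspection: a scan fails when its
genomic inflation factor lambda leaves a configured band, or when small
p-values are in systematic excess of the uniform expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import SDP
from .mixed_model import MixedModelSpec, ScanEngine, ScanResult

DEFAULT_ALPHA = 0.05
DEFAULT_VARIANCE_FRACTION = 0.995
DEFAULT_N_PERM = 100
DEFAULT_LAMBDA_BOUNDS = (0.8, 1.25)
DEFAULT_EXCESS_RATIO = 3.0
DEFAULT_MERGE_DISTANCE = 1_000_000

_CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))


class CalibrationError(ValueError):
    pass


@dataclass
class ThresholdSet:
    """Strict and suggestive genome-wide significance cutoffs."""

    alpha: float
    strict_p: float
    suggestive_p: float
    n_sdps: int
    n_scans: int
    n_eff_pheno: int
    n_eff_geno: int

    def __post_init__(self) -> None:
        if self.strict_p > self.suggestive_p:
            raise CalibrationError("strict cutoff must not exceed suggestive cutoff")


def bonferroni_threshold(n_sdps: int, n_scans: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Family-wise cutoff alpha / (n_sdps * n_scans) over all SDPs and scans."""
    if n_sdps < 1 or n_scans < 1:
        raise CalibrationError("counts must be >= 1")
    if not 0 < alpha < 1:
        raise CalibrationError("alpha must be in (0, 1)")
    return alpha / (n_sdps * n_scans)


def suggestive_threshold(
    n_eff_pheno: int, n_eff_geno: int, alpha: float = DEFAULT_ALPHA
) -> float:
    """Cutoff alpha / (effective phenotype tests x effective genotype tests)."""
    if n_eff_pheno < 1 or n_eff_geno < 1:
        raise CalibrationError("effective test counts must be >= 1")
    if not 0 < alpha < 1:
        raise CalibrationError("alpha must be in (0, 1)")
    return alpha / (n_eff_pheno * n_eff_geno)


def effective_pheno_tests(
    trait_matrix, variance_fraction: float = DEFAULT_VARIANCE_FRACTION
) -> int:
    """Number of trait-covariance eigenvectors explaining the given variance.

    ``trait_matrix`` is observations x traits (DataFrame or array); rows with
    any missing value are dropped.  Returns the smallest k such that the k
    largest eigenvalues of the trait covariance sum to at least
    ``variance_fraction`` of the total.
    """
    M = (
        trait_matrix.dropna().to_numpy(float)
        if isinstance(trait_matrix, pd.DataFrame)
        else np.asarray(trait_matrix, float)
    )
    if M.ndim != 2 or M.shape[1] < 2:
        raise CalibrationError("need at least two traits")
    if not 0 < variance_fraction <= 1:
        raise CalibrationError("variance_fraction must be in (0, 1]")
    w = np.linalg.eigvalsh(np.cov(M, rowvar=False))[::-1]
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total == 0:
        return 1
    cum = np.cumsum(w) / total
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def invert_median_min_p(median_min_p: float) -> int:
    """Effective independent test count = round(1 / median minimum p).

    The inverse-median estimator is used as published; note it is biased for
    a small number m of independent uniform tests, where the median minimum
    is 1 - 2**(-1/m) (inverse ~ m/ln 2), not 1/m.
    """
    if not 0 < median_min_p <= 1:
        raise CalibrationError("median_min_p must be in (0, 1]")
    return int(round(1.0 / median_min_p))


def effective_geno_tests(
    spec: MixedModelSpec,
    sdps: Sequence[SDP],
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    permute: str = "animals",
    engine: Optional[ScanEngine] = None,
) -> tuple[int, float]:
    """Effective number of independent genotype tests per phenotype.

    For each permutation of the phenotype vector the minimum p-value over all
    SDPs is recorded; the effective test count is the rounded inverse of the
    median of these minima.  ``permute='strains'`` permutes strain labels
    (whole strain blocks) instead of individual animals.
    """
    if n_perm < 3:
        raise CalibrationError("need at least three permutations")
    rng = np.random.default_rng(seed)
    if engine is None:
        engine = ScanEngine(spec, sdps)
    if permute == "strains":
        rng = _StrainPermuter(spec, rng)  # type: ignore[assignment]
    elif permute != "animals":
        raise CalibrationError(f"unknown permutation unit {permute!r}")
    minima = engine.min_p_permutations(n_perm, rng)
    if not np.isfinite(minima).all():
        raise CalibrationError("degenerate scan: a permutation produced no statistic")
    med = float(np.median(minima))
    return invert_median_min_p(med), med


class _StrainPermuter:
    """Adapter permuting whole strain blocks of the animal index.

    Requires balanced replicates (equal animals per strain) so that swapping
    strain blocks yields a true permutation of the animal index.
    """

    def __init__(self, spec: MixedModelSpec, rng: np.random.Generator):
        strain_of = spec.Z.argmax(axis=1)
        self._rng = rng
        self._n_strains = spec.Z.shape[1]
        self._members = [np.nonzero(strain_of == s)[0] for s in range(self._n_strains)]
        sizes = {len(m) for m in self._members}
        if len(sizes) != 1:
            raise CalibrationError("strain-label permutation requires balanced replicates")

    def permutation(self, n: int) -> np.ndarray:
        order = self._rng.permutation(self._n_strains)
        out = np.empty(n, dtype=int)
        for src, dst in enumerate(order):
            out[self._members[src]] = self._members[dst]
        return out


# ---------------------------------------------------------------------------
# QQ data and scan QC
# ---------------------------------------------------------------------------

def qq_data(pvals, method: str = "midpoint") -> pd.DataFrame:
    """Expected vs observed p-value quantiles for a QQ plot.

    Observed p-values sorted ascending are paired with uniform quantiles
    (i - 0.5)/n (``method='midpoint'``) or i/(n + 1) (``method='rankit'``).
    Returns a table with raw and -log10 columns.
    """
    p = np.sort(np.asarray(pvals, float))
    if p.size == 0:
        raise CalibrationError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise CalibrationError("p-values must lie in (0, 1]")
    n = p.size
    i = np.arange(1, n + 1)
    if method == "midpoint":
        exp = (i - 0.5) / n
    elif method == "rankit":
        exp = i / (n + 1)
    else:
        raise CalibrationError(f"unknown quantile method {method!r}")
    return pd.DataFrame(
        {
            "expected": exp,
            "observed": p,
            "neg_log10_expected": -np.log10(exp),
            "neg_log10_observed": -np.log10(p),
        }
    )


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor: median association chi-square / null median."""
    p = np.asarray(pvals, float)
    chi2 = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), 1)
    return float(np.median(chi2) / _CHI2_NULL_MEDIAN)


@dataclass
class QcReport:
    passed: bool
    lam: float
    excess_ratio: float
    n_pvals: int
    reasons: list[str] = field(default_factory=list)


def qc_scan(
    pvals,
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
    excess_ratio_max: float = DEFAULT_EXCESS_RATIO,
    excess_p: float = 0.01,
) -> QcReport:
    """Automated stand-in for visual QQ-plot inspection of one scan.

    Fails when genomic inflation lambda leaves ``lambda_bounds`` or when the
    count of p-values below ``excess_p`` exceeds ``excess_ratio_max`` times
    the uniform expectation (inflation at low-to-moderate significance).  A
    handful of true signals among thousands of null tests does not trip
    either rule.
    """
    p = np.asarray(pvals, float)
    if p.size < 100:
        raise CalibrationError("scan QC needs at least 100 p-values")
    lam = genomic_lambda(p)
    ratio = float((p < excess_p).sum() / (excess_p * p.size))
    reasons = []
    if not lambda_bounds[0] <= lam <= lambda_bounds[1]:
        reasons.append(f"lambda {lam:.3f} outside {lambda_bounds}")
    if ratio > excess_ratio_max:
        reasons.append(f"excess of p<{excess_p}: {ratio:.2f}x expected")
    return QcReport(
        passed=not reasons, lam=lam, excess_ratio=ratio, n_pvals=p.size, reasons=reasons
    )


# ---------------------------------------------------------------------------
# Hit classification and locus grouping
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """A merged genomic interval of suggestive/significant markers."""

    locus_id: int
    chrom: str
    start: int
    end: int
    members: pd.DataFrame  # snp_id, pos, sdp_id, p, cls
    n_significant: int
    n_suggestive: int
    top_snp: str
    top_p: float
    linked_loci: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CalibrationError("locus start exceeds end")


def classify_and_group(
    scan: ScanResult,
    thresholds: ThresholdSet,
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
) -> list[Locus]:
    """Label hits and merge nearby ones into loci.

    SNPs are classed significant (p <= strict), suggestive (strict < p <=
    suggestive) or null; labeled SNPs on one chromosome within
    ``merge_distance`` of each other merge into one locus.  Loci on
    different chromosomes that share an identical SDP are cross-annotated in
    ``linked_loci`` but never merged.
    """
    snps = scan.snp_table()
    snps = snps[snps["flag"] != "degenerate"].copy()
    cls = np.where(
        snps["p"] <= thresholds.strict_p,
        "significant",
        np.where(snps["p"] <= thresholds.suggestive_p, "suggestive", "null"),
    )
    snps["cls"] = cls
    hits = snps[snps["cls"] != "null"]
    loci: list[Locus] = []
    for chrom, sub in hits.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > merge_distance)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            chunk = sub.iloc[int(a): int(b)]
            top = chunk.loc[chunk["p"].idxmin()]
            loci.append(
                Locus(
                    locus_id=len(loci),
                    chrom=str(chrom),
                    start=int(chunk["pos"].min()),
                    end=int(chunk["pos"].max()),
                    members=chunk[["snp_id", "pos", "sdp_id", "p", "cls"]].reset_index(drop=True),
                    n_significant=int((chunk["cls"] == "significant").sum()),
                    n_suggestive=int((chunk["cls"] == "suggestive").sum()),
                    top_snp=str(top["snp_id"]),
                    top_p=float(top["p"]),
                )
            )
    # annotate cross-chromosome identical-SDP links
    for i, a in enumerate(loci):
        for j, b in enumerate(loci):
            if j <= i or a.chrom == b.chrom:
                continue
            if set(a.members["sdp_id"]) & set(b.members["sdp_id"]):
                a.linked_loci.append(b.locus_id)
                b.linked_loci.append(a.locus_id)
    return loci


def loci_table(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": l.locus_id,
            "chrom": l.chrom,
            "start": l.start,
            "end": l.end,
            "n_sig": l.n_significant,
            "n_sug": l.n_suggestive,
            "top_snp": l.top_snp,
            "top_p": l.top_p,
            "linked_loci": ",".join(map(str, l.linked_loci)),
        }
        for l in loci
    ]
    return pd.DataFrame(
        rows,
        columns=["locus_id", "chrom", "start", "end", "n_sig", "n_sug",
                 "top_snp", "top_p", "linked_loci"],
    )
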