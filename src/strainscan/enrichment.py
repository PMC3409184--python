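"""Validation statistics: expression enrichment near hits and replication.

Two independent lines of evidence support a set of mapped loci.  First, if
loci for cardiac traits are real, genes near the associated SNPs should be
expressed in the heart more often than genes genome-wide; expressed genes
are defined by fitting a two-component Gaussian mixture to the bimodal log
expression distribution and thresholding on posterior membership in the
high component.  Second, loci should replicate: re-scanning the same SDPs
against independent phenotype panels should clear a nominal significance
level far more often than chance.  Both excesses are scored with exact
one-sided binomial tail tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import (
    GenotypeMatrix,
    KinshipMatrix,
    collapse_sdps,
    filter_informative,
    kinship_ibs,
)
from .mixed_model import ScanEngine, fit_null, make_spec

DEFAULT_CONFIDENCE = 0.95
DEFAULT_WINDOW = 500_000
DEFAULT_MIN_SHARED_STRAINS = 19


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Two-component Gaussian mixture on log expression
# ---------------------------------------------------------------------------

@dataclass
class MixtureModel:
    """EM-fitted two-component Gaussian mixture, canonicalized m1 < m2."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    flagged: bool = False  # degenerate fit (vanishing weight or sd floor)
    expressed_cutoff: Optional[float] = None
    nonexpressed_cutoff: Optional[float] = None

    def posterior_high(self, x) -> np.ndarray:
        """Posterior probability of the high-mean component at x."""
        x = np.asarray(x, float)
        log_p = np.stack(
            [
                np.log(self.weights[k]) + stats.norm.logpdf(x, self.means[k], self.sds[k])
                for k in (0, 1)
            ]
        )
        m = log_p.max(axis=0)
        return np.exp(log_p[1] - m) / np.exp(log_p - m).sum(axis=0)


def fit_mixture2(
    log_expr,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: Optional[int] = None,
) -> MixtureModel:
    """Fit a two-component Gaussian mixture to log expression values by EM.

    Initialization splits the sample at its median (quantile split): the two
    halves provide starting means/sds and equal weights.  Convergence is
    declared when the log-likelihood gain drops below ``tol``; hitting
    ``max_iter`` first returns a model flagged unconverged.  Components are
    canonicalized so means[0] < means[1], making the fit invariant to label
    swaps.  ``seed`` is accepted for interface uniformity; the EM itself is
    deterministic given the data.
    """
    x = np.asarray(log_expr, float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise EnrichmentError("need at least 10 expression values")
    lo, hi = x[x <= np.median(x)], x[x > np.median(x)]
    means = np.array([lo.mean(), hi.mean()])
    sds = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])
    weights = np.array([0.5, 0.5])
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_p = np.stack(
            [np.log(weights[k]) + stats.norm.logpdf(x, means[k], sds[k]) for k in (0, 1)]
        )
        m = log_p.max(axis=0)
        ll = float(np.sum(m + np.log(np.exp(log_p - m).sum(axis=0))))
        resp = np.exp(log_p - m) / np.exp(log_p - m).sum(axis=0)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        means = (resp @ x) / nk
        sds = np.sqrt(np.maximum((resp @ x**2) / nk - means**2, 1e-12))
        sds = np.maximum(sds, 1e-6)
        weights = nk / x.size
        if ll - prev < tol and n_iter > 1:
            converged = True
            prev = ll
            break
        prev = ll
    order = np.argsort(means)
    flagged = bool(weights.min() < 1e-3 or sds.min() <= 1e-6 or not converged)
    return MixtureModel(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik=float(prev),
        n_iter=n_iter,
        converged=converged,
        flagged=flagged,
    )


def expression_cutoffs(
    model: MixtureModel, confidence: float = DEFAULT_CONFIDENCE
) -> tuple[float, float]:
    """Posterior-confidence cutoffs separating expressed / non-expressed genes.

    ``expressed_cutoff`` is the smallest x whose posterior membership in the
    high component reaches ``confidence``; ``nonexpressed_cutoff`` the
    largest x whose membership in the low component does.  Values between the
    two are ambiguous.  Solved by bracketed root finding; requires the
    posterior to be monotone over the bracket (violated only for extreme sd
    ratios, reported as an error).
    """
    if not 0.5 < confidence < 1:
        raise EnrichmentError("confidence must be in (0.5, 1)")
    m1, m2 = model.means
    s1, s2 = model.sds

    # With unequal sds the log posterior odds are quadratic in x, so the
    # wider component also dominates the far tail on the narrow side.  The
    # posterior is monotone increasing only between its stationary point x*
    # and the dominated tail; restrict both solves to that region.
    lo, hi = m1 - 6 * s1, m2 + 6 * s2
    if abs(s1 - s2) > 1e-12:
        x_star = (m1 / s1**2 - m2 / s2**2) / (1 / s1**2 - 1 / s2**2)
        if s1 < s2:
            lo = max(lo, x_star)  # posterior dips to a minimum at x*
        else:
            hi = min(hi, x_star)  # posterior peaks at x*

    def solve(target: float, a: float, b: float) -> float:
        grid = np.linspace(a, b, 512)
        post = model.posterior_high(grid)
        if np.any(np.diff(post) < -1e-9):
            raise EnrichmentError(
                "posterior of the high component is not monotone on the solve "
                "bracket; cutoffs are ill-defined for this sd ratio"
            )
        f = lambda x: float(model.posterior_high(x)) - target
        if f(a) * f(b) > 0:
            raise EnrichmentError(
                f"confidence level {target:.3f} unreachable within [{a:.3g}, {b:.3g}]"
            )
        return float(optimize.brentq(f, a, b, xtol=1e-12))

    expressed = solve(confidence, max(lo, m1), hi)
    nonexpressed = solve(1 - confidence, lo, min(hi, m2))
    model.expressed_cutoff = expressed
    model.nonexpressed_cutoff = nonexpressed
    return expressed, nonexpressed


def classify_expression(genes: pd.DataFrame, model: MixtureModel,
                        confidence: float = DEFAULT_CONFIDENCE) -> pd.DataFrame:
    """Label each gene expressed / ambiguous / non_expressed by cutoff."""
    if model.expressed_cutoff is None:
        expression_cutoffs(model, confidence)
    out = genes.copy()
    x = out["log_expr"].to_numpy(float)
    out["expression_class"] = np.where(
        x > model.expressed_cutoff,
        "expressed",
        np.where(x < model.nonexpressed_cutoff, "non_expressed", "ambiguous"),
    )
    return out


# ---------------------------------------------------------------------------
# Window genes and binomial enrichment
# ---------------------------------------------------------------------------

def genes_near_hits(genes: pd.DataFrame, hits: pd.DataFrame,
                    window: int = DEFAULT_WINDOW) -> set[str]:
    """Genes whose interval intersects a +/- window around any hit SNP.

    ``genes`` needs columns (gene_id, chrom, start, end); ``hits`` needs
    (chrom, pos).  Intervals are closed and 1-based on both sides, so a gene
    ending exactly at ``pos - window`` is included.  The result is a
    de-duplicated set of gene_ids.
    """
    selected: set[str] = set()
    if len(hits) == 0:
        return selected
    for chrom, hsub in hits.groupby("chrom"):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        gs = gsub["start"].to_numpy(np.int64)
        ge = gsub["end"].to_numpy(np.int64)
        for pos in hsub["pos"].to_numpy(np.int64):
            overlap = (ge >= pos - window) & (gs <= pos + window)
            selected.update(gsub.loc[overlap, "gene_id"])
    return selected


def binomial_enrichment(k: int, n: int, p0: float, side: str = "upper") -> float:
    """Exact binomial tail probability by direct summation of the pmf.

    ``side='upper'`` returns P(X >= k) under Binomial(n, p0) — the one-sided
    enrichment test; ``'two'`` doubles the smaller tail, capped at 1.
    """
    if not 0 <= k <= n:
        raise EnrichmentError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise EnrichmentError("p0 must be in (0, 1)")
    upper = float(np.sum(stats.binom.pmf(np.arange(k, n + 1), n, p0)))
    if side == "upper":
        return min(upper, 1.0)
    if side == "two":
        lower = float(np.sum(stats.binom.pmf(np.arange(0, k + 1), n, p0)))
        return min(1.0, 2 * min(upper, lower))
    raise EnrichmentError(f"unknown side {side!r}")


@dataclass
class EnrichmentReport:
    n_window_genes: int
    n_window_expressed: int
    window_fraction: float
    background_fraction: float
    p_value: float


def expression_enrichment(
    genes: pd.DataFrame,
    model: MixtureModel,
    hits: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    confidence: float = DEFAULT_CONFIDENCE,
    side: str = "upper",
) -> EnrichmentReport:
    """Are genes near hit SNPs expressed more often than genes overall?

    The background rate is the expressed fraction among all probed genes
    (window genes are not removed from the background).  Tested with the
    exact one-sided binomial tail.
    """
    labeled = classify_expression(genes, model, confidence)
    background = float((labeled["expression_class"] == "expressed").mean())
    near = genes_near_hits(labeled, hits, window)
    sub = labeled[labeled["gene_id"].isin(near)]
    k = int((sub["expression_class"] == "expressed").sum())
    n = len(sub)
    if n == 0:
        raise EnrichmentError("no genes fall in the hit windows")
    p = binomial_enrichment(k, n, background, side=side)
    return EnrichmentReport(
        n_window_genes=n,
        n_window_expressed=k,
        window_fraction=k / n,
        background_fraction=background,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationRecord:
    locus_id: int
    dataset: str
    testable: bool
    best_p: Optional[float] = None
    corrected_p: Optional[float] = None
    replicated: Optional[bool] = None


@dataclass
class ReplicationSummary:
    records: list[ReplicationRecord]
    n_testable: int
    n_replicated: int
    replication_fraction: float
    lam: float
    p_value: float


def replicate_loci(
    primary_loci: Sequence,
    rep_genotypes: GenotypeMatrix,
    rep_phenotypes: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    gc_correct: bool = True,
    dataset: str = "replication",
    min_shared_strains: int = DEFAULT_MIN_SHARED_STRAINS,
    primary_strains: Optional[Sequence[str]] = None,
    min_called: Optional[int] = None,
    min_minor_strains: int = 4,
    K: Optional[KinshipMatrix] = None,
) -> ReplicationSummary:
    """Re-test primary loci against an independent phenotype panel.

    The replication panel is scanned with the same mixed model over its own
    SDPs; each primary locus is looked up by the snp_ids of its member
    markers.  Scan-wide genomic inflation is estimated from all replication
    p-values and, when ``gc_correct``, each test's chi-square is divided by
    lambda before conversion to a p-value (genomic control).  A locus
    replicates when its best corrected member p-value is <= ``alpha``; loci
    whose markers are absent or degenerate in the replication panel drop out
    of the testable denominator.  The summary p-value is the exact binomial
    tail for the observed replication count at chance rate ``alpha``.
    """
    if primary_strains is not None:
        shared = set(primary_strains) & set(rep_genotypes.strains)
        if len(shared) < min_shared_strains:
            raise EnrichmentError(
                f"replication panel shares only {len(shared)} strains with the "
                f"primary panel (need >= {min_shared_strains})"
            )
    mc = min_called if min_called is not None else max(rep_genotypes.n_strains - 2, 2)
    G = filter_informative(rep_genotypes, mc, min_minor_strains)
    sdps = collapse_sdps(G)
    if K is None:
        K = kinship_ibs(G)
    spec = make_spec(rep_phenotypes, trait, K, meta={"dataset": dataset})
    vc = fit_null(spec)
    scan = ScanEngine(spec, sdps).scan(vc, meta={"dataset": dataset})
    snps = scan.snp_table()
    snps = snps[snps["flag"] != "degenerate"]
    lam = _lambda_from(snps["p"].to_numpy(float))
    by_snp = snps.set_index("snp_id")["p"]

    records: list[ReplicationRecord] = []
    for locus in primary_loci:
        member_ids = [str(s) for s in locus.members["snp_id"]]
        ps = by_snp.loc[by_snp.index.intersection(member_ids)]
        if ps.empty:
            records.append(ReplicationRecord(locus.locus_id, dataset, testable=False))
            continue
        best = float(ps.min())
        corrected = gc_corrected_p(best, lam) if gc_correct else best
        records.append(
            ReplicationRecord(
                locus_id=locus.locus_id,
                dataset=dataset,
                testable=True,
                best_p=best,
                corrected_p=corrected,
                replicated=corrected <= alpha,
            )
        )
    testable = [r for r in records if r.testable]
    n_rep = sum(bool(r.replicated) for r in testable)
    p = binomial_enrichment(n_rep, len(testable), alpha) if testable else 1.0
    return ReplicationSummary(
        records=records,
        n_testable=len(testable),
        n_replicated=n_rep,
        replication_fraction=(n_rep / len(testable)) if testable else 0.0,
        lam=lam,
        p_value=p,
    )


def _lambda_from(pvals: np.ndarray) -> float:
    chi2 = stats.chi2.isf(np.clip(pvals, np.finfo(float).tiny, 1.0), 1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


def gc_corrected_p(p: float, lam: float) -> float:
    """Genomic-control correction: divide the 1-df chi-square by lambda."""
    if lam <= 0:
        raise EnrichmentError("lambda must be positive")
    chi2 = stats.chi2.isf(max(p, np.finfo(float).tiny), 1)
    return float(stats.chi2.sf(chi2 / lam, 1))
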