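"""Synthetic strain panels, replicated treatment phenotypes and expression.

The generators emulate the statistical regime of a classical inbred-strain
pharmacogenetic panel: ~22 strains falling into a handful of ancestral
haplotype groups (long LD, megabase-scale shared blocks), eight to ten
biological replicates per strain and treatment arm, trait heritabilities
above 0.5 with sparse large-effect QTLs, a few percent missing genotype
calls, and a bimodal log-expression distribution whose components peak near
2 (non-expressed) and 6.5 (expressed genes).

One master seed drives everything; each generator derives its own stage seed
from a stable hash of the stage name, so stages are independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, KinshipMatrix, kinship_ibs
from .phenotypes import DEFAULT_TREATMENTS

_ALLELE_CHARS = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass
class QtlEffect:
    """One injected causal variant: allele effect on a trait, optionally
    restricted to a single treatment arm."""

    snp: int
    trait: str
    effect: float
    treatment: Optional[str] = None  # None = all arms


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic panel."""

    n_strains: int = 22
    n_snps: int = 2000
    n_clusters: int = 6
    n_chromosomes: int = 5
    block_len: int = 50            # SNPs per shared haplotype block
    flip_rate: float = 0.05        # within-cluster allele flips
    mean_spacing_bp: int = 30_000
    missing_rate: float = 0.03
    reps_per_cell: int = 9         # emulates eight to ten biological replicates
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    traits: tuple[str, ...] = tuple(f"trait{i:02d}" for i in range(1, 28))
    h2: float = 0.6
    baseline_mean: float = 10.0   # keeps trait values positive (fold changes)
    treatment_effect_sd: float = 0.5
    qtl_spec: list[QtlEffect] = field(default_factory=list)
    # (weight, mean, sd) per expression mixture component; ~55% of genes
    # expressed, components peaking near 2 and 6.5
    mixture_spec: tuple[tuple[float, float, float], ...] = (
        (0.45, 2.0, 0.5),
        (0.55, 6.5, 1.0),
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_strains:
            raise SimulationError("n_clusters cannot exceed n_strains")
        for p, name in ((self.missing_rate, "missing_rate"), (self.flip_rate, "flip_rate")):
            if not 0 <= p <= 1:
                raise SimulationError(f"{name} must be a probability")
        if not 0 <= self.h2 <= 1:
            raise SimulationError("h2 must lie in [0, 1]")
        w = sum(w for w, _, _ in self.mixture_spec)
        if abs(w - 1) > 1e-9:
            raise SimulationError("mixture weights must sum to 1")
        if any(sd <= 0 for _, _, sd in self.mixture_spec):
            raise SimulationError("mixture sds must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.master_seed, zlib.crc32(stage.encode())])
        )


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

def simulate_panel(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate a strain panel with cluster-shared haplotype blocks.

    Strains are assigned to ``n_clusters`` ancestral groups.  The genome is
    tiled by blocks of ``block_len`` consecutive SNPs; within a block each
    cluster carries one of two ancestral haplotypes, so all SNPs of a block
    share one strain distribution pattern up to within-cluster flips.  This
    reproduces the long-LD, low-diversity regime of classical inbred panels
    and gives the kinship matrix pronounced off-diagonal structure.
    """
    rng = cfg.rng("panel")
    n, m = cfg.n_strains, cfg.n_snps
    cluster = np.sort(rng.integers(0, cfg.n_clusters, size=n))
    calls = np.empty((m, n), dtype=np.int8)
    n_blocks = int(np.ceil(m / cfg.block_len))
    for b in range(n_blocks):
        lo, hi = b * cfg.block_len, min((b + 1) * cfg.block_len, m)
        hap_of_cluster = rng.integers(0, 2, size=cfg.n_clusters)
        hapA = rng.integers(0, 2, size=hi - lo).astype(np.int8)
        strain_hap = hap_of_cluster[cluster]  # 0 -> hapA, 1 -> complement
        block = np.where(strain_hap[None, :] == 0, hapA[:, None], 1 - hapA[:, None])
        calls[lo:hi] = block
    if cfg.flip_rate > 0:
        flips = rng.random((m, n)) < cfg.flip_rate
        calls = np.where(flips, 1 - calls, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        calls = np.where(rng.random((m, n)) < cfg.missing_rate, np.int8(-1), calls)

    # coordinates: SNPs split across chromosomes, strictly increasing positions
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    chroms, pos = [], []
    for c, cnt in enumerate(per_chrom, start=1):
        gaps = rng.integers(1, 2 * cfg.mean_spacing_bp, size=cnt)
        pos.append(np.cumsum(gaps))
        chroms.extend([f"chr{c}"] * cnt)
    pos = np.concatenate(pos) if pos else np.array([], dtype=np.int64)

    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    return GenotypeMatrix(
        strains=[f"S{i + 1:02d}" for i in range(n)],
        snp_id=np.array([f"rs{i + 1:06d}" for i in range(m)], dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=pos,
        calls=calls,
        alleles=_ALLELE_CHARS[allele_idx],
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    G: GenotypeMatrix, cfg: SimConfig, K: Optional[KinshipMatrix] = None
) -> pd.DataFrame:
    """Replicated treatment phenotypes with strain-structured heritability.

    Each animal's value decomposes as

        baseline mean            (constant; keeps values positive so that
                                  fold-change effects are well defined)
      + strain polygenic effect  ~ MVN(0, h2 * K)   (per trait)
      + treatment main effect    (per trait x arm, sd ``treatment_effect_sd``)
      + QTL allele effect        (minor-allele count x effect, optionally
                                  treatment-specific, constant across a
                                  strain's replicates)
      + residual noise           ~ N(0, 1 - h2)   (per animal)

    so the strain-level heritability of a QTL-free trait is h2 by
    construction.  Missing genotype calls contribute the major allele to the
    QTL term.
    """
    rng = cfg.rng("phenotypes")
    if K is None:
        K = kinship_ibs(G)
    if K.strains != G.strains:
        raise SimulationError("kinship strains do not match the panel")
    for q in cfg.qtl_spec:
        if not 0 <= q.snp < G.n_snps:
            raise SimulationError(f"qtl_spec references absent SNP {q.snp}")
        if q.trait not in cfg.traits:
            raise SimulationError(f"qtl_spec references absent trait {q.trait!r}")
        if q.treatment is not None and q.treatment not in cfg.treatments:
            raise SimulationError(f"qtl_spec references absent treatment {q.treatment!r}")

    n = cfg.n_strains
    # IBS similarity is not guaranteed PSD; clip tiny negative eigenvalues
    w, U = np.linalg.eigh(K.K)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    sg = np.sqrt(cfg.h2)
    se = np.sqrt(1.0 - cfg.h2)
    rows = []
    polygenic = {t: sg * (L @ rng.standard_normal(n)) for t in cfg.traits}
    arm_effect = {
        (t, a): (0.0 if a == cfg.treatments[0] else rng.normal(0, cfg.treatment_effect_sd))
        for t in cfg.traits
        for a in cfg.treatments
    }
    from .genotypes import minor_patterns

    patterns, _ = minor_patterns(G)
    for si, strain in enumerate(G.strains):
        for arm in cfg.treatments:
            for rep in range(cfg.reps_per_cell):
                rec = {
                    "animal_id": f"{strain}_{arm}_{rep + 1}",
                    "strain": strain,
                    "treatment": arm,
                }
                for t in cfg.traits:
                    val = cfg.baseline_mean + polygenic[t][si] + arm_effect[(t, arm)]
                    val += se * rng.standard_normal()
                    rec[t] = val
                rows.append(rec)
    P = pd.DataFrame(rows)
    for q in cfg.qtl_spec:
        allele = np.maximum(patterns[q.snp], 0)  # missing -> major
        dose = pd.Series(allele, index=G.strains).loc[P["strain"]].to_numpy(float)
        mask = np.ones(len(P), dtype=bool)
        if q.treatment is not None:
            mask = (P["treatment"] == q.treatment).to_numpy()
        P.loc[mask, q.trait] = P.loc[mask, q.trait] + q.effect * dose[mask]
    return P


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(n_genes: int, cfg: SimConfig) -> pd.DataFrame:
    """Gene records with log-expression drawn from the configured mixture.

    Returns columns (gene_id, chrom, start, end, log_expr, component); the
    true component label (0-based, ordered by mean) is retained so mixture
    recovery can be tested.
    """
    if n_genes < 2:
        raise SimulationError("need at least two genes")
    comps = sorted(cfg.mixture_spec, key=lambda c: c[1])
    if len(comps) != 2:
        raise SimulationError("expression mixture must have two components")
    rng = cfg.rng("expression")
    weights = np.array([c[0] for c in comps])
    labels = rng.choice(len(comps), size=n_genes, p=weights)
    means = np.array([c[1] for c in comps])
    sds = np.array([c[2] for c in comps])
    values = rng.normal(means[labels], sds[labels])
    chrom = rng.integers(1, cfg.n_chromosomes + 1, size=n_genes)
    start = rng.integers(1, cfg.n_snps * cfg.mean_spacing_bp + 1, size=n_genes)
    length = rng.integers(2_000, 100_000, size=n_genes)
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:05d}" for i in range(n_genes)],
            "chrom": [f"chr{c}" for c in chrom],
            "start": start,
            "end": start + length,
            "log_expr": values,
            "component": labels,
        }
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
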