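"""End-to-end orchestration of the strain-panel association workflow.

Stage order: informativeness filter -> SDP collapse -> kinship -> per-scan
null REML fit and SDP association scan (raw traits per treatment arm, then
inferred drug effects per contrast after the variance screen) -> QQ/lambda
QC -> thresholds (fixed or calibrated from effective test counts) -> hit
classification, locus grouping and surrogate imputation -> optional
expression enrichment.  Every run directory carries a machine-readable
manifest naming the configuration hash and master seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import enrichment as enr
from . import genotypes as gt
from . import io as sio
from . import mixed_model as mm
from . import phenotypes as ph

logger = logging.getLogger("strainscan")


@dataclass
class PipelineConfig:
    """Run parameters of one analysis; loadable from YAML."""

    genotypes: str
    phenotypes: str
    expression: Optional[str] = None
    strain_include: Optional[list[str]] = None
    treatments: list[str] = field(default_factory=lambda: list(ph.DEFAULT_TREATMENTS))
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("ate", "ctr"), ("iso10", "ctr"), ("iso10", "ate")]
    )
    traits: Optional[list[str]] = None
    min_called: int = gt.DEFAULT_MIN_CALLED
    min_minor_strains: int = gt.DEFAULT_MIN_MINOR_STRAINS
    alpha: float = cal.DEFAULT_ALPHA
    thresholds: str = "fixed"  # "fixed" (strict/suggestive below) or "calibrate"
    strict_p: float = 1e-8
    suggestive_p: float = 1e-6
    n_perm: int = cal.DEFAULT_N_PERM
    variance_fraction: float = cal.DEFAULT_VARIANCE_FRACTION
    lambda_bounds: tuple[float, float] = cal.DEFAULT_LAMBDA_BOUNDS
    excess_ratio_max: float = cal.DEFAULT_EXCESS_RATIO
    qc_override_pass: list[str] = field(default_factory=list)
    k_sd: float = ph.DEFAULT_K_SD
    merge_distance: int = cal.DEFAULT_MERGE_DISTANCE
    surrogate_distance: int = gt.DEFAULT_SURROGATE_DISTANCE
    window: int = enr.DEFAULT_WINDOW
    confidence: float = enr.DEFAULT_CONFIDENCE
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        cfg.lambda_bounds = tuple(cfg.lambda_bounds)
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScanRecord:
    name: str
    kind: str  # "trait" | "effect"
    qc_passed: bool
    screen_passed: bool
    lam: float
    h2: float
    n_hits: int


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Execute the full workflow; returns the run directory.

    Any stage failure aborts with the stage name in the exception while
    leaving previously written outputs intact.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        G = sio.read_genotypes(cfg.genotypes)
        P = sio.read_phenotypes(cfg.phenotypes, treatments=cfg.treatments)
        if cfg.strain_include:
            keep = [s for s in G.strains if s in set(cfg.strain_include)]
            idx = [G.strains.index(s) for s in keep]
            G = gt.GenotypeMatrix(
                strains=keep, snp_id=G.snp_id, chrom=G.chrom, pos=G.pos,
                calls=G.calls[:, idx], alleles=G.alleles,
            )
            P = P[P["strain"].isin(keep)].reset_index(drop=True)
        traits = cfg.traits or ph.trait_columns(P)

        stage = "filter"
        Gf = gt.filter_informative(G, cfg.min_called, cfg.min_minor_strains)
        logger.info("filter: %d of %d SNPs informative", Gf.n_snps, G.n_snps)

        stage = "sdp"
        sdps = gt.collapse_sdps(Gf)
        sio.write_sdp_table(sdps, out / "sdps.tsv")

        stage = "kinship"
        K = gt.kinship_ibs(Gf)

        stage = "scan"
        scans: dict[str, mm.ScanResult] = {}
        records: list[ScanRecord] = []
        heritability: dict[str, float] = {}
        jobs: list[tuple[str, str, pd.DataFrame, str]] = []
        for trait in traits:
            for arm in cfg.treatments:
                sub = P[P["treatment"] == arm]
                jobs.append((f"{trait}__{arm}", "trait", sub, trait))
            for treated, ref in cfg.contrasts:
                eff = ph.drug_effects(P, trait, treated, ref)
                frame = ph.effects_to_phenotype_frame(eff)
                jobs.append((f"{trait}__{treated}_vs_{ref}", "effect", frame, trait))
        for name, kind, frame, trait in jobs:
            screen = ph.variance_screen(frame, trait, cfg.k_sd)
            spec = mm.make_spec(frame, trait, K, meta={"scan": name})
            vc = mm.fit_null(spec)
            heritability[name] = vc.h2
            engine = mm.ScanEngine(spec, sdps)
            scan = engine.scan(vc, meta={"scan": name})
            scans[name] = scan
            qc = cal.qc_scan(
                scan.pvalues, cfg.lambda_bounds, cfg.excess_ratio_max
            )
            qc_ok = qc.passed or name in cfg.qc_override_pass
            if vc.boundary:
                logger.warning("scan %s: REML delta at search boundary", name)
            records.append(
                ScanRecord(name, kind, qc_ok, screen.passed, qc.lam, vc.h2, 0)
            )
            sio.write_scan(scan, out / f"scan_{name}.tsv")
            sio.write_qq(cal.qq_data(scan.pvalues), out / f"qq_{name}.tsv")

        stage = "thresholds"
        passed = [r for r in records if r.qc_passed]
        n_scans = max(len(passed), 1)
        if cfg.thresholds == "calibrate":
            n_eff_pheno = cal.effective_pheno_tests(
                P[traits], cfg.variance_fraction
            )
            first = P[P["treatment"] == cfg.treatments[0]]
            spec0 = mm.make_spec(first, traits[0], K)
            n_eff_geno, _ = cal.effective_geno_tests(
                spec0, sdps, cfg.n_perm, seed=cfg.master_seed
            )
            strict = cal.bonferroni_threshold(len(sdps), n_scans, cfg.alpha)
            sugg = cal.suggestive_threshold(n_eff_pheno, n_eff_geno, cfg.alpha)
            sugg = max(sugg, strict)
        else:
            strict, sugg = cfg.strict_p, cfg.suggestive_p
            n_eff_pheno = n_eff_geno = 1
        thresholds = cal.ThresholdSet(
            alpha=cfg.alpha, strict_p=strict, suggestive_p=sugg,
            n_sdps=len(sdps), n_scans=n_scans,
            n_eff_pheno=n_eff_pheno, n_eff_geno=n_eff_geno,
        )
        sio.write_thresholds(thresholds, out / "thresholds.json")

        stage = "loci"
        sdp_by_id = {s.sdp_id: s for s in sdps}
        all_loci: dict[str, list[cal.Locus]] = {}
        excluded = []
        for rec in records:
            if not (rec.qc_passed and rec.screen_passed):
                excluded.append(rec.name)
                continue
            loci = cal.classify_and_group(scans[rec.name], thresholds, cfg.merge_distance)
            rec.n_hits = sum(l.n_significant + l.n_suggestive for l in loci)
            all_loci[rec.name] = loci
            sio.write_loci(loci, out / f"loci_{rec.name}.tsv")
            corrections = []
            for locus in loci:
                for sdp_id in sorted(set(locus.members["sdp_id"])):
                    sdp = sdp_by_id[int(sdp_id)]
                    if sdp.is_full:
                        continue
                    corr = gt.impute_from_surrogate(
                        sdp, scans[rec.name], sdps, cfg.surrogate_distance
                    )
                    corrections.append({"locus_id": locus.locus_id, **corr.__dict__})
            if corrections:
                pd.DataFrame(corrections).to_csv(
                    out / f"corrections_{rec.name}.tsv", sep="\t",
                    index=False, lineterminator="\n",
                )

        stage = "enrichment"
        if cfg.expression is not None:
            genes = sio.read_expression(cfg.expression)
            model = enr.fit_mixture2(genes["log_expr"].to_numpy())
            enr.expression_cutoffs(model, cfg.confidence)
            hits = _hit_positions(all_loci)
            if len(hits):
                report = enr.expression_enrichment(
                    genes, model, hits, cfg.window, cfg.confidence
                )
                (out / "enrichment.json").write_text(
                    json.dumps(report.__dict__, indent=2) + "\n", encoding="utf-8"
                )

        stage = "manifest"
        summary = pd.DataFrame([r.__dict__ for r in records])
        summary.to_csv(out / "scans.tsv", sep="\t", index=False, lineterminator="\n")
        manifest = {
            "config_hash": cfg.content_hash(),
            "master_seed": cfg.master_seed,
            "n_snps_informative": Gf.n_snps,
            "n_sdps": len(sdps),
            "n_scans_total": len(records),
            "n_scans_passed_qc": len(passed),
            "excluded_scans": excluded,
            "heritability": heritability,
            "versions": _versions(),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _hit_positions(all_loci: dict[str, list[cal.Locus]]) -> pd.DataFrame:
    rows = []
    for loci in all_loci.values():
        for locus in loci:
            for _, m in locus.members.iterrows():
                rows.append({"chrom": locus.chrom, "pos": int(m["pos"])})
    return pd.DataFrame(rows, columns=["chrom", "pos"]).drop_duplicates()


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {
        "strainscan": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
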