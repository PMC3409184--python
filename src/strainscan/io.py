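"""Plain-text file dialects: genotype TSV, phenotype CSV, expression TSV.

All readers validate strictly and report the offending line number; all
writers emit canonical text so that write -> read -> write is byte-stable.

Genotype TSV: header ``snp_id  chr  pos`` followed by one column per strain;
calls are observed allele characters, missing is ``NA``.  Major/minor
recoding is internal, per SNP.

Phenotype CSV: header ``animal_id,strain,treatment`` plus one column per
trait; decimal point, no thousands separators.

Expression TSV: BED-like but 1-based inclusive (documented deviation from
BED), columns ``chrom  start  end  gene_id  log_expr``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .calibration import Locus, ThresholdSet, loci_table
from .genotypes import MISSING, SDP, GenotypeMatrix
from .mixed_model import ScanResult
from .phenotypes import ID_COLUMNS, validate_phenotypes

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file; the message carries the 1-based line number."""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes(G: GenotypeMatrix, path: PathLike) -> None:
    chars = G.char_calls()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["snp_id", "chr", "pos", *G.strains]) + "\n")
        for i in range(G.n_snps):
            row = [str(G.snp_id[i]), str(G.chrom[i]), str(int(G.pos[i]))]
            row.extend("NA" if c == "N" else c for c in chars[i])
            fh.write("\t".join(row) + "\n")


def read_genotypes(path: PathLike) -> GenotypeMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["snp_id", "chr", "pos"]:
            raise FormatError(f"{path}:1: header must start with snp_id, chr, pos")
        strains = header[3:]
        if not strains:
            raise FormatError(f"{path}:1: no strain columns")
        snp_id, chrom, pos = [], [], []
        calls_rows, allele_rows = [], []
        seen_pos: dict[str, int] = {}
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + len(strains):
                raise FormatError(f"{path}:{ln}: expected {3 + len(strains)} fields")
            sid, chm, p = parts[0], parts[1], parts[2]
            try:
                p = int(p)
            except ValueError:
                raise FormatError(f"{path}:{ln}: position {p!r} is not an integer")
            if chm in seen_pos and p < seen_pos[chm]:
                raise FormatError(f"{path}:{ln}: unsorted position on {chm}")
            seen_pos[chm] = p
            obs = parts[3:]
            alleles: list[str] = []
            codes = np.empty(len(strains), dtype=np.int8)
            for j, c in enumerate(obs):
                if c == "NA":
                    codes[j] = MISSING
                    continue
                if len(c) != 1:
                    raise FormatError(f"{path}:{ln}: bad call {c!r}")
                if c not in alleles:
                    alleles.append(c)
                    if len(alleles) > 2:
                        raise FormatError(
                            f"{path}:{ln}: more than two alleles observed ({alleles})"
                        )
                codes[j] = alleles.index(c)
            if not alleles:
                alleles = ["A"]
            if len(alleles) == 1:
                alleles.append("N")  # placeholder; never written back
            snp_id.append(sid)
            chrom.append(chm)
            pos.append(p)
            calls_rows.append(codes)
            allele_rows.append(alleles[:2])
    return GenotypeMatrix(
        strains=strains,
        snp_id=np.array(snp_id, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        calls=np.stack(calls_rows) if calls_rows else np.empty((0, len(strains)), np.int8),
        alleles=np.array(allele_rows, dtype="<U1") if allele_rows else np.empty((0, 2), "<U1"),
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(P: pd.DataFrame, path: PathLike) -> None:
    cols = ID_COLUMNS + [c for c in P.columns if c not in ID_COLUMNS]
    P[cols].to_csv(path, index=False, lineterminator="\n")


def read_phenotypes(path: PathLike,
                    treatments: Sequence[str] | None = None) -> pd.DataFrame:
    P = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ID_COLUMNS if c not in P.columns]
    if missing:
        raise FormatError(f"{path}:1: phenotype header lacks {missing}")
    dup = P["animal_id"][P["animal_id"].duplicated()]
    if len(dup):
        first = P.index[P["animal_id"] == dup.iloc[0]][0]
        raise FormatError(
            f"{path}:{first + 2}: duplicate animal_id {dup.iloc[0]!r}"
        )
    if treatments is not None:
        bad = ~P["treatment"].isin(list(treatments))
        if bad.any():
            ln = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise FormatError(
                f"{path}:{ln}: unknown treatment {P.loc[bad, 'treatment'].iloc[0]!r}"
            )
        validate_phenotypes(P, tuple(treatments))
    return P


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_EXPR_HEADER = ["chrom", "start", "end", "gene_id", "log_expr"]


def write_expression(E: pd.DataFrame, path: PathLike) -> None:
    out = E[_EXPR_HEADER].copy()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# coordinates are 1-based inclusive (not BED 0-based)\n")
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_expression(path: PathLike) -> pd.DataFrame:
    E = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _EXPR_HEADER if c not in E.columns]
    if missing:
        raise FormatError(f"{path}: expression header lacks {missing}")
    bad = E["end"] < E["start"]
    if bad.any():
        raise FormatError(
            f"{path}: gene {E.loc[bad, 'gene_id'].iloc[0]!r} has end < start"
        )
    return E


# ---------------------------------------------------------------------------
# Derived outputs
# ---------------------------------------------------------------------------

def write_sdp_table(sdps: Sequence[SDP], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sdp_id\tpattern\tn_members\tmembers\n")
        for s in sdps:
            members = ",".join(m[0] for m in s.members)
            fh.write(f"{s.sdp_id}\t{s.pattern_string()}\t{len(s.members)}\t{members}\n")


def write_scan(scan: ScanResult, path: PathLike) -> None:
    scan.snp_table().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_loci(loci: Sequence[Locus], path: PathLike) -> None:
    loci_table(loci).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_thresholds(t: ThresholdSet, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {
                "alpha": t.alpha,
                "strict_p": t.strict_p,
                "suggestive_p": t.suggestive_p,
                "n_sdps": t.n_sdps,
                "n_scans": t.n_scans,
                "n_eff_pheno": t.n_eff_pheno,
                "n_eff_geno": t.n_eff_geno,
                "neg_log10_strict": -np.log10(t.strict_p),
                "neg_log10_suggestive": -np.log10(t.suggestive_p),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_qq(qq: pd.DataFrame, path: PathLike) -> None:
    qq.to_csv(path, sep="\t", index=False, lineterminator="\n")
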