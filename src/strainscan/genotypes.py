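"""Strain-panel genotype model.

Genotypes are biallelic calls over a fixed, ordered panel of inbred strains.
Because every strain is homozygous, a SNP is summarized by its strain
distribution pattern (SDP): the binary assignment of major/minor allele across
the panel.  SNPs sharing an SDP are statistically indistinguishable in a
strain-level association test and are collapsed into a single test.

Coordinates are 1-based inclusive base pairs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

MISSING: int = -1

# Default informativeness filter, tuned to a 22-strain panel: allele calls
# known in >= 20 strains and minor allele carried by >= 4 strains.
DEFAULT_MIN_CALLED = 20
DEFAULT_MIN_MINOR_STRAINS = 4

#: Default surrogate search radius; LD in classical inbred strains spans
#: roughly a megabase, so a fully-typed proxy is sought within 1 Mb.
DEFAULT_SURROGATE_DISTANCE = 1_000_000


class GenotypeError(ValueError):
    """Raised for malformed genotype data."""


@dataclass
class GenotypeMatrix:
    """Biallelic strain-level calls with genomic coordinates.

    Parameters
    ----------
    strains
        Ordered strain labels; the order is fixed across all SNPs.
    snp_id, chrom, pos
        Per-SNP identifier, chromosome label and 1-based position.
        Positions must be non-decreasing within a chromosome.
    calls
        ``(n_snps, n_strains)`` int8 array of allele indices: 0 and 1 index
        into ``alleles``; :data:`MISSING` (-1) marks a missing call.
    alleles
        ``(n_snps, 2)`` array of single-character allele labels.
    """

    strains: list[str]
    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snp_id), len(self.strains)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.snp_id)} SNPs x {len(self.strains)} strains"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise GenotypeError("calls must be 0, 1 or missing (-1)")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise GenotypeError(f"positions not sorted on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the SNPs selected by ``index``."""
        return GenotypeMatrix(
            strains=list(self.strains),
            snp_id=self.snp_id[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            calls=self.calls[index],
            alleles=self.alleles[index],
        )

    def char_calls(self) -> np.ndarray:
        """Calls as allele characters, with ``'N'`` for missing."""
        out = np.full(self.calls.shape, "N", dtype="<U1")
        for a in (0, 1):
            mask = self.calls == a
            rows = np.nonzero(mask.any(axis=1))[0]
            for i in rows:
                out[i, mask[i]] = self.alleles[i, a]
        return out

    def __eq__(self, other: object) -> bool:  # semantic: same observed alleles
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.strains == other.strains
            and np.array_equal(self.snp_id, other.snp_id)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.char_calls(), other.char_calls())
        )


@dataclass
class SDP:
    """A de-duplicated strain distribution pattern.

    ``pattern`` is the minor-allele indicator over strains; entries under
    ``mask`` (missing calls) are undefined, stored as 0 and excluded from all
    comparisons.  ``members`` lists the SNPs carrying this pattern as
    ``(snp_id, chrom, pos)`` tuples.
    """

    sdp_id: int
    pattern: np.ndarray
    mask: np.ndarray
    members: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pattern.shape != self.mask.shape:
            raise GenotypeError("pattern and mask length mismatch")
        if not self.members:
            raise GenotypeError("SDP must have at least one member SNP")

    @property
    def n_strains(self) -> int:
        return len(self.pattern)

    @property
    def is_full(self) -> bool:
        """True when every strain has a known call."""
        return not self.mask.any()

    def pattern_string(self) -> str:
        """Pattern over ``{0,1,N}`` in strain order."""
        chars = np.where(self.mask, "N", self.pattern.astype(str))
        return "".join(chars)


@dataclass
class KinshipMatrix:
    """Strain-by-strain genetic similarity (allele-sharing fraction).

    Symmetric, unit diagonal, entries in [0, 1].  :meth:`ridged` adds a small
    diagonal ridge so the matrix is safely positive definite when used as the
    covariance of the random genetic effect.
    """

    strains: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.strains)
        if self.K.shape != (n, n):
            raise GenotypeError("kinship shape does not match strain count")
        if not np.allclose(self.K, self.K.T):
            raise GenotypeError("kinship must be symmetric")

    def ridged(self, eps: float = 1e-6) -> np.ndarray:
        """PSD projection plus a diagonal ridge.

        Pairwise-complete IBS matrices with a forced unit diagonal can carry
        small negative eigenvalues (order 1e-3), so negative eigenvalues are
        clipped to zero before the ridge is added.
        """
        w, U = np.linalg.eigh(self.K)
        if w[0] < 0:
            Kp = (U * np.clip(w, 0.0, None)) @ U.T
        else:
            Kp = self.K
        return Kp + eps * np.eye(len(self.strains))

    def subset(self, strains: Sequence[str]) -> "KinshipMatrix":
        idx = [self.strains.index(s) for s in strains]
        return KinshipMatrix(list(strains), self.K[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Minor-allele orientation
# ---------------------------------------------------------------------------

def minor_patterns(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Recode calls to minor-allele indicators.

    Returns ``(patterns, minor_counts)`` where ``patterns`` is an
    ``(n_snps, n_strains)`` int8 array over {0, 1, -1} with 1 marking the
    minor allele, and ``minor_counts`` the number of strains carrying it.

    The minor allele is the less frequent allele among non-missing calls.
    On an exact tie the allele carried by the first called strain in panel
    order is deemed major (a deterministic, documented convention).
    """
    calls = G.calls
    called = calls != MISSING
    n1 = ((calls == 1) & called).sum(axis=1)
    n0 = ((calls == 0) & called).sum(axis=1)
    # minor allele index per SNP
    minor = np.where(n1 < n0, 1, 0).astype(np.int8)
    ties = n1 == n0
    if ties.any():
        for i in np.nonzero(ties)[0]:
            idx = np.nonzero(called[i])[0]
            if idx.size == 0:
                minor[i] = 1
            else:
                # allele of the first called strain is major
                minor[i] = 1 - calls[i, idx[0]]
    patterns = np.where(called, (calls == minor[:, None]).astype(np.int8), MISSING)
    patterns = patterns.astype(np.int8)
    minor_counts = np.where(minor == 1, n1, n0)
    return patterns, minor_counts


# ---------------------------------------------------------------------------
# Informativeness filter
# ---------------------------------------------------------------------------

def filter_informative(
    G: GenotypeMatrix,
    min_called: int = DEFAULT_MIN_CALLED,
    min_minor_strains: int = DEFAULT_MIN_MINOR_STRAINS,
) -> GenotypeMatrix:
    """Retain SNPs with enough known calls and a common enough minor allele.

    A SNP is informative when its allele is known in at least ``min_called``
    strains and at least ``min_minor_strains`` strains carry the minor allele.
    Monomorphic SNPs (no minor allele among called strains) are excluded,
    not an error.
    """
    if min_called > G.n_strains:
        raise GenotypeError("min_called exceeds the number of strains")
    if min_minor_strains < 1:
        raise GenotypeError("min_minor_strains must be >= 1")
    called = (G.calls != MISSING).sum(axis=1)
    _, minor_counts = minor_patterns(G)
    keep = (called >= min_called) & (minor_counts >= min_minor_strains)
    return G.subset_snps(keep)


# ---------------------------------------------------------------------------
# SDP collapsing and compatibility
# ---------------------------------------------------------------------------

def collapse_sdps(G: GenotypeMatrix, merge_masked_into_full: bool = False) -> list[SDP]:
    """Collapse SNPs sharing a strain distribution pattern into SDPs.

    Two SNPs belong to one SDP when their (minor-allele pattern, missing
    mask) pairs are identical; patterns equal on jointly observed strains but
    with different masks count as distinct SDPs by default.  With
    ``merge_masked_into_full=True`` an incomplete SDP is merged into a
    fully-called SDP whose pattern it is compatible with, when at least one
    exists (ties go to the full SDP with the most member SNPs, then the one
    encountered first).

    Association statistics are computed once per SDP and broadcast to its
    member SNPs.
    """
    patterns, _ = minor_patterns(G)
    masks = patterns == MISSING
    canon = np.where(masks, np.int8(2), patterns).astype(np.int8)
    groups: dict[bytes, SDP] = {}
    for i in range(G.n_snps):
        key = canon[i].tobytes()
        member = (str(G.snp_id[i]), str(G.chrom[i]), int(G.pos[i]))
        if key in groups:
            groups[key].members.append(member)
        else:
            groups[key] = SDP(
                sdp_id=len(groups),
                pattern=np.where(masks[i], 0, patterns[i]).astype(np.int8),
                mask=masks[i].copy(),
                members=[member],
            )
    sdps = list(groups.values())
    if merge_masked_into_full:
        full = [s for s in sdps if s.is_full]
        merged: list[SDP] = list(full)
        for s in sdps:
            if s.is_full:
                continue
            hosts = [f for f in full if sdp_compatible(s, f)]
            if hosts:
                host = max(hosts, key=lambda f: (len(f.members), -f.sdp_id))
                host.members.extend(s.members)
            else:
                merged.append(s)
        sdps = merged
        for new_id, s in enumerate(sdps):
            s.sdp_id = new_id
    return sdps


def sdp_compatible(a: SDP, b: SDP) -> bool:
    """True iff the patterns agree at every strain observed in both SDPs."""
    if a.n_strains != b.n_strains:
        raise GenotypeError("SDPs are defined over different strain panels")
    both = ~(a.mask | b.mask)
    return bool(np.all(a.pattern[both] == b.pattern[both]))


# ---------------------------------------------------------------------------
# Surrogate imputation for incomplete SDPs
# ---------------------------------------------------------------------------

@dataclass
class SurrogateCorrection:
    """Outcome of surrogate imputation at an incompletely genotyped SDP."""

    status: str  # "corrected" | "no surrogate"
    target_sdp: int
    surrogate_snp: Optional[str] = None
    surrogate_sdp: Optional[int] = None
    distance: Optional[int] = None
    p_value: Optional[float] = None
    beta: Optional[float] = None


def impute_from_surrogate(
    target: SDP,
    scan,
    all_sdps: Iterable[SDP],
    max_distance: int = DEFAULT_SURROGATE_DISTANCE,
) -> SurrogateCorrection:
    """Correct an incomplete SDP's statistics using a nearby full surrogate.

    A hit whose SDP has missing strain calls may owe its signal to the
    unobserved strains.  The correction looks for the nearest fully-called
    SNP, within ``max_distance`` of any member of the target SDP, whose SDP
    is compatible with the target (agrees at all jointly observed strains),
    and reports that surrogate's scan statistics flagged ``"corrected"``.
    Ties are broken by smaller distance, then lower genomic coordinate.
    Returns a ``"no surrogate"`` record when no such SNP exists.

    ``scan`` must provide per-SDP statistics via ``scan.stat(sdp_id)``
    returning an object with ``p`` and ``beta`` attributes (see
    :class:`strainscan.mixed_model.ScanResult`).
    """
    if target.is_full:
        raise GenotypeError("target SDP is fully called; nothing to impute")
    best: Optional[tuple[int, int, str, str, int]] = None  # (dist, pos, snp, chrom, sdp_id)
    targets_by_chrom: dict[str, list[int]] = {}
    for _, chrom, pos in target.members:
        targets_by_chrom.setdefault(chrom, []).append(pos)
    for cand in all_sdps:
        if not cand.is_full or not sdp_compatible(target, cand):
            continue
        for snp_id, chrom, pos in cand.members:
            tpos = targets_by_chrom.get(chrom)
            if not tpos:
                continue
            dist = min(abs(pos - t) for t in tpos)
            if dist > max_distance:
                continue
            key = (dist, pos, snp_id, chrom, cand.sdp_id)
            if best is None or key[:2] < best[:2]:
                best = key
    if best is None:
        return SurrogateCorrection(status="no surrogate", target_sdp=target.sdp_id)
    dist, _, snp_id, _, sdp_id = best
    stat = scan.stat(sdp_id)
    return SurrogateCorrection(
        status="corrected",
        target_sdp=target.sdp_id,
        surrogate_snp=snp_id,
        surrogate_sdp=sdp_id,
        distance=dist,
        p_value=float(stat.p),
        beta=float(stat.beta),
    )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def kinship_ibs(G: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: shared-allele fraction per strain pair.

    ``K[s, t]`` is the proportion of SNPs, among those called in both
    strains, at which *s* and *t* carry the same allele.  The diagonal is
    forced to exactly 1.  A strain pair with no jointly-called SNP is an
    error.
    """
    if G.n_strains < 2:
        raise GenotypeError("kinship needs at least two strains")
    calls = G.calls.astype(np.float64)
    called = (G.calls != MISSING).astype(np.float64)
    calls = np.where(G.calls == MISSING, 0.0, calls)
    pairs = called.T @ called  # jointly called counts
    if np.any(pairs == 0):
        i, j = np.argwhere(pairs == 0)[0]
        raise GenotypeError(
            f"strains {G.strains[i]!r} and {G.strains[j]!r} share no called SNP"
        )
    # same-allele count = #(1,1) + #(0,0) over jointly called SNPs
    both1 = calls.T @ calls
    zeros = called - calls  # 1 where call == 0
    both0 = zeros.T @ zeros
    K = (both1 + both0) / pairs
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(list(G.strains), K)
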