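"""EMMA-style linear mixed model for strain-panel association scans.

Model: for animal-level phenotypes y,

    y = X b + Z u + e,   Var(u) = sg2 * K,   Var(e) = se2 * I,

where Z maps animals to strains and K is the strain kinship matrix.  Writing
delta = se2 / sg2, the restricted likelihood is profiled down to a
one-dimensional function of delta via a spectral decomposition, maximized by
a grid search on log(delta) refined with bounded scalar optimization.

For a genome scan the variance components are estimated once on the null
model (no SNP) and re-used for every SDP; each SDP's allele code is then
tested by generalized least squares under the null covariance, with an
F-test on the SNP coefficient.  An exact mode that re-estimates the variance
components per SDP is available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import MISSING, SDP, KinshipMatrix

# delta = se2/sg2 search range; natural-log grid refined by Brent to 1e-8
DELTA_MIN = 1e-5
DELTA_MAX = 1e5
_N_GRID = 100
_RIDGE = 1e-6


class ModelError(ValueError):
    """Raised for singular designs or degenerate model inputs."""


@dataclass
class MixedModelSpec:
    """Inputs of one scan: response, fixed effects, strain incidence, kinship.

    ``X`` holds the intercept and any treatment covariates but never the SNP
    column; the scan appends allele codes itself.  ``strains`` orders the
    columns of ``Z`` and the rows of ``K``.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    K: KinshipMatrix
    strains: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ModelError("row counts of y, X, Z differ")
        if self.Z.shape[1] != len(self.strains):
            raise ModelError("Z column count does not match strain count")
        if not np.all(self.Z.sum(axis=1) == 1):
            raise ModelError("each animal must map to exactly one strain")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ModelError("fixed-effect design X is singular")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class VarianceComponents:
    """REML variance components of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    h2: float
    reml_loglik: float
    boundary: bool = False


def make_spec(
    phen: pd.DataFrame,
    trait: str,
    K: KinshipMatrix,
    value_col: Optional[str] = None,
    treatment_covariate: bool = False,
    baseline_treatment: str = "ctr",
    meta: Optional[dict] = None,
) -> MixedModelSpec:
    """Build a :class:`MixedModelSpec` from a per-animal table.

    ``phen`` needs columns ``strain`` and (if ``treatment_covariate``)
    ``treatment``, plus the trait column.  Animals with a missing trait value
    are dropped; strains losing all animals are dropped from Z and K.
    """
    col = value_col or trait
    df = phen.loc[phen[col].notna()].reset_index(drop=True)
    if df.empty:
        raise ModelError(f"no non-missing values for trait {trait!r}")
    strains = [s for s in K.strains if s in set(df["strain"])]
    df = df[df["strain"].isin(strains)].reset_index(drop=True)
    sidx = {s: i for i, s in enumerate(strains)}
    n = len(df)
    Z = np.zeros((n, len(strains)))
    Z[np.arange(n), [sidx[s] for s in df["strain"]]] = 1.0
    cols = [np.ones(n)]
    if treatment_covariate:
        levels = [t for t in pd.unique(df["treatment"]) if t != baseline_treatment]
        for t in sorted(levels):
            cols.append((df["treatment"] == t).to_numpy(float))
    X = np.column_stack(cols)
    return MixedModelSpec(
        y=df[col].to_numpy(float),
        X=X,
        Z=Z,
        K=K.subset(strains),
        strains=strains,
        meta={"trait": trait, **(meta or {})},
    )


# ---------------------------------------------------------------------------
# REML for the null model
# ---------------------------------------------------------------------------

def _restricted_spectrum(spec: MixedModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-pairs of the genetic covariance on the residual space of X.

    Projects H = Z K Z' onto an explicit orthonormal basis of the orthogonal
    complement of col(X) (complete QR).  Working in that basis keeps the
    zero-eigenvalue directions of H cleanly separated from col(X), which a
    naive eigendecomposition of S H S does not guarantee.
    """
    q = spec.X.shape[1]
    H = spec.Z @ spec.K.ridged(_RIDGE) @ spec.Z.T
    Qfull, _ = np.linalg.qr(spec.X, mode="complete")
    Q2 = Qfull[:, q:]
    w, V = np.linalg.eigh(Q2.T @ H @ Q2)
    order = np.argsort(w)[::-1]
    return w[order], Q2 @ V[:, order]


def _reml_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    nq = len(xi)
    denom = xi + delta
    rss = float(np.sum(eta2 / denom))
    return 0.5 * (
        nq * (np.log(nq / (2 * np.pi)) - 1 - np.log(rss)) - float(np.sum(np.log(denom)))
    )


def _maximize_delta(xi: np.ndarray, eta2: np.ndarray) -> tuple[float, float, bool]:
    """Grid + Brent maximization of the restricted likelihood over delta."""
    logs = np.linspace(np.log(DELTA_MIN), np.log(DELTA_MAX), _N_GRID + 1)
    vals = np.array([_reml_loglik(np.exp(t), xi, eta2) for t in logs])
    best_t, best_ll = logs[int(np.argmax(vals))], float(np.max(vals))
    # refine around every local maximum of the grid
    for i in range(1, _N_GRID):
        if vals[i] >= vals[i - 1] and vals[i] >= vals[i + 1]:
            res = optimize.minimize_scalar(
                lambda t: -_reml_loglik(np.exp(t), xi, eta2),
                bounds=(logs[i - 1], logs[i + 1]),
                method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun > best_ll:
                best_ll, best_t = -float(res.fun), float(res.x)
    boundary = best_t <= logs[0] + 1e-6 or best_t >= logs[-1] - 1e-6
    return float(np.exp(best_t)), best_ll, boundary


def fit_null(spec: MixedModelSpec) -> VarianceComponents:
    """REML variance components of the mixed model without any SNP.

    The heritability estimate h2 = sg2 / (sg2 + se2) = 1 / (1 + delta) is
    the strain-level fraction of phenotypic variance captured by the kinship
    random effect; fitting this null model is also how per-trait
    heritabilities are reported.
    """
    if len(spec.strains) < 3:
        raise ModelError("need at least three strains to fit variance components")
    xi, U = _restricted_spectrum(spec)
    eta2 = (U.T @ spec.y) ** 2
    delta, ll, boundary = _maximize_delta(xi, eta2)
    nq = len(xi)
    sg2 = float(np.sum(eta2 / (xi + delta))) / nq
    se2 = delta * sg2
    return VarianceComponents(
        sigma_g2=sg2,
        sigma_e2=se2,
        delta=delta,
        h2=sg2 / (sg2 + se2),
        reml_loglik=ll,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

@dataclass
class SdpStat:
    """Association statistics of one SDP."""

    sdp_id: int
    n_strains_used: int
    beta: float
    se: float
    F: float
    df1: int
    df2: int
    p: float
    var_explained: float
    flag: str = ""


@dataclass
class ScanResult:
    """Per-SDP association statistics plus scan metadata.

    Member SNPs of one SDP share the SDP's statistics exactly;
    :meth:`snp_table` broadcasts them to SNP rows.
    """

    table: pd.DataFrame
    sdps: list[SDP]
    vc: VarianceComponents
    meta: dict = field(default_factory=dict)

    def stat(self, sdp_id: int) -> pd.Series:
        return self.table.loc[sdp_id]

    @property
    def pvalues(self) -> np.ndarray:
        ok = self.table["flag"] != "degenerate"
        return self.table.loc[ok, "p"].to_numpy(float)

    def min_p(self) -> float:
        return float(np.nanmin(self.pvalues))

    def snp_table(self) -> pd.DataFrame:
        rows = []
        for sdp in self.sdps:
            stat = self.table.loc[sdp.sdp_id]
            for snp_id, chrom, pos in sdp.members:
                rows.append(
                    {
                        "snp_id": snp_id,
                        "chrom": chrom,
                        "pos": pos,
                        "sdp_id": sdp.sdp_id,
                        "n_strains": stat["n_strains_used"],
                        "beta": stat["beta"],
                        "se": stat["se"],
                        "F": stat["F"],
                        "p": stat["p"],
                        "neg_log10_p": -np.log10(stat["p"]) if stat["p"] > 0 else np.inf,
                        "flag": stat["flag"],
                    }
                )
        df = pd.DataFrame(rows)
        return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


class ScanEngine:
    """Precomputed spectral machinery for scanning a set of SDPs.

    SDPs are grouped by their missing mask; within a group, strains masked at
    the SDP are dropped (per-SDP complete case) and one eigendecomposition of
    the subset covariance serves every member.  The engine supports repeated
    scans of permuted responses at marginal cost, which the effective-tests
    calibration exploits.
    """

    def __init__(self, spec: MixedModelSpec, sdps: Sequence[SDP]):
        self.spec = spec
        self.sdps = list(sdps)
        self._groups: list[dict] = []
        strain_index = {s: i for i, s in enumerate(spec.strains)}
        n_panel = len(spec.strains)
        by_mask: dict[bytes, list[SDP]] = {}
        for sdp in self.sdps:
            if sdp.n_strains != n_panel:
                raise ModelError("SDP strain count does not match the spec panel")
            by_mask.setdefault(sdp.mask.tobytes(), []).append(sdp)
        H = spec.Z @ spec.K.ridged(_RIDGE) @ spec.Z.T
        for mask_key, group in by_mask.items():
            mask = np.frombuffer(mask_key, dtype=bool)
            keep_strain = ~mask
            rows = spec.Z[:, keep_strain].sum(axis=1) > 0
            idx = np.nonzero(rows)[0]
            Zs = spec.Z[np.ix_(idx, np.nonzero(keep_strain)[0])]
            lam, U = np.linalg.eigh(H[np.ix_(idx, idx)])
            Uy = U.T @ spec.y[idx]
            UX = U.T @ spec.X[idx]
            # allele codes broadcast from strains to animals
            G = np.stack([sdp.pattern.astype(float) for sdp in group])
            Ganim = (spec.Z[idx] @ G.T)  # (n_sub, n_sdps) — masked strains absent
            degenerate = np.array(
                [
                    (Zs @ sdp.pattern[keep_strain]).std() == 0
                    or len(np.unique(sdp.pattern[keep_strain])) < 2
                    for sdp in group
                ]
            )
            self._groups.append(
                {
                    "sdps": group,
                    "idx": idx,
                    "lam": lam,
                    "U": U,
                    "Uy": Uy,
                    "UX": UX,
                    "UG": U.T @ Ganim,
                    "degenerate": degenerate,
                    "n_strains_used": int(keep_strain.sum()),
                }
            )

    @staticmethod
    def _group_stats(
        g: dict, delta: float, Uy: Optional[np.ndarray] = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
        """GLS F-tests of every SDP in a mask group at fixed delta."""
        w = 1.0 / np.sqrt(g["lam"] + delta)
        ty = (Uy if Uy is not None else g["Uy"]) * w
        TX = g["UX"] * w[:, None]
        TG = g["UG"] * w[:, None]
        Q, _ = np.linalg.qr(TX)
        ry = ty - Q @ (Q.T @ ty)
        RG = TG - Q @ (Q.T @ TG)
        gg = np.einsum("ij,ij->j", RG, RG)
        gy = RG.T @ ry
        rss0 = float(ry @ ry)
        safe = gg > 1e-12
        beta = np.where(safe, gy / np.where(safe, gg, 1.0), np.nan)
        rss1 = np.maximum(rss0 - np.where(safe, beta**2 * gg, 0.0), 0.0)
        df2 = len(ty) - TX.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (rss0 - rss1) * df2 / np.where(rss1 > 0, rss1, np.nan)
            se = np.sqrt(rss1 / df2 / np.where(safe, gg, np.nan))
        ve = np.where(rss0 > 0, 1.0 - rss1 / rss0, 0.0)
        return beta, se, F, ve, df2

    def scan(self, vc: VarianceComponents, meta: Optional[dict] = None) -> ScanResult:
        """Score every SDP under the null variance components."""
        rows = []
        for g in self._groups:
            beta, se, F, ve, df2 = self._group_stats(g, vc.delta)
            for j, sdp in enumerate(g["sdps"]):
                if g["degenerate"][j] or not np.isfinite(F[j]):
                    rows.append(
                        SdpStat(sdp.sdp_id, g["n_strains_used"], np.nan, np.nan,
                                np.nan, 1, df2, np.nan, np.nan, "degenerate")
                    )
                    continue
                p = float(stats.f.sf(F[j], 1, df2))
                rows.append(
                    SdpStat(
                        sdp_id=sdp.sdp_id,
                        n_strains_used=g["n_strains_used"],
                        beta=float(beta[j]),
                        se=float(se[j]),
                        F=float(F[j]),
                        df1=1,
                        df2=df2,
                        p=max(p, np.finfo(float).tiny),
                        var_explained=float(np.clip(ve[j], 0.0, 1.0)),
                    )
                )
        table = pd.DataFrame([r.__dict__ for r in rows]).set_index("sdp_id").sort_index()
        return ScanResult(table=table, sdps=self.sdps, vc=vc,
                          meta={**self.spec.meta, **(meta or {})})

    def min_p_permutations(
        self, n_perm: int, rng: np.random.Generator, refit_null: bool = True
    ) -> np.ndarray:
        """Minimum scan p-value for each permutation of y across animals.

        The restricted spectrum depends only on X, so the null REML refit per
        permutation reduces to a cheap 1-D search; the SDP statistics re-use
        the cached eigendecompositions.
        """
        xi, Ur = _restricted_spectrum(self.spec)
        minima = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(self.spec.n)
            yp = self.spec.y[perm]
            if refit_null:
                eta2 = (Ur.T @ yp) ** 2
                delta, _, _ = _maximize_delta(xi, eta2)
            else:
                delta = 1.0
            best = np.inf
            for g in self._groups:
                Uy = g["U"].T @ yp[g["idx"]]
                _, _, F, _, df2 = self._group_stats(g, delta, Uy=Uy)
                ok = ~g["degenerate"] & np.isfinite(F)
                if ok.any():
                    best = min(best, float(stats.f.sf(np.max(F[ok]), 1, df2)))
            minima[b] = best
        return minima


def assoc_scan(
    spec: MixedModelSpec,
    sdps: Sequence[SDP],
    vc: Optional[VarianceComponents] = None,
    exact_reml: bool = False,
    meta: Optional[dict] = None,
) -> ScanResult:
    """Mixed-model association scan over a set of SDPs.

    By default the variance components come from one null fit and are re-used
    for every SDP (the EMMA population-parameters shortcut).  With
    ``exact_reml=True`` the variance components are re-estimated for each
    SDP with the allele code in the design — slower, used for cross-checks.
    """
    if vc is None:
        vc = fit_null(spec)
    engine = ScanEngine(spec, sdps)
    result = engine.scan(vc, meta=meta)
    if exact_reml:
        for sdp in sdps:
            row = result.table.loc[sdp.sdp_id]
            if row["flag"] == "degenerate":
                continue
            sub = _per_sdp_spec(spec, sdp)
            g = (sub.Z @ sdp.pattern[_kept(spec, sdp)]).astype(float)
            X1 = np.column_stack([sub.X, g])
            spec1 = replace(sub, X=X1)
            vc1 = fit_null(spec1)
            stat = _gls_last_column(spec1, vc1)
            for k, v in stat.items():
                result.table.loc[sdp.sdp_id, k] = v
        result.meta["reml_mode"] = "exact"
    return result


def _kept(spec: MixedModelSpec, sdp: SDP) -> np.ndarray:
    return ~sdp.mask


def _per_sdp_spec(spec: MixedModelSpec, sdp: SDP) -> MixedModelSpec:
    keep_strain = ~sdp.mask
    rows = spec.Z[:, keep_strain].sum(axis=1) > 0
    idx = np.nonzero(rows)[0]
    strains = [s for s, k in zip(spec.strains, keep_strain) if k]
    return MixedModelSpec(
        y=spec.y[idx],
        X=spec.X[idx],
        Z=spec.Z[np.ix_(idx, np.nonzero(keep_strain)[0])],
        K=spec.K.subset(strains),
        strains=strains,
        meta=spec.meta,
    )


def _gls_last_column(spec: MixedModelSpec, vc: VarianceComponents) -> dict:
    """F-test of the last column of X under the spec's covariance at vc.delta."""
    H = spec.Z @ spec.K.ridged(_RIDGE) @ spec.Z.T
    lam, U = np.linalg.eigh(H)
    w = 1.0 / np.sqrt(lam + vc.delta)
    ty = (U.T @ spec.y) * w
    TX = (U.T @ spec.X) * w[:, None]
    X0, g = TX[:, :-1], TX[:, -1]
    Q, _ = np.linalg.qr(X0)
    ry = ty - Q @ (Q.T @ ty)
    rg = g - Q @ (Q.T @ g)
    gg = float(rg @ rg)
    beta = float(rg @ ry) / gg
    rss0 = float(ry @ ry)
    rss1 = max(rss0 - beta**2 * gg, 0.0)
    df2 = len(ty) - TX.shape[1]
    if rss1 <= rss0 * 1e-14:  # numerically perfect fit
        return {
            "beta": beta,
            "se": 0.0,
            "F": np.inf,
            "df2": df2,
            "p": np.finfo(float).tiny,
            "var_explained": 1.0,
        }
    F = (rss0 - rss1) * df2 / rss1
    return {
        "beta": beta,
        "se": float(np.sqrt(rss1 / df2 / gg)),
        "F": float(F),
        "df2": df2,
        "p": max(float(stats.f.sf(F, 1, df2)), np.finfo(float).tiny),
        "var_explained": float(np.clip(1 - rss1 / rss0, 0, 1)),
    }


def variance_explained(spec: MixedModelSpec, sdp: SDP,
                       vc: Optional[VarianceComponents] = None) -> float:
    """Fraction of phenotypic variance explained by one SDP.

    Computed as 1 - RSS(with SNP)/RSS(without SNP) after whitening by the
    null-model covariance, i.e. the generalized R^2 of the allele code.
    """
    if vc is None:
        vc = fit_null(spec)
    sub = _per_sdp_spec(spec, sdp)
    g = (sub.Z @ sdp.pattern[~sdp.mask]).astype(float)
    if np.std(g) == 0:
        raise ModelError("SDP is monomorphic among usable strains")
    spec1 = replace(sub, X=np.column_stack([sub.X, g]))
    return _gls_last_column(spec1, vc)["var_explained"]
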