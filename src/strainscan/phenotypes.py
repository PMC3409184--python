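"""Per-animal phenotypes and inferred drug-response effects.

Treated and control animals belong to separate cohorts, so individual drug
responses cannot be measured directly.  They are inferred per treated animal
as the difference — or, for most traits, the fold change — between that
animal's value and the mean of the reference-arm animals of the same strain.
Fold changes are log-transformed before association analysis; differences are
analyzed untransformed.

A variance screen excludes scans containing gross outliers: a scan fails when
any animal's deviation from its strain mean exceeds ``k_sd`` pooled residual
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ID_COLUMNS = ["animal_id", "strain", "treatment"]
DEFAULT_TREATMENTS = ("ctr", "ate", "iso1", "iso10")

#: Traits analyzed as plain differences; every other trait uses fold changes.
DIFFERENCE_TRAITS = ("Qamp", "QRSarea", "Samp")

DEFAULT_K_SD = 3.0


class PhenotypeError(ValueError):
    pass


def validate_phenotypes(
    P: pd.DataFrame, treatments: tuple[str, ...] = DEFAULT_TREATMENTS
) -> pd.DataFrame:
    """Check the per-animal table: unique ids, known treatment labels."""
    missing = [c for c in ID_COLUMNS if c not in P.columns]
    if missing:
        raise PhenotypeError(f"phenotype table lacks columns {missing}")
    dup = P["animal_id"][P["animal_id"].duplicated()]
    if len(dup):
        raise PhenotypeError(f"duplicate animal_id values: {sorted(set(dup))[:5]}")
    bad = set(P["treatment"]) - set(treatments)
    if bad:
        raise PhenotypeError(f"unknown treatment labels: {sorted(bad)}")
    return P


def trait_columns(P: pd.DataFrame) -> list[str]:
    return [c for c in P.columns if c not in ID_COLUMNS]


def default_effect_mode(trait: str) -> str:
    return "difference" if trait in DIFFERENCE_TRAITS else "log_fold_change"


def strain_reference_means(
    P: pd.DataFrame, trait: str, reference_treatment: str = "ctr"
) -> pd.Series:
    """Arithmetic mean of the trait over reference-arm animals, per strain."""
    ref = P[P["treatment"] == reference_treatment]
    means = ref.groupby("strain")[trait].mean()
    empty = [s for s in P["strain"].unique() if s not in means.index or pd.isna(means[s])]
    if empty:
        raise PhenotypeError(
            f"no {reference_treatment!r} values of {trait!r} for strains {sorted(empty)}"
        )
    return means


def drug_effects(
    P: pd.DataFrame,
    trait: str,
    treated_arm: str,
    reference_arm: str = "ctr",
    mode: Optional[str] = None,
    log_base: float = np.e,
) -> pd.DataFrame:
    """Per-animal drug effect of ``treated_arm`` relative to ``reference_arm``.

    difference mode: effect = individual - strain reference mean.
    log_fold_change mode: effect = log(individual / strain reference mean);
    all values and reference means must be strictly positive.

    Returns a table (animal_id, strain, contrast, trait, mode, value) with one
    row per treated-arm animal.  Drug-vs-drug contrasts (e.g. ``iso10`` vs
    ``ate``) follow the same scheme with the other drug arm as reference.
    """
    mode = mode or default_effect_mode(trait)
    if mode not in ("difference", "log_fold_change"):
        raise PhenotypeError(f"unknown effect mode {mode!r}")
    means = strain_reference_means(P, trait, reference_arm)
    treated = P[P["treatment"] == treated_arm]
    if treated.empty:
        raise PhenotypeError(f"no animals in treated arm {treated_arm!r}")
    vals = treated[trait].to_numpy(float)
    ref = means.loc[treated["strain"]].to_numpy(float)
    if mode == "difference":
        eff = vals - ref
    else:
        bad_mask = (vals <= 0) | (ref <= 0)
        if bad_mask.any():
            bad = treated["animal_id"].to_numpy()[bad_mask]
            raise PhenotypeError(
                f"non-positive values in fold-change mode for animals {list(bad)}"
            )
        eff = np.log(vals / ref) / np.log(log_base)
    return pd.DataFrame(
        {
            "animal_id": treated["animal_id"].to_numpy(),
            "strain": treated["strain"].to_numpy(),
            "contrast": f"{treated_arm} vs {reference_arm}",
            "trait": trait,
            "mode": mode,
            "value": eff,
        }
    )


@dataclass
class VarianceScreenResult:
    passed: bool
    sd: float
    k_sd: float
    offending: pd.DataFrame = field(default_factory=pd.DataFrame)


def variance_screen(
    values: pd.DataFrame,
    value_col: str,
    k_sd: float = DEFAULT_K_SD,
    per_strain_sd: bool = False,
) -> VarianceScreenResult:
    """Outlier screen on one scan's values (raw trait or inferred effects).

    Fails when any |individual - strain mean| exceeds ``k_sd`` times the
    residual standard deviation.  The SD pools residuals across strains by
    default (per-strain SDs on ~9 animals are unstable); ``per_strain_sd``
    switches to within-strain SDs.  Failed scans are excluded from locus
    reporting downstream.
    """
    df = values.loc[values[value_col].notna()].copy()
    if len(df) < 2:
        raise PhenotypeError("variance screen needs at least two animals")
    grp = df.groupby("strain")[value_col]
    resid = df[value_col] - grp.transform("mean")
    if per_strain_sd:
        sd_ref = grp.transform("std").fillna(0.0)
        sd = float(resid.std(ddof=1))
    else:
        sd = float(resid.std(ddof=1))
        sd_ref = pd.Series(sd, index=df.index)
    if sd == 0:
        return VarianceScreenResult(passed=True, sd=0.0, k_sd=k_sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        bad = resid.abs() > k_sd * sd_ref
    offending = df.loc[bad.fillna(False)]
    return VarianceScreenResult(
        passed=offending.empty, sd=sd, k_sd=k_sd, offending=offending
    )


def effects_to_phenotype_frame(E: pd.DataFrame) -> pd.DataFrame:
    """Reshape an effect table into the (animal, strain, value) layout the
    mixed model consumes, one column named after the trait."""
    if E["trait"].nunique() != 1 or E["contrast"].nunique() != 1:
        raise PhenotypeError("expected a single (trait, contrast) effect table")
    trait = E["trait"].iloc[0]
    out = E[["animal_id", "strain"]].copy()
    out["treatment"] = E["contrast"].iloc[0]
    out[trait] = E["value"].to_numpy(float)
    return out
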