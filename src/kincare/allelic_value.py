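"""Brood-level allelic-value statistics under extra-pair paternity.

For a social pair (male *i*, female *j*) rearing a brood, each offspring is
either a within-pair offspring (WPO, sired by *i*) or an extra-pair offspring
(EPO, sired by some other male *q*).  Relatedness between a focal parent and
an offspring it rears follows from the pair's kinship and inbreeding
coefficients:

    r_iWPO = 1/2 + k_ij + f_i / 2        r_jWPO = 1/2 + k_ij + f_j / 2
    r_iEPO = k_ij + k_iq                 r_jEPO = 1/2 + k_jq + f_j / 2

The brood's total allelic value to a parent (TAV_i, TAV_j) is the sum of
these per-offspring relatedness values: the expected number of copies of a
focal parental allele present in the brood.  PAV is the potential allelic
value had the male sired every offspring, PAV = BS * r_iWPO, and the lost
allelic value is LAV = PAV - TAV_i: the relatedness the male loses to
extra-pair paternity, discounted by however related he is to the cuckolders.
In the classical outbred, unrelated limit (all k = f = 0) these reduce to
TAV_i = N_WPO / 2, TAV_j = BS / 2 and LAV = BS * P_EPO / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree, KinshipTable, kinship, inbreeding

__all__ = [
    "Brood",
    "BroodAllelicValues",
    "relatedness_wpo",
    "relatedness_epo_male",
    "relatedness_epo_female",
    "brood_allelic_values",
    "standardize_tav",
    "metrics_frame",
    "load_broods",
]

STATUSES = ("monogamous", "primary_polygynous", "secondary_polygynous")


@dataclass
class Brood:
    """One nest: social pair, status, and offspring with genetic sires.

    All maternity is by the social female; an offspring whose genetic sire
    differs from the social male is an EPO.  ``offspring`` holds
    ``(offspring_id, genetic_sire_id)`` pairs; a genetic sire of ``None``
    means the sire could not be assigned.
    """

    nest_id: str
    social_male: str
    social_female: str
    status: str
    offspring: list[tuple[str, str | None]]
    lay_date: int = 0

    def __post_init__(self) -> None:
        if len(self.offspring) < 1:
            raise ValueError(f"brood {self.nest_id!r} has no offspring")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}; expected one of {STATUSES}")

    @property
    def brood_size(self) -> int:
        return len(self.offspring)


@dataclass
class BroodAllelicValues:
    """Per-brood allelic-value summary (one row of the metrics table)."""

    nest_id: str
    BS: int
    N_WPO: int
    P_WPO: float
    P_EPO: float
    r_per_offspring_male: list[float]
    r_per_offspring_female: list[float]
    TAV_i: float
    TAV_j: float
    PAV: float
    LAV: float
    k_ij: float
    f_i: float
    f_j: float
    male_id: str = ""
    female_id: str = ""


def _check_unit(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return float(value)


def relatedness_wpo(k_mate: float, f_self: float) -> float:
    """Parent-to-within-pair-offspring relatedness: 1/2 + k_mate + f_self/2."""
    return 0.5 + _check_unit("k_mate", k_mate) + 0.5 * _check_unit("f_self", f_self)


def relatedness_epo_male(k_ij: float, k_iq: float) -> float:
    """Social male's relatedness to an extra-pair offspring: k_ij + k_iq.

    Nonzero only when the male is related to the offspring's mother (his
    social mate) or to its genetic sire.
    """
    return _check_unit("k_ij", k_ij) + _check_unit("k_iq", k_iq)


def relatedness_epo_female(k_jq: float, f_j: float) -> float:
    """Mother-to-extra-pair-offspring relatedness: 1/2 + k_jq + f_j/2."""
    return 0.5 + _check_unit("k_jq", k_jq) + 0.5 * _check_unit("f_j", f_j)


def _lookup(kin: Pedigree | KinshipTable, i: str, j: str) -> float:
    if isinstance(kin, Pedigree):
        return kinship(kin, i, j)
    return kin.k(i, j)


def _lookup_f(kin: Pedigree | KinshipTable, i: str) -> float:
    if isinstance(kin, Pedigree):
        return inbreeding(kin, i)
    return kin.f(i)


def brood_allelic_values(
    brood: Brood,
    kin: Pedigree | KinshipTable,
    unknown_sire: str = "phantom",
) -> BroodAllelicValues:
    """Compute TAV_i, TAV_j, PAV, LAV and paternity fractions for one brood.

    ``kin`` may be a :class:`Pedigree` (coefficients computed on demand) or a
    prebuilt :class:`KinshipTable` containing every required pair.  An
    offspring with an unresolved genetic sire is handled per ``unknown_sire``:
    ``"phantom"`` treats the sire as an unrelated phantom founder
    (k_iq = k_jq = 0, with a warning), ``"strict"`` raises.
    """
    i, j = brood.social_male, brood.social_female
    k_ij = _lookup(kin, i, j)
    f_i = _lookup_f(kin, i)
    f_j = _lookup_f(kin, j)

    r_male: list[float] = []
    r_female: list[float] = []
    n_wpo = 0
    for off_id, sire in brood.offspring:
        if sire == i:
            n_wpo += 1
            r_male.append(relatedness_wpo(k_ij, f_i))
            r_female.append(relatedness_wpo(k_ij, f_j))
            continue
        if sire is None:
            if unknown_sire == "strict":
                raise ValueError(
                    f"offspring {off_id!r} in brood {brood.nest_id!r} has no genetic sire"
                )
            warnings.warn(
                f"offspring {off_id!r} in brood {brood.nest_id!r} has an unknown "
                "genetic sire; treating it as an unrelated phantom founder",
                stacklevel=2,
            )
            k_iq = 0.0
            k_jq = 0.0
        else:
            k_iq = _lookup(kin, i, sire)
            k_jq = _lookup(kin, j, sire)
        r_male.append(relatedness_epo_male(k_ij, k_iq))
        r_female.append(relatedness_epo_female(k_jq, f_j))

    bs = brood.brood_size
    tav_i = float(sum(r_male))
    tav_j = float(sum(r_female))
    pav = bs * relatedness_wpo(k_ij, f_i)
    return BroodAllelicValues(
        nest_id=brood.nest_id,
        BS=bs,
        N_WPO=n_wpo,
        P_WPO=n_wpo / bs,
        P_EPO=(bs - n_wpo) / bs,
        r_per_offspring_male=r_male,
        r_per_offspring_female=r_female,
        TAV_i=tav_i,
        TAV_j=tav_j,
        PAV=pav,
        LAV=pav - tav_i,
        k_ij=k_ij,
        f_i=f_i,
        f_j=f_j,
        male_id=i,
        female_id=j,
    )


def standardize_tav(
    values: Iterable[tuple[str, int, float]]
) -> list[tuple[str, float]]:
    """z-standardize TAV within each brood-size class.

    TAV_z = (TAV - mean_BS) / sd_BS with the sample (n - 1) standard
    deviation taken across the supplied broods of the same size.  A class
    with a single brood, or with no TAV dispersion, gets TAV_z = 0: a
    centred value carrying no dispersion information.  This isolates
    relatedness variation from the brood-size gradient itself.
    """
    rows = list(values)
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["nest_id", "BS", "TAV"])
    out = np.zeros(len(df))
    for _, grp in df.groupby("BS"):
        if len(grp) > 1:
            sd = grp["TAV"].std(ddof=1)
            if sd > 0:
                out[grp.index] = (grp["TAV"] - grp["TAV"].mean()) / sd
    return list(zip(df["nest_id"], out.astype(float)))


def metrics_frame(
    broods: Sequence[Brood],
    kin: Pedigree | KinshipTable,
    unknown_sire: str = "phantom",
) -> pd.DataFrame:
    """Per-brood metrics table for a collection of broods.

    One row per brood with all :class:`BroodAllelicValues` scalars plus the
    within-brood-size standardized ``TAV_i_z`` / ``TAV_j_z``, brood status
    and lay date — the covariate table the mixed models join against.
    """
    vals = [brood_allelic_values(b, kin, unknown_sire=unknown_sire) for b in broods]
    df = pd.DataFrame(
        {
            "nest_id": [v.nest_id for v in vals],
            "BS": [v.BS for v in vals],
            "N_WPO": [v.N_WPO for v in vals],
            "P_WPO": [v.P_WPO for v in vals],
            "P_EPO": [v.P_EPO for v in vals],
            "TAV_i": [v.TAV_i for v in vals],
            "TAV_j": [v.TAV_j for v in vals],
            "PAV": [v.PAV for v in vals],
            "LAV": [v.LAV for v in vals],
            "k_ij": [v.k_ij for v in vals],
            "f_i": [v.f_i for v in vals],
            "f_j": [v.f_j for v in vals],
            "status": [b.status for b in broods],
            "lay_date": [b.lay_date for b in broods],
            "social_male": [b.social_male for b in broods],
            "social_female": [b.social_female for b in broods],
        }
    )
    for col, tav in (("TAV_i_z", "TAV_i"), ("TAV_j_z", "TAV_j")):
        z = dict(standardize_tav(zip(df["nest_id"], df["BS"], df[tav])))
        df[col] = df["nest_id"].map(z)
    return df


def load_broods(path) -> list[Brood]:
    """Read a brood/parentage table (one row per offspring).

    Columns: nest_id, social_male, social_female, status, offspring_id,
    genetic_sire, lay_date.  An empty genetic_sire marks an unresolved sire.
    """
    from pathlib import Path

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    broods = []
    for nest_id, grp in df.groupby("nest_id", sort=False):
        males = grp["social_male"].unique()
        females = grp["social_female"].unique()
        if len(males) != 1 or len(females) != 1:
            raise ValueError(f"brood {nest_id!r} lists multiple social parents")
        broods.append(
            Brood(
                nest_id=str(nest_id),
                social_male=males[0],
                social_female=females[0],
                status=grp["status"].iloc[0],
                offspring=[
                    (r.offspring_id, r.genetic_sire or None) for r in grp.itertuples()
                ],
                lay_date=int(grp["lay_date"].iloc[0]) if "lay_date" in grp else 0,
            )
        )
    return broods
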