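"""Household diet-quality scoring.

Three measures per household-wave:

1. **Intake sufficiency** — 7-day intake of each assessed nutrient
   (dietary energy, carbohydrate, protein, fat, iron, zinc, vitamin A,
   folate) against the household requirement, i.e. the sum over members
   of the age-sex class estimated average requirement (EAR; estimated
   energy requirement EER for energy) times seven.
2. **Macronutrient balance** — the WHO ranges for the share of
   macronutrient-derived energy: 10-15% protein, 15-30% fat, 55-75%
   carbohydrate (Atwater factors 4/9/4 kcal per g); classes are
   below/within/above, boundary-inclusive.
3. **NRFI** — an NRF9.3-style nutrient-rich food index: densities per
   2,000 kcal of nine qualifying components (protein, fibre, vitamins
   A, C, E, calcium, iron, magnesium, potassium), each capped at 100%
   of its reference amount, minus the uncapped densities of three
   moderation components (saturated fat, added sugar, sodium).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nutrients import NUTRIENTS, ATWATER, ADEQUACY_NUTRIENTS

__all__ = [
    "default_requirements", "household_requirement", "intake_from_quantities",
    "intake_sufficiency", "macronutrient_balance", "nrfi",
    "diet_quality_report", "NRF_REFERENCES", "WHO_RANGES",
]

#: daily reference amounts for the nine qualifying components (per
#: 2,000 kcal basis) and the three moderation components
NRF_REFERENCES = {
    "protein_g": 50.0, "fibre_g": 28.0, "vitamin_a_ug": 900.0,
    "vitamin_c_mg": 90.0, "vitamin_e_mg": 15.0, "calcium_mg": 1300.0,
    "iron_mg": 18.0, "magnesium_mg": 420.0, "potassium_mg": 4700.0,
}
NRF_MODERATION = {
    "saturated_fat_g": 20.0, "added_sugar_g": 50.0, "sodium_mg": 2300.0,
}

#: WHO recommended shares of macronutrient energy, boundary inclusive
WHO_RANGES = {"protein": (0.10, 0.15), "fat": (0.15, 0.30),
              "carbohydrate": (0.55, 0.75)}

#: default daily EER (kcal) and EARs by age-sex class; a documented,
#: config-replaceable stand-in in the spirit of standard dietary
#: reference intakes (synthetic values, not an official table)
_REQ_CLASSES = [
    # (sex, age_lo, age_hi, EER, carb g, protein g, fat g, iron mg,
    #  zinc mg, vitA ug, folate ug)
    ("m", 0, 4, 1000, 100, 11, 30, 3.0, 2.5, 210, 120),
    ("m", 4, 9, 1400, 100, 15, 35, 4.1, 4.0, 275, 160),
    ("m", 9, 14, 2000, 100, 27, 50, 5.9, 7.0, 445, 250),
    ("m", 14, 19, 2800, 100, 44, 65, 7.7, 8.5, 630, 330),
    ("m", 19, 31, 2700, 100, 46, 62, 6.0, 9.4, 625, 320),
    ("m", 31, 51, 2600, 100, 46, 60, 6.0, 9.4, 625, 320),
    ("m", 51, 121, 2200, 100, 46, 52, 6.0, 9.4, 625, 320),
    ("f", 0, 4, 1000, 100, 11, 30, 3.0, 2.5, 210, 120),
    ("f", 4, 9, 1300, 100, 15, 33, 4.1, 4.0, 275, 160),
    ("f", 9, 14, 1800, 100, 27, 45, 5.7, 7.0, 420, 250),
    ("f", 14, 19, 2200, 100, 38, 52, 7.9, 7.3, 485, 330),
    ("f", 19, 31, 2100, 100, 38, 49, 8.1, 6.8, 500, 320),
    ("f", 31, 51, 2000, 100, 38, 47, 8.1, 6.8, 500, 320),
    ("f", 51, 121, 1800, 100, 38, 43, 5.0, 6.8, 500, 320),
]


def default_requirements() -> pd.DataFrame:
    """Daily EER/EAR table by 14 age-sex classes (documented defaults)."""
    cols = ["sex", "age_lo", "age_hi", "energy_kcal", "carbohydrate_g",
            "protein_g", "fat_g", "iron_mg", "zinc_mg", "vitamin_a_ug",
            "folate_ug"]
    return pd.DataFrame(_REQ_CLASSES, columns=cols)


def household_requirement(roster: pd.DataFrame,
                          requirements: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """7-day household requirement per assessed nutrient.

    Sums each member's age-sex class daily requirement and multiplies
    by seven.  Raises if a member's age/sex maps to no class.
    """
    if roster.empty:
        raise ValueError("roster is empty")
    req = requirements if requirements is not None else default_requirements()
    nut_cols = [c for c in req.columns if c not in ("sex", "age_lo", "age_hi")]
    vals = np.zeros((len(roster), len(nut_cols)))
    matched = np.zeros(len(roster), bool)
    age = roster["age"].values
    sex = roster["sex"].values
    for row in req.itertuples():
        m = (sex == row.sex) & (age >= row.age_lo) & (age < row.age_hi)
        vals[m] = [getattr(row, c) for c in nut_cols]
        matched |= m
    if not matched.all():
        bad = roster.loc[~matched, ["hh", "member", "age", "sex"]]
        raise ValueError(f"roster members outside requirement classes:\n{bad}")
    per_member = pd.DataFrame(vals * 7.0, columns=nut_cols)
    per_member["hh"] = roster["hh"].values
    return per_member.groupby("hh").sum()


def intake_from_quantities(quantities, composition: pd.DataFrame
                           ) -> np.ndarray:
    """Nutrient intake from group quantities (kg): 10 * q_kg * per-100g."""
    q = np.atleast_2d(np.asarray(quantities, float))
    if np.any(q < 0):
        raise ValueError("negative quantities")
    return 10.0 * q @ composition.values


def intake_sufficiency(intake, requirement):
    """Boundary-inclusive sufficiency flags: intake >= requirement."""
    intake = np.asarray(intake, float)
    requirement = np.asarray(requirement, float)
    if np.any(intake < 0):
        raise ValueError("negative intake")
    return intake >= requirement


def macronutrient_balance(protein_g, fat_g, carb_g):
    """Energy shares of the three macronutrients and WHO balance classes.

    Shares are computed over macronutrient-derived energy (4/9/4), so
    they sum to one by construction.  Classes are boundary-inclusive:
    a share on the WHO limit counts as "within".
    """
    p = np.atleast_1d(np.asarray(protein_g, float)) * ATWATER["protein_g"]
    f = np.atleast_1d(np.asarray(fat_g, float)) * ATWATER["fat_g"]
    c = np.atleast_1d(np.asarray(carb_g, float)) * ATWATER["carbohydrate_g"]
    total = p + f + c
    if np.any(total <= 0):
        raise ValueError("all-zero macronutrient intake")
    shares = {"protein": p / total, "fat": f / total, "carbohydrate": c / total}
    classes = {}
    for name, s in shares.items():
        lo, hi = WHO_RANGES[name]
        classes[name] = np.select([s < lo, s > hi], ["below", "above"],
                                  default="within")
    return shares, classes


def nrfi(intake, energy_kcal, references=None, moderation=None):
    """Nutrient-rich food index on a 2,000 kcal basis.

    ``intake`` maps nutrient name -> amount (any consistent period);
    qualifying densities are credited up to 100% of the reference,
    moderation densities are debited without a cap.  Scale-invariant:
    multiplying all intakes and energy by c > 0 leaves the score
    unchanged.
    """
    refs = references or NRF_REFERENCES
    mods = moderation or NRF_MODERATION
    energy = np.atleast_1d(np.asarray(energy_kcal, float))
    if np.any(energy <= 0):
        raise ValueError("energy intake must be positive")
    if isinstance(intake, pd.DataFrame):
        intake = {c: intake[c].values for c in intake.columns}
    missing = [n for n in list(refs) + list(mods) if n not in intake]
    if missing:
        raise ValueError(f"missing NRFI components: {missing}")
    scale = 2000.0 / energy
    score = np.zeros_like(energy, dtype=float)
    for n, ref in refs.items():
        dens = np.atleast_1d(np.asarray(intake[n], float)) * scale
        score += np.minimum(100.0, 100.0 * dens / ref)
    for n, ref in mods.items():
        dens = np.atleast_1d(np.asarray(intake[n], float)) * scale
        score -= 100.0 * dens / ref
    return score if score.size > 1 else float(score[0])


def diet_quality_report(quantities, composition, roster, hh_ids,
                        requirements=None) -> pd.DataFrame:
    """Per-observation diet quality table.

    ``quantities`` is (N, J) weekly kg aligned with ``hh_ids``;
    requirements are matched by household.  Returns intake and
    requirement columns, sufficiency flags, macronutrient shares and
    classes, and the NRFI score.
    """
    intake = intake_from_quantities(quantities, composition)
    idf = pd.DataFrame(intake, columns=composition.columns)
    req = household_requirement(roster, requirements)
    out = pd.DataFrame({"hh": np.asarray(hh_ids)})
    for n in NUTRIENTS:
        out[f"intake_{n}"] = idf[n].values
    for n in ADEQUACY_NUTRIENTS:
        r = req[n].reindex(out["hh"]).values
        out[f"req_{n}"] = r
        out[f"suff_{n}"] = intake_sufficiency(idf[n].values, r)
    shares, classes = macronutrient_balance(
        idf["protein_g"].values, idf["fat_g"].values,
        idf["carbohydrate_g"].values)
    for name in shares:
        out[f"share_{name}"] = shares[name]
        out[f"class_{name}"] = classes[name]
    out["nrfi"] = nrfi(idf, idf["energy_kcal"].values)
    return out
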