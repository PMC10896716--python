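"""Nutrient name constants shared across composition, diet and elasticity code.

Contents are expressed per 100 g of food as consumed: energy in kcal,
vitamin A in ug retinol activity equivalents, folate in ug, the other
micronutrients in mg, macronutrients and fibre in g.
"""

NUTRIENTS = [
    "energy_kcal",
    "carbohydrate_g",
    "protein_g",
    "fat_g",
    "iron_mg",
    "zinc_mg",
    "vitamin_a_ug",
    "folate_ug",
    "fibre_g",
    "vitamin_c_mg",
    "vitamin_e_mg",
    "calcium_mg",
    "magnesium_mg",
    "potassium_mg",
    "saturated_fat_g",
    "added_sugar_g",
    "sodium_mg",
]

#: kcal per gram of carbohydrate, protein and fat (Atwater factors)
ATWATER = {"carbohydrate_g": 4.0, "protein_g": 4.0, "fat_g": 9.0}

#: nutrients assessed against household estimated average requirements
ADEQUACY_NUTRIENTS = [
    "energy_kcal", "carbohydrate_g", "protein_g", "fat_g",
    "iron_mg", "zinc_mg", "vitamin_a_ug", "folate_ug",
]
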