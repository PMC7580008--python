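"""Published summary numbers from the Serbian dietary survey, used as inputs.

These are inputs to the acceptance computations (count pairs behind printed
percentage cells, the early-vs-late comparison p-values, and the adult mean
intake profile), not expected outputs.
"""

# name -> (numerator, denominator) behind printed percentage cells
PRINTED_COUNTS = {
    "pct_obese_adults": (34, 254),
    "pct_overweight_adults": (84, 254),
    "pct_dqs45_among_after2000_eaters": (36, 193),
    "pct_dqs45_among_not_after2000": (30, 67),
    "pct_early_eaters_dqs01": (35, 75),
    "pct_early_eaters_dqs23": (58, 135),
    "pct_early_eaters_dqs45": (36, 50),
    "pct_female_among_after2000_eaters": (98, 193),
}

# early-vs-late eater comparison p-values; "<0.001" encoded as 0.0005
EARLY_LATE_PVALUES = [
    0.0005, 0.029, 0.0005, 0.874, 0.764, 0.111, 0.103, 0.153, 0.733,
    0.219, 0.008, 0.065, 0.893, 0.748, 0.636, 0.075, 0.089,
]

# adult mean intake metrics (two-day averages)
ADULT_MEAN_INTAKE = {
    "energy": 2265.0,             # kcal/day
    "carbohydrate_pct": 44.0,     # % of energy
    "protein_pct": 16.0,
    "fat_pct": 40.0,
    "saturated_fat_pct": 13.0,
    "sugar_pct": 13.2,
    "fiber_density": 10.9,        # g/1000 kcal
    "fruit": 184.0,               # g/day
    "vegetables": 289.0,
    "sodium": 3.99,               # g/day
    "water": 2246.0,              # ml/day
    "protein_per_kg": 1.11,       # g/kg body weight
    "energy_density": 0.89,       # kcal/g food
    "occasions_per_day": 6.1,
}
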