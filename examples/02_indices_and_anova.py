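"""Efficiency indices and split-plot statistics for one simulated season.

Computes the full index table (sugar content/yield, ET, WUE, WUEi, FAE,
PFP and sugar variants), runs the split-plot ANOVA with its two error
strata, and prints the LSD compact letter display for root yield.
"""

from fertigation import (SeasonWater, SyntheticTruth, build_index_table,
                         lsd_letters, make_design, simulate_trial,
                         splitplot_anova, summarize_index_table)

design = make_design()
truth = SyntheticTruth(seed=7)
obs = simulate_trial(design, truth, n_years=1)

water = {(2020, lvl): SeasonWater.from_m3ha("2020", dose, precip_mm=309.46)
         for lvl, dose in design.irr_levels.items()}
table = build_index_table(obs, water,
                          {f: design.fert_total(f) for f in design.fert_levels},
                          dict(design.irr_levels))
summary = summarize_index_table(table)
print("treatment means (first rows):")
cols = ["fert_level", "irr_level", "yield_t_ha", "WUE_kg_m3", "WUEi_kg_m3",
        "FAE_kg_kg", "PFP_kg_kg"]
print(summary[cols].head(6).round(2).to_string(index=False))

anova = splitplot_anova(table, "yield_t_ha")
print("\nsplit-plot ANOVA for yield (F tested against error a, "
      "W and FxW against error b):")
print(anova.table.round(3).to_string(index=False))

means = table.groupby(["fert_level", "irr_level"])["yield_t_ha"].agg(
    ["mean", "std"])
disp = lsd_letters(means["mean"], anova.ms_error_b, anova.df_error_b,
                   n_per_mean=design.n_reps, sds=means["std"])
print(f"\nLSD letter display (LSD = {disp.lsd:.2f} t/ha; treatments sharing"
      " a letter do not differ at alpha = 0.05):")
print(disp.annotate().to_string())
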