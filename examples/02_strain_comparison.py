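"""Compare strain presets: wildtype vs MatP deletion vs ATPase-dead MukB.

Renders a small population per preset, analyzes every cell, and reproduces
the qualitative strain phenotypes: MukB spreads asymmetrically over the
ori in wildtype, overlaps ter more often without MatP, and compacts the
chromosome only when it can hydrolyze ATP.
"""

import toroquant as tq

N = 25  # cells per strain; increase for tighter statistics

tables = {}
for strain in ("wildtype", "delta_matp", "mukb_eq"):
    specs = tq.sample_population_specs(strain, N, seed=42)
    stack, truths = tq.render_population(specs, seed=42)
    df = tq.analyze_stack(stack, strain_label=strain)
    tables[strain] = df[~df["discarded"].eq(True)]

print(f"{'strain':>12} {'A(DNA)':>7} {'A(MukB)':>8} {'compaction':>11} {'ter coloc':>10}")
for strain, df in tables.items():
    print(
        f"{strain:>12} {df['asymmetricity_dna'].median():7.2f} "
        f"{df['asymmetricity_mukb'].median():8.2f} "
        f"{df['compaction_ratio'].mean():11.2f} "
        f"{df['ter_overlaps_mukb'].eq(True).mean():10.0%}"
    )

wt = tables["wildtype"]["compaction_ratio"].dropna()
eq = tables["mukb_eq"]["compaction_ratio"].dropna()
F, p = tq.one_way_anova([wt, eq])
print(
    f"\ncompaction wildtype vs ATPase-dead: F = {F:.1f}, p = {p:.2g} "
    f"({tq.significance_stars(p)})"
)
print(
    "\nMedian A(MukB) > A(DNA) in wildtype shows the condensin favors one\n"
    "arm; the higher ter colocalization in the mutants shows MukB lingers\n"
    "at the terminus when MatP or ATP hydrolysis is missing; compaction\n"
    "near 1 in the EQ mutant shows compaction requires ATP hydrolysis."
)
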