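"""Periodate enrichment ratios and normalization-cohort selection.

Periodate oxidation / beta-elimination destroys the ligatable 3' end of
unmethylated (Ago1-loaded) molecules, so the periodate:total abundance
ratio E tracks how much of a species sits in Ago2. The normalization
cohort is the set of abundant, Ago1-enriched, Dora-insensitive miRNAs.
"""

import pandas as pd
from scipy.stats import spearmanr

from tddseq import SimConfig, ago2_enrichment, mirna_space_abundance, simulate_counts
from tddseq.simulate import SampleDesign, build_ground_truth, graded_loading_truth

# --- enrichment tracks true Ago2 loading across a graded population
config = SimConfig(seed=3, periodate_leak=0.05)
truth = graded_loading_truth(20, seed=3)
designs = [SampleDesign("WT", lib, f"WT_c{c}", depth=100_000)
           for lib in ("total", "periodate") for c in (1, 2, 3)]
table = simulate_counts(truth, designs, config).species_level()
names = [s.name for s in truth]
total = mirna_space_abundance(table.counts[table.sample_ids(library_type="total")], names)
peri = mirna_space_abundance(table.counts[table.sample_ids(library_type="periodate")], names)
enrichment = ago2_enrichment(total, peri)
truth_frac = pd.Series({s.name: s.ago2_fraction for s in truth})
rho = spearmanr(enrichment[names], truth_frac[names]).statistic
print("species   true ago2   enrichment E")
for name in names[::5]:
    print(f"  {name}   {truth_frac[name]:.2f}       {enrichment[name]:.2f}")
print(f"Spearman rho(E, true ago2 fraction) = {rho:.3f}")
print("-> E rises monotonically with Ago2 loading; E<1 marks Ago1-enriched "
      "species, E>3 strongly Ago2-enriched ones.\n")

# --- cohort selection on the designed population
from tddseq import analyze_counts
from tddseq.simulate import default_designs

config = SimConfig(seed=4)
truth = build_ground_truth(config)
counts = simulate_counts(truth, default_designs(config, depth=30_000), config)
mirnas = [s.name for s in truth if s.rna_class == "miRNA"]
analysis = analyze_counts(counts.species_level(), counts, mirnas)
designated = sorted(s.name for s in truth if "ago1_cohort" in s.tags)
print("designated Ago1 cohort:", designated)
print("selected   Ago1 cohort:", analysis.cohort_ago1.members)
print("selection stages:", analysis.cohort_ago1.criteria["stage_counts"])
print("-> the abundant, Ago1-enriched, Dora-insensitive set is recovered "
      "and becomes the normalization denominator.")
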