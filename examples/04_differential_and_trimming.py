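"""Dora-sensitivity calls and the trimming-change statistic.

Runs the cohort-normalized Welch differential test on Ago1-IP vs Ago2-IP
libraries (dora vs wild type) and computes, per siRNA, the summed change in
trimmed-isoform fractional abundance upon loss of Dora.
"""

from tddseq import SimConfig, analyze_counts, simulate_counts, welch_t
from tddseq.simulate import build_ground_truth, default_designs

config = SimConfig(seed=5)
truth = build_ground_truth(config)
counts = simulate_counts(truth, default_designs(config, depth=50_000), config)
mirnas = [s.name for s in truth if s.rna_class == "miRNA"]
analysis = analyze_counts(counts.species_level(), counts, mirnas)

sensitive = {s.name for s in truth if "dora_sensitive" in s.tags}
for library in ("ago1_ip", "ago2_ip"):
    de = analysis.de[library]
    flagged = sorted(de.index[de["sensitive"]])
    print(f"{library}: {len(flagged)} species up-regulated upon loss of Dora")
    for name in flagged:
        print(f"  {name:14s} log2FC={de.at[name, 'log2FC']:+.2f} "
              f"p_adj={de.at[name, 'p_adj']:.2e}")
print(f"planted Dora-sensitive species: {sorted(sensitive)}")
print("-> TDD substrates surface only in the Ago1 pool; Ago2-loaded copies "
      "of the very same species are untouched.\n")

trimming = analysis.trimming
groups = {True: [], False: []}
for name, row in trimming.iterrows():
    groups[name in sensitive].append(row["delta"])
res = welch_t(groups[True], groups[False])
print("trimming-change statistic (sum of dora - WT trimmed fractions):")
print(f"  sensitive   mean delta = {sum(groups[True]) / len(groups[True]):+.3f}")
print(f"  insensitive mean delta = {sum(groups[False]) / len(groups[False]):+.3f}")
print(f"  Welch t = {res.t:.2f}, p = {res.p:.2e}")
print("-> losing Dora leaves sensitive species' Ago1-loaded molecules "
      "engaged with their targets longer, so trimmed isoforms accumulate.")
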