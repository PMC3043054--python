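"""Headline arithmetic of the packaged per-residue encounter table.

The package ships the per-residue binding time and primary/secondary hit
counts of Ca2+ around wild-type and E60D Calbindin D9k (1 microsecond of
trajectory each).  Pooling both variants reproduces the headline numbers.
"""

import ionshells as ish

table = ish.load_residue_encounter_table()
stats = ish.summarize_encounters(table)

print(f"pooled primary encounters:   {stats['primary_count']}")
print(f"pooled secondary encounters: {stats['secondary_count']}")
print(f"secondary/primary ratio:     {stats['secondary_primary_ratio']:.2f}")
print(f"mean interval between primary hits:   {stats['mean_primary_interval_ns']:.1f} ns")
print(f"mean interval between secondary hits: {stats['mean_secondary_interval_ns']:.1f} ns")

top = (
    table.groupby("residue", as_index=False)[["binding_time_ps", "primary_encounters"]]
    .sum()
    .nlargest(5, "binding_time_ps")
)
print("\ntop 5 residues by total binding time (both variants):")
print(top.to_string(index=False))
# about a quarter of all contacts are reached by surface transfer rather
# than directly from solution, and a handful of acidic residues dominate
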