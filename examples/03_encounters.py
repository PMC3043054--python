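"""Primary vs secondary encounter bookkeeping on a surface-hopping ledger.

A continuous-time Markov chain hops an ion between labelled surface sites
and the bulk; the classifier labels each contact primary (arrived from
bulk) or secondary (transferred from another site without leaving the
first shell) and the result is checked against the generator's own books.
"""

import ionshells as ish
from ionshells.encounters import (
    classify_encounters, contacts_from_indicators, summary_stats, transfer_counts,
)

ind, first_shell, times, ledger = ish.gen_hopping_contacts(
    n_sites=4, entry_rate=0.002, hop_rate=0.005, escape_rate=0.05,
    t_total=500_000.0, seed=4,
)
events = classify_encounters(contacts_from_indicators(ind, 2), first_shell, times)
stats = summary_stats(events, len(times), 1.0)

print(f"contacts: {len(events)}  "
      f"primary: {stats['primary_count']}  secondary: {stats['secondary_count']}")
print(f"secondary/primary ratio: {stats['secondary_primary_ratio']:.2f} "
      f"(ledger: {ledger.summary['secondary_primary_ratio']:.2f})")
print(f"free fraction: {stats['free_fraction']:.2f}  "
      f"mean interval between primary hits: {stats['mean_primary_interval']/1000:.1f} ns")
print("\nbinding table (per site):")
print(ish.binding_table(events).to_string(index=False))
print("\ntransfers between site pairs (either direction):")
for pair, n in sorted(transfer_counts(events).items(), key=lambda kv: -kv[1]):
    print(f"  {' <-> '.join(sorted(pair))}: {n}")
# the ratio counts how often the surface passes the ion between sites
# instead of releasing it to the bulk -- the antenna effect
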