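# ionshells

Solvation-shell residence, surface diffusion and encounter kinetics of ions
around proteins, from molecular-dynamics trajectories.

Small ions such as Ca²⁺ do not bind a protein in a single step: they linger
in discrete solvation shells around the surface, skim laterally between
charged residues, and are often handed from one surface site to the next
before reaching a specific binding site. `ionshells` turns raw MD
trajectories (or its own ground-truthed synthetic ones) into the
quantities that describe this process:

- **Shell occupancy** — the ion–protein distance `d` (minimum-image
  distance to the nearest heavy protein atom) is discretized into
  concentric shells: direct contact `d < 0.35` nm, a water-mediated second
  shell `0.35 ≤ d < 0.60` nm, then 0.25 nm layers out to 2.1 nm.
- **Residence kinetics** — maximal stays in a shell (excursions ≤ 2 ps are
  bridged) give a survival curve `N(t) = #{stays ≥ t}`, fitted with
  `N(t) ≈ A₁e^(−t/τ₁) + A₂e^(−t/τ₂)` on the section with counts above 10;
  τ₁ is the fast brush-past phase, τ₂ the electrostatically trapped one.
- **Diffusion** — `D = slope/6` of the time-origin-averaged MSD over a
  configurable lag window, optionally conditioned on the ion staying in
  one shell, and per-residence-event maximum MSD in the protein-fitted
  (Kabsch-superposed) frame to measure surface roaming.
- **Encounters** — ion–residue contacts are classified *primary* (reached
  from the bulk) or *secondary* (transferred from another residue without
  leaving the first shell); per-residue binding times, hit counts,
  transfer counts and headline ratios follow.
- **Kinetics** — Debye length, and the Debye–Smoluchowski
  diffusion-limited rate `k_on = 4π(D₁+D₂)R_eff·N_A` with
  `1/R_eff = ∫_R^∞ e^{U(r)/k_BT} r⁻² dr` for a screened-Coulomb `U`, for
  comparison with measured encounter intervals.

Trajectory input goes through MDAnalysis (PDB/GRO topologies; XTC/TRR/DCD
coordinates); a plain-text internal format supports diffable fixtures.
Seeded synthetic generators (free Brownian ion, Langevin ion around a
sphere with attractive surface wells, Markov site-hopping with an exact
event ledger) provide ground truth for every stage.

## Worked example

```python
import ionshells as ish
out = ish.pseudo_first_order(3e10, 0.025)   # k_on [M^-1 s^-1], [Ca2+] [M]
print(out)                                   # {'rate': 7.5e8, 'mean_interval_ns': 1.33}
```

A diffusion-limited `k_on` of 3×10¹⁰ M⁻¹s⁻¹ at 25 mM free ion gives an
apparent rate of ~0.8×10⁹ s⁻¹, i.e. one bulk encounter every ~1.3 ns.
The packaged per-residue encounter table reproduces the same number from
trajectory bookkeeping:

```
$ ionshells summarize-table
{
 "mean_primary_interval_ns": 1.2961762799740766,
 "mean_secondary_interval_ns": 4.3763676148796495,
 "primary_count": 1543,
 "secondary_count": 457,
 "secondary_primary_ratio": 0.2961762799740765,
 ...
}
```

Primary encounters arrive every ~1.3 ns (matching the diffusion-limited
prediction), secondary transfers every ~4 ns, and roughly 0.3 secondary
hits occur per primary hit — a quarter of all contacts reach their residue
by surface transfer rather than from solution.

The scripts in `examples/` each exercise one capability end to end
(shell/residence analysis, diffusion recovery, encounter classification
against a generator ledger, kinetics, printed-table summaries), e.g.:

```
$ python examples/02_diffusion.py
generator D = 1.584e-05 cm^2/s
recovered D = 1.571e-05 cm^2/s  (r^2 = 1.00000)
first-shell D = 6.022e-06 cm^2/s vs bulk D = 1.176e-05 cm^2/s
the surface wells slow the ion: shell-conditioned D < bulk D
```

A thin CLI (`ionshells simulate|run-all|shells|residence|diffusion|`
`encounters|kinetics|summarize-table`) wraps the same library calls for
shell use; `run-all` executes every stage from a YAML config and writes
deterministic CSV/JSON tables plus a reproducibility manifest.

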