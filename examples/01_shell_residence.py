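"""Shell occupancy and residence kinetics of a surface-trapped ion.

Generates a Brownian ion around a pseudo-protein sphere with attractive
surface wells, assigns each frame to a distance shell, and fits the
bi-exponential survival of first-shell residence events.
"""

import numpy as np

import ionshells as ish
from ionshells.config import BULK, ShellScheme

scheme = ShellScheme()
traj, ledger = ish.gen_langevin_surface(well_depth=7.0, n_steps=40_000, seed=1)
ds = ish.min_distance_series(traj, "CA1")
shells = ish.assign_shells(ds.d, scheme)

print("occupancy fraction per shell (1 = direct contact):")
for s in range(1, 5):
    print(f"  shell {s} ({scheme.label(s)} nm): {np.mean(shells == s):.3f}")
print(f"  bulk   ({scheme.label(BULK)} nm): {np.mean(shells == BULK):.3f}")

events = ish.extract_residence_events(shells, traj.times, scheme, grace_time=2.0)
shell1 = [e for e in events if e.shell == 1]
curve = ish.survival_curve(shell1, dt=traj.dt)
fit = ish.fit_exponential(curve, order=2, seed=1)
print(f"\nfirst-shell residence: {len(shell1)} events")
print(f"bi-exponential fit: tau1={fit.taus[0]:.2f} ps (brief brushes), "
      f"tau2={fit.taus[1]:.1f} ps (well-trapped stays), "
      f"rel RMS error {fit.rel_rms_error:.3f}")
# the slow tau measures how long the wells hold the ion; deeper wells
# stretch it while the fast tau stays at the frame-scale collision time
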