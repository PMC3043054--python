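"""Analysis configuration: shell scheme and global parameters.

All distances are in nm and all times in ps throughout the package;
unit conversions happen only at the I/O boundary and in the kinetics
module (which reports rates in the conventional cm^2/s and M^-1 s^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Default shell boundaries (nm) measured from the protein surface:
#: first shell is direct contact (d < 0.35 nm), second shell is one
#: water-mediated layer (0.35-0.60 nm), then consecutive 0.25 nm layers
#: out to 2.10 nm; everything beyond is bulk.
DEFAULT_SHELL_BOUNDARIES = (0.35, 0.60, 0.85, 1.10, 1.35, 1.60, 1.85, 2.10)

#: Sentinel shell index for "beyond the last boundary".
BULK = -1


@dataclass(frozen=True)
class ShellScheme:
    """Concentric distance layers around the protein surface.

    Shells are half-open intervals ``[lo, hi)``: shell 1 is ``[0, b[0])``,
    shell i is ``[b[i-2], b[i-1])``, and distances at or beyond the last
    boundary are bulk.  Shell indices are 1-based; :data:`BULK` marks bulk.
    """

    boundaries: tuple[float, ...] = DEFAULT_SHELL_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size == 0:
            raise ValueError("boundaries must be a non-empty 1-D sequence")
        if not np.all(np.diff(b) > 0) or b[0] <= 0:
            raise ValueError("shell boundaries must be positive and strictly increasing")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def n_shells(self) -> int:
        return len(self.boundaries)

    def label(self, index: int) -> str:
        """Human-readable distance range for a shell index."""
        if index == BULK:
            return f"d>{self.boundaries[-1]:g}"
        if index == 1:
            return f"d<{self.boundaries[0]:g}"
        return f"{self.boundaries[index - 2]:g}<d<{self.boundaries[index - 1]:g}"


@dataclass(frozen=True)
class AnalysisConfig:
    """Bundle of the tunable parameters shared across analysis stages.

    Parameters
    ----------
    shell_boundaries : sequence of float
        Shell edges in nm (see :class:`ShellScheme`).
    contact_cutoff : float
        Ion--heavy-atom distance (nm) below which a residue/atom is "in
        contact".  Default 0.35 nm, the first-shell boundary; 0.30 nm is
        the common stricter alternative.
    grace_time : float
        Excursions away from a shell (or contact) lasting at most this
        long (ps) do not terminate a residence period.  Default 2 ps.
    msd_fit_window : (float, float)
        Lag-time window (ps) for the linear MSD fit.
    min_fit_count : int
        Survival-curve points with counts at or below this value are
        discarded before exponential fitting.  Default 10.
    heavy_atoms_only : bool
        Whether hydrogens are ignored in all distance work.
    seed : int
        Seed for any stochastic step (multi-start fits, generators).
    """

    shell_boundaries: Sequence[float] = DEFAULT_SHELL_BOUNDARIES
    contact_cutoff: float = 0.35
    grace_time: float = 2.0
    msd_fit_window: tuple[float, float] = (10.0, 100.0)
    min_fit_count: int = 10
    heavy_atoms_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        ShellScheme(tuple(self.shell_boundaries))  # validates monotonicity
        if self.grace_time < 0:
            raise ValueError("grace_time must be >= 0")
        if self.min_fit_count < 1:
            raise ValueError("min_fit_count must be >= 1")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")
        lo, hi = self.msd_fit_window
        if not lo < hi:
            raise ValueError("msd_fit_window must be an increasing (lo, hi) pair")

    @property
    def shells(self) -> ShellScheme:
        return ShellScheme(tuple(self.shell_boundaries))
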