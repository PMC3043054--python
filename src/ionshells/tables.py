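"""Packaged reference tables and their summary arithmetic.

Two small tables from the Calbindin D9k / Ca2+ study ship with the package:

* ``shell_residence_times.csv`` -- per-shell bi-exponential residence time
  constants (tau1, tau2 in ps) and the relative RMS error of each fit;
* ``residue_encounters.csv`` -- per-residue total binding time and
  primary/secondary encounter counts for the wild-type and E60D variants
  (1 microsecond of trajectory each).

:func:`summarize_encounters` reproduces the headline bookkeeping: the
pooled secondary/primary ratio and the mean time between primary (and
between secondary) encounters over the total simulated time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_shell_residence_table",
    "load_residue_encounter_table",
    "summarize_encounters",
]

#: Total simulated time behind the encounter table: 10 x 100 ns per variant.
ENCOUNTER_TABLE_TOTAL_NS = 2000.0


def _read(name: str) -> pd.DataFrame:
    with resources.files("ionshells.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_shell_residence_table() -> pd.DataFrame:
    """Per-shell residence time constants (columns: shell_range, tau1_ps,
    tau2_ps, rel_rms_error)."""
    return _read("shell_residence_times.csv")


def load_residue_encounter_table(variant: str | None = None) -> pd.DataFrame:
    """Per-residue binding times and encounter counts.

    ``variant`` filters to "WT" or "E60D"; default returns both.
    """
    df = _read("residue_encounters.csv")
    if variant is not None:
        if variant not in ("WT", "E60D"):
            raise ValueError("variant must be 'WT' or 'E60D'")
        df = df[df["variant"] == variant].reset_index(drop=True)
    return df


def summarize_encounters(
    table: pd.DataFrame | None = None,
    total_time_ns: float = ENCOUNTER_TABLE_TOTAL_NS,
) -> dict[str, float]:
    """Pooled encounter statistics from a per-residue count table.

    The secondary/primary ratio pools every row of the given table (both
    variants when uncut), and the mean encounter intervals divide the total
    simulated time by the pooled counts.
    """
    if table is None:
        table = load_residue_encounter_table()
    n_prim = int(table["primary_encounters"].sum())
    n_sec = int(table["secondary_encounters"].sum())
    if n_prim == 0:
        raise ValueError("no primary encounters in table")
    return {
        "primary_count": n_prim,
        "secondary_count": n_sec,
        "secondary_primary_ratio": n_sec / n_prim,
        "mean_primary_interval_ns": total_time_ns / n_prim,
        "mean_secondary_interval_ns": (total_time_ns / n_sec) if n_sec else float("inf"),
        "total_binding_time_ps": float(table["binding_time_ps"].sum()),
    }
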