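"""Mean-square displacement and diffusion-coefficient estimation.

MSD curves are time-origin averaged within segments (so shell-conditioned
statistics never average across a shell exit), the diffusion coefficient is
the slope/6 of a straight-line fit over a configurable lag window, and the
per-residence-event "maximum MSD" measures how far an ion roamed over the
protein surface during a single stay, in the protein-fixed frame.

Unit convention: positions in nm, lags in ps; 1 nm^2/ps = 1e-2 cm^2/s, so
D is reported in cm^2/s via slope/6 * 1e-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy import stats

from .shells import ResidenceEvent

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "EventMobility",
    "msd_curve",
    "estimate_D",
    "shell_conditioned_msd",
    "event_max_msd",
    "exceedance_curve",
    "NM2_PER_PS_TO_CM2_PER_S",
]

log = logging.getLogger(__name__)

NM2_PER_PS_TO_CM2_PER_S = 1e-2  # (1e-7 cm)^2 / 1e-12 s


@dataclass
class MSDCurve:
    """Time-origin-averaged mean-square displacement.

    ``n_samples[k]`` is the number of (origin, origin+lag) pairs that
    contributed at lag ``lags[k]``; ``n_contributing_sims`` counts distinct
    source trajectories.
    """

    lags: np.ndarray  # ps
    msd: np.ndarray  # nm^2
    n_samples: np.ndarray
    n_contributing_sims: int = 1


@dataclass
class DiffusionEstimate:
    D: float  # cm^2/s
    fit_window: tuple[float, float]  # ps
    slope_stderr: float  # cm^2/s equivalent on D
    linearity_r2: float


@dataclass
class EventMobility:
    """Maximum squared displacement from the entry position during one
    residence event, in the protein-fitted frame."""

    event: ResidenceEvent
    max_msd: float  # nm^2


def _segment_msd_sums(
    x: np.ndarray, segments: list[tuple[int, int]], max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared displacements and pair counts per lag (1..max_lag),
    pairs restricted to lie within a single [a, b) segment."""
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    for a, b in segments:
        seg = x[a:b]
        n = b - a
        for lag in range(1, min(max_lag, n - 1) + 1):
            d = seg[lag:] - seg[:-lag]
            sums[lag] += np.einsum("ij,ij->", d, d)
            counts[lag] += n - lag
    counts[0] = sum(b - a for a, b in segments)
    return sums, counts


def msd_curve(
    positions: np.ndarray,
    dt: float,
    segments: list[tuple[int, int]] | None = None,
    max_lag_frames: int | None = None,
    n_contributing_sims: int = 1,
) -> MSDCurve:
    """Time-origin-averaged MSD of an unwrapped position series.

    ``segments`` are half-open frame ranges; displacement pairs never cross
    a segment boundary.  Default: the whole series, lags up to a quarter of
    its length (origin statistics degrade beyond that).
    """
    x = np.asarray(positions, dtype=float)
    n = x.shape[0]
    if segments is None:
        segments = [(0, n)]
    for a, b in segments:
        if not (0 <= a < b <= n):
            raise ValueError(f"segment ({a}, {b}) outside series of length {n}")
    longest = max(b - a for a, b in segments)
    if max_lag_frames is None:
        max_lag_frames = max(longest // 4, 1)
    sums, counts = _segment_msd_sums(x, segments, max_lag_frames)
    valid = counts > 0
    if not valid[1:].any():
        raise ValueError("no displacement pair available at any requested lag")
    lags = np.flatnonzero(valid) * dt
    msd = np.where(counts[valid] > 0, sums[valid] / np.maximum(counts[valid], 1), 0.0)
    return MSDCurve(
        lags=lags,
        msd=msd,
        n_samples=counts[valid],
        n_contributing_sims=n_contributing_sims,
    )


def estimate_D(
    curve: MSDCurve,
    fit_window: tuple[float, float] = (10.0, 100.0),
    r2_warn: float = 0.98,
) -> DiffusionEstimate:
    """Diffusion coefficient from the MSD slope over a lag window.

    For 3-D diffusion MSD(t) = 6 D t, so D = slope/6, converted from
    nm^2/ps to cm^2/s.  Poor linearity (r^2 below ``r2_warn``) is logged:
    it signals a ballistic, confined or under-sampled regime where the
    Einstein relation does not hold on the chosen window.
    """
    lo, hi = fit_window
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 MSD lags inside fit window {fit_window}")
    res = stats.linregress(curve.lags[sel], curve.msd[sel])
    r2 = float(res.rvalue**2)
    if r2 < r2_warn:
        log.warning("MSD fit linearity r^2=%.4f below %.2f on window %s", r2, r2_warn, fit_window)
    D = float(res.slope) / 6.0 * NM2_PER_PS_TO_CM2_PER_S
    return DiffusionEstimate(
        D=max(D, 0.0),
        fit_window=(float(lo), float(hi)),
        slope_stderr=float(res.stderr) / 6.0 * NM2_PER_PS_TO_CM2_PER_S,
        linearity_r2=r2,
    )


def shell_conditioned_msd(
    runs: list[tuple[np.ndarray, list[tuple[int, int]]]],
    dt: float,
    min_sims: int = 8,
    max_lag_frames: int | None = None,
) -> MSDCurve:
    """Pool MSD statistics over segments during which the ion stayed in one
    shell, across independent simulations.

    ``runs`` is a list of ``(unwrapped_positions, segments)`` per
    simulation; segments are typically the frame ranges of grace-bridged
    residence events in the shell of interest.  At least ``min_sims``
    simulations must contribute a usable segment.
    """
    contributing = [
        (x, [(a, b) for a, b in segs if b - a >= 2]) for x, segs in runs
    ]
    contributing = [(x, segs) for x, segs in contributing if segs]
    if len(contributing) < min_sims:
        raise ValueError(
            f"only {len(contributing)} simulations contribute segments; "
            f"need at least {min_sims}"
        )
    if max_lag_frames is None:
        longest = max(b - a for _, segs in contributing for a, b in segs)
        max_lag_frames = max(longest // 4, 1)
    sums = np.zeros(max_lag_frames + 1)
    counts = np.zeros(max_lag_frames + 1, dtype=np.int64)
    for x, segs in contributing:
        s, c = _segment_msd_sums(np.asarray(x, float), segs, max_lag_frames)
        sums += s
        counts += c
    valid = counts > 0
    if not valid[1:].any():
        raise ValueError("no displacement pair available at any lag")
    return MSDCurve(
        lags=np.flatnonzero(valid) * dt,
        msd=sums[valid] / np.maximum(counts[valid], 1),
        n_samples=counts[valid],
        n_contributing_sims=len(contributing),
    )


def event_max_msd(
    events: list[ResidenceEvent],
    positions: np.ndarray,
    times: np.ndarray,
) -> list[EventMobility]:
    """Per-event maximum squared displacement from the entry position.

    ``positions`` must be the ion path in the protein-fitted frame (global
    protein rotation/translation removed) on the grid ``times``.
    """
    x = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(x) != len(times):
        raise ValueError("positions/times length mismatch")
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    out = []
    for e in events:
        a = int(round((e.t_start - times[0]) / dt))
        b = a + int(round(e.duration / dt))
        if a < 0 or b > len(x):
            raise ValueError("event lies outside the position series")
        d = x[a:b] - x[a]
        out.append(EventMobility(event=e, max_msd=float((d**2).sum(axis=1).max())))
    return out


def exceedance_curve(mobilities: list[EventMobility], thresholds: np.ndarray) -> np.ndarray:
    """Fraction of events whose maximum MSD is at least each threshold
    (non-increasing, in [0, 1])."""
    if not mobilities:
        raise ValueError("no event mobilities")
    vals = np.sort([m.max_msd for m in mobilities])
    thresholds = np.asarray(thresholds, dtype=float)
    return 1.0 - np.searchsorted(vals, thresholds - 1e-12, side="left") / len(vals)
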