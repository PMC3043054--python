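"""Shell occupancy, residence-event extraction, survival curves, exp fits.

An ion's distance to the nearest protein atom is discretized into concentric
shells.  Residence periods in a shell are maximal runs of frames, where brief
excursions to other shells (at most the grace time, 2 ps by default) are
bridged and do not terminate the period.  The survival curve N(t) counts the
residence occurrences lasting at least t; it is fitted with one or two
exponentials, keeping only the section of the curve with counts above a
minimum (10 by default) where the statistics are reliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import BULK, ShellScheme

__all__ = [
    "ResidenceEvent",
    "SurvivalCurve",
    "ExpFit",
    "assign_shells",
    "occupancy_histogram",
    "bridge_indicator",
    "extract_residence_events",
    "survival_curve",
    "fit_exponential",
    "directional_residence",
]


@dataclass(frozen=True)
class ResidenceEvent:
    """One uninterrupted (grace-bridged) stay of an ion in one shell.

    ``duration`` counts the occupied frames times the frame spacing (a
    single-frame visit lasts one frame time).  ``exit_direction`` records
    which way the ion left: toward the protein ("inward"), away from it
    ("outward"), or "end_of_data" when the trajectory ends mid-stay.
    """

    ion: str
    shell: int
    t_start: float  # ps
    t_end: float  # ps
    duration: float  # ps
    exit_direction: str  # inward | outward | end_of_data

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.exit_direction not in ("inward", "outward", "end_of_data"):
            raise ValueError(f"bad exit_direction {self.exit_direction!r}")


@dataclass
class SurvivalCurve:
    """N(t): number of residence occurrences lasting at least t."""

    t: np.ndarray  # ps grid
    N: np.ndarray  # counts, non-increasing

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if np.any(np.diff(self.N) > 0):
            raise ValueError("survival counts must be non-increasing")


@dataclass
class ExpFit:
    """Mono- or bi-exponential fit N(t) ~ sum_i A_i exp(-t / tau_i).

    ``taus`` are sorted ascending (tau1 = fast, tau2 = slow).  The relative
    RMS error is RMS(residuals)/RMS(N) over the points retained by the
    count filter.
    """

    order: int
    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]
    rel_rms_error: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for A, tau in zip(self.amplitudes, self.taus):
            out = out + A * np.exp(-t / tau)
        return out


def assign_shells(d: np.ndarray, scheme: ShellScheme) -> np.ndarray:
    """Map distances to 1-based shell indices; beyond the last boundary is
    :data:`BULK`.  Intervals are half-open ``[lo, hi)``."""
    d = np.asarray(d, dtype=float)
    idx = np.searchsorted(scheme.boundaries, d, side="right") + 1
    out = np.where(idx > scheme.n_shells, BULK, idx)
    return out.astype(int)


def occupancy_histogram(
    d: np.ndarray, bin_width: float = 0.01, d_max: float = 1.2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percent-of-time histogram of the ion--protein distance.

    Only frames with ``d <= d_max`` enter the denominator, mirroring the
    convention of expressing the dwelling probability relative to the time
    the ion spends within 1.2 nm of the protein.

    Returns ``(bin_edges, percent, cumulative_percent)``; percents sum to
    100 over the bins.
    """
    d = np.asarray(d, dtype=float)
    inside = d[d <= d_max]
    if inside.size == 0:
        raise ValueError(f"no frames within d_max={d_max} nm")
    edges = np.arange(0.0, d_max + bin_width, bin_width)
    counts, edges = np.histogram(inside, bins=edges)
    pct = 100.0 * counts / inside.size
    return edges, pct, np.cumsum(pct)


def bridge_indicator(ind: np.ndarray, max_gap_frames: int) -> np.ndarray:
    """Fill False-gaps of length <= max_gap_frames that separate True runs.

    Leading/trailing gaps are never bridged (there is no run on one side).
    """
    ind = np.asarray(ind, dtype=bool).copy()
    if max_gap_frames <= 0 or not ind.any():
        return ind
    n = len(ind)
    i = 0
    prev_true_end = -1
    while i < n:
        if ind[i]:
            i += 1
            continue
        j = i
        while j < n and not ind[j]:
            j += 1
        # gap [i, j); bridge only if bounded by True on both sides
        if i > 0 and j < n and (j - i) <= max_gap_frames:
            ind[i:j] = True
        i = j
    del prev_true_end
    return ind


def extract_residence_events(
    shell_series: np.ndarray,
    times: np.ndarray,
    scheme: ShellScheme,
    grace_time: float = 2.0,
    ion: str = "ion",
) -> list[ResidenceEvent]:
    """Residence events for every shell (bulk included) of one ion.

    For each shell, frames in the shell form an indicator series; excursions
    of at most ``grace_time`` are bridged, and each maximal run becomes one
    event.  The exit direction compares the shell occupied at the first
    frame after the run with the run's shell (bulk counts as outermost).
    """
    shell_series = np.asarray(shell_series)
    times = np.asarray(times, dtype=float)
    if len(times) != len(shell_series):
        raise ValueError("shell series and times length mismatch")
    if len(times) < 2:
        raise ValueError("need at least two frames")
    dt = float(times[1] - times[0])
    if not np.allclose(np.diff(times), dt, rtol=1e-6):
        raise ValueError("residence extraction requires a uniform time step")
    max_gap = int(np.floor(grace_time / dt + 1e-9))

    def radial(s: int) -> int:
        # bulk is the outermost "shell" for direction purposes
        return scheme.n_shells + 1 if s == BULK else s

    events: list[ResidenceEvent] = []
    shells_present = np.unique(shell_series)
    for s in shells_present:
        ind = bridge_indicator(shell_series == s, max_gap)
        padded = np.concatenate(([False], ind, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
        for a, b in zip(starts, ends):
            if b >= len(shell_series):
                direction = "end_of_data"
            else:
                nxt = int(shell_series[b])
                direction = "inward" if radial(nxt) < radial(int(s)) else "outward"
            events.append(
                ResidenceEvent(
                    ion=ion,
                    shell=int(s),
                    t_start=float(times[a]),
                    t_end=float(times[a] + (b - a) * dt),
                    duration=float((b - a) * dt),
                    exit_direction=direction,
                )
            )
    events.sort(key=lambda e: (e.t_start, e.shell))
    return events


def survival_curve(events: list[ResidenceEvent], dt: float | None = None) -> SurvivalCurve:
    """Survival count N(t) = #{events with duration >= t} on the frame grid."""
    if not events:
        raise ValueError("no residence events")
    durations = np.array([e.duration for e in events])
    if dt is None:
        dt = float(np.min(durations))
    grid = np.arange(0.0, durations.max() + dt, dt)
    dsort = np.sort(durations)
    # N(t) = #durations >= t, with a tolerance for grid/duration float ties
    N = len(dsort) - np.searchsorted(dsort, grid - 1e-9, side="left")
    return SurvivalCurve(t=grid, N=N.astype(float))


def _log_linear_tau(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Amplitude and tau from a straight-line fit to log(y)."""
    good = y > 0
    if good.sum() < 2:
        return float(max(y.max(), 1.0)), max(float(t[-1] - t[0]), 1.0)
    slope, intercept = np.polyfit(t[good], np.log(y[good]), 1)
    tau = -1.0 / slope if slope < 0 else float(t[-1] - t[0] + 1.0)
    return float(np.exp(intercept)), float(tau)


def fit_exponential(
    curve: SurvivalCurve,
    order: int = 2,
    min_count: int = 10,
    n_restarts: int = 20,
    seed: int = 0,
) -> ExpFit:
    """Nonlinear least-squares exponential fit of a survival curve.

    Only points with counts strictly above ``min_count`` are retained, and
    the leading saturated plateau (points still equal to the total event
    count) is dropped: every event lasts at least one frame, so those
    points are fixed by the event count alone and carry no decay
    information, while their large values would otherwise dominate the
    least squares.  Parameters are optimized in log space (positivity by
    construction) with head/tail log-linear initial guesses and up to
    ``n_restarts`` seeded multi-start perturbations; the best sum of
    squares wins, making the result deterministic given (data, config).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    keep = curve.N > min_count
    # drop the saturated head: when several leading points equal the total
    # event count, the curve has not started decaying there (every event
    # lasts at least one frame) and those points are purely definitional
    sat = np.flatnonzero(curve.N >= curve.N.max())
    if len(sat) > 1:
        keep[sat] = False
    t, N = curve.t[keep], curve.N[keep]
    if len(t) < 3 * order:
        raise ValueError(
            f"only {len(t)} points above the count filter; need >= {3 * order}"
        )

    def model(p: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            A = np.exp(np.clip(p[:order], -700, 700))
            tau = np.exp(np.clip(p[order:], -700, 700))
            return (A[:, None] * np.exp(-t[None, :] / tau[:, None])).sum(axis=0)

    def resid(p: np.ndarray) -> np.ndarray:
        r = model(p) - N
        return np.where(np.isfinite(r), r, 1e12)

    # initial guesses: tail -> slow tau, remainder head -> fast tau
    n = len(t)
    A_tail, tau_slow = _log_linear_tau(t[n // 2 :], N[n // 2 :])
    if order == 1:
        starts = [np.log([max(A_tail, 1e-6), max(tau_slow, 1e-3)])]
    else:
        head = N[: max(n // 4, 3)] - A_tail * np.exp(-t[: max(n // 4, 3)] / tau_slow)
        A_fast, tau_fast = _log_linear_tau(t[: max(n // 4, 3)], np.clip(head, 0, None))
        tau_fast = min(tau_fast, 0.9 * tau_slow)
        starts = [
            np.log(
                [
                    max(A_fast, 1e-6),
                    max(A_tail, 1e-6),
                    max(tau_fast, 1e-3),
                    max(tau_slow, 1e-3),
                ]
            )
        ]
    rng = np.random.default_rng(seed)
    starts += [starts[0] + rng.normal(scale=0.5, size=2 * order) for _ in range(n_restarts)]

    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    if best is None:
        raise RuntimeError("exponential fit failed to converge from any start")

    A = np.exp(best.x[:order])
    tau = np.exp(best.x[order:])
    idx = np.argsort(tau)
    A, tau = A[idx], tau[idx]
    rel = float(np.sqrt(np.mean(resid(best.x) ** 2)) / np.sqrt(np.mean(N**2)))
    return ExpFit(
        order=order,
        amplitudes=tuple(float(a) for a in A),
        taus=tuple(float(x) for x in tau),
        rel_rms_error=rel,
    )


def directional_residence(
    events: list[ResidenceEvent],
    direction: str,
    fit: bool = False,
    min_count: int = 10,
) -> dict[int, float | ExpFit]:
    """Per-shell mean residence time restricted to one exit direction.

    With ``fit=True`` the value is instead the slow time constant of a
    mono-exponential fit of that sub-population's survival curve.
    """
    if direction not in ("inward", "outward", "end_of_data"):
        raise ValueError(f"bad direction {direction!r}")
    chosen = [e for e in events if e.exit_direction == direction]
    if not chosen:
        raise ValueError(f"no events with exit_direction={direction!r}")
    out: dict[int, float | ExpFit] = {}
    for s in sorted({e.shell for e in chosen}):
        evs = [e for e in chosen if e.shell == s]
        if fit:
            out[s] = fit_exponential(survival_curve(evs), order=1, min_count=min_count)
        else:
            out[s] = float(np.mean([e.duration for e in evs]))
    return out
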