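"""Ion--residue contact detection and encounter bookkeeping.

A contact is a maximal interval during which at least one heavy atom of an
entity (a residue, a single oxygen atom, or a merged carboxylate pair) lies
within a cutoff of the ion, with short gaps bridged.  Each contact is then
classified:

* **primary** -- the ion arrived from the bulk;
* **secondary** -- the ion transferred from another surface entity without
  ever leaving the (grace-bridged) first solvation shell in between.

Secondary encounters are the signature of surface hopping: the protein
surface acts as an antenna that passes the ion between nearby residues.
The module also aggregates per-entity binding times, hit counts, transfer
counts between entity pairs, and headline statistics (secondary/primary
ratio, encounter intervals, contact concurrency, free fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import min_image_displacement
from .shells import bridge_indicator

__all__ = [
    "ContactEvent",
    "detect_contacts",
    "contacts_from_indicators",
    "classify_encounters",
    "binding_table",
    "transfer_counts",
    "summary_stats",
]

Entity = Hashable


@dataclass(frozen=True)
class ContactEvent:
    """One classified ion--entity contact on the frame grid [start, end)."""

    ion: str
    entity: Entity
    start_frame: int
    end_frame: int  # exclusive
    t_start: float  # ps
    t_end: float  # ps
    classification: str  # primary | secondary
    origin_entity: Entity | None = None  # previous entity for secondary

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("contact must have positive duration")
        if self.classification not in ("primary", "secondary"):
            raise ValueError(f"bad classification {self.classification!r}")
        if self.classification == "secondary" and self.origin_entity in (None, self.entity):
            raise ValueError("secondary contact requires a distinct origin entity")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _runs(ind: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], np.asarray(ind, bool), [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return list(zip(starts.tolist(), ends.tolist()))


def _entity_key(atom, granularity: str) -> Entity:
    reslab = f"{atom.residue_name}{atom.residue_id}"
    if granularity == "residue":
        return reslab
    if granularity == "atom":
        return f"{reslab}:{atom.atom_name}"
    if granularity == "carboxylate":
        if atom.oxygen_class == "sidechain_carboxylate":
            return f"{reslab}:COO"
        return f"{reslab}:{atom.atom_name}"
    raise ValueError(f"unknown granularity {granularity!r}")


def detect_contacts(
    traj,
    ion_label: str,
    cutoff: float = 0.35,
    granularity: str = "residue",
    grace_time: float = 2.0,
    heavy_only: bool = True,
    atom_filter=None,
) -> dict[Entity, list[tuple[int, int]]]:
    """Raw contact intervals per entity, as half-open frame ranges.

    ``granularity`` is one of ``"residue"``, ``"atom"`` or
    ``"carboxylate"`` (atom-level, but the two carboxylate oxygens of an
    ASP/GLU side chain count as a single entity, since an ion shuttling
    between them has not left the group).  ``atom_filter`` optionally
    restricts the atoms considered (callable AtomMeta -> bool), e.g. to
    backbone carbonyl or side-chain oxygens only.
    """
    i = traj.ion_index(ion_label)
    keep = [
        k
        for k, a in enumerate(traj.atoms)
        if (a.is_heavy or not heavy_only) and (atom_filter is None or atom_filter(a))
    ]
    if not keep:
        raise ValueError("no atoms left after filtering")
    dt = traj.dt
    max_gap = int(np.floor(grace_time / dt + 1e-9))
    ion_xyz = traj.ion_coords[:, i, :][:, None, :]
    coords = traj.protein_coords[:, keep, :]
    F = traj.n_frames
    within = np.empty((F, len(keep)), dtype=bool)
    chunk = max(1, int(2e6 // max(len(keep), 1)))  # bound temp memory
    for a0 in range(0, F, chunk):
        a1 = min(a0 + chunk, F)
        delta = min_image_displacement(
            coords[a0:a1] - ion_xyz[a0:a1], traj.box[a0:a1, None, :]
        )
        within[a0:a1] = np.einsum("fad,fad->fa", delta, delta) < cutoff**2

    entities: dict[Entity, np.ndarray] = {}
    for col, k in enumerate(keep):
        key = _entity_key(traj.atoms[k], granularity)
        if key in entities:
            entities[key] = entities[key] | within[:, col]
        else:
            entities[key] = within[:, col].copy()
    return contacts_from_indicators(entities, max_gap)


def contacts_from_indicators(
    indicators: Mapping[Entity, np.ndarray], max_gap_frames: int
) -> dict[Entity, list[tuple[int, int]]]:
    """Grace-bridged contact intervals from per-entity boolean series."""
    out: dict[Entity, list[tuple[int, int]]] = {}
    for key, ind in indicators.items():
        runs = _runs(bridge_indicator(np.asarray(ind, bool), max_gap_frames))
        if runs:
            out[key] = runs
    return out


def classify_encounters(
    contacts: Mapping[Entity, Sequence[tuple[int, int]]],
    first_shell: np.ndarray,
    times: np.ndarray,
    grace_time: float = 2.0,
    ion: str = "ion",
) -> list[ContactEvent]:
    """Label every contact primary or secondary.

    ``first_shell`` is the per-frame boolean indicator of first-shell
    occupancy on the same grid as the contacts; exits of at most
    ``grace_time`` are bridged before applying the rule.  A contact is
    secondary iff the ion has remained continuously within the bridged
    first shell since the last frame it touched a *different* entity
    (including an entity it is still touching); the origin is the most
    recently touched such entity, ties broken by entity repr.
    """
    times = np.asarray(times, dtype=float)
    first_shell = np.asarray(first_shell, dtype=bool)
    if len(first_shell) != len(times):
        raise ValueError("first_shell and times length mismatch")
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    max_gap = int(np.floor(grace_time / dt + 1e-9))
    shell = bridge_indicator(first_shell, max_gap)

    # start frame of the bridged first-shell run containing each frame
    run_start = np.full(len(shell), -1, dtype=int)
    for a, b in _runs(shell):
        run_start[a:b] = a

    flat = [
        (int(a), int(b), ent)
        for ent, runs in contacts.items()
        for a, b in runs
    ]
    flat.sort(key=lambda r: (r[0], r[1], repr(r[2])))

    events: list[ContactEvent] = []
    for a, b, ent in flat:
        origin: Entity | None = None
        if shell[a] and run_start[a] >= 0:
            lo = run_start[a]
            best = None  # ranked by (last touch frame, entity repr)
            for a2, b2, ent2 in flat:
                if ent2 == ent or a2 >= a:
                    continue  # same entity, or not a *prior* contact
                last_touch = min(b2 - 1, a)  # most recent in-contact frame <= a
                if last_touch < lo:
                    continue  # ion left the first shell in between
                key = (last_touch, repr(ent2))
                if best is None or key > best[0]:
                    best = (key, ent2)
            if best is not None:
                origin = best[1]
        events.append(
            ContactEvent(
                ion=ion,
                entity=ent,
                start_frame=a,
                end_frame=b,
                t_start=float(times[a]),
                t_end=float(times[a] + (b - a) * dt),
                classification="primary" if origin is None else "secondary",
                origin_entity=origin,
            )
        )
    return events


def binding_table(events: Sequence[ContactEvent]) -> pd.DataFrame:
    """Per-entity totals: binding time, primary/secondary counts, mean dwell.

    ``binding_time`` is the union length of the entity's contact intervals
    (intervals of one entity are disjoint by construction, so the union is
    the plain sum).
    """
    rows: dict[Entity, dict] = {}
    for e in events:
        r = rows.setdefault(
            e.entity,
            {"binding_time": 0.0, "primary_count": 0, "secondary_count": 0, "dwells": []},
        )
        r["binding_time"] += e.duration
        r["dwells"].append(e.duration)
        r["primary_count" if e.classification == "primary" else "secondary_count"] += 1
    table = pd.DataFrame(
        [
            {
                "entity": ent,
                "binding_time": r["binding_time"],
                "primary_count": r["primary_count"],
                "secondary_count": r["secondary_count"],
                "mean_dwell": float(np.mean(r["dwells"])),
            }
            for ent, r in rows.items()
        ]
    )
    if len(table):
        table = table.sort_values("entity", key=lambda s: s.map(repr)).reset_index(drop=True)
    return table


def transfer_counts(
    events: Sequence[ContactEvent],
    pairs: Sequence[frozenset] | None = None,
) -> dict[frozenset, int]:
    """Number of ion transfers between entity pairs, both directions pooled.

    Each secondary contact contributes one transfer on the unordered
    (origin, destination) pair.  ``pairs`` restricts the report; default is
    every pair observed.
    """
    counts: dict[frozenset, int] = {}
    for e in events:
        if e.classification != "secondary":
            continue
        key = frozenset((e.origin_entity, e.entity))
        counts[key] = counts.get(key, 0) + 1
    if pairs is not None:
        return {frozenset(p): counts.get(frozenset(p), 0) for p in pairs}
    return counts


def summary_stats(
    events: Sequence[ContactEvent],
    n_frames: int,
    dt: float,
    total_time: float | None = None,
    entity_class: Mapping[Entity, str] | None = None,
) -> dict:
    """Headline encounter statistics.

    Returns secondary/primary ratio (None when no primary), mean interval
    between primary and between secondary encounters (total_time / count),
    mean number of simultaneously contacted entities over bound frames, and
    the fraction of frames free of any contact.  ``entity_class`` adds a
    per-class secondary/primary ratio breakdown (e.g. by oxygen class).
    """
    if total_time is None:
        total_time = n_frames * dt
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    n_prim = sum(e.classification == "primary" for e in events)
    n_sec = len(events) - n_prim

    contact_count = np.zeros(n_frames, dtype=int)
    for e in events:
        contact_count[e.start_frame : e.end_frame] += 1
    bound = contact_count > 0

    out = {
        "primary_count": int(n_prim),
        "secondary_count": int(n_sec),
        "secondary_primary_ratio": (n_sec / n_prim) if n_prim else None,
        "mean_primary_interval": (total_time / n_prim) if n_prim else None,
        "mean_secondary_interval": (total_time / n_sec) if n_sec else None,
        "mean_concurrent_contacts": float(contact_count[bound].mean()) if bound.any() else 0.0,
        "free_fraction": float(1.0 - bound.mean()),
    }
    if entity_class is not None:
        per_class: dict[str, dict] = {}
        for e in events:
            cls = entity_class.get(e.entity, "other")
            c = per_class.setdefault(cls, {"primary": 0, "secondary": 0})
            c[e.classification] += 1
        out["ratio_by_class"] = {
            cls: (c["secondary"] / c["primary"] if c["primary"] else None)
            for cls, c in per_class.items()
        }
    return out
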