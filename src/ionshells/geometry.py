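"""Periodic geometry: minimum-image distances, ion unwrapping, superposition.

The ion--protein distance that drives the whole shell analysis is defined as
the minimum-image distance between the ion and its nearest protein atom
(heavy atoms only by default).  Unwrapping removes box jumps so mean-square
displacements can be computed, and Kabsch superposition expresses the ion's
path in the protein's own frame, removing global protein rotation and
translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceSeries",
    "RigidTransform",
    "min_distance_series",
    "min_image_displacement",
    "unwrap_ion",
    "kabsch",
    "superpose_to_reference",
]


@dataclass
class DistanceSeries:
    """Per-frame minimum ion--protein distance.

    ``nearest_atom[f]`` is the atom_id of the closest protein atom at frame
    ``f`` (ties broken by lowest atom_id).
    """

    times: np.ndarray  # ps
    d: np.ndarray  # nm
    nearest_atom: np.ndarray  # atom_id per frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.nearest_atom = np.asarray(self.nearest_atom, dtype=int)
        if not (len(self.times) == len(self.d) == len(self.nearest_atom)):
            raise ValueError("length mismatch in DistanceSeries")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class RigidTransform:
    """Proper rotation + translation mapping one frame onto the reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), nm
    rmsd: float  # nm

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.rotation.T + self.translation


def min_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention for an
    orthorhombic box (component-wise nearest periodic image)."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_distance_series(traj, ion_label: str, heavy_only: bool = True) -> DistanceSeries:
    """Minimum-image distance from an ion to its nearest protein atom, per
    frame, via an exhaustive vectorized scan over atoms."""
    i = traj.ion_index(ion_label)
    mask = traj.heavy_mask() if heavy_only else np.ones(len(traj.atoms), bool)
    if not mask.any():
        raise ValueError("no protein atoms left after heavy-atom filtering")
    atom_ids = np.array([a.atom_id for a in traj.atoms])[mask]
    # lowest atom_id wins ties: scan in ascending-atom_id order
    order = np.argsort(atom_ids, kind="stable")
    coords = traj.protein_coords[:, mask, :][:, order, :]  # (F, A, 3)
    ion = traj.ion_coords[:, i, :][:, None, :]  # (F, 1, 3)
    F = traj.n_frames
    d_out = np.empty(F)
    nearest = np.empty(F, dtype=int)
    chunk = max(1, int(2e6 // max(coords.shape[1], 1)))  # bound temp memory
    ids_sorted = atom_ids[order]
    for a0 in range(0, F, chunk):
        a1 = min(a0 + chunk, F)
        delta = min_image_displacement(coords[a0:a1] - ion[a0:a1], traj.box[a0:a1, None, :])
        dist = np.sqrt(np.einsum("fad,fad->fa", delta, delta))
        best = np.argmin(dist, axis=1)  # argmin returns the first minimum
        rows = np.arange(a1 - a0)
        d_out[a0:a1] = dist[rows, best]
        nearest[a0:a1] = ids_sorted[best]
    return DistanceSeries(times=traj.times.copy(), d=d_out, nearest_atom=nearest)


def unwrap_ion(traj, ion_label: str) -> np.ndarray:
    """Continuous (unwrapped) ion coordinates.

    Accumulates minimum-image inter-frame displacements; requires the true
    per-frame displacement to stay below half a box length on every axis,
    otherwise the nearest image is ambiguous.
    """
    i = traj.ion_index(ion_label)
    x = traj.ion_coords[:, i, :]
    if traj.n_frames == 1:
        return x.copy()
    steps = min_image_displacement(np.diff(x, axis=0), traj.box[1:])
    half = traj.box[1:] / 2.0
    if np.any(np.abs(steps) >= half - 1e-12):
        raise ValueError(
            "inter-frame ion displacement reaches half the box; "
            "finer time sampling is required to unwrap unambiguously"
        )
    out = np.empty_like(x)
    out[0] = x[0]
    out[1:] = x[0] + np.cumsum(steps, axis=0)
    return out


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Classic SVD solution: with both point sets centered, the optimal proper
    rotation is ``V diag(1,1,s) W^T`` where ``U S W^T = svd(X^T Y)`` and the
    sign ``s`` enforces det = +1.  Returns the transform and its RMSD.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need matching (N>=3, 3) point sets")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear) sets leave the rotation about the line free
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    resid = X0 @ R.T - Y0
    rmsd = float(np.sqrt((resid**2).sum() / X.shape[0]))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def superpose_to_reference(
    traj,
    fit_selection: np.ndarray | None = None,
    ion_positions: dict[str, np.ndarray] | None = None,
    reference_frame: int = 0,
) -> tuple[list[RigidTransform], dict[str, np.ndarray]]:
    """Superpose every frame's fit atoms onto a reference frame and carry the
    (unwrapped) ion positions into the protein-fixed frame.

    Parameters
    ----------
    fit_selection : bool or index array over protein atoms, optional
        Atoms used for the fit.  Defaults to C-alpha atoms, falling back to
        all heavy atoms when no CA atoms exist (e.g. pseudo-proteins).
    ion_positions : mapping label -> (F, 3) unwrapped coordinates, optional
        Defaults to unwrapping every tracked ion.

    Returns
    -------
    transforms, ion_in_protein_frame
    """
    if fit_selection is None:
        ca = np.array([a.atom_name.upper() == "CA" for a in traj.atoms])
        fit_selection = ca if ca.any() else traj.heavy_mask()
    sel = np.asarray(fit_selection)
    pts = traj.protein_coords[:, sel, :] if sel.dtype == bool else traj.protein_coords[:, sel, :]
    if pts.shape[1] < 3:
        raise ValueError("need at least 3 fit atoms")
    if ion_positions is None:
        ion_positions = {lab: unwrap_ion(traj, lab) for lab in traj.ions}

    ref = pts[reference_frame]
    transforms: list[RigidTransform] = []
    fitted = {lab: np.empty_like(x) for lab, x in ion_positions.items()}
    for f in range(traj.n_frames):
        tr = kabsch(pts[f], ref)
        transforms.append(tr)
        for lab, x in ion_positions.items():
            fitted[lab][f] = tr.apply(x[f])
    return transforms, fitted
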