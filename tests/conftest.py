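import numpy as np
import pytest

from ionshells import AtomMeta, Trajectory


def make_traj(
    ion_xyz: np.ndarray,
    protein_xyz: np.ndarray | None = None,
    atoms: list[AtomMeta] | None = None,
    box: float = 10.0,
    dt: float = 1.0,
) -> Trajectory:
    """Small trajectory builder: ion_xyz (F, 3); protein_xyz either (A, 3)
    static or (F, A, 3); default atoms are heavy carbons."""
    ion_xyz = np.asarray(ion_xyz, dtype=float)
    F = ion_xyz.shape[0]
    if protein_xyz is None:
        protein_xyz = np.zeros((F, 0, 3))
    else:
        protein_xyz = np.asarray(protein_xyz, dtype=float)
        if protein_xyz.ndim == 2:
            protein_xyz = np.broadcast_to(protein_xyz, (F,) + protein_xyz.shape)
    A = protein_xyz.shape[1]
    if atoms is None:
        atoms = [
            AtomMeta(atom_id=k, residue_id=k, residue_name="ALA", atom_name="CA",
                     element="C", is_heavy=True)
            for k in range(A)
        ]
    return Trajectory(
        times=np.arange(F) * dt,
        box=np.full((F, 3), float(box)),
        protein_coords=protein_xyz,
        ion_coords=ion_xyz[:, None, :],
        atoms=atoms,
        ions=["ION1"],
    )


@pytest.fixture
def traj_factory():
    return make_traj
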