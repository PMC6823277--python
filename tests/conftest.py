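import numpy as np
import pytest

from ionbridge import synth
from ionbridge.io import AtomRecord, Topology, Trajectory


@pytest.fixture(scope="session")
def trimer():
    """Toy trimer topology and reference frame (no dynamics)."""
    spec = synth.default_spec(p=0.75, n_frames=10, seed=0)
    topology, ref = synth.build_toy_trimer(spec)
    return topology, ref


@pytest.fixture()
def single_chain_mke():
    """Met1–Lys2–Glu3 chain: N/CA/C backbones plus CE and CD side chains."""
    atoms = []
    coords = []
    serial = 1
    layout = [
        ("MET", 1, ["N", "CA", "C"]),
        ("LYS", 2, ["N", "CA", "C", "CE"]),
        ("GLU", 3, ["N", "CA", "C", "CD"]),
    ]
    for res_name, seq, names in layout:
        for k, name in enumerate(names):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    residue_name=res_name,
                    residue_seq=seq,
                    chain_id="A",
                    element=name[0],
                )
            )
            coords.append([seq * 0.4 + 0.1 * k, 0.3 * (name in ("CE", "CD")), 0.0])
            serial += 1
    return Topology(atoms=atoms), np.asarray(coords, dtype=float)


def make_two_atom_trajectory(distances, atom_names=("CE", "CD"), res=("LYS", "GLU")):
    """Trajectory of two reference atoms separated by the given distances."""
    atoms = [
        AtomRecord(1, atom_names[0], res[0], 1, "A", "C"),
        AtomRecord(2, atom_names[1], res[1], 2, "A", "C"),
    ]
    topology = Topology(atoms=atoms)
    d = np.asarray(distances, dtype=float)
    coords = np.zeros((d.size, 2, 3))
    coords[:, 1, 2] = d
    traj = Trajectory(coords=coords, frame_times=np.arange(d.size, dtype=float))
    return topology, traj
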