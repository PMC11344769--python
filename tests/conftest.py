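"""Shared fixtures: handwritten PDB text and synthetic toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from foldswitch.structure_io import read_structure
from foldswitch.synthetic import ToyPairSpec, make_ideal_backbone, make_toy_pair

# Three residues (ALA, GLY, SER) with backbone + CB where applicable.
# The GLY has no CB; the SER CA carries two altlocs (A occ 0.60, B occ 0.40).
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 12.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 11.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 11.50           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00 13.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 20.00           N
ATOM      7  CA  GLY A   2       3.988   2.830   0.050  1.00 22.00           C
ATOM      8  C   GLY A   2       5.490   2.690   0.100  1.00 21.00           C
ATOM      9  O   GLY A   2       6.030   1.580   0.120  1.00 21.50           O
ATOM     10  N   SER A   3       6.180   3.830   0.120  1.00 30.00           N
ATOM     11  CA ASER A   3       7.630   3.850   0.170  0.60 32.00           C
ATOM     12  CA BSER A   3       7.700   3.950   0.270  0.40 33.00           C
ATOM     13  C   SER A   3       8.210   5.250   0.200  1.00 31.00           C
ATOM     14  O   SER A   3       7.500   6.260   0.190  1.00 31.50           O
ATOM     15  OG  SER A   3       8.120   3.100  -0.940  1.00 34.00           O
END
"""


@pytest.fixture()
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture()
def three_residue_model(three_residue_pdb):
    return read_structure(three_residue_pdb, chain="A")


@pytest.fixture(scope="session")
def toy_pair():
    """Default 80-residue fold-switch pair (region 25-60, H vs E)."""
    return make_toy_pair(ToyPairSpec(seed=0))


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_backbone("H" * 20, seed=3, model_id="helix20")


def grid_search_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Independent superposition oracle: exhaustive Euler-angle rotation
    grid (10 deg sweep refined locally at 1 deg), optimal translation by
    centroid matching.  Used only to validate the Kabsch implementation.
    """
    from scipy.spatial.transform import Rotation

    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def best_over(angles_list):
        rots = Rotation.from_euler("zyz", angles_list, degrees=True).as_matrix()
        # residuals for all rotations at once: (K, n, 3)
        diff = Pc[None, :, :] - np.einsum("kij,nj->kni", rots, Qc)
        rmsds = np.sqrt((diff**2).sum(axis=(1, 2)) / len(P))
        k = int(np.argmin(rmsds))
        return rmsds[k], angles_list[k]

    coarse = [
        (a, b, c)
        for a in range(0, 360, 10)
        for b in range(0, 181, 10)
        for c in range(0, 360, 10)
    ]
    _, (a0, b0, c0) = best_over(coarse)
    fine = [
        (a0 + da, b0 + db, c0 + dc)
        for da in range(-10, 11)
        for db in range(-10, 11)
        for dc in range(-10, 11)
    ]
    best, _ = best_over(fine)
    return float(best)


def random_rigid_transform(seed: int = 0):
    """A random proper rotation + translation for invariance tests."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def apply_rigid(model, R, t):
    """Return a copy of a StructureModel with all atoms rigidly moved."""
    from foldswitch.structure_io import AtomRecord, Residue, StructureModel

    res_out = []
    for res in model.residues:
        atoms = {
            name: AtomRecord(name, a.element, R @ a.xyz + t, a.bfactor, a.occupancy)
            for name, a in res.atoms.items()
        }
        res_out.append(Residue(res.author_number, res.insertion_code,
                               res.index, res.name, atoms))
    return StructureModel(id=model.id + "|moved", chain_id=model.chain_id,
                          residues=res_out)
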