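"""Deterministic toy structures in PDB format.

Every generator is a pure function of its arguments: the same spec and seed
produce byte-identical PDB text, so tests and examples run without downloading
real structures.  Geometry is schematic (spacings chosen so default-scheme
networks are connected), not stereochemically valid -- the network model
depends only on node positions and identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, Structure, parse_pdb, write_pdb

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_ca_chain",
    "make_helix",
    "make_random_cloud",
    "make_mixed_complex",
    "perturb_rigid",
    "random_rotation",
    "rigid_transform",
]

#: the 24 proper rotations of the cube, as signed permutations; they map the
#: 1e-3 coordinate grid of the PDB format onto itself, so a perturbed file
#: round-trips losslessly through the fixed-precision text format
_CUBE_ROTATIONS = [
    m for m in (
        np.array([[sx if p[0] == 0 else 0, sx if p[0] == 1 else 0, sx if p[0] == 2 else 0],
                  [sy if p[1] == 0 else 0, sy if p[1] == 1 else 0, sy if p[1] == 2 else 0],
                  [sz if p[2] == 0 else 0, sz if p[2] == 1 else 0, sz if p[2] == 2 else 0]],
                 float)
        for p in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
        for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)
    )
    if np.isclose(np.linalg.det(m), 1.0)
]
assert len(_CUBE_ROTATIONS) == 24


@dataclass
class FixtureSpec:
    kind: str = "ca_chain"  # ca_chain | helix | mixed_complex | random_cloud
    n_residues: int = 10
    n_nucleotides: int = 0
    n_ligand_atoms: int = 0
    spacing: float = 3.8
    seed: int = 0


def make_fixture(spec: FixtureSpec) -> str:
    if spec.kind == "ca_chain":
        return make_ca_chain(spec.n_residues, spacing=spec.spacing, seed=spec.seed)
    if spec.kind == "helix":
        return make_helix(spec.n_residues, seed=spec.seed)
    if spec.kind == "random_cloud":
        return make_random_cloud(spec.n_residues, seed=spec.seed)
    if spec.kind == "mixed_complex":
        return make_mixed_complex(spec.n_residues, spec.n_nucleotides,
                                  spec.n_ligand_atoms, seed=spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def _ca_atom(i: int, pos, b: float, chain: str = "A", resname: str = "ALA") -> Atom:
    return Atom(serial=i + 1, name="CA", element="C", residue_name=resname,
                chain_id=chain, residue_number=i + 1, insertion_code="",
                alt_loc="", position=np.round(np.asarray(pos, float), 3),
                occupancy=1.0, b_factor=b, record_kind="ATOM")


def _smooth_b(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.round(15.0 + 10.0 * np.sin(2.0 * np.pi * i / max(n, 2)), 2)


def _compact_walk(n: int, spacing: float, rng) -> np.ndarray:
    """Self-avoiding-ish random walk confined to a ball of radius ~3.5 n^(1/3).

    Keeps the chain globular, so even long chains are stiff against bending:
    an extended, nearly collinear chain would have soft modes approaching the
    rigid-body tolerance.  Steps keep exactly ``spacing`` length; candidates
    closer than 2 A to any previous residue or outside the ball are rejected.
    """
    radius = max(2.0 * spacing, 3.5 * n ** (1.0 / 3.0))
    pos = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(500):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = pos[i - 1] + spacing * u
            if np.linalg.norm(cand) <= radius and \
                    np.min(np.linalg.norm(pos[:i] - cand, axis=1)) >= 2.0:
                pos[i] = cand
                break
        else:  # pathological corner: step straight out and enlarge the ball
            pos[i] = pos[i - 1] + spacing * np.array([1.0, 0.0, 0.0])
            radius += spacing
    return pos


def make_ca_chain(n: int, spacing: float = 3.8, jitter: float = 0.5,
                  seed: int = 0) -> str:
    """PDB text for an n-residue poly-ALA Calpha chain.

    Residues follow a seeded compact 3-D random walk with consecutive spacing
    ``spacing``, randomized in all three axes, so chains of three or more
    residues are non-collinear and the default-scheme network is connected.
    With ``jitter=0`` the chain is a straight line along x; ``jitter=0, n=2``
    is the analytic two-node system.
    """
    if n < 2:
        raise ValueError(f"need at least 2 residues, got {n}")
    rng = np.random.RandomState(seed)
    if jitter == 0.0:
        pos = np.zeros((n, 3))
        pos[:, 0] = spacing * np.arange(n)
    else:
        pos = _compact_walk(n, spacing, rng)
    b = _smooth_b(n)
    atoms = [_ca_atom(i, pos[i], b[i]) for i in range(n)]
    return write_pdb(Structure(atoms=atoms, source_label=f"ca_chain(n={n},seed={seed})"))


def make_helix(n: int, rise: float = 1.5, radius: float = 2.3,
               turn_deg: float = 100.0, seed: int = 0) -> str:
    """PDB text for an idealized alpha-helical Calpha trace."""
    if n < 2:
        raise ValueError(f"need at least 2 residues, got {n}")
    i = np.arange(n)
    theta = np.deg2rad(turn_deg) * i
    pos = np.stack([radius * np.cos(theta), radius * np.sin(theta), rise * i], axis=1)
    b = _smooth_b(n)
    atoms = [_ca_atom(k, pos[k], b[k]) for k in range(n)]
    return write_pdb(Structure(atoms=atoms, source_label=f"helix(n={n})"))


def make_random_cloud(n: int, box: float = None, seed: int = 0) -> str:
    """PDB text for n Calpha pseudo-residues scattered in a cube.

    The box edge scales with n^(1/3) to hold the density roughly constant, so
    default-scheme networks on these clouds are connected with high
    probability at any n.
    """
    if n < 2:
        raise ValueError(f"need at least 2 residues, got {n}")
    rng = np.random.RandomState(seed)
    if box is None:
        box = 5.5 * n ** (1.0 / 3.0)
    pos = rng.uniform(0.0, box, size=(n, 3))
    b = _smooth_b(n)
    atoms = [_ca_atom(i, pos[i], b[i]) for i in range(n)]
    return write_pdb(Structure(atoms=atoms, source_label=f"random_cloud(n={n},seed={seed})"))


def make_mixed_complex(n_res: int, n_nt: int, n_lig: int, seed: int = 0) -> str:
    """PDB text for a schematic protein / nucleic-acid / ligand complex.

    A Calpha protein chain (chain A), a mock nucleotide chain (chain B,
    alternating DA/DT) in which each residue carries atoms named P, C4' and C2
    except the 5'-terminal one which lacks P, one multi-atom HETATM ligand
    (LIG, chain C) and one water (HOH).  Components are placed within the
    default 15 A contact range of each other so the network is connected.
    """
    if n_res + n_nt + n_lig < 2:
        raise ValueError("need at least 2 potential nodes in total")
    rng = np.random.RandomState(seed)
    atoms: list[Atom] = []
    serial = 1

    def add(name, element, resname, chain, resnum, pos, b=20.0, kind="ATOM"):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=element,
                          residue_name=resname, chain_id=chain,
                          residue_number=resnum, insertion_code="", alt_loc="",
                          position=np.round(np.asarray(pos, float), 3),
                          occupancy=1.0, b_factor=b, record_kind=kind))
        serial += 1

    b_prot = _smooth_b(max(n_res, 1))
    for i in range(n_res):
        pos = np.array([3.8 * i, 0.0, 0.0]) + rng.uniform(-0.4, 0.4, 3)
        add("CA", "C", "ALA", "A", i + 1, pos, b=b_prot[i])

    for j in range(n_nt):
        resname = "DA" if j % 2 == 0 else "DT"
        origin = np.array([5.0 * j, 7.0, 0.0])
        if j > 0:  # 5'-terminal nucleotide has no phosphate
            add("P", "P", resname, "B", j + 1,
                origin + np.array([-1.0, 0.5, 0.8]) + rng.uniform(-0.2, 0.2, 3), b=25.0)
        add("C4'", "C", resname, "B", j + 1,
            origin + rng.uniform(-0.2, 0.2, 3), b=22.0)
        add("C2", "C", resname, "B", j + 1,
            origin + np.array([1.6, 1.2, -0.7]) + rng.uniform(-0.2, 0.2, 3), b=21.0)

    lig_center = np.array([1.9 * max(n_res - 1, 1), -6.0, 1.0])
    for k in range(n_lig):
        pos = lig_center + np.array([1.6 * (k % 3), 1.6 * (k // 3), 0.9 * (k % 2)])
        pos = pos + rng.uniform(-0.15, 0.15, 3)
        add(f"C{k + 1}", "C", "LIG", "C", 1, pos, b=30.0, kind="HETATM")

    add("O", "O", "HOH", "W", 1, np.array([0.0, -3.5, 4.0]), b=40.0, kind="HETATM")
    return write_pdb(Structure(
        atoms=atoms,
        source_label=f"mixed_complex({n_res},{n_nt},{n_lig},seed={seed})"))


def random_rotation(seed: int = 0) -> np.ndarray:
    """A uniformly random proper rotation matrix (for in-memory transforms)."""
    rng = np.random.RandomState(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform(positions: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Apply R x + t to every row of an (N, 3) coordinate array."""
    return np.asarray(positions, float) @ np.asarray(rotation, float).T \
        + np.asarray(translation, float)


def perturb_rigid(pdb_text: str, seed: int = 0) -> str:
    """Apply a seeded random rigid motion to all coordinates of a PDB file.

    The rotation is drawn from the 24 proper lattice rotations and the
    translation snapped to the 1e-3 A grid, so the motion commutes exactly
    with the PDB format's three-decimal coordinate columns: pairwise distances
    and the ANM spectrum of the perturbed file match the original exactly.
    Atom identities are untouched.
    """
    rng = np.random.RandomState(seed)
    rot = _CUBE_ROTATIONS[rng.randint(len(_CUBE_ROTATIONS))]
    trans = np.round(rng.uniform(-20.0, 20.0, size=3), 3)
    st = parse_pdb(pdb_text)
    for atom in st.atoms:
        atom.position = rigid_transform(atom.position[None, :], rot, trans)[0]
        if atom.adp is not None:
            atom.adp = rot @ atom.adp @ rot.T
    return write_pdb(st)
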