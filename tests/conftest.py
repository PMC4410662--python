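"""Shared helpers: tiny independent readers/oracles used only by tests."""

import numpy as np
import pytest

from anmkit import Atom, Structure, parse_pdb, write_pdb


def simple_xyz_reader(text):
    """Minimal multi-frame .xyz reader (independent of the package writer)."""
    lines = text.splitlines()
    frames, labels = [], None
    i = 0
    while i < len(lines):
        n = int(lines[i])
        block = lines[i + 2: i + 2 + n]
        labels = [ln.split()[0] for ln in block]
        frames.append(np.array([[float(v) for v in ln.split()[1:4]] for ln in block]))
        i += 2 + n
    return labels, frames


def make_atom(serial, name, resname, chain, resnum, pos, element="C",
              kind="ATOM", b=10.0, occ=1.0, altloc="", icode=""):
    return Atom(serial=serial, name=name, element=element, residue_name=resname,
                chain_id=chain, residue_number=resnum, insertion_code=icode,
                alt_loc=altloc, position=np.asarray(pos, float), occupancy=occ,
                b_factor=b, record_kind=kind)


def pdb_from_atoms(atoms):
    return write_pdb(Structure(atoms=list(atoms)))


def protein_nucleotide_pdb(n_res=3, n_nt=2, complete=True, with_water=False):
    """A hand-laid-out PDB: n_res ALA CA + n_nt complete nucleotides (P, C4',
    C2 each) kept within contact range; optional water."""
    atoms = []
    s = 1
    for i in range(n_res):
        atoms.append(make_atom(s, "CA", "ALA", "A", i + 1, (3.8 * i, 0, 0.3 * i)))
        s += 1
    for j in range(n_nt):
        base = np.array([4.0 * j, 6.0, 0.0])
        names = ["P", "C4'", "C2"] if complete else ["C4'", "C2"]
        offs = {"P": (0, 0, 0), "C4'": (1.4, 0.8, 0.5), "C2": (2.5, 1.6, -0.4)}
        for name in names:
            el = "P" if name == "P" else "C"
            atoms.append(make_atom(s, name, "DA" if j % 2 == 0 else "DT", "B",
                                   j + 1, base + np.array(offs[name]), element=el))
            s += 1
    if with_water:
        atoms.append(make_atom(s, "O", "HOH", "W", 1, (0.0, 3.0, 2.0),
                               element="O", kind="HETATM"))
    return pdb_from_atoms(atoms)


def brute_force_contacts(positions, ranges):
    """All-pairs contact enumeration oracle."""
    out = []
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(positions[j] - positions[i]))
            if d <= ranges[i] + ranges[j]:
                out.append((i, j))
    return out


def harmonic_energy(flat_coords, contacts, d0s):
    """ANM potential E = sum (gamma/2)(|R_i - R_j| - d0)^2 (test oracle)."""
    pos = flat_coords.reshape(-1, 3)
    e = 0.0
    for (i, j, _, gamma), d0 in zip(contacts, d0s):
        e += 0.5 * gamma * (np.linalg.norm(pos[j] - pos[i]) - d0) ** 2
    return e


def finite_difference_hessian(positions, contacts, h=1e-4):
    """Central-difference Hessian of the harmonic network energy."""
    x0 = np.asarray(positions, float).ravel()
    d0s = [c[2] for c in contacts]
    dim = x0.size

    def e(x):
        return harmonic_energy(x, contacts, d0s)

    out = np.zeros((dim, dim))
    for a in range(dim):
        for b in range(a, dim):
            xa = np.zeros(dim); xa[a] = h
            xb = np.zeros(dim); xb[b] = h
            val = (e(x0 + xa + xb) - e(x0 + xa - xb)
                   - e(x0 - xa + xb) + e(x0 - xa - xb)) / (4 * h * h)
            out[a, b] = out[b, a] = val
    return out


@pytest.fixture
def two_node_pdb():
    from anmkit import fixtures
    return fixtures.make_ca_chain(2, spacing=3.8, jitter=0.0, seed=0)


@pytest.fixture
def two_node_modes(two_node_pdb):
    from anmkit import build_contacts, build_hessian, compute_modes, select_nodes
    nodes = select_nodes(parse_pdb(two_node_pdb))
    h = build_hessian(nodes, build_contacts(nodes))
    return nodes, compute_modes(h, n_modes=1, allow_disconnected=True)
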