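"""From structure to elastic network: node selection, per-type interaction
ranges, contact enumeration under the pairwise cutoff t_i + t_j, and the
anisotropic network model (ANM) Hessian.

The coarse-graining follows the three-nodes-per-nucleotide convention (P, C4',
C2), one Calpha node per amino acid, and one node per ligand heavy atom.  The
pair cutoff is the sum of per-atom-type interaction ranges t_i; with an empty
range table every t_i = r_c/2, which reduces exactly to the classical single
cutoff r_c (default 15 A).

The harmonic network potential is E = sum_contacts (gamma/2) (|R_i - R_j| -
d0_ij)^2.  Its Hessian at the equilibrium structure has 3x3 super-elements
H[i,j] = -(gamma/d0^2) r_ij r_ij^T for contacts (r_ij the equilibrium
separation vector), with diagonal blocks closing each super-row to zero --
translation invariance by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .errors import ConfigError, DegenerateNetworkError
from .structure_io import Atom, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "NodeScheme",
    "Node",
    "NodeSet",
    "ContactList",
    "select_nodes",
    "assign_ranges",
    "build_contacts",
    "build_hessian",
    "read_range_table",
    "connected_components",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split()
)
STANDARD_NUCLEOTIDES = frozenset(
    ["A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"]
)
DEFAULT_WATER_RESIDUES = frozenset(["HOH", "WAT", "DOD"])


@dataclass
class NodeScheme:
    """Rules mapping atoms to network nodes and nodes to interaction ranges.

    ``range_table`` maps a type key ("PRO:CA", "NUC:P", "LIG:C1") or a bare
    atom name ("CA", fallback across classes) to an interaction range t in
    Angstrom.  Nodes whose type is absent from the table get t = cutoff/2, so
    an empty table reproduces the uniform-cutoff ANM.
    """

    protein_atoms: tuple = ("CA",)
    nucleotide_atoms: tuple = ("P", "C4'", "C2")
    include_ligands: bool = True
    ligand_exclude_residues: frozenset = DEFAULT_WATER_RESIDUES
    range_table: dict = field(default_factory=dict)
    cutoff: float = 15.0

    def __post_init__(self):
        self.protein_atoms = tuple(self.protein_atoms)
        self.nucleotide_atoms = tuple(self.nucleotide_atoms)
        self.ligand_exclude_residues = frozenset(
            r.upper() for r in self.ligand_exclude_residues)
        if self.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff}")
        for key, t in self.range_table.items():
            if t <= 0:
                raise ConfigError(f"interaction range for {key!r} must be positive, got {t}")


@dataclass
class Node:
    index: int
    atom_ref: Atom
    position: np.ndarray
    type_key: str
    t: float = 0.0
    b_factor_exp: float = 0.0


@dataclass
class NodeSet:
    nodes: list

    @property
    def N(self) -> int:
        return len(self.nodes)

    def __len__(self):
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __getitem__(self, i):
        return self.nodes[i]

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], float)

    def ranges(self) -> np.ndarray:
        return np.array([n.t for n in self.nodes], float)

    def b_factors(self) -> np.ndarray:
        return np.array([n.b_factor_exp for n in self.nodes], float)


@dataclass
class ContactList:
    """Springs of the network: (i, j, equilibrium distance, spring constant)."""

    pairs: list  # of (i, j, d0, gamma) with i < j
    gamma_default: float = 1.0

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _type_key(atom: Atom) -> str:
    if atom.record_kind == "HETATM":
        cls = "LIG"
    elif atom.residue_name in STANDARD_NUCLEOTIDES:
        cls = "NUC"
    else:
        cls = "PRO"
    return f"{cls}:{atom.name}"


def select_nodes(structure: Structure, scheme: Optional[NodeScheme] = None) -> NodeSet:
    """Map atoms to network nodes under the scheme, in file order.

    Amino-acid residues contribute one node per scheme protein atom present
    (default Calpha); standard nucleotides one node per scheme nucleotide atom
    present (default P, C4', C2; a 5'-terminal nucleotide missing P simply
    contributes fewer nodes, with a logged warning); non-hydrogen HETATM atoms
    outside the excluded residues (waters by default) become ligand nodes.
    Hydrogens never become nodes.
    """
    scheme = scheme or NodeScheme()
    if not structure.atoms:
        raise DegenerateNetworkError("degenerate network: structure has no atoms")

    nodes: list[Node] = []
    seen_residues: dict = {}
    for atom in structure.atoms:
        if atom.is_hydrogen:
            continue
        res_key = (atom.chain_id, atom.residue_number, atom.insertion_code,
                   atom.residue_name)
        take = False
        if atom.record_kind == "HETATM":
            take = (scheme.include_ligands
                    and atom.residue_name.upper() not in scheme.ligand_exclude_residues)
        elif atom.residue_name in STANDARD_AMINO_ACIDS:
            take = atom.name in scheme.protein_atoms
        elif atom.residue_name in STANDARD_NUCLEOTIDES:
            take = atom.name in scheme.nucleotide_atoms
        if take:
            nodes.append(Node(
                index=len(nodes),
                atom_ref=atom,
                position=np.asarray(atom.position, float),
                type_key=_type_key(atom),
                b_factor_exp=atom.b_factor,
            ))
        seen_residues.setdefault(res_key, set()).add(atom.name)

    # warn about nucleotides missing scheme atoms (typically the 5' P)
    for (chain, num, icode, resname), names in seen_residues.items():
        if resname in STANDARD_NUCLEOTIDES:
            missing = set(scheme.nucleotide_atoms) - names
            if missing:
                logger.warning(
                    "nucleotide %s %s%s%s lacks scheme atoms %s; contributing fewer nodes",
                    resname, chain, num, icode, sorted(missing))

    if len(nodes) < 2:
        raise DegenerateNetworkError(
            f"degenerate network: only {len(nodes)} node(s) selected")
    return assign_ranges(NodeSet(nodes), scheme)


def assign_ranges(nodes: NodeSet, scheme: Optional[NodeScheme] = None) -> NodeSet:
    """Assign per-node interaction ranges t_i from the scheme's range table.

    Lookup order: exact type key ("NUC:P"), bare atom name ("P"), else the
    uniform fallback cutoff/2.
    """
    scheme = scheme or NodeScheme()
    table = scheme.range_table
    for node in nodes:
        atom_name = node.type_key.split(":", 1)[1]
        t = table.get(node.type_key, table.get(atom_name, scheme.cutoff / 2.0))
        if t <= 0:
            raise ConfigError(
                f"interaction range for {node.type_key!r} must be positive, got {t}")
        node.t = float(t)
    return nodes


def build_contacts(nodes: NodeSet, gamma: float = 1.0) -> ContactList:
    """Enumerate spring contacts: pair (i,j) iff |R_i - R_j| <= t_i + t_j.

    A KD-tree prunes the candidate pairs at the largest possible cutoff
    2*max(t); the pair-dependent test applied afterwards makes the result
    identical to exhaustive all-pairs enumeration.
    """
    pos = nodes.positions()
    t = nodes.ranges()
    if np.any(t <= 0):
        raise ConfigError("all nodes must carry a positive interaction range")
    tree = cKDTree(pos)
    candidates = tree.query_pairs(2.0 * float(t.max()), output_type="ndarray")
    pairs = []
    for i, j in sorted(map(tuple, candidates)):
        d0 = float(np.linalg.norm(pos[j] - pos[i]))
        if d0 <= 1e-6:
            a, b = nodes[i].atom_ref, nodes[j].atom_ref
            raise DegenerateNetworkError(
                "coincident nodes: "
                f"{a.residue_name} {a.chain_id}{a.residue_number} {a.name} and "
                f"{b.residue_name} {b.chain_id}{b.residue_number} {b.name} "
                f"are {d0:.2e} A apart")
        if d0 <= t[i] + t[j]:
            pairs.append((int(i), int(j), d0, float(gamma)))
    return ContactList(pairs=pairs, gamma_default=float(gamma))


def build_hessian(nodes: NodeSet, contacts: ContactList) -> sp.csr_matrix:
    """Assemble the 3N x 3N ANM Hessian (sparse CSR, symmetric PSD).

    Off-diagonal super-element for a contact: H[i,j] = -(gamma/d0^2) r r^T
    with r = R_j - R_i; diagonal super-elements close each super-row to zero.
    """
    if len(contacts) == 0:
        raise DegenerateNetworkError("fully disconnected network: no contacts")
    pos = nodes.positions()
    n = nodes.N
    rows, cols, vals = [], [], []
    diag = np.zeros((n, 3, 3))
    for i, j, d0, gamma in contacts:
        r = pos[j] - pos[i]
        block = -(gamma / d0 ** 2) * np.outer(r, r)
        diag[i] -= block
        diag[j] -= block
        for a in range(3):
            for b in range(3):
                rows.append(3 * i + a); cols.append(3 * j + b); vals.append(block[a, b])
                rows.append(3 * j + a); cols.append(3 * i + b); vals.append(block[a, b])
    for i in range(n):
        for a in range(3):
            for b in range(3):
                if diag[i, a, b] != 0.0:
                    rows.append(3 * i + a); cols.append(3 * i + b)
                    vals.append(diag[i, a, b])
    h = sp.csr_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n))
    return h


def connected_components(n_nodes: int, contacts: ContactList) -> int:
    """Number of connected components of the contact graph."""
    rows = [p[0] for p in contacts]
    cols = [p[1] for p in contacts]
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                        shape=(n_nodes, n_nodes))
    ncomp, _ = sp.csgraph.connected_components(adj, directed=False)
    return int(ncomp)


def read_range_table(text: str) -> dict:
    """Parse a plain-text range table: one 'TYPEKEY value_A' per line, with
    '#' comments."""
    table = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ConfigError(f"range table line {lineno}: expected 'KEY value', got {line!r}")
        try:
            value = float(parts[1])
        except ValueError:
            raise ConfigError(
                f"range table line {lineno}: non-numeric range {parts[1]!r}") from None
        if value <= 0:
            raise ConfigError(f"range table line {lineno}: range must be positive")
        table[parts[0]] = value
    return table
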