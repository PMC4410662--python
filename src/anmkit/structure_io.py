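"""Reading and writing the structural file formats the toolkit touches.

PDB ATOM/HETATM/ANISOU records are parsed with :mod:`gemmi`; on top of that
this module applies the policies a single-conformation network model needs
(first model only, one alternate-location conformer per atom, hydrogens kept
for later filtering) and exposes plain dataclasses so the rest of the package
never depends on gemmi objects.

Writers are direct fixed-column formatters (wwPDB v3.3 columns) because the
toolkit fixes its own numeric conventions: the isotropic B column of an ADP
record is (8*pi^2/3)*trace(U) and ANISOU stores round(U_ij * 1e4).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .errors import DimensionError, EmptyStructureError, PDBParseError

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "parse_pdb",
    "read_pdb",
    "write_pdb",
    "write_pdb_with_anisou",
    "write_xyz_trajectory",
    "read_matrix",
    "write_matrix",
]

# (start, end, kind, what) for the fixed-width numeric fields gemmi will not
# complain about on its own. 0-based half-open column ranges.
_ATOM_NUMERIC_FIELDS = [
    (22, 26, int, "residue number"),
    (30, 38, float, "x coordinate"),
    (38, 46, float, "y coordinate"),
    (46, 54, float, "z coordinate"),
    (54, 60, float, "occupancy"),
    (60, 66, float, "B-factor"),
]
_ANISOU_NUMERIC_FIELDS = [(28 + 7 * k, 35 + 7 * k, int, f"U({k})") for k in range(6)]


@dataclass
class Atom:
    """One ATOM/HETATM record (plus any attached ANISOU tensor)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    alt_loc: str
    position: np.ndarray  # (3,) Angstrom
    occupancy: float
    b_factor: float  # Angstrom^2
    adp: Optional[np.ndarray] = None  # symmetric (3,3), Angstrom^2
    record_kind: str = "ATOM"  # ATOM | HETATM

    @property
    def identity_key(self):
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.name, self.alt_loc)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def label(self) -> str:
        """Display label: element symbol when known, else first name char."""
        if self.element and self.element not in ("X", ""):
            return self.element
        return self.name[:1]


@dataclass
class Structure:
    atoms: list
    model_id: int = 1
    source_label: str = ""

    def __len__(self):
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], float)


@dataclass
class Trajectory:
    """Multi-frame coordinate set for one animated normal mode."""

    labels: Sequence[str]
    frames: list  # list of (N,3) arrays, Angstrom
    mode_index: int = 0
    amplitude: float = 0.0

    def __post_init__(self):
        n = len(self.labels)
        for f in self.frames:
            if np.asarray(f).shape != (n, 3):
                raise DimensionError(
                    f"every trajectory frame must be {n}x3, got {np.asarray(f).shape}"
                )


def _normalize_atom_name(name: str) -> str:
    # old PDB dialect writes primes as '*' (C4* for C4')
    return name.strip().replace("*", "'")


def _validate_fixed_columns(text: str) -> None:
    """Raise a line-numbered parse error for malformed numeric fields.

    gemmi parses leniently (a garbled coordinate silently becomes 0.0), so the
    numeric columns are checked up front.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            fields = _ATOM_NUMERIC_FIELDS
        elif rec == "ANISOU":
            fields = _ANISOU_NUMERIC_FIELDS
        else:
            continue
        for start, end, kind, what in fields:
            raw = line[start:end].strip()
            if raw == "" and kind is float and start >= 54:
                continue  # occupancy/B occasionally absent in minimal files
            try:
                kind(raw)
            except (TypeError, ValueError):
                raise PDBParseError(
                    f"line {lineno}: malformed {what} field {raw!r} in {rec} record"
                ) from None


def parse_pdb(text: str, source_label: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Only the first model is retained (a notice is logged for multi-model
    files).  For alternate locations the highest-occupancy conformer wins,
    ties going to the first conformer in the file.  ANISOU tensors are
    attached as symmetric 3x3 arrays in Angstrom^2 (stored integer * 1e-4).
    Hydrogens are retained; node selection filters them later.
    """
    _validate_fixed_columns(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(e)) from e

    if len(st) == 0:
        raise EmptyStructureError("empty structure: no ATOM/HETATM record found")
    if len(st) > 1:
        logger.info("multi-model file: keeping model 1 of %d", len(st))

    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for a in res:
                aniso = None
                if a.aniso.nonzero():
                    u = a.aniso
                    aniso = np.array(
                        [[u.u11, u.u12, u.u13],
                         [u.u12, u.u22, u.u23],
                         [u.u13, u.u23, u.u33]], float)
                altloc = a.altloc if a.altloc != "\x00" else ""
                atoms.append(Atom(
                    serial=a.serial,
                    name=_normalize_atom_name(a.name),
                    element=a.element.name if a.element.name != "X" else "",
                    residue_name=res.name.strip(),
                    chain_id=chain.name.strip(),
                    residue_number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    alt_loc=altloc,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z], float),
                    occupancy=float(a.occ),
                    b_factor=float(a.b_iso),
                    adp=aniso,
                    record_kind="HETATM" if res.het_flag == "H" else "ATOM",
                ))

    if not atoms:
        raise EmptyStructureError("empty structure: no ATOM/HETATM record found")

    # altloc resolution: best occupancy per (chain, resnum, icode, name)
    best: dict = {}
    order: list = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occupancy > best[key].occupancy:
            best[key] = atom
    kept = [best[k] for k in order]
    if len(kept) < len(atoms):
        logger.info("altloc filtering kept %d of %d atoms", len(kept), len(atoms))

    model_id = int(getattr(model, "num", getattr(model, "name", 1)) or 1)
    return Structure(atoms=kept, model_id=model_id, source_label=source_label)


def read_pdb(path) -> Structure:
    with open(path) as fh:
        return parse_pdb(fh.read(), source_label=str(path))


def _format_atom_name(name: str) -> str:
    # short names start in column 14 unless they begin with a digit
    if len(name) >= 4 or name[:1].isdigit():
        return name.ljust(4)[:4]
    return (" " + name).ljust(4)


def _atom_record(atom: Atom, serial: int, position, b_factor: float,
                 kind: str | None = None) -> str:
    x, y, z = position
    return (
        f"{(kind or atom.record_kind):<6}{serial:>5} {_format_atom_name(atom.name)}"
        f"{atom.alt_loc or ' ':1}{atom.residue_name:>3} {atom.chain_id or 'A':1}"
        f"{atom.residue_number:>4}{atom.insertion_code or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{b_factor:6.2f}"
        f"          {atom.element:>2}"
    )


def _anisou_record(atom: Atom, serial: int, u: np.ndarray) -> str:
    ints = [int(round(v * 1e4)) for v in
            (u[0, 0], u[1, 1], u[2, 2], u[0, 1], u[0, 2], u[1, 2])]
    body = "".join(f"{v:>7}" for v in ints)
    return (
        f"ANISOU{serial:>5} {_format_atom_name(atom.name)}"
        f"{atom.alt_loc or ' ':1}{atom.residue_name:>3} {atom.chain_id or 'A':1}"
        f"{atom.residue_number:>4}{atom.insertion_code or ' ':1} "
        f"{body}      {atom.element:>2}"
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure back to PDB text (retained fields only)."""
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        lines.append(_atom_record(atom, i, atom.position, atom.b_factor))
        if atom.adp is not None:
            lines.append(_anisou_record(atom, i, atom.adp))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb_with_anisou(nodes, adps, scale: float = 1.0) -> str:
    """Write one ATOM + ANISOU pair per network node.

    The B column carries the isotropic equivalent (8*pi^2/3)*trace(U)*scale and
    the ANISOU integers are round(U_ij*scale*1e4); parsing the output back
    recovers the tensors to within the integer quantization (1e-4*scale).

    ``nodes`` is a NodeSet (or any iterable of objects with ``atom_ref``);
    ``adps`` an ADPSet or an (N,3,3) array.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    u_all = np.asarray(getattr(adps, "U", adps), float)
    node_list = list(getattr(nodes, "nodes", nodes))
    if u_all.shape != (len(node_list), 3, 3):
        raise DimensionError(
            f"expected {len(node_list)} ADP tensors, got array of shape {u_all.shape}"
        )
    lines = []
    for i, node in enumerate(node_list):
        atom = node.atom_ref
        u = u_all[i] * scale
        b = (8.0 * math.pi ** 2 / 3.0) * float(np.trace(u))
        lines.append(_atom_record(atom, i + 1, node.position, b))
        lines.append(_anisou_record(atom, i + 1, u))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_xyz_trajectory(traj: Trajectory) -> str:
    """Multi-frame .xyz text: per frame a count line, a comment line, and one
    "label x y z" line per node."""
    if not traj.frames:
        raise ValueError("empty trajectory")
    n = len(traj.labels)
    out = []
    for f, frame in enumerate(traj.frames):
        out.append(str(n))
        out.append(f"frame {f} mode {traj.mode_index} amplitude {traj.amplitude:.4f}")
        for label, (x, y, z) in zip(traj.labels, np.asarray(frame, float)):
            out.append(f"{label:<2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    return "\n".join(out) + "\n"


def write_matrix(m: np.ndarray) -> str:
    """Whitespace-delimited numeric matrix with a '# rows cols' header."""
    m = np.atleast_2d(np.asarray(m, float))
    rows = [f"# {m.shape[0]} {m.shape[1]}"]
    for row in m:
        rows.append(" ".join(f"{v:.6e}" for v in row))
    return "\n".join(rows) + "\n"


def read_matrix(text: str) -> np.ndarray:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty matrix file")
    header = re.match(r"#\s*(\d+)\s+(\d+)", lines[0])
    data_lines = lines[1:] if header else lines
    try:
        m = np.array([[float(v) for v in ln.split()] for ln in data_lines])
    except ValueError as e:
        raise ValueError(f"non-numeric matrix entry: {e}") from None
    if header:
        want = (int(header.group(1)), int(header.group(2)))
        if m.shape != want:
            raise DimensionError(f"matrix header says {want}, data is {m.shape}")
    return m
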