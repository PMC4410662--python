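"""The :class:`ANM` estimator: one object from structure to observables.

The estimator is decomposition-shaped in the scikit-learn sense: ``fit`` takes
a structure (a parsed :class:`~anmkit.structure_io.Structure`, PDB text, or a
path), builds the elastic network, and eigendecomposes its Hessian; the
low-frequency eigenpairs are the fitted components.  Observable methods derive
B-factors, ADP tensors, correlation and distance-fluctuation maps, and mode
animations from the fitted modes.

Example
-------
>>> from anmkit import ANM, fixtures
>>> est = ANM(n_modes=10).fit(fixtures.make_ca_chain(40, seed=1))
>>> est.eigenvalues_.shape
(10,)
>>> profile = est.square_fluctuations()
"""

from __future__ import annotations

import os

import numpy as np
from sklearn.base import BaseEstimator

from . import network, modes, observables
from .structure_io import Structure, parse_pdb, read_pdb

__all__ = ["ANM"]


class ANM(BaseEstimator):
    """Anisotropic network model with atom-type-specific interaction ranges.

    Parameters
    ----------
    cutoff : float, default 15.0
        Uniform cutoff distance r_c in Angstrom; a node without an entry in
        ``range_table`` gets interaction range t = cutoff/2, so the pair
        cutoff t_i + t_j reduces to r_c between two such nodes.
    protein_atoms, nucleotide_atoms : sequences of atom names defining the
        coarse-graining (defaults: CA; P, C4', C2).
    include_ligands : bool
        Map non-hydrogen HETATM atoms (outside excluded residues) to nodes.
    ligand_exclude_residues : residue names never mapped to ligand nodes
        (waters by default).
    range_table : dict or None
        Per-type interaction ranges t_i in Angstrom, keyed by "CLASS:NAME"
        (e.g. "NUC:P") or bare atom name.
    gamma : float, default 1.0
        Uniform spring constant (arbitrary units; all fluctuation outputs are
        relative).
    n_modes : int, default 20
        Number of nonzero modes to compute.
    solver : {'auto', 'dense', 'subset'}
    allow_disconnected : bool
        Proceed with a warning when the network has other than six rigid-body
        modes.

    Attributes (after ``fit``)
    --------------------------
    nodes_ : NodeSet; contacts_ : ContactList; hessian_ : sparse 3N x 3N
    matrix; modes_ : ModeSet; eigenvalues_, eigenvectors_ : its arrays;
    n_zero_modes_ : rigid-body modes skipped.
    """

    def __init__(self, cutoff: float = 15.0, protein_atoms=("CA",),
                 nucleotide_atoms=("P", "C4'", "C2"), include_ligands: bool = True,
                 ligand_exclude_residues=("HOH", "WAT", "DOD"),
                 range_table=None, gamma: float = 1.0, n_modes: int = 20,
                 solver: str = "auto", allow_disconnected: bool = False):
        self.cutoff = cutoff
        self.protein_atoms = protein_atoms
        self.nucleotide_atoms = nucleotide_atoms
        self.include_ligands = include_ligands
        self.ligand_exclude_residues = ligand_exclude_residues
        self.range_table = range_table
        self.gamma = gamma
        self.n_modes = n_modes
        self.solver = solver
        self.allow_disconnected = allow_disconnected

    # -- fitting -----------------------------------------------------------

    def _scheme(self) -> network.NodeScheme:
        return network.NodeScheme(
            protein_atoms=tuple(self.protein_atoms),
            nucleotide_atoms=tuple(self.nucleotide_atoms),
            include_ligands=self.include_ligands,
            ligand_exclude_residues=frozenset(self.ligand_exclude_residues),
            range_table=dict(self.range_table or {}),
            cutoff=float(self.cutoff),
        )

    @staticmethod
    def _as_structure(X) -> Structure:
        if isinstance(X, Structure):
            return X
        if isinstance(X, (str, os.PathLike)):
            text = str(X)
            if "\n" not in text and os.path.isfile(text):
                return read_pdb(text)
            return parse_pdb(text)
        raise TypeError(f"cannot interpret {type(X).__name__} as a structure")

    def fit(self, X, y=None):
        """Build the network and compute normal modes for a structure.

        ``X`` may be a Structure, PDB text, or a path to a PDB file; ``y`` is
        ignored (scikit-learn API compatibility).
        """
        structure = self._as_structure(X)
        scheme = self._scheme()
        self.structure_ = structure
        self.nodes_ = network.select_nodes(structure, scheme)
        self.contacts_ = network.build_contacts(self.nodes_, gamma=self.gamma)
        self.hessian_ = network.build_hessian(self.nodes_, self.contacts_)
        self.modes_ = modes.compute_modes(
            self.hessian_, n_modes=self.n_modes, solver=self.solver,
            allow_disconnected=self.allow_disconnected)
        self.eigenvalues_ = self.modes_.eigenvalues
        self.eigenvectors_ = self.modes_.eigenvectors
        self.n_zero_modes_ = self.modes_.n_zero_skipped
        return self

    def _check_fitted(self):
        if not hasattr(self, "modes_"):
            raise AttributeError("this ANM instance is not fitted yet; call fit first")

    # -- observables -------------------------------------------------------

    def square_fluctuations(self) -> observables.FluctuationProfile:
        self._check_fitted()
        return observables.square_fluctuations(self.modes_)

    def fit_experimental_b(self, b_exp=None, with_offset: bool = False):
        """Scale theoretical B onto experimental B (defaults to the input
        structure's B-factor column); returns (scale, pearson_r)."""
        self._check_fitted()
        profile = self.square_fluctuations()
        if b_exp is None:
            b_exp = self.nodes_.b_factors()
        return observables.fit_experimental_b(profile, b_exp, with_offset=with_offset)

    def adp_tensors(self) -> observables.ADPSet:
        self._check_fitted()
        return observables.adp_tensors(self.modes_)

    def cross_correlation(self) -> np.ndarray:
        self._check_fitted()
        return observables.cross_correlation_map(self.modes_)

    def distance_fluctuations(self) -> np.ndarray:
        self._check_fitted()
        return observables.distance_fluctuation_map(self.modes_)

    def animate(self, mode_index: int, amplitude: float = 2.0, n_frames: int = 20):
        self._check_fitted()
        return observables.animate_mode(self.nodes_, self.modes_, mode_index,
                                        amplitude=amplitude, n_frames=n_frames)
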