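"""Normal modes of the network Hessian.

The Hessian of a connected, non-collinear 3-D network has exactly six zero
eigenvalues (rigid translations and rotations); the interesting dynamics live
in the smallest nonzero eigenpairs.  Two solvers are provided: a dense
eigendecomposition for small systems and a shift-invert sparse subset solver
(ARPACK via scipy) for large ones.  Both return the same eigenpairs; the
dense/subset threshold is a performance heuristic only.

Externally computed mode vectors (e.g. PCA of a trajectory) can be imported
as long as their dimension matches 3N for the current node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DimensionError, DisconnectedNetworkError
from .structure_io import read_matrix

logger = logging.getLogger(__name__)

__all__ = ["ModeSet", "compute_modes", "import_external_modes", "mode_overlap"]

#: modes with eigenvalue below max(REL_ZERO_TOL * lambda_max, ABS_ZERO_TOL)
#: are classified as rigid-body modes
REL_ZERO_TOL = 1e-8
ABS_ZERO_TOL = 1e-10
DENSE_SIZE_LIMIT = 1500  # 3N above which the subset solver is preferred


@dataclass
class ModeSet:
    """Eigenpairs of the ANM Hessian (or imported equivalents).

    eigenvalues are ascending and strictly above the zero-mode tolerance;
    eigenvectors are columns of a (3N, m) array, unit norm.
    """

    eigenvalues: np.ndarray  # (m,)
    eigenvectors: np.ndarray  # (3N, m), column k pairs with eigenvalues[k]
    n_zero_skipped: int = 0
    source: str = "computed"

    @property
    def N(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def __len__(self):
        return self.n_modes

    def node_vectors(self, k: int) -> np.ndarray:
        """Mode k (0-based) reshaped to per-node (N,3) displacement vectors."""
        return self.eigenvectors[:, k].reshape(self.N, 3)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Reproducible sign convention: largest-|component| entry positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        idx = np.argmax(np.abs(out[:, k]))
        if out[idx, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _lambda_max(h) -> float:
    if sp.issparse(h):
        if h.shape[0] <= 6:
            return float(np.max(scipy.linalg.eigvalsh(h.toarray())))
        return float(spla.eigsh(h, k=1, which="LA",
                                return_eigenvectors=False)[0])
    return float(np.max(scipy.linalg.eigvalsh(np.asarray(h))))


def compute_modes(h, n_modes: int = 20, solver: str = "auto",
                  allow_disconnected: bool = False) -> ModeSet:
    """Smallest nonzero eigenpairs of the Hessian.

    Parameters
    ----------
    h : (3N, 3N) symmetric matrix, dense or sparse.
    n_modes : number of nonzero modes to return (default 20, the classical
        server default); capped by 3N - 6.
    solver : 'dense', 'subset', or 'auto' (dense for 3N <= 1500).
    allow_disconnected : if True, a network with other than six rigid-body
        modes only logs a warning instead of raising.
    """
    dim = h.shape[0]
    if dim % 3 != 0 or h.shape[0] != h.shape[1]:
        raise DimensionError(f"Hessian must be square 3Nx3N, got {h.shape}")
    n = dim // 3
    # a collinear two-node network has a single nonzero (stretching) mode
    # even though 3N - 6 = 0, so the cap never drops below one
    max_modes = max(3 * n - 6, 1)
    if n_modes < 1:
        raise ValueError(f"n_modes must be positive, got {n_modes}")
    if n_modes > max_modes:
        raise ValueError(
            f"n_modes={n_modes} exceeds 3N-6={3 * n - 6} for N={n} nodes")

    if solver == "auto":
        solver = "dense" if dim <= DENSE_SIZE_LIMIT else "subset"
    if solver not in ("dense", "subset"):
        raise ValueError(f"unknown solver {solver!r}")

    lam_max = _lambda_max(h)
    zero_tol = max(REL_ZERO_TOL * lam_max, ABS_ZERO_TOL)

    if solver == "dense":
        dense = h.toarray() if sp.issparse(h) else np.asarray(h, float)
        vals, vecs = scipy.linalg.eigh(dense)
    else:
        hs = h if sp.issparse(h) else sp.csr_matrix(np.asarray(h, float))
        # shift-invert about a point just below zero: H + |sigma| I is PD for
        # a PSD Hessian, so the factorization avoids the singular H itself.
        sigma = -max(1e-6 * lam_max, 1e-12)
        want = min(n_modes + 6 + 4, dim - 1)
        vals, vecs = spla.eigsh(hs.tocsc(), k=want, sigma=sigma, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    nonzero = vals > zero_tol
    n_zero = int(np.sum(~nonzero))

    if n_zero != 6:
        msg = (f"disconnected or degenerate network: found {n_zero} rigid-body "
               f"modes, expected 6")
        if allow_disconnected:
            logger.warning(msg)
        else:
            raise DisconnectedNetworkError(msg, n_components=max(n_zero // 6, 1))

    vals_nz = vals[nonzero]
    vecs_nz = vecs[:, nonzero]
    if vals_nz.size < n_modes:
        if solver == "subset":
            # rare: more rigid modes than anticipated; fall back to asking for more
            return compute_modes(h, n_modes=n_modes, solver="dense",
                                 allow_disconnected=allow_disconnected)
        raise ValueError(
            f"only {vals_nz.size} nonzero modes available, {n_modes} requested")
    vals_nz = vals_nz[:n_modes]
    vecs_nz = _fix_signs(vecs_nz[:, :n_modes])
    return ModeSet(eigenvalues=np.asarray(vals_nz, float),
                   eigenvectors=np.asarray(vecs_nz, float),
                   n_zero_skipped=n_zero, source="computed")


def import_external_modes(matrix, nodes) -> ModeSet:
    """Build a ModeSet from externally computed mode vectors.

    ``matrix`` is a (3N, m) array, a (3N+1, m) array whose first row holds
    eigenvalues, or text in the same layout.  Vectors are normalized to unit
    length; mutual orthogonality is not enforced (a warning is logged when the
    largest off-diagonal overlap exceeds 1e-3).
    """
    if isinstance(matrix, str):
        matrix = read_matrix(matrix)
    m = np.atleast_2d(np.asarray(matrix, float))
    n3 = 3 * len(nodes)
    if m.shape[0] == n3:
        values = np.ones(m.shape[1])
        vectors = m
    elif m.shape[0] == n3 + 1:
        values = m[0]
        vectors = m[1:]
    else:
        raise DimensionError(
            f"imported mode vectors must have 3N = {n3} rows "
            f"(optionally 3N+1 with a leading eigenvalue row); got {m.shape[0]}")
    if not np.all(np.isfinite(vectors)):
        raise ValueError("imported mode matrix contains non-finite entries")
    norms = np.linalg.norm(vectors, axis=0)
    if np.any(norms == 0):
        raise ValueError("imported mode vectors must be nonzero")
    vectors = vectors / norms
    order = np.argsort(values, kind="stable")
    values, vectors = values[order], vectors[:, order]
    overlap = np.abs(vectors.T @ vectors)
    np.fill_diagonal(overlap, 0.0)
    if overlap.size and overlap.max() > 1e-3:
        logger.warning("imported modes are not mutually orthogonal "
                       "(max |u_k.u_l| = %.3g)", overlap.max())
    return ModeSet(eigenvalues=np.asarray(values, float),
                   eigenvectors=np.asarray(vectors, float),
                   n_zero_skipped=0, source="imported")


def mode_overlap(a: ModeSet, b: ModeSet) -> np.ndarray:
    """Matrix of absolute inner products |u_k(a) . u_l(b)| in [0, 1]."""
    if a.N != b.N:
        raise DimensionError(f"node counts differ: {a.N} vs {b.N}")
    return np.abs(a.eigenvectors.T @ b.eigenvectors)
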