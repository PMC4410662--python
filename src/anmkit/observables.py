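"""Fluctuation observables derived from a mode set.

Under the harmonic network ensemble the displacement covariance between nodes
i and j is the 3x3 block of the Hessian pseudo-inverse,

    <dR_i dR_j^T> = (k_B T / gamma) sum_k (1/lambda_k) u_k,i u_k,j^T ,

with the sum over nonzero modes.  Everything here follows from that one
expression: mean-square fluctuations (its diagonal traces), theoretical
B-factors (8 pi^2 / 3 times MSF), anisotropic displacement tensors (the
diagonal blocks), cross-correlation maps (normalized block traces), and
distance-fluctuation maps.  The prefactor k_B T / gamma is taken as 1, so all
outputs are in relative units; a least-squares scale against experimental
B-factors is provided for absolute comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DimensionError
from .modes import ModeSet
from .structure_io import Trajectory

__all__ = [
    "FluctuationProfile",
    "ADPSet",
    "square_fluctuations",
    "fit_experimental_b",
    "adp_tensors",
    "cross_correlation_map",
    "distance_fluctuation_map",
    "covariance_blocks",
    "animate_mode",
]

B_FROM_MSF = 8.0 * math.pi ** 2 / 3.0


@dataclass
class FluctuationProfile:
    """Per-node mean-square fluctuations and theoretical B-factors."""

    msf: np.ndarray  # (N,), relative units ~ A^2
    b_theory: np.ndarray  # (N,) = (8 pi^2/3) * msf
    n_modes_used: int
    scale: Optional[float] = None  # fitted s against experimental B
    pearson_r: Optional[float] = None


@dataclass
class ADPSet:
    """Per-node anisotropic displacement tensors (symmetric PSD 3x3)."""

    U: np.ndarray  # (N, 3, 3)

    def __len__(self):
        return self.U.shape[0]

    def traces(self) -> np.ndarray:
        return np.trace(self.U, axis1=1, axis2=2)


def _inv_lambda_weighted(m: ModeSet) -> np.ndarray:
    """(3N, m) eigenvector matrix scaled column-wise by 1/sqrt(lambda)."""
    if m.n_modes == 0:
        raise ValueError("empty mode set")
    return m.eigenvectors / np.sqrt(m.eigenvalues)


def covariance_blocks(m: ModeSet) -> np.ndarray:
    """(N, N, 3, 3) displacement covariance blocks sum_k u_k,i u_k,j^T / lambda_k."""
    w = _inv_lambda_weighted(m)  # (3N, m)
    n = m.N
    cov = w @ w.T  # (3N, 3N), equals pinv(H) when all modes are used
    return cov.reshape(n, 3, n, 3).transpose(0, 2, 1, 3)


def square_fluctuations(m: ModeSet) -> FluctuationProfile:
    """MSF_i = sum_k |u_k,i|^2 / lambda_k and B_theory = (8 pi^2/3) MSF."""
    w = _inv_lambda_weighted(m)
    msf = (w ** 2).reshape(m.N, 3, m.n_modes).sum(axis=(1, 2))
    return FluctuationProfile(msf=msf, b_theory=B_FROM_MSF * msf,
                              n_modes_used=m.n_modes)


def fit_experimental_b(profile: FluctuationProfile, b_exp,
                       with_offset: bool = False):
    """Least-squares scale of theoretical onto experimental B-factors.

    Returns ``(s, r)`` where s minimizes sum (s*b_theory - b_exp)^2 in closed
    form (s = <b_theory, b_exp>/<b_theory, b_theory>) and r is the Pearson
    correlation.  With ``with_offset`` the fit is affine (s, intercept) but the
    returned scale is still the slope.  The fitted values are also stored on
    the profile.
    """
    b_exp = np.asarray(b_exp, float)
    bt = profile.b_theory
    if b_exp.shape != bt.shape:
        raise DimensionError(
            f"experimental B length {b_exp.shape} != profile length {bt.shape}")
    if np.ptp(b_exp) == 0 or np.ptp(bt) == 0:
        raise ValueError("undefined correlation: zero-variance B-factors")
    if with_offset:
        a = np.vstack([bt, np.ones_like(bt)]).T
        s, _ = np.linalg.lstsq(a, b_exp, rcond=None)[0]
    else:
        s = float(bt @ b_exp) / float(bt @ bt)
    r = float(np.corrcoef(bt, b_exp)[0, 1])
    profile.scale = float(s)
    profile.pearson_r = r
    return float(s), r


def adp_tensors(m: ModeSet) -> ADPSet:
    """U_i = sum_k u_k,i u_k,i^T / lambda_k (trace(U_i) = MSF_i)."""
    w = _inv_lambda_weighted(m).reshape(m.N, 3, m.n_modes)
    u = np.einsum("iak,ibk->iab", w, w)
    return ADPSet(U=u)


def cross_correlation_map(m: ModeSet) -> np.ndarray:
    """C_ij = trace<dR_i dR_j^T> / sqrt(MSF_i MSF_j), in [-1, 1]."""
    w = _inv_lambda_weighted(m).reshape(m.N, 3, m.n_modes)
    cov = np.einsum("iak,jak->ij", w, w)
    msf = np.diag(cov).copy()
    if np.any(msf <= 0):
        bad = int(np.argmin(msf))
        raise ValueError(
            f"undefined correlation: node {bad} has zero mean-square fluctuation")
    denom = np.sqrt(np.outer(msf, msf))
    c = cov / denom
    np.fill_diagonal(c, 1.0)
    return c


def distance_fluctuation_map(m: ModeSet) -> np.ndarray:
    """D_ij = <|dR_i - dR_j|^2> = MSF_i + MSF_j - 2 trace<dR_i dR_j^T>."""
    w = _inv_lambda_weighted(m).reshape(m.N, 3, m.n_modes)
    cov = np.einsum("iak,jak->ij", w, w)
    msf = np.diag(cov)
    d = msf[:, None] + msf[None, :] - 2.0 * cov
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0) if d.min() > -1e-12 else d


def animate_mode(nodes, m: ModeSet, mode_index: int, amplitude: float = 2.0,
                 n_frames: int = 20) -> Trajectory:
    """Oscillate the structure along one mode over a full sine period.

    ``mode_index`` is 1-based (mode 1 = softest).  Frame f displaces each node
    by a * sin(2 pi f / n_frames) * u_i, with a chosen so the maximum per-node
    displacement over all frames equals ``amplitude`` (Angstrom).  Frame 0 is
    the input structure exactly.
    """
    if not (1 <= mode_index <= m.n_modes):
        raise ValueError(
            f"mode_index must be in 1..{m.n_modes}, got {mode_index}")
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    pos = nodes.positions()
    u = m.node_vectors(mode_index - 1)  # (N, 3), unit 3N-norm
    phases = np.sin(2.0 * np.pi * np.arange(n_frames) / n_frames)
    peak = np.max(np.abs(phases)) * np.max(np.linalg.norm(u, axis=1))
    a = amplitude / peak
    frames = [pos if s == 0.0 else pos + (a * s) * u for s in phases]
    labels = [node.atom_ref.label() for node in nodes]
    return Trajectory(labels=labels, frames=frames,
                      mode_index=mode_index, amplitude=amplitude)
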