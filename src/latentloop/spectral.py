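"""Non-normality diagnostics for the latent interaction matrix.

A matrix is normal when A A^T = A^T A, i.e. when it has an orthonormal
eigenbasis; then its eigenvalues tell the whole linear story.  Fitted
interaction matrices are typically far from normal, and the resulting
transient amplification is invisible to eigenvalues alone.  This module
provides the standard diagnostics:

* the normalized Henrici departure from normality,
  d_F(A) = sqrt(||A||_F^2 - sum_i |lambda_i|^2) / ||A||_F, in [0, 1];
* the resolvent norm ||(zI - A)^{-1}||_2 and pseudospectrum maps, with an
  alignment field that asks whether the most amplifiable input direction
  at each z lives in the coding or the residual subspace;
* an ordered real Schur decomposition A = Q T Q^T (negative-real
  eigenvalues first) whose strictly triangular energy quantifies hidden
  feedforward structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SchurDecomposition",
    "PseudospectrumGrid",
    "henrici_index",
    "feedforward_energy",
    "resolvent_norm",
    "pseudospectrum_map",
    "residual_alignment_map",
    "schur_modes",
    "project_schur",
]

#: Resolvent-norm contour levels used for reporting pseudospectra.
DEFAULT_CONTOUR_LEVELS = (5e-2, 4e-2, 3e-2, 2e-2, 1e-2, 5e-3)


@dataclass
class SchurDecomposition:
    """Real Schur form A = Q T Q^T with negative-real eigenvalues first.

    Q has orthonormal columns (the Schur modes); T is quasi-triangular with
    2x2 diagonal blocks for complex-conjugate pairs.
    """

    Q: np.ndarray
    T: np.ndarray
    eig_real: np.ndarray
    ordering: str = "negative-first"

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.eig_real < 0))


@dataclass
class PseudospectrumGrid:
    """Resolvent-norm (and optional alignment) fields over a complex lattice."""

    z_grid: np.ndarray  # complex (ny, nx)
    resolvent_norm: np.ndarray  # (ny, nx)
    alignment: np.ndarray | None = None  # (ny, nx) in [0, 1]
    contour_levels: tuple[float, ...] = DEFAULT_CONTOUR_LEVELS


def _square(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix")
    return A


def henrici_index(A: np.ndarray) -> float:
    """Normalized Henrici departure from normality, in [0, 1].

    0 for any normal matrix; 1 for any nonzero nilpotent matrix, where the
    spectrum carries no information and all linear dynamics arise from
    non-orthogonal eigenvector interactions.  Tiny negative round-off under
    the square root is clamped to 0.
    """
    A = _square(A)
    fro2 = float(np.sum(A * A))
    if fro2 == 0.0:
        raise ValueError("Henrici index is undefined for the zero matrix")
    eig2 = float(np.sum(np.abs(np.linalg.eigvals(A)) ** 2))
    return float(np.sqrt(max(fro2 - eig2, 0.0) / fro2))


def feedforward_energy(A: np.ndarray) -> float:
    """Strictly triangular energy of the (complex) Schur factor of A.

    Equals ||A||_F^2 - sum_i |lambda_i|^2 — the unnormalized squared
    Henrici departure — and measures the hidden feedforward coupling
    between Schur modes.
    """
    A = _square(A)
    T, _ = scipy.linalg.schur(A.astype(complex), output="complex")
    return float(np.sum(np.abs(np.triu(T, k=1)) ** 2))


def resolvent_norm(A: np.ndarray, z: complex, singular_tol: float = 1e-12) -> float:
    """Largest singular value of (zI - A)^{-1}, i.e. 1 / sigma_min(zI - A).

    Returns ``inf`` when z sits on the spectrum to within ``singular_tol``
    (relative to the matrix scale) — the resolvent is unbounded there.
    """
    A = _square(A)
    s = scipy.linalg.svdvals(z * np.eye(A.shape[0]) - A)
    smin = s[-1]
    scale = max(np.abs(z), np.linalg.norm(A, 2), 1.0)
    if smin <= singular_tol * scale:
        return float("inf")
    return float(1.0 / smin)


def _default_grid(A: np.ndarray, n: int, margin: float) -> np.ndarray:
    eigs = np.linalg.eigvals(A)
    radius = max(np.max(np.abs(eigs)), 1e-3) * margin
    x = np.linspace(-radius, radius, n)
    y = np.linspace(-radius, radius, n)
    return x[None, :] + 1j * y[:, None]


def pseudospectrum_map(
    A: np.ndarray,
    z_grid: np.ndarray | None = None,
    n_grid: int = 201,
    margin: float = 1.5,
    contour_levels: tuple[float, ...] = DEFAULT_CONTOUR_LEVELS,
) -> PseudospectrumGrid:
    """Resolvent norm over a complex lattice surrounding the spectrum.

    The default lattice is ``n_grid x n_grid`` over a box ``margin`` times
    the spectral radius.  Values at (near-)eigenvalue points are ``inf``.
    """
    A = _square(A)
    if z_grid is None:
        z_grid = _default_grid(A, n_grid, margin)
    z_grid = np.asarray(z_grid, dtype=complex)
    field = np.empty(z_grid.shape)
    for idx, z in np.ndenumerate(z_grid):
        field[idx] = resolvent_norm(A, z)
    return PseudospectrumGrid(
        z_grid=z_grid, resolvent_norm=field, contour_levels=tuple(contour_levels)
    )


def residual_alignment_map(
    A: np.ndarray,
    n_coding: int,
    z_grid: np.ndarray | None = None,
    n_grid: int = 101,
    margin: float = 1.5,
) -> PseudospectrumGrid:
    """Alignment of the most amplifiable direction with the residual subspace.

    For each z the top right-singular vector v1(z) of (zI - A)^{-1} is the
    unit input direction maximally amplified by the resolvent; the field is
    ||R v1(z)|| where R projects onto the residual latent coordinates
    (canonical coordinates n_coding+1 .. P).  0 means fully coding-aligned,
    1 fully residual-aligned.
    """
    A = _square(A)
    P = A.shape[0]
    if not 0 < n_coding < P:
        raise ValueError("need 0 < n_coding < P")
    if z_grid is None:
        z_grid = _default_grid(A, n_grid, margin)
    z_grid = np.asarray(z_grid, dtype=complex)
    res = np.empty(z_grid.shape)
    align = np.empty(z_grid.shape)
    I = np.eye(P)
    for idx, z in np.ndenumerate(z_grid):
        M = z * I - A
        # (zI-A)^{-1} = V diag(1/s) U^H, so its top right-singular vector is
        # the left-singular vector of (zI-A) belonging to sigma_min.
        u, s, _ = np.linalg.svd(M)
        v1 = u[:, -1]
        smin = s[-1]
        res[idx] = np.inf if smin < 1e-14 else 1.0 / smin
        align[idx] = np.linalg.norm(v1[n_coding:])
    return PseudospectrumGrid(z_grid=z_grid, resolvent_norm=res, alignment=align)


def schur_modes(A: np.ndarray) -> SchurDecomposition:
    """Ordered real Schur decomposition of the interaction matrix.

    Modes are reordered so that eigenvalues with negative real parts come
    first; complex-conjugate pairs appear as 2x2 blocks in T.  Within
    degenerate or complex-pair invariant subspaces the decomposition is not
    unique — only the reconstruction A = Q T Q^T, the orthogonality of Q
    and the negative/positive partition are contract-guaranteed.
    """
    A = _square(A)
    T, Q, _ = scipy.linalg.schur(A, output="real", sort="lhp")
    # LAPACK standardizes 2x2 blocks with equal diagonal entries, so the
    # diagonal of T carries Re(lambda) for every mode.
    eig_real = np.diag(T).copy()
    return SchurDecomposition(Q=Q, T=T, eig_real=eig_real)


def project_schur(m: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Schur-mode trajectories s(t) = Q^T m(t).

    ``m`` may be a single latent vector (P,) or a trajectory (T, P); columns
    of Q are the Schur modes, so the projection is an orthogonal change of
    coordinates and preserves norms.
    """
    m = np.asarray(m, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if m.shape[-1] != Q.shape[0]:
        raise ValueError("latent dimension mismatch with Schur basis")
    return m @ Q
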