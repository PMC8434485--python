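"""Elastic network models of coarse-grained protein dynamics.

Two classic models are provided in a model/results idiom:

* :class:`ANM` — anisotropic network model.  Every residue is a node at
  its Cα position; residue pairs within a cutoff (default 15 Å) are
  joined by harmonic springs of uniform force constant γ, giving a
  ``3N × 3N`` Hessian ``H``.  For a connected, non-collinear structure
  diagonalisation yields exactly six zero eigenvalues (rigid-body
  motions) and ``3N − 6`` internal modes.
* :class:`GNM` — Gaussian network model.  The isotropic counterpart: an
  ``N × N`` Kirchhoff (graph Laplacian) matrix built with a 10 Å cutoff,
  with one zero mode for a connected structure and ``N − 1`` internal
  modes whose shapes give per-residue fluctuation magnitudes.

``model.fit()`` returns a :class:`ModeResults` carrying the spectrum,
the pseudo-inverse covariance and fluctuation profiles.  Mode indices in
user-facing APIs are 1-based over the nonzero modes ("mode 1" is the
slowest internal motion).

Two analyses on top of the spectra:

* :func:`cumulative_overlap` — correspondence between two sets of k
  modes, ``Overlap(k) = sqrt((1/k) Σ_i Σ_j (u_i · v_j)²)``, with the
  matrix of absolute pairwise inner products (eigenvector sign is
  arbitrary, so only magnitudes are reported).
* :func:`reduce_to_subsystem` — vibrational subsystem analysis: the
  environment's degrees of freedom are eliminated by the Schur
  complement ``H_ss − H_se · H_ee⁺ · H_es``, yielding an effective
  stiffness for the subsystem (e.g. one protein of a complex) that
  retains the elastic coupling to its partner.

γ is kept at 1 (arbitrary units) by convention: the model never fixes
an absolute energy scale, so every derived quantity is reported in
γ-relative units and only ratios and shapes are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structio import CoarseStructure, ResidueSelection

logger = logging.getLogger("allodyn.enm")

__all__ = [
    "ElasticModel",
    "ANM",
    "GNM",
    "ModeResults",
    "OverlapResult",
    "build_model",
    "decompose",
    "mode_fluctuations",
    "cumulative_overlap",
    "reduce_to_subsystem",
    "rigid_motion_basis",
    "substructure",
]

DEFAULT_CUTOFF = {"ANM": 15.0, "GNM": 10.0}
DEFAULT_ZERO_TOL = 1e-8


class ElasticModel:
    """An undecomposed elastic network: stiffness matrix plus parameters.

    Use :class:`ANM` or :class:`GNM` directly; ``fit()`` diagonalises the
    stiffness matrix and returns a :class:`ModeResults`.
    """

    kind: str = ""

    def __init__(
        self,
        structure: CoarseStructure,
        cutoff: float | None = None,
        gamma: float = 1.0,
    ) -> None:
        if structure.n_residues < 2:
            raise ValueError("elastic models need at least 2 residues")
        self.structure = structure
        self.cutoff = float(cutoff) if cutoff is not None else DEFAULT_CUTOFF[self.kind]
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.gamma = float(gamma)
        self.matrix = self._build_matrix()

    # contact rule: Cα–Cα distance ≤ cutoff, boundary inclusive
    def _contacts(self) -> np.ndarray:
        d = squareform(pdist(self.structure.ca_coords))
        contact = d <= self.cutoff
        np.fill_diagonal(contact, False)
        return contact

    def _build_matrix(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_residues(self) -> int:
        return self.structure.n_residues

    def fit(self, zero_tol: float = DEFAULT_ZERO_TOL) -> "ModeResults":
        """Diagonalise the stiffness matrix.

        ``zero_tol`` separates rigid-body (zero) modes from internal
        modes, relative to the largest eigenvalue.
        """
        return decompose(self, zero_tol)


class ANM(ElasticModel):
    """Anisotropic network model: 3N×3N Hessian from Cα contacts."""

    kind = "ANM"

    def _build_matrix(self) -> np.ndarray:
        coords = self.structure.ca_coords
        n = len(coords)
        contact = self._contacts()
        H = np.zeros((3 * n, 3 * n))
        ii, jj = np.nonzero(np.triu(contact, 1))
        for i, j in zip(ii, jj):
            d = coords[j] - coords[i]
            r2 = d @ d
            block = -self.gamma * np.outer(d, d) / r2
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            H[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
        return H

    @classmethod
    def from_matrix(
        cls,
        structure: CoarseStructure,
        matrix: np.ndarray,
        cutoff: float,
        gamma: float = 1.0,
    ) -> "ANM":
        """Wrap a precomputed effective Hessian (used by subsystem reduction)."""
        model = cls.__new__(cls)
        model.structure = structure
        model.cutoff = cutoff
        model.gamma = gamma
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3 * structure.n_residues,) * 2:
            raise ValueError("Hessian shape does not match structure")
        model.matrix = 0.5 * (matrix + matrix.T)  # enforce exact symmetry
        return model


class GNM(ElasticModel):
    """Gaussian network model: N×N Kirchhoff matrix from Cα contacts."""

    kind = "GNM"

    def _build_matrix(self) -> np.ndarray:
        contact = self._contacts()
        K = -self.gamma * contact.astype(float)
        np.fill_diagonal(K, -K.sum(axis=1))
        return K


@dataclass
class ModeResults:
    """Eigendecomposition of an elastic model.

    ``eigenvalues`` ascending with column-matched ``eigenvectors``;
    ``n_zero`` counts the near-zero (rigid-body) modes.  Internal modes
    are addressed 1-based: mode 1 is the slowest nonzero mode.
    """

    model: ElasticModel
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    zero_tol: float

    @property
    def structure(self) -> CoarseStructure:
        return self.model.structure

    @property
    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]

    def modes(self, k: int | None = None) -> np.ndarray:
        """First ``k`` nonzero eigenvectors as columns (all if ``k`` None)."""
        sl = slice(self.n_zero, None if k is None else self.n_zero + k)
        return self.eigenvectors[:, sl]

    def covariance(self) -> np.ndarray:
        """Pseudo-inverse of the stiffness matrix over nonzero modes.

        In γ-relative units: the thermal prefactor (k_B T) is omitted.
        """
        w = self.nonzero_eigenvalues
        V = self.modes()
        return (V / w) @ V.T

    def msf(self) -> np.ndarray:
        """Per-residue mean-square fluctuation profile (γ-relative).

        GNM: diagonal of the Kirchhoff pseudo-inverse.  ANM: trace of
        each residue's 3×3 diagonal covariance block.
        """
        diag = np.einsum(
            "ij,ij->i", self.modes(), self.modes() / self.nonzero_eigenvalues
        )
        if self.model.kind == "ANM":
            return diag.reshape(-1, 3).sum(axis=1)
        return diag

    def mode_fluctuations(self, mode_index: int) -> np.ndarray:
        """Squared shape of one nonzero mode (1-based), summing to 1."""
        return mode_fluctuations(self, mode_index)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"{m.kind} mode decomposition",
            f"  residues:        {m.n_residues}",
            f"  cutoff:          {m.cutoff:g} A",
            f"  gamma:           {m.gamma:g}",
            f"  matrix size:     {m.matrix.shape[0]}",
            f"  zero modes:      {self.n_zero}",
            f"  nonzero modes:   {len(self.nonzero_eigenvalues)}",
        ]
        k = min(5, len(self.nonzero_eigenvalues))
        ev = ", ".join(f"{x:.5g}" for x in self.nonzero_eigenvalues[:k])
        lines.append(f"  slowest eigenvalues: {ev}")
        return "\n".join(lines)


def build_model(
    structure: CoarseStructure,
    kind: str = "ANM",
    cutoff: float | None = None,
    gamma: float = 1.0,
) -> ElasticModel:
    """Build an undecomposed ANM or GNM from a coarse structure."""
    kind = kind.upper()
    if kind == "ANM":
        return ANM(structure, cutoff, gamma)
    if kind == "GNM":
        return GNM(structure, cutoff, gamma)
    raise ValueError(f"unknown model kind {kind!r}")


def decompose(model: ElasticModel, zero_tol: float = DEFAULT_ZERO_TOL) -> ModeResults:
    """Eigendecompose an elastic model's stiffness matrix.

    Eigenvalues are returned ascending; ``n_zero`` counts eigenvalues
    below ``zero_tol`` times the largest one.  A connected non-collinear
    ANM has 6 zero modes, a connected GNM exactly 1; more indicates a
    disconnected or degenerate structure and triggers a warning.
    """
    if not np.all(np.isfinite(model.matrix)):
        raise FloatingPointError("stiffness matrix contains non-finite entries")
    w, V = np.linalg.eigh(model.matrix)
    lam_max = float(w[-1])
    if lam_max <= 0:
        raise FloatingPointError("stiffness matrix has no positive eigenvalues")
    n_zero = int(np.sum(w < zero_tol * lam_max))
    expected = 6 if model.kind == "ANM" else 1
    if n_zero > expected:
        logger.warning(
            "%s has %d near-zero modes (expected %d): structure is "
            "disconnected or degenerate at cutoff %g A",
            model.kind, n_zero, expected, model.cutoff,
        )
    return ModeResults(model, w, V, n_zero, zero_tol)


def mode_fluctuations(results: ModeResults, mode_index: int) -> np.ndarray:
    """Per-residue squared shape of a nonzero mode (1-based index).

    For a GNM this is the per-residue contribution of that mode to the
    mean-square fluctuation profile; its local minima mark hinge sites.
    The profile sums to 1 (unit eigenvector).
    """
    n_nonzero = len(results.nonzero_eigenvalues)
    if not 1 <= mode_index <= n_nonzero:
        raise IndexError(
            f"mode_index must be in [1, {n_nonzero}] over nonzero modes, "
            f"got {mode_index}"
        )
    u = results.eigenvectors[:, results.n_zero + mode_index - 1]
    if results.model.kind == "ANM":
        return (u.reshape(-1, 3) ** 2).sum(axis=1)
    return u**2


@dataclass
class OverlapResult:
    """Mode-set correspondence: |u_i·v_j| pairs and cumulative overlap."""

    pair_matrix: np.ndarray
    cumulative: np.ndarray

    @property
    def overlap(self) -> float:
        """Overlap(k) for the full k requested."""
        return float(self.cumulative[-1])


def _as_mode_matrix(modes, k: int | None) -> np.ndarray:
    if isinstance(modes, ModeResults):
        modes = modes.modes(k)
    modes = np.asarray(modes, dtype=float)
    if modes.ndim != 2:
        raise ValueError("mode set must be a 2-D (dim × k) array")
    if k is not None:
        modes = modes[:, :k]
    return modes


def cumulative_overlap(set_a, set_b, k: int | None = None) -> OverlapResult:
    """Correspondence between the first k modes of two states.

    ``Overlap(k) = sqrt((1/k) Σ_{i≤k} Σ_{j≤k} (u_i·v_j)²)`` for each k up
    to the number of modes supplied; identical (or fully re-mixed
    complete) mode sets give 1, mutually orthogonal sets 0.  Accepts
    :class:`ModeResults` (nonzero modes are taken) or plain column
    matrices of equal dimension and count.
    """
    A = _as_mode_matrix(set_a, k)
    B = _as_mode_matrix(set_b, k)
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"mode sets live in different spaces ({A.shape[0]} vs {B.shape[0]})"
        )
    if A.shape[1] != B.shape[1]:
        raise ValueError("mode sets must contain the same number of modes")
    pair = np.abs(A.T @ B)
    sq = pair**2
    kk = np.arange(1, pair.shape[0] + 1)
    cum = np.sqrt(np.cumsum(np.cumsum(sq, axis=0), axis=1).diagonal() / kk)
    return OverlapResult(pair, np.minimum(cum, 1.0 + 1e-12))


def rigid_motion_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N × 6) of rigid translations/rotations.

    Rotations are taken about the centroid; the QR factor is returned so
    the columns are orthonormal.  Useful for projecting covariance
    matrices onto the internal (non-rigid) subspace.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    c = coords - coords.mean(axis=0)
    Z = np.zeros((3 * n, 6))
    Z[0::3, 0] = Z[1::3, 1] = Z[2::3, 2] = 1.0
    x, y, z = c.T
    Z[1::3, 3], Z[2::3, 3] = -z, y
    Z[0::3, 4], Z[2::3, 4] = z, -x
    Z[0::3, 5], Z[1::3, 5] = -y, x
    Q, _ = np.linalg.qr(Z)
    return Q


def substructure(structure: CoarseStructure, indices: list[int]) -> CoarseStructure:
    """The coarse structure restricted to the given residue indices."""
    return CoarseStructure(
        [structure.residues[i] for i in indices],
        structure.ca_coords[indices],
        structure.cb_coords[indices],
    )


def reduce_to_subsystem(model: ANM, subsystem: ResidueSelection) -> ANM:
    """Effective ANM of a subsystem coupled to its environment.

    Environment degrees of freedom are eliminated by static condensation
    (Schur complement): ``H_eff = H_ss − H_se · H_ee⁺ · H_es``, with a
    pseudo-inverse over the environment block so that environment
    rigid-body null directions are tolerated.  The result is an ANM over
    the subsystem residues and can be decomposed like any other; its
    internal covariance equals the subsystem block of the full model's
    covariance restricted to the subsystem's internal subspace.
    """
    if model.kind != "ANM":
        raise ValueError("subsystem reduction is defined for ANM models")
    subsystem.validate(model.structure)
    sub = subsystem.sorted()
    n = model.n_residues
    env = [i for i in range(n) if i not in subsystem.indices]
    if not env:
        raise ValueError("subsystem must be a proper subset of the residues")
    sdof = np.ravel(3 * np.array(sub)[:, None] + np.arange(3))
    edof = np.ravel(3 * np.array(env)[:, None] + np.arange(3))
    H = model.matrix
    Hss = H[np.ix_(sdof, sdof)]
    Hse = H[np.ix_(sdof, edof)]
    Hee = H[np.ix_(edof, edof)]
    if np.allclose(Hse, 0.0):
        H_eff = Hss
    else:
        H_eff = Hss - Hse @ np.linalg.pinv(Hee, rcond=1e-10, hermitian=True) @ Hse.T
    return ANM.from_matrix(
        substructure(model.structure, sub), H_eff, model.cutoff, model.gamma
    )
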