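"""Synthetic coarse-grained structures and mode-sampled trajectories.

Test-bed systems with analytically known dynamics, standing in for
modelled complexes and long molecular-dynamics sampling:

* ``globule`` — a compact single-domain fold: a self-avoiding random
  walk confined to a sphere, Cα–Cα bond length 3.8 Å, hard-core
  separation 3.0 Å between non-successive residues.
* ``dumbbell`` — two compact domains joined by a near-extended linker;
  the only ≤ 10 Å contacts between the domains run through the linker,
  so the slowest network mode hinges there by construction.
* ``two-chain-complex`` — two chains whose contact interface holds a
  requested minimum number of inter-chain residue pairs within 6.5 Å.

Pseudo-Cβ atoms are placed 1.5 Å from each Cα along the local chain
normal; glycines (placed periodically) carry none, so downstream code
exercises the Cα fallback.

:func:`sample_enm_trajectory` draws Gaussian frames along the nonzero
modes of a decomposed anisotropic network model, ``c_k ~ N(0,
amplitude/λ_k)`` independently per frame, so the expected displacement
covariance is exactly ``amplitude`` times the Hessian pseudo-inverse.
Rigid-body modes are never sampled: the frames contain no net drift and
need no superposition before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .enm import ModeResults
from .structio import CoarseStructure, ResidueKey, Trajectory

logger = logging.getLogger("allodyn.synth")

__all__ = ["SynthSpec", "GenerationError", "make_structure", "sample_enm_trajectory"]

BOND_LENGTH = 3.8       # successive Calpha-Calpha distance, Angstrom
MIN_SEPARATION = 3.0    # hard core between non-successive residues
CB_LENGTH = 1.5         # pseudo-Cbeta offset from Calpha
DOMAIN_GAP = 10.5       # enforced inter-domain clearance (> GNM cutoff)
GLYCINE_PERIOD = 7      # every 7th residue is GLY (no Cbeta)


class GenerationError(RuntimeError):
    """A structure satisfying the spec could not be generated."""


@dataclass
class SynthSpec:
    """Recipe for one synthetic structure.

    ``linker_range`` is the half-open residue-index interval of the
    flexible linker (dumbbell only); ``interface_pairs`` the minimum
    number of inter-chain contacts within 6.5 Å (complex only).
    """

    n_residues: int
    topology: str = "globule"
    linker_range: Optional[tuple[int, int]] = None
    interface_pairs: int = 3
    seed: int = 0
    bond_length: float = BOND_LENGTH

    def __post_init__(self) -> None:
        if self.n_residues < 6:
            raise ValueError("need at least 6 residues")
        if self.topology not in ("globule", "dumbbell", "two-chain-complex"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "dumbbell":
            if self.linker_range is None:
                raise ValueError("dumbbell topology needs a linker_range")
            lo, hi = self.linker_range
            if not (0 < lo < hi < self.n_residues):
                raise ValueError("linker_range must be interior to [0, N)")
            if lo < 3 or self.n_residues - hi < 3:
                raise ValueError("domains flanking the linker need >= 3 residues")


def _confinement_radius(n: int) -> float:
    # loose random packing of 3 A hard cores; compact enough that the
    # 15 A ANM contact graph is rigid (exactly 6 zero modes)
    return 1.9 * n ** (1.0 / 3.0) + 3.0


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _grow_chain(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    radius: float,
    start: np.ndarray,
    bond: float,
    obstacles: np.ndarray | None,
    clearance: float = MIN_SEPARATION,
) -> np.ndarray | None:
    """Self-avoiding walk of ``n`` beads inside a sphere; None on failure."""
    start = np.asarray(start, dtype=float)
    if obstacles is not None and cdist(start[None], obstacles).min() < clearance:
        return None
    pos = [start]
    for _ in range(1, n):
        placed = False
        for _try in range(200):
            cand = pos[-1] + bond * _random_unit(rng)
            if np.linalg.norm(cand - center) > radius:
                continue
            if len(pos) > 1 and cdist(cand[None], np.array(pos[:-1])).min() < MIN_SEPARATION:
                continue
            if obstacles is not None and cdist(cand[None], obstacles).min() < clearance:
                continue
            pos.append(cand)
            placed = True
            break
        if not placed:
            return None
    return np.array(pos)


def _grow_with_restarts(rng, n, center, radius, bond, obstacles=None,
                        clearance=MIN_SEPARATION, restarts=1000, start=None):
    for _ in range(restarts):
        s = start if start is not None else center + rng.uniform(-1, 1, 3)
        coords = _grow_chain(rng, n, center, radius, s, bond, obstacles, clearance)
        if coords is not None:
            return coords
    raise GenerationError(
        f"could not grow a {n}-residue self-avoiding chain in radius {radius:.1f} A"
    )


def _pseudo_cb(ca: np.ndarray, is_gly: np.ndarray) -> np.ndarray:
    """Place Cβ 1.5 Å from Cα along the local normal of the chain."""
    n = len(ca)
    cb = np.full((n, 3), np.nan)
    for i in range(n):
        if is_gly[i]:
            continue
        a = ca[max(i - 1, 0)]
        b = ca[min(i + 1, n - 1)]
        v1 = ca[i] - a if i > 0 else b - ca[i]
        v2 = b - ca[i] if i < n - 1 else ca[i] - a
        normal = np.cross(v1, v2)
        norm = np.linalg.norm(normal)
        if norm < 1e-8:  # locally straight: any perpendicular direction
            ref = np.array([1.0, 0.0, 0.0])
            if abs(v1 @ ref) > 0.9 * np.linalg.norm(v1):
                ref = np.array([0.0, 1.0, 0.0])
            normal = np.cross(v1, ref)
            norm = np.linalg.norm(normal)
        cb[i] = ca[i] + CB_LENGTH * normal / norm
    return cb


def _residue_keys(n: int, chain: str, is_gly: np.ndarray, start: int = 1):
    return [
        ResidueKey(chain, start + i, "GLY" if is_gly[i] else "ALA")
        for i in range(n)
    ]


def _finish(ca_blocks, chains, spec: SynthSpec) -> CoarseStructure:
    residues: list[ResidueKey] = []
    ca_all = []
    cb_all = []
    offset = 0
    for ca, chain in zip(ca_blocks, chains):
        n = len(ca)
        is_gly = (np.arange(offset, offset + n) % GLYCINE_PERIOD) == 3
        residues.extend(_residue_keys(n, chain, is_gly))
        ca_all.append(ca)
        cb_all.append(_pseudo_cb(ca, is_gly))
        offset += n
    return CoarseStructure(residues, np.vstack(ca_all), np.vstack(cb_all))


def _make_globule(spec: SynthSpec, rng: np.random.Generator) -> CoarseStructure:
    radius = _confinement_radius(spec.n_residues)
    ca = _grow_with_restarts(rng, spec.n_residues, np.zeros(3), radius,
                             spec.bond_length)
    return _finish([ca], ["A"], spec)


def _make_dumbbell(spec: SynthSpec, rng: np.random.Generator) -> CoarseStructure:
    lo, hi = spec.linker_range
    n_a, n_link, n_b = lo, hi - lo, spec.n_residues - hi
    r_a = _confinement_radius(n_a)
    r_b = _confinement_radius(n_b)
    bond = spec.bond_length
    for _attempt in range(200):
        ca_a = _grow_with_restarts(rng, n_a, np.zeros(3), r_a, bond)
        anchor = ca_a[-1]
        axis = anchor - ca_a.mean(axis=0)
        if np.linalg.norm(axis) < 1e-6:
            axis = np.array([1.0, 0.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        # near-extended linker marching radially out of domain A;
        # steps are renormalised so successive distances stay exactly bond
        link = []
        ok = True
        prev = anchor
        for k in range(n_link):
            jitter = 0.35 * rng.standard_normal(3)
            jitter -= (jitter @ axis) * axis
            target = anchor + bond * (k + 1) * axis + jitter
            step = target - prev
            cand = prev + bond * step / np.linalg.norm(step)
            if cdist(cand[None], ca_a[:-1]).min() < MIN_SEPARATION:
                ok = False
                break
            link.append(cand)
            prev = cand
        if not ok:
            continue
        link = np.array(link)
        start_b = link[-1] + bond * axis
        center_b = link[-1] + (bond + 0.8 * r_b) * axis
        obstacles = np.vstack([ca_a, link])
        try:
            ca_b = _grow_with_restarts(
                rng, n_b, center_b, r_b, bond, obstacles=ca_a,
                clearance=DOMAIN_GAP, restarts=50, start=start_b,
            )
        except GenerationError:
            continue
        # linker clearance against domain B interior (hard core only)
        if cdist(link, ca_b).min() < MIN_SEPARATION:
            continue
        if cdist(ca_a, ca_b).min() <= DOMAIN_GAP:
            continue
        return _finish([np.vstack([ca_a, link, ca_b])], ["A"], spec)
    raise GenerationError("could not assemble a dumbbell satisfying the spec")


def _make_complex(spec: SynthSpec, rng: np.random.Generator) -> CoarseStructure:
    n_a = spec.n_residues // 2
    n_b = spec.n_residues - n_a
    r_a = _confinement_radius(n_a)
    r_b = _confinement_radius(n_b)
    bond = spec.bond_length
    ca_a = _grow_with_restarts(rng, n_a, np.zeros(3), r_a, bond)
    axis = np.array([1.0, 0.0, 0.0])
    for approach in np.arange(1.0, -6.0, -0.5):
        center_b = (r_a + r_b + approach) * axis
        for _ in range(60):
            try:
                ca_b = _grow_with_restarts(
                    rng, n_b, center_b, r_b, bond, obstacles=ca_a, restarts=50
                )
            except GenerationError:
                break
            n_contacts = int((cdist(ca_a, ca_b) <= 6.5).sum())
            if n_contacts >= spec.interface_pairs:
                return _finish([ca_a, ca_b], ["A", "B"], spec)
    raise GenerationError(
        f"could not build an interface with >= {spec.interface_pairs} contacts"
    )


def make_structure(spec: SynthSpec) -> CoarseStructure:
    """Generate a synthetic coarse structure from a spec.

    Fully reproducible for a fixed ``spec.seed``.  Raises
    :class:`GenerationError` if the geometric constraints cannot be met
    within bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.topology == "globule":
        return _make_globule(spec, rng)
    if spec.topology == "dumbbell":
        return _make_dumbbell(spec, rng)
    return _make_complex(spec, rng)


def sample_enm_trajectory(
    modes: ModeResults,
    n_frames: int,
    amplitude: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Draw Gaussian frames along the nonzero modes of a decomposed ANM.

    Each frame is ``reference + Σ_k c_k u_k`` with independent
    ``c_k ~ N(0, amplitude/λ_k)``, so the expected 3N×3N displacement
    covariance equals ``amplitude · H⁺``.  Zero modes are excluded:
    frames carry no rigid-body drift and the trajectory is returned
    flagged aligned.
    """
    if not isinstance(modes, ModeResults):
        raise TypeError("model must be decomposed first (call .fit())")
    if modes.model.kind != "ANM":
        raise ValueError("trajectory sampling requires an ANM mode set")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    ref = modes.structure.ca_coords
    n = modes.structure.n_residues
    w = modes.nonzero_eigenvalues
    V = modes.modes()
    coeffs = rng.standard_normal((n_frames, len(w))) * np.sqrt(amplitude / w)
    disp = coeffs @ V.T
    frames = ref[None, :, :] + disp.reshape(n_frames, n, 3)
    return Trajectory(frames, modes.structure, aligned=True)
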