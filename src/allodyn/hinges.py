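"""Hinge-site prediction from Gaussian-network mode shapes.

Hinges are the pivot points between cooperatively moving domains.  In a
GNM mode the residues of each rigid block move with a common sign and
large amplitude, while the pivot residues sit near the node of the
eigenvector — so hinges are read off as local minima of the
per-residue squared mode shape.  A residue is called a hinge when its
profile value is the strict minimum of a ``±window`` neighbourhood
within its own chain and lies below ``floor`` times the profile
maximum (deep minima only; chain termini are never hinges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .enm import ModeResults, mode_fluctuations
from .structio import CoarseStructure, ResidueSelection

logger = logging.getLogger("allodyn.hinges")

__all__ = ["HingeSet", "find_hinges", "find_mode_hinges"]

DEFAULT_WINDOW = 3
DEFAULT_FLOOR = 0.2


@dataclass
class HingeSet:
    """Hinge residues found in one mode profile."""

    mode_index: int
    indices: list[int]
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.indices = sorted(int(i) for i in self.indices)

    def selection(self, label: str = "hinge") -> ResidueSelection:
        if not self.indices:
            raise ValueError("no hinges found; cannot build a selection")
        return ResidueSelection(frozenset(self.indices), label)

    def labels(self, structure: CoarseStructure) -> list[str]:
        return [structure.labels[i] for i in self.indices]


def _chain_ranges(structure: CoarseStructure | None, n: int):
    if structure is None:
        return [(0, n)]
    return [(s.start, s.stop) for s in structure.chain_slices().values()]


def find_hinges(
    profile: np.ndarray,
    window: int = DEFAULT_WINDOW,
    floor: float = DEFAULT_FLOOR,
    structure: CoarseStructure | None = None,
    mode_index: int = 1,
) -> HingeSet:
    """Local-minimum hinge detection on a squared mode-shape profile.

    Residue ``i`` is a hinge iff ``profile[i]`` is the strict minimum of
    ``profile[i-window : i+window+1]`` (windows never cross chain
    boundaries) and ``profile[i] <= floor * max(profile)``.  The first
    and last ``window`` residues of each chain are excluded.  A flat
    profile yields an empty set with a warning.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n < 2 * window + 1:
        raise ValueError(f"profile of length {n} too short for window {window}")
    if np.ptp(profile) == 0.0:
        logger.warning("flat mode profile: no hinges detectable")
        return HingeSet(mode_index, [], profile)
    ceiling = floor * profile.max()
    hinges: list[int] = []
    for lo, hi in _chain_ranges(structure, n):
        for i in range(lo + window, hi - window):
            seg = profile[i - window: i + window + 1]
            if profile[i] <= ceiling and np.sum(seg == seg.min()) == 1 \
                    and profile[i] == seg.min():
                hinges.append(i)
    return HingeSet(mode_index, hinges, profile)


def find_mode_hinges(
    modes: ModeResults,
    mode_index: int = 1,
    window: int = DEFAULT_WINDOW,
    floor: float = DEFAULT_FLOOR,
) -> HingeSet:
    """Hinges of one nonzero GNM mode (1-based index)."""
    if modes.model.kind != "GNM":
        raise ValueError("hinge prediction uses GNM mode profiles")
    profile = mode_fluctuations(modes, mode_index)
    return find_hinges(profile, window, floor, modes.structure, mode_index)
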