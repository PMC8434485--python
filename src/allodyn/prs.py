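"""Perturbation response scanning (PRS) on an anisotropic network model.

Linear response: a force applied to the network produces displacements
``ΔR = H⁻¹ F`` (Hooke's law, with the pseudo-inverse over internal
modes standing in for ``H⁻¹``).  PRS probes the network one residue at
a time: a force of fixed magnitude and random orientation is applied at
effector residue ``i`` and the mean squared displacement of every
sensor residue ``k`` is recorded.  Averaged over isotropically
distributed unit forces this has the closed form

    ``S_PRS[i, k] = (1/3) · ‖C_ki‖²_F``

where ``C_ki`` is the 3×3 block of the covariance ``C = H⁺`` coupling
residues ``k`` and ``i`` — the deterministic infinite-sample limit of
the random-force average.  Row-normalising by the diagonal (response to
unit *deformation* at the perturbed site) gives ``S̄_PRS`` with unit
diagonal.  The effectiveness profile of residue ``i`` is the mean of
its normalised row over all other residues (how strongly perturbing
``i`` moves the rest of the network); the sensitivity profile of ``k``
is the corresponding column mean (how strongly ``k`` responds to
perturbations elsewhere).  Self-terms are excluded from both: the
normalised diagonal is identically 1 and carries no signal.

Because γ only scales ``C`` globally, the normalised matrix, the
profiles' ranks, and everything downstream are γ-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import ModeResults
from .structio import CoarseStructure, ResidueSelection

__all__ = ["PRSResult", "PerturbationResponseScan", "prs_matrix", "perturb_site",
           "rank_sites"]


@dataclass
class PRSResult:
    """Raw and row-normalised PRS matrices with effector/sensor profiles."""

    raw: np.ndarray
    normalized: np.ndarray
    effectiveness: np.ndarray
    sensitivity: np.ndarray
    structure: CoarseStructure

    @property
    def n_residues(self) -> int:
        return self.raw.shape[0]

    def perturb_site(self, effector: int) -> np.ndarray:
        return perturb_site(self, effector)

    def rank_sites(self, selection: ResidueSelection) -> pd.DataFrame:
        return rank_sites(self, selection)

    def summary(self) -> str:
        eff_top = np.argsort(self.effectiveness)[::-1][:5]
        sen_top = np.argsort(self.sensitivity)[::-1][:5]
        labels = self.structure.labels
        return "\n".join([
            "Perturbation response scan",
            f"  residues:       {self.n_residues}",
            "  top effectors:  " + ", ".join(labels[i] for i in eff_top),
            "  top sensors:    " + ", ".join(labels[i] for i in sen_top),
        ])


class PerturbationResponseScan:
    """PRS of a decomposed ANM; ``fit()`` returns a :class:`PRSResult`."""

    def __init__(self, modes: ModeResults) -> None:
        if not isinstance(modes, ModeResults):
            raise TypeError("PRS needs a decomposed model (call .fit() first)")
        if modes.model.kind != "ANM":
            raise ValueError("PRS is defined on an ANM Hessian")
        self.modes = modes

    def fit(self) -> PRSResult:
        C = self.modes.covariance()
        n = self.modes.structure.n_residues
        blocks = C.reshape(n, 3, n, 3)
        # raw[i, k]: effector i (row), sensor k; (1/3)|C_ki|_F^2
        raw = np.einsum("kaib,kaib->ik", blocks, blocks) / 3.0
        diag = np.diag(raw).copy()
        if np.any(diag <= 0):
            raise FloatingPointError("PRS diagonal must be positive")
        normalized = raw / diag[:, None]
        off = ~np.eye(n, dtype=bool)
        effectiveness = np.where(off, normalized, 0.0).sum(axis=1) / (n - 1)
        sensitivity = np.where(off, normalized, 0.0).sum(axis=0) / (n - 1)
        return PRSResult(raw, normalized, effectiveness, sensitivity,
                         self.modes.structure)


def prs_matrix(modes: ModeResults) -> PRSResult:
    """Closed-form PRS matrix of a decomposed ANM."""
    return PerturbationResponseScan(modes).fit()


def perturb_site(result: PRSResult, effector: int) -> np.ndarray:
    """Normalised response profile of one effector (self-response = 1)."""
    if not 0 <= effector < result.n_residues:
        raise IndexError(f"effector index {effector} out of range")
    return result.normalized[effector].copy()


def rank_sites(result: PRSResult, selection: ResidueSelection) -> pd.DataFrame:
    """Effectiveness/sensitivity of selected sites with dense global ranks.

    Ranks are computed over *all* residues (rank 1 = largest, ties share
    a rank) and the table is restricted to the selection, so a site's
    rank reflects its standing in the whole structure.  Values agreeing
    to 9 significant digits are treated as tied, so exact symmetries are
    not split by floating-point noise.
    """
    selection.validate(result.structure)
    eff = pd.Series(result.effectiveness)
    sen = pd.Series(result.sensitivity)

    def dense_rank(series: pd.Series) -> pd.Series:
        scaled = np.round(series / series.abs().max(), 9)
        return scaled.rank(ascending=False, method="dense").astype(int)

    eff_rank = dense_rank(eff)
    sen_rank = dense_rank(sen)
    rows = selection.sorted()
    return pd.DataFrame({
        "residue": [result.structure.labels[i] for i in rows],
        "effectiveness": eff[rows].to_numpy(),
        "eff_rank": eff_rank[rows].to_numpy(),
        "sensitivity": sen[rows].to_numpy(),
        "sens_rank": sen_rank[rows].to_numpy(),
    })
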